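# Methods

`mrcvasc` grows paired arterial and venous tree networks confined to a
closed triangulated surface, mimicking the superficial cortical (pial)
vasculature of the cerebrum at the mesoscale: the vessels that run on the
brain surface between the millimetre-scale major arteries/veins and the
penetrating microvasculature.  This note documents the model, its
assumptions, the synthetic study conditions, and the numerical choices.

## The growth substrate

**Surface.** The substrate is a closed, orientable triangle mesh Γ with
positions in mm.  Real hemispheres come from imaging; the built-in generator
stands in for them with a star-shaped radial surface: an ellipsoid base
(default semi-axes 34 × 27 × 24 mm, total area ≈ 10⁴ mm²), multiplied by a
smooth medial groove factor `1 − g·exp(−(u_x/w)²)` (defaults g = 0.08,
w = 0.18) so the shape reads as a left/right hemisphere pair, plus an
optional radial fold displacement
`A·sin²θ·sin(kθ)·cos(kφ)` (amplitude A in mm, integer wavenumber k,
default 8) emulating gyri and sulci.  A crease-free star-shaped surface was
chosen over two mirrored half-ellipsoids with a flat medial wall because it
keeps the signed distance field and its gradient well-behaved everywhere;
the folded/smooth contract (fold amplitude > 0 strictly increases area at
fixed resolution) is preserved.  What the generator does **not** emulate:
realistic sulcal geometry (folds are periodic, real sulci are not), the
brainstem/cerebellum cutout, inter-hemispheric asymmetry, and imaging noise.
Passing tests on these fixtures therefore demonstrate the algorithmic
contracts and scaling behaviour, not anatomical fidelity.

**Signed distance field (SDF).** ψ(x) is the signed Euclidean distance to Γ
(negative inside — the mesh encloses a volume), sampled on a uniform
Cartesian grid of spacing h (default 0.5 mm, a typical image resolution)
with a margin ≥ ψ_th + 2h.  Magnitudes are exact point-to-triangle
distances minimised over a KD-tree preselection (16 nearest triangle
centroids plus the triangles incident to the nearest vertex); the sign comes
from ray-crossing parity along grid lines, exact for closed meshes (a fixed
per-vertex 10⁻⁷ perturbation of the projected coordinates removes
edge/vertex ray degeneracies).  Values and gradients anywhere are trilinear;
points are projected onto Γ by damped Newton steps x ← x − ψ∇ψ/|∇ψ| with
tolerance 0.05·h and a cap of 10 iterations (non-converged points are left
at the best iterate and counted).

**Subregions.** The surface is partitioned into N_d edge-connected patches
("vascular subregions", the supply units that collect matched arterial and
venous terminals) by seeded region growing: seed triangles drawn uniformly
at random, then multi-source hop-count expansion over triangle adjacency
with ties broken by lower triangle index (deterministic per seed).  Nested
second-level partitions run the same routine inside each first-level patch.
Areas |D_i| are sums of member triangle areas, so Σ|D_i| = |D_total| holds
to machine precision by construction.

**Roots.** Each root edge runs from a start point just off the surface to
an end point on Γ.  The synthetic generator samples end points area-
uniformly (optionally with a minimum mutual separation, default 12 mm for
the stock scenarios, which keeps the handful of roots spread out the way
macroscale terminal branches are), draws radii from a clipped normal
(default 1.0 ± 0.2 mm), and offsets starts 0.8 mm outward along ∇ψ so whole
root edges sit inside the growth shell for the default ψ_th = 1 mm.  Root
tables can also be loaded from CSV; off-surface ends are extended straight
to Γ and extensions longer than a configurable drop threshold are discarded
(vessels that do not supply this surface).

## Growth model

**Edges and radii.** A network is a forest of rooted trees; every edge is a
polyline of subpoints with a radius.  Radii follow from two assumptions:
(i) the total inflow splits across subregions in proportion to area, each
terminal in D_i carrying an equal share |D_i|/N_term(D_i) ("coverage" S);
(ii) wall shear stress τ = 4μQ/(πa³) is equal on every edge of a tree.
Together these give the cube-root law a_n = (S_n/S_root)^{1/3}·a_root, where
S_n sums the coverage of the terminals downstream of edge n.  The nominal
flow Q_total and viscosity μ cancel: radii depend only on topology,
subregion areas and the root radius.  The root edge keeps a_root exactly,
including the upstream fragment after the root edge is split.

**One insertion step.** A candidate terminal is drawn by: uniform subregion
→ area-weighted triangle within it → uniform barycentric point (this fixed
RNG consumption order is part of the reproducibility contract).  The
candidate is accepted only if (1) it lies within l_th (default 20 mm) of
the closest existing edge of the same vessel type — distance to the
half-arc-length midpoint of the polyline, searched over *all* trees of that
type so multiple roots compete for territory — and (2) its subregion is
below the permitted terminal count; otherwise it is redrawn (cap 10⁴
attempts).  When the remaining budget equals the number of subregions still
below their minimum, sampling restricts to those subregions, which
guarantees coverage.

The closest edge is split at a branching vertex chosen among four candidate
patterns: the three side midpoints of the triangle (closest-edge endpoints
v_n1, v_n2 and new terminal) and its centroid.  Each pattern's three
edges are built as straight chords, subdivided to the SDF grid spacing,
confined (subpoints with |ψ| > ψ_th projected onto Γ; a branching vertex
outside the shell is itself projected first), and scored by the
intravascular-volume proxy E′ = Σ L·a² with tentative cube-root radii that
count the new terminal in its subregion's quota.  The minimal-E′ pattern is
inserted (ties go to the lowest pattern index).  Only these three edges
differ between patterns, so the global volume difference equals the E′
difference.  A dense grid search over branch positions (flat-domain
diagnostic, 50 random triads) puts the chosen pattern's E′ within ~10–25 %
of the continuous optimum at the median.

Coverage sizes are maintained incrementally: accepting a terminal in D_i
updates S along the new terminal's ancestor path and along the ancestor
paths of every other terminal in D_i (whose equal shares shrank).  A
from-scratch recomputation is the test oracle and agrees to ~10⁻¹³ relative.

**Multilevel orchestration.** Veins grow first at the coarse level (LV1),
then arteries on the same subregions.  Every LV1 terminal seeds a root for
an independent fine-level (LV2) growth confined to its subregion, with the
LV2 root edge inheriting the LV1 terminal's geometry and radius.  Root tips
count as terminals toward budgets and minimum quotas; a subregion that
inherits more tips than its permitted maximum simply receives no further
terminals, and when clustered tips make the exact preset count unable to
cover all minima the budget is raised by the minimal amount needed (the
at-least-one-terminal-per-subregion guarantee takes precedence; the excess
is well under 1 % of terminals in practice).

## Default parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| α | 2 | terminal arteries : veins |
| ψ_th | 1 mm | half-width of the growth shell Ω around Γ |
| l_th | 20 mm | max distance of a candidate to the closest edge |
| LV1 artery / vein per subregion | 1–6 / exactly 1 | permitted terminal counts |
| LV2 artery / vein per subregion | exactly 2 / exactly 1 | permitted terminal counts |
| N_d(total) | N_term/(α+1) | one subregion per terminal vein |
| h | 0.5 mm | SDF grid spacing, also edge subdivision length |
| projection tolerance | 0.05·h | Newton projection stop |

## Morphometry

Arteries and veins are always analysed separately, after connecting each
LV2 tree onto the LV1 terminal that seeded it (the duplicated inherited
root edge replaces that terminal, so merged networks stay trees).

**Diameter-defined Strahler.** Terminal edges are pinned at order 1 (the
model has no capillaries, which would be order 0).  A classic Strahler pass
seeds the orders; then per-order diameter means/SDs define interval
boundaries halfway between (mean+SD) of order n and (mean−SD) of order n+1,
and any non-terminal edge whose diameter falls in a neighbouring order's
interval moves there; iterate to a fixed point with a cap of 30 sweeps.
On generated forests roughly half the trees oscillate between two nearly
identical states and stop at the cap; the returned state carries a
`converged` flag.  Connected same-order edges merge into *elements*; an
element's diameter is the length-weighted mean of its member edges and its
length their sum.

**Horton regressions.** Ordinary least squares of log₁₀(mean element
diameter), log₁₀(mean element length) and log₁₀(element count) on the order
n, fitted over n ∈ [1, 5], and over n ≥ 6 with the last (sparsest) order
dropped.  Whether the low fit also drops the last order is exposed as an
option (`exclude_last`); the default drops it only for the high range.

**Scale sensitivity (a known limitation).** At the desk scale used here
(2.4×10⁴ terminals) merged arterial forests span ~8 diameter-defined orders
rather than ~14, so adjacent low orders overlap more in diameter and the
reassignment merges them more aggressively: b(d) ≈ 0.11 and
b(N_elem) ≈ −0.34 on the n ∈ [1, 5] fits, versus ≈ 0.17 / −0.53 for classic
(non-diameter-defined) Strahler on the same forests — whose N_elem relation
is almost perfectly log-linear (R² ≈ 1.00).  The diameter-defined slopes are
therefore not scale-free, while the classic ones are much closer to it.

**Paths and territories.** Per terminal: Euclidean distance L from the root
start vertex, path length C (sum of edge lengths), tortuosity C/L − 1
(lognormal fit by closed-form MLE on log values, zeros floored at 10⁻⁶),
bifurcation count, and an OLS line of C on L.  Vascular territories assign
each LV1 subregion to the arterial root label with the most terminal ends
in it (ties: larger summed coverage S, then lexicographic label — recorded
per subregion in the output); label areas are sums of subregion areas, and
ratios divide by the same-side PCA-family label.

## Problem sizes used by the tests and the acceptance script

The stock desk-scale scenario uses 2.4×10⁴ total terminals, 400 LV1
subregions (~20 LV2 subregions each), 12+12 roots and h = 0.5 mm on the
~10⁴ mm² smooth surface; the acceptance script averages the n ∈ [1, 5]
Horton slopes over three seeds of this scenario.  The folded-vs-smooth
comparison runs five matched seed pairs at 6×10³ terminals / 100 LV1
subregions / h = 0.75 mm with fold amplitude 2 mm, and the N_u sweep runs
N_u ∈ {100, 200, 400} at 1.2×10⁴ terminals — sizes chosen so the full suite
completes in minutes while the contrasts of interest remain well resolved.

## Known limitations

- Trees only: no anastomoses, and arterial growth ignores the already-grown
  venous geometry (crossings are allowed).
- The per-level inheritance is strictly terminal-to-root; midstream
  branching from a higher level is not modelled.
- Blood flow enters only through the equal-shear sizing rule; no pressure
  or flow field is solved.
- The diameter-defined Strahler slopes depend on total network depth (see
  above); comparisons across scales should use matched terminal counts.
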