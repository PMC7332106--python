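"""Geometry-prioritized CCO growth and the multilevel orchestration.

One terminal is added per step.  A candidate terminal position is drawn on
the surface (subregion, then triangle, then barycentric point), accepted only
if (1) it lies within l_th of the closest existing edge of the same vessel
type (distance to the polyline half-arc-length midpoint) and (2) its
subregion is still below the permitted terminal count.  The closest edge is
split at a branching vertex chosen among four candidate patterns — the three
side midpoints of the triangle (closest-edge endpoints + new terminal) and
its centroid — scoring each pattern by the volume proxy
E' = Σ L·a² over the three modified edges (with tentative cube-root radii)
and keeping the minimum.  All candidate edges are subdivided and confined to
the shell |ψ| ≤ ψ_th, with out-of-shell subpoints projected onto Γ.

The multilevel driver grows veins first, then arteries, on the first-level
(LV1) subregions; every LV1 terminal then seeds a root for an independent
second-level (LV2) growth confined to its subregion.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .partition import SubregionPartition
from .roots import RootEdge
from .sdf import DistanceField
from .surface import TriSurface, sample_barycentric
from .vessels import VesselNetwork, polyline_midpoint

__all__ = [
    "GrowthConfig",
    "GrowthError",
    "CandidateBifurcation",
    "VoxelEdgeIndex",
    "find_closest_edge",
    "enumerate_bifurcations",
    "relocate_to_domain",
    "grow_level",
    "run_mrc",
    "VesselForest",
]


class GrowthError(RuntimeError):
    """Growth could not proceed (infeasible quotas or exhausted rejections)."""


@dataclass
class GrowthConfig:
    """Growth parameters for a two-level run.

    Defaults mirror the reference parameterization: artery:vein ratio α = 2,
    shell half-width ψ_th = 1 mm, candidate distance threshold l_th = 20 mm,
    permitted terminals per LV1 subregion 1–6 (artery) / exactly 1 (vein) and
    per LV2 subregion exactly 2 (artery) / exactly 1 (vein).  Either
    ``n_terminals_total`` or ``terminal_density`` (num/mm², applied to the
    surface area) fixes the overall scale.
    """

    n_terminals_total: int | None = None
    terminal_density: float | None = None  # num/mm^2 alternative
    alpha: float = 2.0
    n_lv1_subregions: int = 400
    lv1_artery_limits: tuple[int, int] = (1, 6)
    lv1_vein_limits: tuple[int, int] = (1, 1)
    lv2_artery_limits: tuple[int, int] = (2, 2)
    lv2_vein_limits: tuple[int, int] = (1, 1)
    psi_th: float = 1.0
    l_th: float = 20.0
    seed: int = 0
    max_rejections: int = 10_000
    subdivision_length: float | None = None  # default: SDF grid spacing h

    def __post_init__(self) -> None:
        for name in (
            "lv1_artery_limits",
            "lv1_vein_limits",
            "lv2_artery_limits",
            "lv2_vein_limits",
        ):
            setattr(self, name, tuple(getattr(self, name)))
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.psi_th <= 0 or self.l_th <= 0:
            raise ValueError("psi_th and l_th must be positive")
        if self.n_terminals_total is None and self.terminal_density is None:
            raise ValueError("set n_terminals_total or terminal_density")

    def resolve_total(self, total_area: float) -> int:
        if self.n_terminals_total is not None:
            return int(self.n_terminals_total)
        return int(round(self.terminal_density * total_area))

    def n_subregions_total(self, total_area: float) -> int:
        # total subregions = number of terminal veins = N_term/(α+1)
        return int(round(self.resolve_total(total_area) / (self.alpha + 1.0)))

    def n_lv2_per_lv1(self, total_area: float) -> int:
        return max(1, round(self.n_subregions_total(total_area) / self.n_lv1_subregions))


@dataclass
class CandidateBifurcation:
    """One scored branch pattern (P1..P4)."""

    pattern: int  # 1..4
    branch_vertex: np.ndarray
    sub_up: np.ndarray  # relocated subpoints v_n1 → v_{M+2}
    sub_down: np.ndarray  # v_{M+2} → v_n2
    sub_term: np.ndarray  # v_{M+2} → v_{M+1}
    lengths: tuple[float, float, float]
    radii: tuple[float, float, float]
    score: float  # E′


class VoxelEdgeIndex:
    """Uniform-grid nearest-edge-midpoint index with ring expansion.

    Exhaustive numpy search below ``exhaustive_below`` edges; results are
    identical to an exhaustive scan, with ties broken by ascending
    (tree id, edge id).
    """

    def __init__(self, bin_size: float, exhaustive_below: int = 64) -> None:
        self.bin = float(bin_size)
        self.exhaustive_below = exhaustive_below
        self.cells: dict[tuple[int, int, int], list[int]] = {}
        self.n = 0

    def _cell(self, p: np.ndarray) -> tuple[int, int, int]:
        return (
            int(np.floor(p[0] / self.bin)),
            int(np.floor(p[1] / self.bin)),
            int(np.floor(p[2] / self.bin)),
        )

    def insert(self, eid: int, midpoint: np.ndarray) -> None:
        self.cells.setdefault(self._cell(midpoint), []).append(eid)
        self.n += 1

    def relocate(self, eid: int, old: np.ndarray, new: np.ndarray) -> None:
        co, cn = self._cell(old), self._cell(new)
        if co == cn:
            return
        self.cells[co].remove(eid)
        if not self.cells[co]:
            del self.cells[co]
        self.cells.setdefault(cn, []).append(eid)

    def query(self, point: np.ndarray, network: VesselNetwork) -> tuple[int, float]:
        """(edge id, distance) of the nearest midpoint; exact."""
        if network.n_edges == 0:
            raise GrowthError("closest-edge query on an empty forest")
        if network.n_edges < self.exhaustive_below:
            return _exhaustive_closest(network, point)
        cx, cy, cz = self._cell(point)
        best_eid, best_d = -1, np.inf
        r = 0
        while True:
            cand: list[int] = []
            for ix in range(cx - r, cx + r + 1):
                for iy in range(cy - r, cy + r + 1):
                    for iz in range(cz - r, cz + r + 1):
                        if max(abs(ix - cx), abs(iy - cy), abs(iz - cz)) != r:
                            continue
                        cand.extend(self.cells.get((ix, iy, iz), ()))
            if cand:
                mids = network.midpoints()[cand]
                d = np.linalg.norm(mids - point, axis=1)
                for j in np.argsort(d, kind="stable"):
                    eid, dj = cand[j], d[j]
                    if dj < best_d or (
                        dj == best_d
                        and (network.tree_id[eid], eid)
                        < (network.tree_id[best_eid], best_eid)
                    ):
                        best_eid, best_d = eid, dj
            # any unscanned cell is at Chebyshev ring ≥ r+1, hence at
            # Euclidean distance ≥ r·bin from the query point
            if best_d <= r * self.bin:
                break
            r += 1
            if r > 10_000:  # pragma: no cover - safety net
                raise RuntimeError("voxel ring expansion failed to terminate")
        return best_eid, float(best_d)


def _exhaustive_closest(network: VesselNetwork, point: np.ndarray) -> tuple[int, float]:
    if network.n_edges == 0:
        raise GrowthError("closest-edge query on an empty forest")
    d = np.linalg.norm(network.midpoints() - point, axis=1)
    dmin = d.min()
    ties = np.nonzero(d == dmin)[0]
    if len(ties) > 1:
        ties = sorted(ties, key=lambda e: (network.tree_id[e], e))
    return int(ties[0]), float(dmin)


def find_closest_edge(
    network: VesselNetwork, point: np.ndarray, index: VoxelEdgeIndex | None = None
) -> tuple[int, int, float]:
    """(tree id, edge id, distance) of the edge whose polyline midpoint is
    nearest to ``point`` among all trees of the vessel-type context."""
    point = np.asarray(point, dtype=float)
    if index is not None:
        eid, d = index.query(point, network)
    else:
        eid, d = _exhaustive_closest(network, point)
    return network.tree_id[eid], eid, d


# -- geometry helpers ------------------------------------------------------


def _chord_subpoints(p0: np.ndarray, p1: np.ndarray, target_len: float) -> np.ndarray:
    n = max(1, int(np.ceil(np.linalg.norm(p1 - p0) / target_len)))
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return p0 * (1.0 - t) + p1 * t


def relocate_to_domain(
    subpoints: np.ndarray,
    fieldref: DistanceField,
    psi_th: float,
) -> np.ndarray:
    """Project interior subpoints with |ψ| > ψ_th onto Γ; endpoints fixed."""
    sp = np.asarray(subpoints, dtype=float).copy()
    if len(sp) <= 2:
        return sp
    inner = sp[1:-1]
    psi = fieldref.psi_at(inner)
    bad = np.abs(psi) > psi_th
    if bad.any():
        proj, _ = fieldref.project_to_surface(inner[bad])
        inner[bad] = proj
    return sp


def _confine_chord(
    p0: np.ndarray,
    p1: np.ndarray,
    fieldref: DistanceField,
    psi_th: float,
    target_len: float,
) -> np.ndarray:
    return relocate_to_domain(_chord_subpoints(p0, p1, target_len), fieldref, psi_th)


def enumerate_bifurcations(
    network: VesselNetwork,
    eid: int,
    terminal_pos: np.ndarray,
    fieldref: DistanceField,
    psi_th: float,
    target_len: float,
    radii: tuple[float, float, float],
) -> list[CandidateBifurcation]:
    """Build and score the four branch patterns for a terminal on edge eid.

    ``radii`` are the tentative (upstream, downstream, terminal-edge) radii;
    they are pattern-independent because the coverage split does not depend on
    where the branching vertex sits.
    """
    a, b = network.vertex_positions(eid)
    t = np.asarray(terminal_pos, dtype=float)
    xs = np.stack([(a + b) / 2, (a + t) / 2, (b + t) / 2, (a + b + t) / 3])
    psi = fieldref.psi_at(xs)
    bad = np.abs(psi) > psi_th
    if bad.any():
        proj, _ = fieldref.project_to_surface(xs[bad])
        xs[bad] = proj
    a_up, a_down, a_term = radii
    out: list[CandidateBifurcation] = []
    for p in range(4):
        x = xs[p]
        sub_up = _confine_chord(a, x, fieldref, psi_th, target_len)
        sub_down = _confine_chord(x, b, fieldref, psi_th, target_len)
        sub_term = _confine_chord(x, t, fieldref, psi_th, target_len)
        lengths = tuple(
            float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())
            for s in (sub_up, sub_down, sub_term)
        )
        score = (
            lengths[0] * a_up**2
            + lengths[1] * a_down**2
            + lengths[2] * a_term**2
        )
        out.append(
            CandidateBifurcation(
                pattern=p + 1,
                branch_vertex=x,
                sub_up=sub_up,
                sub_down=sub_down,
                sub_term=sub_term,
                lengths=lengths,  # type: ignore[arg-type]
                radii=radii,
                score=float(score),
            )
        )
    return out


# -- quota bookkeeping -----------------------------------------------------


class _QuotaState:
    def __init__(
        self,
        n_subregions: int,
        limits: tuple[int, int],
        initial_counts: dict[int, int],
    ) -> None:
        self.min, self.cfg_max = limits
        self.counts = np.zeros(n_subregions, dtype=np.int64)
        for i, c in initial_counts.items():
            self.counts[i] = c
        # inherited root tips cannot be removed: a subregion that starts above
        # the permitted maximum simply receives no further terminals
        self.eff_max = np.maximum(self.cfg_max, self.counts)

    def below_min(self) -> np.ndarray:
        return np.nonzero(self.counts < self.min)[0]

    def open_subregions(self) -> np.ndarray:
        return np.nonzero(self.counts < self.eff_max)[0]

    def deficit(self) -> int:
        return int(np.maximum(self.min - self.counts, 0).sum())


@dataclass
class InsertionRecord:
    step: int
    subregion: int
    closest_edge: int
    distance: float
    pattern: int
    scores: tuple[float, float, float, float]
    edge_up: int
    edge_down: int
    edge_term: int
    rejections_d: int  # constraint (1) rejections before acceptance


@dataclass
class GrowthLog:
    insertions: list[InsertionRecord] = dc_field(default_factory=list)
    rejections_distance: int = 0
    projection_failures: int = 0


# -- level growth ----------------------------------------------------------


def make_triangle_locator(surface: TriSurface):
    """Point → nearest triangle id (exact over a centroid-KNN candidate set)."""
    from scipy.spatial import cKDTree

    from .sdf import point_triangle_distance_sq

    centroids = surface.triangle_centroids()
    tree = cKDTree(centroids)
    tri_pts = surface.vertices[surface.triangles]
    k = min(8, surface.n_triangles)

    def locate(point: np.ndarray) -> int:
        _, cand = tree.query(point.reshape(1, 3), k=k)
        cand = np.atleast_1d(np.asarray(cand).ravel())
        d2 = point_triangle_distance_sq(
            np.repeat(point.reshape(1, 3), len(cand), axis=0), tri_pts[cand]
        )
        return int(cand[int(np.argmin(d2))])

    return locate


def grow_level(
    roots: list[tuple[np.ndarray, float, str]],
    partition: SubregionPartition,
    surface: TriSurface,
    fieldref: DistanceField,
    *,
    vessel_type: str,
    level: str,
    budget: int,
    limits: tuple[int, int],
    l_th: float,
    psi_th: float,
    rng: np.random.Generator,
    max_rejections: int = 10_000,
    subdivision_length: float | None = None,
    subregion_triangles: dict[int, np.ndarray] | None = None,
    tri_lookup=None,
    audit_callback=None,
    raise_budget_to_cover_minima: bool = False,
) -> tuple[VesselNetwork, GrowthLog]:
    """Grow all trees of one (level, vessel type) to an exact terminal budget.

    ``roots``: (subpoint polyline, root radius, label) per tree; the root tip
    counts as a terminal.  ``budget`` is the final number of terminal edges.
    Raises :class:`GrowthError` on infeasible quota/budget combinations or
    when rejection sampling exhausts ``max_rejections`` for one terminal.
    """
    target_len = subdivision_length if subdivision_length is not None else fieldref.h
    if tri_lookup is None:
        tri_lookup = make_triangle_locator(surface)

    net = VesselNetwork(vessel_type, level)
    init_counts: dict[int, int] = {}
    for sp, a0, label in roots:
        sub = int(partition.labels[tri_lookup(np.asarray(sp)[-1])])
        net.add_tree(sp, a0, sub, label)
        init_counts[sub] = init_counts.get(sub, 0) + 1

    quota = _QuotaState(partition.n_subregions, limits, init_counts)
    n_initial = len(roots)
    if budget < n_initial:
        raise GrowthError(
            f"budget {budget} below the {n_initial} inherited root terminals"
        )
    remaining = budget - n_initial
    if remaining < quota.deficit():
        if raise_budget_to_cover_minima:
            # inherited tips clustered above the per-subregion cap: grow just
            # enough extra terminals to still cover every subregion's minimum
            remaining = quota.deficit()
        else:
            raise GrowthError(
                f"budget {budget} cannot satisfy per-subregion minimum "
                f"{quota.min} over {partition.n_subregions} subregions"
            )
    if remaining > int((quota.eff_max - quota.counts).sum()):
        raise GrowthError(
            f"budget {budget} exceeds the per-subregion maximum capacity"
        )

    # initialise S with current terminal counts (root tips)
    for t in range(net.n_trees):
        e = net.tree_roots[t]
        i = net.subregion[e]
        net.S[e] = partition.areas[i] / quota.counts[i]

    # per-subregion triangle tables for area-weighted triangle draws
    if subregion_triangles is None:
        subregion_triangles = {
            i: partition.members(i) for i in range(partition.n_subregions)
        }
    cum_areas = {
        i: np.cumsum(surface.triangle_areas[tris])
        for i, tris in subregion_triangles.items()
    }

    index = VoxelEdgeIndex(bin_size=l_th / 4.0)
    for e in range(net.n_edges):
        index.insert(e, net.midpoints()[e])

    # registry: terminal edge ids per subregion
    registry: dict[int, list[int]] = {}
    for e in range(net.n_edges):
        registry.setdefault(net.subregion[e], []).append(e)

    log = GrowthLog()
    step = 0
    while remaining > 0:
        below = quota.below_min()
        restricted = len(below) >= remaining
        pool = below if restricted else quota.open_subregions()
        rejections = 0
        while True:
            if rejections >= max_rejections:
                raise GrowthError(
                    "max rejection attempts exceeded; binding constraint: "
                    + (
                        "distance to closest edge (l_th)"
                        if len(pool)
                        else "per-subregion terminal quota"
                    )
                )
            i = int(pool[rng.integers(len(pool))])
            tris = subregion_triangles[i]
            ca = cum_areas[i]
            tri = tris[int(np.searchsorted(ca, rng.random() * ca[-1]))]
            bary = sample_barycentric(1, rng)[0]
            pos = bary @ surface.vertices[surface.triangles[tri]]
            eid, dist = index.query(pos, net)
            if dist >= l_th:
                rejections += 1
                log.rejections_distance += 1
                continue
            break

        # tentative coverage with the new terminal counted in N_term(D_i)
        area_i = partition.areas[i]
        n_old = int(quota.counts[i])
        quota_new = area_i / (n_old + 1)
        delta = (quota_new - area_i / n_old) if n_old > 0 else 0.0
        terms_i = registry.get(i, [])
        n_down = 0
        tree_j = net.tree_id[eid]
        m_j = 0
        for tg in terms_i:
            if net.tree_id[tg] == tree_j:
                m_j += 1
            if tg == eid or eid in net.ancestors(tg):
                n_down += 1
        s_down = net.S[eid] + n_down * delta
        s_term = quota_new
        s_up = s_down + s_term
        root_e = net.tree_roots[tree_j]
        s_root_new = net.S[root_e] + m_j * delta + s_term
        a0 = net.a_root[tree_j]
        a_up = a0 if eid == root_e else (s_up / s_root_new) ** (1 / 3) * a0
        a_down = (s_down / s_root_new) ** (1 / 3) * a0
        a_term = (s_term / s_root_new) ** (1 / 3) * a0

        cands = enumerate_bifurcations(
            net, eid, pos, fieldref, psi_th, target_len, (a_up, a_down, a_term)
        )
        best = min(cands, key=lambda c: (c.score, c.pattern))

        # --- insert: e_up replaces eid's geometry; two new edges appended
        old_mid = net.midpoints()[eid].copy()
        was_terminal = net.terminal[eid]
        old_children = net.children[eid]
        old_sub = net.subregion[eid]

        e_down = net._append_edge(
            parent=eid,
            tree=tree_j,
            subpoints=best.sub_down,
            terminal=was_terminal,
            subregion=old_sub if was_terminal else -1,
        )
        e_term = net._append_edge(
            parent=eid,
            tree=tree_j,
            subpoints=best.sub_term,
            terminal=True,
            subregion=i,
        )
        net.children[e_down] = old_children
        for c in old_children:
            net.parent[c] = e_down
        net.subpoints[eid] = best.sub_up
        net.length[eid] = best.lengths[0]
        net.children[eid] = [e_down, e_term]
        net.terminal[eid] = False
        net.subregion[eid] = -1
        net._midpoints[eid] = polyline_midpoint(best.sub_up)
        index.relocate(eid, old_mid, net._midpoints[eid])
        index.insert(e_down, net._midpoints[e_down])
        index.insert(e_term, net._midpoints[e_term])

        # --- incremental S maintenance
        net.S[e_down] = net.S[eid]  # carries eid's old downstream coverage
        if was_terminal:
            lst = registry[old_sub]
            lst[lst.index(eid)] = e_down
        if n_old > 0 and delta != 0.0:
            for tg in registry.get(i, []):
                for e in net.ancestors(tg):
                    net.S[e] += delta
        for e in net.ancestors(e_term):
            net.S[e] += s_term
        registry.setdefault(i, []).append(e_term)
        quota.counts[i] += 1
        remaining -= 1
        step += 1
        rec = InsertionRecord(
            step=step,
            subregion=i,
            closest_edge=eid,
            distance=dist,
            pattern=best.pattern,
            scores=tuple(c.score for c in cands),  # type: ignore[arg-type]
            edge_up=eid,
            edge_down=e_down,
            edge_term=e_term,
            rejections_d=rejections,
        )
        log.insertions.append(rec)
        if audit_callback is not None:
            audit_callback(net, rec)

    return net, log


# -- multilevel orchestration ---------------------------------------------


@dataclass
class VesselForest:
    """All grown networks plus the LV1-terminal → LV2-tree linkage."""

    lv1: dict[str, VesselNetwork] = dc_field(default_factory=dict)
    lv2: dict[tuple[str, int], VesselNetwork] = dc_field(default_factory=dict)
    # (vessel_type, lv1 edge id) -> (lv1 subregion, tree index in lv2 network)
    linkage: dict[tuple[str, int], tuple[int, int]] = dc_field(default_factory=dict)
    logs: dict[str, GrowthLog] = dc_field(default_factory=dict)

    def networks(self) -> list[VesselNetwork]:
        return list(self.lv1.values()) + list(self.lv2.values())


def run_mrc(
    surface: TriSurface,
    fieldref: DistanceField,
    lv1_partition: SubregionPartition,
    lv2_partitions: dict[int, SubregionPartition],
    roots: list[RootEdge],
    config: GrowthConfig,
) -> VesselForest:
    """Two-level growth: LV1 veins, LV1 arteries, then per-subregion LV2.

    Returns the forest with every network validated against its terminal
    budget and quotas.  Deterministic for a given config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_lv1_vein, rng_lv1_art, rng_lv2 = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    tri_lookup = make_triangle_locator(surface)
    forest = VesselForest()

    nd1 = lv1_partition.n_subregions
    budgets = {
        "vein": nd1 * config.lv1_vein_limits[0],
        "artery": int(round(config.alpha * nd1 * config.lv1_vein_limits[0])),
    }
    limits = {"vein": config.lv1_vein_limits, "artery": config.lv1_artery_limits}
    rngs = {"vein": rng_lv1_vein, "artery": rng_lv1_art}
    for vessel_type in ("vein", "artery"):  # veins first
        rts = [
            (_root_polyline(r, fieldref), r.radius, r.label)
            for r in roots
            if r.vessel_type == vessel_type
        ]
        if not rts:
            raise GrowthError(f"no {vessel_type} roots supplied")
        net, log = grow_level(
            rts,
            lv1_partition,
            surface,
            fieldref,
            vessel_type=vessel_type,
            level="LV1",
            budget=budgets[vessel_type],
            limits=limits[vessel_type],
            l_th=config.l_th,
            psi_th=config.psi_th,
            rng=rngs[vessel_type],
            max_rejections=config.max_rejections,
            subdivision_length=config.subdivision_length,
            tri_lookup=tri_lookup,
            raise_budget_to_cover_minima=True,
        )
        forest.lv1[vessel_type] = net
        forest.logs[f"LV1/{vessel_type}"] = log

    lv2_limits = {"vein": config.lv2_vein_limits, "artery": config.lv2_artery_limits}
    for i in sorted(lv2_partitions):
        part2 = lv2_partitions[i]
        sub_rng = np.random.default_rng(rng_lv2.integers(2**31))
        for vessel_type in ("vein", "artery"):
            lv1_net = forest.lv1[vessel_type]
            tips = [
                e
                for e in lv1_net.terminal_ids()
                if lv1_net.subregion[e] == i
            ]
            if not tips:
                raise GrowthError(
                    f"LV1 subregion {i} has no {vessel_type} terminal to seed LV2"
                )
            rts = [
                (lv1_net.subpoints[e].copy(), lv1_net.radius(e), f"sub{i}")
                for e in tips
            ]
            nd2 = part2.n_subregions
            per = lv2_limits[vessel_type][0]
            budget = nd2 * per
            budget = max(budget, len(rts))
            net, log = grow_level(
                rts,
                part2,
                surface,
                fieldref,
                vessel_type=vessel_type,
                level=f"LV2@{i}",
                budget=budget,
                limits=lv2_limits[vessel_type],
                l_th=config.l_th,
                psi_th=config.psi_th,
                rng=sub_rng,
                max_rejections=config.max_rejections,
                subdivision_length=config.subdivision_length,
                subregion_triangles={
                    j: lv1_partition.members(i)[part2.labels == j]
                    for j in range(nd2)
                },
                tri_lookup=_local_lookup(surface, lv1_partition, i, tri_lookup),
                raise_budget_to_cover_minima=True,
            )
            forest.lv2[(vessel_type, i)] = net
            forest.logs[f"LV2@{i}/{vessel_type}"] = log
            for tree_idx, e in enumerate(tips):
                forest.linkage[(vessel_type, e)] = (i, tree_idx)
    return forest


def _root_polyline(root: RootEdge, fieldref: DistanceField) -> np.ndarray:
    return _chord_subpoints(root.start, root.end, fieldref.h)


def _local_lookup(surface, lv1_partition, i, tri_lookup):
    """Global triangle locator remapped to a parent patch's local indices."""
    members = lv1_partition.members(i)
    global_to_local = {int(t): j for j, t in enumerate(members)}
    centroids = surface.triangle_centroids()[members]

    def locate(point: np.ndarray) -> int:
        tri = int(tri_lookup(point))
        if tri in global_to_local:
            return global_to_local[tri]
        # tip marginally outside the parent patch (projection round-off):
        # snap to the nearest member triangle
        return int(np.argmin(np.linalg.norm(centroids - point, axis=1)))

    return locate
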