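"""Vessel network data model and flow-derived sizing.

A vessel network is a forest of rooted trees.  Every edge is a polyline of
subpoints (mm) joining two vertices; an edge is terminal when it has no
children.  Radii follow from a Poiseuille flow argument under two
assumptions: total inflow splits across subregions in proportion to area
(each terminal in subregion D_i carries an equal share |D_i|/N_term(D_i) of
that subregion's "coverage"), and wall shear stress is equal on every edge of
a tree.  Writing S_n for the summed coverage of the terminals downstream of
edge n, both assumptions combine into the cube-root sizing rule

    a_n = (S_n / S_root)^(1/3) · a_root,

so the final radii depend only on topology, subregion areas and the root
radius — the nominal inflow Q_total and viscosity μ cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FlowAssumptions:
    """Nominal flow parameters; radii are invariant to both (they cancel)."""

    q_total: float = 1.0
    viscosity: float = 1.0

    def __post_init__(self) -> None:
        if self.q_total <= 0 or self.viscosity <= 0:
            raise ValueError("flow parameters must be positive")


def polyline_length(subpoints: np.ndarray) -> float:
    """Length of a subpoint polyline: Σ_k ‖p_k → p_{k+1}‖.

    Raises on coincident consecutive subpoints (zero-length segment).
    """
    subpoints = np.asarray(subpoints, dtype=float)
    seg = np.linalg.norm(np.diff(subpoints, axis=0), axis=1)
    if len(seg) == 0:
        raise ValueError("edge needs at least one segment")
    if np.any(seg == 0.0):
        raise ValueError("zero-length segment (coincident consecutive subpoints)")
    return float(seg.sum())


def edge_mean_radius(segment_radii: np.ndarray) -> float:
    """Arithmetic mean of per-segment cylinder radii."""
    r = np.asarray(segment_radii, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("segment radii must be positive")
    return float(r.mean())


def polyline_midpoint(subpoints: np.ndarray) -> np.ndarray:
    """Point at half arc length along the subpoint polyline."""
    subpoints = np.asarray(subpoints, dtype=float)
    seg = np.linalg.norm(np.diff(subpoints, axis=0), axis=1)
    cum = np.cumsum(seg)
    half = 0.5 * cum[-1]
    k = int(np.searchsorted(cum, half))
    prev = cum[k - 1] if k > 0 else 0.0
    t = (half - prev) / seg[k]
    return subpoints[k] + t * (subpoints[k + 1] - subpoints[k])


class VesselNetwork:
    """One growth context: all trees of a single (vessel_type, level).

    Flat, append-only edge storage; topology via parent/children edge ids.
    Coverage sizes S are maintained incrementally during growth and can be
    recomputed from scratch with :func:`coverage_sizes`.
    """

    def __init__(self, vessel_type: str, level: str) -> None:
        self.vessel_type = vessel_type
        self.level = level
        self.parent: list[int] = []
        self.children: list[list[int]] = []
        self.tree_id: list[int] = []
        self.subpoints: list[np.ndarray] = []
        self.length: list[float] = []
        self.S: list[float] = []
        self.terminal: list[bool] = []
        self.subregion: list[int] = []
        # per-tree
        self.tree_roots: list[int] = []
        self.a_root: list[float] = []
        self.root_label: list[str] = []
        self.initial_tip_subregions: list[int] = []
        self._midpoints = np.empty((64, 3))

    # -- construction -----------------------------------------------------

    def add_tree(
        self,
        subpoints: np.ndarray,
        a_root: float,
        subregion: int,
        label: str = "",
    ) -> int:
        """Add a new tree consisting of a single root edge; returns edge id."""
        eid = self._append_edge(
            parent=-1,
            tree=len(self.tree_roots),
            subpoints=subpoints,
            terminal=True,
            subregion=subregion,
        )
        self.tree_roots.append(eid)
        self.a_root.append(float(a_root))
        self.root_label.append(label)
        self.initial_tip_subregions.append(int(subregion))
        self.S[eid] = 0.0
        return eid

    def _append_edge(
        self,
        parent: int,
        tree: int,
        subpoints: np.ndarray,
        terminal: bool,
        subregion: int,
    ) -> int:
        eid = len(self.parent)
        self.parent.append(parent)
        self.children.append([])
        self.tree_id.append(tree)
        self.subpoints.append(np.asarray(subpoints, dtype=float))
        self.length.append(polyline_length(subpoints))
        self.S.append(0.0)
        self.terminal.append(terminal)
        self.subregion.append(subregion)
        if eid >= len(self._midpoints):
            grown = np.empty((2 * len(self._midpoints), 3))
            grown[: len(self._midpoints)] = self._midpoints
            self._midpoints = grown
        self._midpoints[eid] = polyline_midpoint(subpoints)
        return eid

    # -- accessors --------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.parent)

    @property
    def n_trees(self) -> int:
        return len(self.tree_roots)

    def midpoints(self) -> np.ndarray:
        return self._midpoints[: self.n_edges]

    def s_root(self, tree: int) -> float:
        return self.S[self.tree_roots[tree]]

    def radius(self, eid: int) -> float:
        """Cube-root sizing; the root edge keeps a_root exactly."""
        tree = self.tree_id[eid]
        a0 = self.a_root[tree]
        if self.parent[eid] == -1:
            return a0
        s_root = self.s_root(tree)
        if s_root <= 0.0:
            raise ValueError("S_root is zero: coverage sizes not assigned")
        return float((self.S[eid] / s_root) ** (1.0 / 3.0) * a0)

    def radii(self) -> np.ndarray:
        return np.array([self.radius(e) for e in range(self.n_edges)])

    def ancestors(self, eid: int) -> list[int]:
        """Edge ids on the path eid → root, inclusive of both."""
        path = [eid]
        while self.parent[path[-1]] != -1:
            path.append(self.parent[path[-1]])
        return path

    def terminals_of_tree(self, tree: int) -> list[int]:
        return [
            e
            for e in range(self.n_edges)
            if self.terminal[e] and self.tree_id[e] == tree
        ]

    def terminal_ids(self) -> list[int]:
        return [e for e in range(self.n_edges) if self.terminal[e]]

    def vertex_positions(self, eid: int) -> tuple[np.ndarray, np.ndarray]:
        sp = self.subpoints[eid]
        return sp[0], sp[-1]

    def path_length_to_root(self, eid: int) -> float:
        return float(sum(self.length[e] for e in self.ancestors(eid)))


def tree_volume_score(network: VesselNetwork, edge_ids=None) -> float:
    """Intravascular volume proxy Σ L_n a_n² (mm⁴ as printed; no π factor)."""
    ids = range(network.n_edges) if edge_ids is None else edge_ids
    return float(
        sum(network.length[e] * network.radius(e) ** 2 for e in ids)
    )


def coverage_sizes(
    network: VesselNetwork,
    subregion_areas: np.ndarray,
    terminal_counts: dict[int, int] | None = None,
) -> np.ndarray:
    """Recompute every edge's coverage size S from scratch.

    Terminal edge in D_i: S = |D_i| / N_term(D_i); internal edge: sum of its
    children; root: sum over all its tree's terminals.  ``terminal_counts``
    defaults to the counts observed in the network itself (across all trees of
    this context, as quotas are shared across trees of one vessel type).
    """
    if terminal_counts is None:
        terminal_counts = {}
        for e in network.terminal_ids():
            terminal_counts[network.subregion[e]] = (
                terminal_counts.get(network.subregion[e], 0) + 1
            )
    S = np.zeros(network.n_edges)
    order = _topo_order(network)
    for e in reversed(order):  # children before parents
        if network.terminal[e]:
            i = network.subregion[e]
            if i < 0:
                raise ValueError(f"terminal edge {e} has no subregion assignment")
            S[e] = subregion_areas[i] / terminal_counts[i]
        else:
            S[e] = sum(S[c] for c in network.children[e])
    return S


def _topo_order(network: VesselNetwork) -> list[int]:
    """Edges in root→leaf order (parents before children)."""
    order: list[int] = []
    stack = list(network.tree_roots)
    while stack:
        e = stack.pop()
        order.append(e)
        stack.extend(network.children[e])
    return order


def assign_radii(
    network: VesselNetwork, subregion_areas: np.ndarray | None = None
) -> np.ndarray:
    """Refresh S from scratch and return the per-edge radii a_n.

    a_n = (S_n/S_root)^{1/3}·a_root applied uniformly to all segments of an
    edge; the root edge keeps a_root exactly.  When ``subregion_areas`` is
    omitted the |D_i| are recovered from the current terminal S values.
    """
    if subregion_areas is None:
        subregion_areas = _areas_from(network)
    S = coverage_sizes(network, subregion_areas)
    network.S = list(S)
    return network.radii()


def _areas_from(network: VesselNetwork) -> np.ndarray:
    # reconstruct |D_i| from the incrementally maintained S of terminals
    counts: dict[int, int] = {}
    for e in network.terminal_ids():
        counts[network.subregion[e]] = counts.get(network.subregion[e], 0) + 1
    n = max(counts) + 1 if counts else 0
    areas = np.zeros(n)
    for e in network.terminal_ids():
        i = network.subregion[e]
        areas[i] = network.S[e] * counts[i]
    return areas


def wall_shear_stress(
    network: VesselNetwork,
    flow: FlowAssumptions = FlowAssumptions(),
    total_area: float | None = None,
) -> np.ndarray:
    """Per-edge wall shear stress τ = 4μQ/(πa³) under the coverage flow split.

    Q_n = (S_n/|D_total|)·Q_total.  Equal-shear sizing makes τ identical for
    every edge of a tree, for any (Q_total, μ).
    """
    if total_area is None:
        total_area = sum(network.s_root(t) for t in range(network.n_trees))
    out = np.empty(network.n_edges)
    for e in range(network.n_edges):
        q = network.S[e] / total_area * flow.q_total
        out[e] = 4.0 * flow.viscosity * q / (np.pi * network.radius(e) ** 3)
    return out


def validate_tree(network: VesselNetwork, rtol: float = 1e-9) -> list[str]:
    """Report violations of the structural invariants (empty list = valid)."""
    v: list[str] = []
    seen = np.zeros(network.n_edges, dtype=bool)
    for t, root in enumerate(network.tree_roots):
        if network.parent[root] != -1:
            v.append(f"root edge {root} of tree {t} has a parent")
        stack = [root]
        while stack:
            e = stack.pop()
            if seen[e]:
                v.append(f"edge {e} reachable twice (cycle or shared child)")
                continue
            seen[e] = True
            for c in network.children[e]:
                if network.parent[c] != e:
                    v.append(f"edge {c} parent pointer inconsistent")
                stack.append(c)
    if not seen.all():
        v.append("unreachable edges present")
    for e in range(network.n_edges):
        nchild = len(network.children[e])
        if network.terminal[e] != (nchild == 0):
            v.append(f"edge {e} terminal flag inconsistent with children")
        if nchild not in (0, 2):
            v.append(f"edge {e} has {nchild} children (expected 0 or 2)")
        sp = network.subpoints[e]
        if len(sp) < 2:
            v.append(f"edge {e} has fewer than 2 subpoints")
            continue
        if abs(polyline_length(sp) - network.length[e]) > 1e-9 * (
            1.0 + network.length[e]
        ):
            v.append(f"edge {e} cached length stale")
        if nchild == 2:
            s_kids = sum(network.S[c] for c in network.children[e])
            if abs(network.S[e] - s_kids) > rtol * (1.0 + abs(network.S[e])):
                v.append(f"edge {e} S-additivity violated")
            for c in network.children[e]:
                if not np.allclose(network.subpoints[c][0], sp[-1]):
                    v.append(f"edge {c} does not start at parent {e}'s end vertex")
        if network.S[e] < 0:
            v.append(f"edge {e} has negative S")
    # radius monotonicity root → terminal
    for e in range(network.n_edges):
        p = network.parent[e]
        if p != -1 and network.radius(e) > network.radius(p) * (1 + rtol):
            v.append(f"radius increases from edge {p} to child {e}")
    return v


# -- serialization --------------------------------------------------------


def edges_frame(network: VesselNetwork) -> pd.DataFrame:
    rows = []
    for e in range(network.n_edges):
        rows.append(
            {
                "edge_id": e,
                "parent_edge_id": network.parent[e],
                "tree_id": network.tree_id[e],
                "type": network.vessel_type,
                "level": network.level,
                "terminal_flag": int(network.terminal[e]),
                "subregion_id": network.subregion[e],
                "radius_mm": network.radius(e),
                "length_mm": network.length[e],
                "S_mm2": network.S[e],
            }
        )
    return pd.DataFrame(rows)


def subpoints_frame(network: VesselNetwork) -> pd.DataFrame:
    rows = []
    for e in range(network.n_edges):
        r = network.radius(e)
        for k, p in enumerate(network.subpoints[e]):
            rows.append(
                {
                    "edge_id": e,
                    "k": k,
                    "x": p[0],
                    "y": p[1],
                    "z": p[2],
                    "radius_mm": r,
                }
            )
    return pd.DataFrame(rows)


def write_vtk_polydata(networks: list[VesselNetwork], path: str, orders=None) -> None:
    """VTK legacy ASCII polydata: one polyline per edge with point radii.

    Cell data: vessel type (artery=0/vein=1), level index, tree id, and the
    Strahler order when provided as {network index: per-edge order array}.
    """
    pts: list[np.ndarray] = []
    lines: list[list[int]] = []
    pt_radius: list[float] = []
    cell_type: list[int] = []
    cell_level: list[int] = []
    cell_tree: list[int] = []
    cell_order: list[int] = []
    offset = 0
    for ni, net in enumerate(networks):
        lvl = 1 if net.level.startswith("LV1") else 2
        for e in range(net.n_edges):
            sp = net.subpoints[e]
            r = net.radius(e)
            pts.append(sp)
            pt_radius.extend([r] * len(sp))
            lines.append(list(range(offset, offset + len(sp))))
            offset += len(sp)
            cell_type.append(0 if net.vessel_type == "artery" else 1)
            cell_level.append(lvl)
            cell_tree.append(net.tree_id[e])
            if orders is not None and ni in orders:
                cell_order.append(int(orders[ni][e]))
    allpts = np.vstack(pts) if pts else np.empty((0, 3))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvessel network\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(allpts)} float\n")
        for p in allpts:
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        size = sum(len(l) + 1 for l in lines)
        f.write(f"LINES {len(lines)} {size}\n")
        for l in lines:
            f.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        f.write(f"POINT_DATA {len(allpts)}\nSCALARS radius_mm float 1\n")
        f.write("LOOKUP_TABLE default\n")
        for r in pt_radius:
            f.write(f"{r:.6f}\n")
        f.write(f"CELL_DATA {len(lines)}\nSCALARS vessel_type int 1\n")
        f.write("LOOKUP_TABLE default\n")
        for x in cell_type:
            f.write(f"{x}\n")
        f.write("SCALARS level int 1\nLOOKUP_TABLE default\n")
        for x in cell_level:
            f.write(f"{x}\n")
        f.write("SCALARS tree_id int 1\nLOOKUP_TABLE default\n")
        for x in cell_tree:
            f.write(f"{x}\n")
        if cell_order:
            f.write("SCALARS strahler_order int 1\nLOOKUP_TABLE default\n")
            for x in cell_order:
                f.write(f"{x}\n")


def write_swc(network: VesselNetwork, tree: int, path: str) -> None:
    """SWC-like export of one tree (sample per subpoint, type 2=artery 3=vein)."""
    swc_type = 2 if network.vessel_type == "artery" else 3
    rows = []
    last_sample_of_edge: dict[int, int] = {}
    sample = 0
    order = [e for e in _topo_order(network) if network.tree_id[e] == tree]
    for e in order:
        sp = network.subpoints[e]
        r = network.radius(e)
        parent_edge = network.parent[e]
        parent_sample = last_sample_of_edge.get(parent_edge, -1)
        start = 0 if parent_edge == -1 else 1  # skip shared junction point
        for k in range(start, len(sp)):
            sample += 1
            rows.append(
                f"{sample} {swc_type} {sp[k][0]:.4f} {sp[k][1]:.4f} "
                f"{sp[k][2]:.4f} {r:.5f} {parent_sample}"
            )
            parent_sample = sample
        last_sample_of_edge[e] = sample
    with open(path, "w") as f:
        f.write("# SWC-like vessel tree export\n")
        f.write("\n".join(rows) + "\n")
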