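"""Morphometric evaluation of grown vascular networks.

Covers the full evaluation suite: merging the fine level into the coarse
level per root, diameter-defined Strahler ordering (terminal edges pinned at
order 1, per-order diameter statistics iteratively reassigning orders, and
connected same-order runs merged into *elements*), Horton regressions
log10 q = a + b·n for element diameter / length / count, terminal-diameter
summaries, whole-path metrics (Euclidean distance L, path length C,
tortuosity C/L − 1 with a lognormal fit), and vascular territories of
labelled roots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth import VesselForest
from .partition import SubregionPartition
from .vessels import VesselNetwork


# -- merged per-root trees -------------------------------------------------


@dataclass
class MergedTree:
    """One root's LV1+LV2 network flattened for analysis."""

    label: str
    parent: np.ndarray  # (E,) parent edge index, -1 at root
    length: np.ndarray  # (E,) mm
    diameter: np.ndarray  # (E,) mm (2·a_n)
    level: np.ndarray  # (E,) 1 or 2
    tip_pos: np.ndarray  # (E, 3) distal vertex of each edge
    root_pos: np.ndarray  # (3,)
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = [[] for _ in range(len(self.parent))]
            for e, p in enumerate(self.parent):
                if p >= 0:
                    self.children[p].append(e)

    @property
    def n_edges(self) -> int:
        return len(self.parent)

    @property
    def terminal_mask(self) -> np.ndarray:
        return np.array([len(c) == 0 for c in self.children])

    def topo_order(self) -> list[int]:
        order, stack = [], [e for e, p in enumerate(self.parent) if p == -1]
        while stack:
            e = stack.pop()
            order.append(e)
            stack.extend(self.children[e])
        return order


def merge_levels(forest: VesselForest, vessel_type: str) -> list[MergedTree]:
    """Connect each LV2 tree onto the LV1 terminal that seeded it.

    The LV2 root edge inherits (and geometrically duplicates) its seeding LV1
    terminal edge, so the merge replaces that terminal with the LV2 root's
    possibly-split chain.  Returns one tree per LV1 root.
    """
    lv1 = forest.lv1[vessel_type]
    out: list[MergedTree] = []
    for t in range(lv1.n_trees):
        parent: list[int] = []
        length: list[float] = []
        diameter: list[float] = []
        level: list[int] = []
        tips: list[np.ndarray] = []

        def _add(p: int, ln: float, d: float, lv: int, tip: np.ndarray) -> int:
            parent.append(p)
            length.append(ln)
            diameter.append(d)
            level.append(lv)
            tips.append(tip)
            return len(parent) - 1

        def _copy_lv2(net2: VesselNetwork, root_eid: int, at_parent: int) -> None:
            stack = [(root_eid, at_parent)]
            while stack:
                e, p = stack.pop()
                idx = _add(
                    p, net2.length[e], 2 * net2.radius(e), 2, net2.subpoints[e][-1]
                )
                for c in net2.children[e]:
                    stack.append((c, idx))

        stack: list[tuple[int, int]] = [(lv1.tree_roots[t], -1)]
        while stack:
            e, p = stack.pop()
            link = forest.linkage.get((vessel_type, e))
            if link is not None:
                if not lv1.terminal[e]:
                    raise ValueError(f"linkage attached to non-terminal LV1 edge {e}")
                i, tree_idx = link
                net2 = forest.lv2[(vessel_type, i)]
                _copy_lv2(net2, net2.tree_roots[tree_idx], p)
                continue
            idx = _add(p, lv1.length[e], 2 * lv1.radius(e), 1, lv1.subpoints[e][-1])
            for c in lv1.children[e]:
                stack.append((c, idx))
        out.append(
            MergedTree(
                label=lv1.root_label[t],
                parent=np.asarray(parent),
                length=np.asarray(length),
                diameter=np.asarray(diameter),
                level=np.asarray(level),
                tip_pos=np.asarray(tips),
                root_pos=lv1.subpoints[lv1.tree_roots[t]][0].copy(),
            )
        )
    return out


# -- diameter-defined Strahler ordering ------------------------------------


@dataclass
class StrahlerResult:
    orders: np.ndarray  # per-edge order
    element_id: np.ndarray  # per-edge element index
    elements: pd.DataFrame  # per-element: order, length, diameter
    table: pd.DataFrame  # per-order: mean_d, sd_d, mean_l, sd_l, n_elem
    iterations: int
    converged: bool


def _classic_strahler(tree: MergedTree) -> np.ndarray:
    orders = np.zeros(tree.n_edges, dtype=np.int64)
    for e in reversed(tree.topo_order()):
        kids = tree.children[e]
        if not kids:
            orders[e] = 1
        else:
            ko = orders[kids]
            m = int(ko.max())
            orders[e] = m + 1 if np.sum(ko == m) > 1 else m
    return orders


def strahler_order(
    tree: MergedTree, max_iterations: int = 30
) -> StrahlerResult:
    """Diameter-defined Strahler ordering with terminal edges pinned at 1.

    A classic Strahler pass seeds the orders; then, per order n, the mean and
    SD of the member diameters define interval boundaries halfway between
    (mean+SD) of order n−1 and (mean−SD) of order n, and a non-terminal edge
    whose diameter falls in a neighbouring order's interval is moved there.
    Iterates to a fixed point (or ``max_iterations``), after which connected
    same-order edges are merged into elements.
    """
    if np.any(tree.diameter <= 0):
        raise ValueError("all edge diameters must be positive")
    orders = _classic_strahler(tree)
    terminal = tree.terminal_mask
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        nmax = int(orders.max())
        mean = np.full(nmax + 2, np.nan)
        sd = np.full(nmax + 2, np.nan)
        for n in range(1, nmax + 1):
            d = tree.diameter[orders == n]
            if len(d):
                mean[n] = d.mean()
                sd[n] = d.std()
        lower = np.full(nmax + 2, -np.inf)
        upper = np.full(nmax + 2, np.inf)
        for n in range(1, nmax + 1):
            if np.isfinite(mean[n - 1]) and np.isfinite(mean[n]):
                lower[n] = 0.5 * (mean[n - 1] + sd[n - 1] + mean[n] - sd[n])
            if np.isfinite(mean[n + 1]) and np.isfinite(mean[n]):
                upper[n] = 0.5 * (mean[n] + sd[n] + mean[n + 1] - sd[n + 1])
        new_orders = orders.copy()
        movable = ~terminal
        for e in np.nonzero(movable)[0]:
            n = orders[e]
            d = tree.diameter[e]
            if d < lower[n] and n > 1:
                new_orders[e] = n - 1
            elif d > upper[n] and n < nmax:
                new_orders[e] = n + 1
        if np.array_equal(new_orders, orders):
            converged = True
            break
        orders = new_orders

    element_id = _form_elements(tree, orders)
    elements = _element_table(tree, orders, element_id)
    return StrahlerResult(
        orders=orders,
        element_id=element_id,
        elements=elements,
        table=order_table(elements),
        iterations=it,
        converged=converged,
    )


def _form_elements(tree: MergedTree, orders: np.ndarray) -> np.ndarray:
    """Union connected same-order edges into elements."""
    parent_uf = np.arange(tree.n_edges)

    def find(x: int) -> int:
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    for e in range(tree.n_edges):
        p = tree.parent[e]
        if p >= 0 and orders[e] == orders[p]:
            parent_uf[find(e)] = find(p)
    roots = np.array([find(e) for e in range(tree.n_edges)])
    _, element_id = np.unique(roots, return_inverse=True)
    return element_id


def _element_table(
    tree: MergedTree, orders: np.ndarray, element_id: np.ndarray
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "element": element_id,
            "order": orders,
            "length": tree.length,
            "wd": tree.length * tree.diameter,
        }
    )
    el = df.groupby("element").agg(
        order=("order", "first"),
        length=("length", "sum"),
        wd=("wd", "sum"),
    )
    el["diameter"] = el["wd"] / el["length"]  # length-weighted mean diameter
    return el[["order", "length", "diameter"]].reset_index(drop=True)


def order_table(elements: pd.DataFrame) -> pd.DataFrame:
    """Per-order mean/SD of element diameter and length, plus element count."""
    per = elements.groupby("order").agg(
        mean_d=("diameter", "mean"),
        sd_d=("diameter", "std"),
        mean_l=("length", "mean"),
        sd_l=("length", "std"),
        n_elem=("diameter", "size"),
    )
    return per.fillna({"sd_d": 0.0, "sd_l": 0.0}).reset_index()


def pooled_order_table(results: list[StrahlerResult]) -> pd.DataFrame:
    """Per-order statistics pooling the elements of several trees."""
    return order_table(pd.concat([r.elements for r in results], ignore_index=True))


# -- Horton regressions ----------------------------------------------------


@dataclass
class HortonFit:
    quantity: str  # "d" | "l" | "N_elem"
    orders: tuple[int, ...]
    intercept: float
    slope: float
    r_squared: float
    available: bool = True


def horton_fit(
    table: pd.DataFrame,
    quantity: str,
    order_range: str = "low",
    exclude_last: bool | None = None,
) -> HortonFit:
    """OLS of log10(q) on the element order n.

    ``order_range``: "low" fits n ∈ [1, 5]; "high" fits n ≥ 6 excluding the
    last (sparsest) order.  ``exclude_last`` overrides the exclusion rule for
    the chosen range (by default only the high range drops the last order).
    """
    col = {"d": "mean_d", "l": "mean_l", "N_elem": "n_elem"}[quantity]
    tab = table.sort_values("order")
    nmax = int(tab["order"].max())
    if order_range == "low":
        sel = tab[(tab["order"] >= 1) & (tab["order"] <= 5)]
        drop_last = bool(exclude_last) if exclude_last is not None else False
    elif order_range == "high":
        sel = tab[tab["order"] >= 6]
        drop_last = exclude_last if exclude_last is not None else True
    else:
        raise ValueError("order_range must be 'low' or 'high'")
    if drop_last:
        sel = sel[sel["order"] < nmax]
    sel = sel[sel[col] > 0]
    if len(sel) < 2:
        return HortonFit(quantity, tuple(sel["order"]), np.nan, np.nan, np.nan, False)
    n = sel["order"].to_numpy(dtype=float)
    q = np.log10(sel[col].to_numpy(dtype=float))
    res = stats.linregress(n, q)
    return HortonFit(
        quantity=quantity,
        orders=tuple(int(x) for x in sel["order"]),
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


# -- terminal diameters ----------------------------------------------------


def terminal_diameter_stats(networks: list[VesselNetwork]) -> dict[str, float]:
    """Five-number summary (min, Q1, median, Q3, max) of terminal diameters."""
    d = np.array(
        [2 * net.radius(e) for net in networks for e in net.terminal_ids()]
    )
    if len(d) == 0:
        raise ValueError("no terminal edges")
    q = np.percentile(d, [0, 25, 50, 75, 100])
    return {
        "min": float(q[0]),
        "q1": float(q[1]),
        "median": float(q[2]),
        "q3": float(q[3]),
        "max": float(q[4]),
        "n": int(len(d)),
    }


# -- whole-path metrics ----------------------------------------------------


@dataclass
class PathMetrics:
    per_terminal: pd.DataFrame  # L, C, tortuosity, n_bifurcations, label
    lognormal_mu: float  # MLE on log tortuosity
    lognormal_sigma: float
    cl_slope: float  # OLS of C on L
    cl_intercept: float
    n_excluded: int  # terminals with L = 0


def path_metrics(trees: list[MergedTree], floor: float = 1e-6) -> PathMetrics:
    """Per-terminal Euclidean distance L, path length C and tortuosity C/L−1.

    The tortuosity distribution is summarised by a lognormal fit (closed-form
    MLE on log values, zero tortuosity floored at ``floor``); the C–L relation
    by an OLS line.
    """
    rows = []
    excluded = 0
    for tree in trees:
        cum = np.zeros(tree.n_edges)
        nbif = np.zeros(tree.n_edges, dtype=int)
        for e in tree.topo_order():
            p = tree.parent[e]
            cum[e] = tree.length[e] + (cum[p] if p >= 0 else 0.0)
            nbif[e] = (nbif[p] + (len(tree.children[p]) == 2)) if p >= 0 else 0
        for e in np.nonzero(tree.terminal_mask)[0]:
            L = float(np.linalg.norm(tree.tip_pos[e] - tree.root_pos))
            C = float(cum[e])
            if L == 0.0:
                excluded += 1
                continue
            rows.append(
                {
                    "label": tree.label,
                    "L": L,
                    "C": C,
                    "tortuosity": C / L - 1.0,
                    "n_bifurcations": int(nbif[e]),
                }
            )
    df = pd.DataFrame(rows)
    logt = np.log(np.maximum(df["tortuosity"].to_numpy(), floor))
    res = stats.linregress(df["L"], df["C"])
    return PathMetrics(
        per_terminal=df,
        lognormal_mu=float(logt.mean()),
        lognormal_sigma=float(logt.std()),
        cl_slope=float(res.slope),
        cl_intercept=float(res.intercept),
        n_excluded=excluded,
    )


# -- vascular territories --------------------------------------------------


def territory_report(
    forest: VesselForest,
    partition: SubregionPartition,
    reference_family: str = "PCA",
) -> pd.DataFrame:
    """Assign each LV1 subregion to the arterial root label supplying the most
    terminal ends in it (ties: larger summed terminal coverage S, then
    lexicographic label) and total the areas per label.

    Returns a per-label table (label, area_mm2, n_roots, ratio_to_reference);
    the ratio divides by the same-side reference-family label (e.g. LMCA by
    LPCA) when such a label exists.
    """
    net = forest.lv1["artery"]
    assign: dict[int, str] = {}
    for i in range(partition.n_subregions):
        votes: dict[str, tuple[int, float]] = {}
        for e in net.terminal_ids():
            if net.subregion[e] != i:
                continue
            lab = net.root_label[net.tree_id[e]]
            cnt, s = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, s + net.S[e])
        if not votes:
            raise ValueError(f"subregion {i} has no arterial terminal end")
        assign[i] = min(
            votes, key=lambda lab: (-votes[lab][0], -votes[lab][1], lab)
        )
    labels = sorted({lab for lab in assign.values()} | set(net.root_label))
    area = {lab: 0.0 for lab in labels}
    for i, lab in assign.items():
        area[lab] += float(partition.areas[i])
    n_roots = {
        lab: sum(1 for x in net.root_label if x == lab) for lab in labels
    }
    rows = []
    for lab in labels:
        ref = _reference_label(lab, labels, reference_family)
        rows.append(
            {
                "label": lab,
                "area_mm2": area[lab],
                "n_roots": n_roots[lab],
                "ratio_to_reference": (
                    area[lab] / area[ref] if ref is not None and area[ref] > 0 else np.nan
                ),
                "subregions": sum(1 for x in assign.values() if x == lab),
            }
        )
    return pd.DataFrame(rows)


def _reference_label(
    label: str, labels: list[str], family: str
) -> str | None:
    if label.endswith(family):
        return None
    side = label[0]
    ref = side + family
    return ref if ref in labels else None


def root_count_ratios(
    counts: dict[str, int], reference_family: str = "PCA"
) -> pd.DataFrame:
    """Ratios of per-label root counts to the same-side reference label.

    E.g. counts {LACA: 18, ..., LPCA: 8} give LACA ratio 18/8 = 2.25.
    """
    labels = sorted(counts)
    rows = []
    for lab in labels:
        ref = _reference_label(lab, labels, reference_family)
        rows.append(
            {
                "label": lab,
                "n_roots": counts[lab],
                "ratio_to_reference": (
                    counts[lab] / counts[ref] if ref is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
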