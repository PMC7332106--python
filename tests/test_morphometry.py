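import numpy as np
import pandas as pd
import pytest

from mrcvasc import morphometry as mm
from mrcvasc.morphometry import (
    MergedTree,
    horton_fit,
    merge_levels,
    path_metrics,
    root_count_ratios,
    strahler_order,
    terminal_diameter_stats,
    territory_report,
)


def make_tree(parent, length, diameter, tips=None, root_pos=(0, 0, 0), label="A"):
    parent = np.asarray(parent)
    n = len(parent)
    tips = np.zeros((n, 3)) if tips is None else np.asarray(tips, float)
    return MergedTree(
        label=label,
        parent=parent,
        length=np.asarray(length, float),
        diameter=np.asarray(diameter, float),
        level=np.ones(n, dtype=int),
        tip_pos=tips,
        root_pos=np.asarray(root_pos, float),
    )


def perfect_binary_tree(depth, d_root=2.0, ratio=2 ** (-1 / 3)):
    """Generation-g edges have diameter d_root·ratio^g."""
    parent, diam = [-1], [d_root]
    frontier = [0]
    for g in range(1, depth + 1):
        nxt = []
        for p in frontier:
            for _ in range(2):
                parent.append(p)
                diam.append(d_root * ratio**g)
                nxt.append(len(parent) - 1)
        frontier = nxt
    length = np.ones(len(parent))
    return make_tree(parent, length, diam)


# -- merging ---------------------------------------------------------------


def test_merge_counts_terminals(small_run):
    forest = small_run["forest"]
    for vt in ("artery", "vein"):
        lv1 = forest.lv1[vt]
        lv2_terms = sum(
            len(n.terminal_ids()) for (t, _), n in forest.lv2.items() if t == vt
        )
        lv2_edges = sum(
            n.n_edges for (t, _), n in forest.lv2.items() if t == vt
        )
        trees = merge_levels(forest, vt)
        merged_terms = sum(int(t.terminal_mask.sum()) for t in trees)
        merged_edges = sum(t.n_edges for t in trees)
        n_linked = sum(1 for (t, _e) in forest.linkage if t == vt)
        assert merged_terms == lv2_terms
        # merged edge count: all LV1 edges minus replaced terminals + all LV2
        assert merged_edges == lv1.n_edges - n_linked + lv2_edges


def test_merge_is_acyclic_single_root(small_run):
    trees = merge_levels(small_run["forest"], "artery")
    for t in trees:
        assert np.sum(t.parent == -1) == 1
        order = t.topo_order()
        assert len(order) == t.n_edges  # every edge reachable exactly once


def test_merge_without_lv2_is_identity():
    from mrcvasc.growth import VesselForest
    from mrcvasc.vessels import VesselNetwork

    net = VesselNetwork("artery", "LV1")
    net.add_tree(np.array([[0.0, 0, 0], [1.0, 0, 0]]), 1.0, 0, label="X")
    net.S[0] = 1.0
    forest = VesselForest(lv1={"artery": net})
    (tree,) = merge_levels(forest, "artery")
    assert tree.n_edges == 1
    assert tree.label == "X"


# -- Strahler --------------------------------------------------------------


def test_single_edge_order_one():
    tree = make_tree([-1], [1.0], [0.5])
    res = strahler_order(tree)
    assert res.orders[0] == 1
    assert len(res.elements) == 1
    assert res.table.iloc[0]["n_elem"] == 1


def test_perfect_binary_tree_orders_retained():
    """Murray-scaled generations have well-separated diameters, so the
    diameter pass keeps the classic orders 1..5."""
    tree = perfect_binary_tree(depth=4)
    res = strahler_order(tree)
    assert res.converged
    # classic Strahler of a perfect tree: order = 5 - generation
    gen = np.zeros(tree.n_edges, dtype=int)
    for e in tree.topo_order():
        p = tree.parent[e]
        gen[e] = gen[p] + 1 if p >= 0 else 0
    np.testing.assert_array_equal(res.orders, 5 - gen)
    tab = res.table.set_index("order")
    assert list(tab.index) == [1, 2, 3, 4, 5]
    np.testing.assert_array_equal(tab["n_elem"], [16, 8, 4, 2, 1])


def test_unbranched_path_merges_into_one_element():
    tree = make_tree([-1, 0, 1], [1, 1, 1], [0.5, 0.5, 0.5])
    res = strahler_order(tree)
    assert np.all(res.orders == 1)
    assert len(res.elements) == 1
    assert res.elements.iloc[0]["length"] == 3.0


def test_terminals_pinned_at_one(small_run):
    trees = merge_levels(small_run["forest"], "artery")
    for t in trees[:3]:
        res = strahler_order(t)
        assert np.all(res.orders[t.terminal_mask] == 1)
        root = int(np.nonzero(t.parent == -1)[0][0])
        assert res.orders[root] == res.orders.max()


def test_mean_element_diameter_increases_with_order(small_run):
    trees = merge_levels(small_run["forest"], "artery")
    tab = mm.pooled_order_table([strahler_order(t) for t in trees])
    d = tab.sort_values("order")["mean_d"].to_numpy()
    assert np.all(np.diff(d) > 0)


# -- Horton fits -----------------------------------------------------------


def test_exact_exponential_recovery():
    orders = np.arange(1, 7)
    q = 10 ** (0.2 + 0.15 * orders)
    tab = pd.DataFrame({"order": orders, "mean_d": q, "mean_l": q, "n_elem": q})
    fit = horton_fit(tab, "d")
    assert fit.intercept == pytest.approx(0.2, abs=1e-12)
    assert fit.slope == pytest.approx(0.15, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.orders == (1, 2, 3, 4, 5)


def test_constant_gives_zero_slope():
    tab = pd.DataFrame(
        {"order": [1, 2, 3, 4], "mean_d": [2.0] * 4, "mean_l": [1] * 4, "n_elem": [1] * 4}
    )
    assert horton_fit(tab, "d").slope == pytest.approx(0.0, abs=1e-14)


def test_high_range_excludes_last_order():
    orders = np.arange(1, 10)
    tab = pd.DataFrame(
        {"order": orders, "mean_d": 10.0 ** orders, "mean_l": orders, "n_elem": orders}
    )
    fit = horton_fit(tab, "d", order_range="high")
    assert fit.orders == (6, 7, 8)  # 9 dropped as the last order


def test_too_few_orders_marked_unavailable():
    tab = pd.DataFrame({"order": [1], "mean_d": [1.0], "mean_l": [1.0], "n_elem": [1]})
    assert not horton_fit(tab, "d").available


def test_noisy_exponential_slope_recovery():
    """Monte-Carlo: multiplicative lognormal noise, recovered slope unbiased."""
    rng = np.random.default_rng(31)
    b_true, slopes, ses = 0.12, [], []
    orders = np.arange(1, 9, dtype=float)
    for _ in range(100):
        q = 10 ** (0.3 + b_true * orders) * np.exp(rng.normal(0, 0.05, len(orders)))
        tab = pd.DataFrame({"order": orders, "mean_d": q, "mean_l": q, "n_elem": q})
        fit = horton_fit(tab, "d", exclude_last=False)
        # include orders beyond 5 by fitting manually over all orders
        slopes.append(fit.slope)
    slopes = np.asarray(slopes)
    se = slopes.std(ddof=1) / np.sqrt(len(slopes))
    assert abs(slopes.mean() - b_true) < 2 * se + 1e-3


# -- terminal diameters ----------------------------------------------------


def test_terminal_stats_median():
    from mrcvasc.vessels import VesselNetwork

    net = VesselNetwork("artery", "LV1")
    for d in (1.0, 2.0, 3.0):
        e = net.add_tree(np.array([[0.0, 0, 0], [1.0, 0, 0]]), a_root=d / 2, subregion=0)
        net.S[e] = 1.0
    stats = terminal_diameter_stats([net])
    assert stats["median"] == 2.0
    assert stats["min"] == 1.0 and stats["max"] == 3.0


def test_single_terminal_all_quartiles_equal():
    from mrcvasc.vessels import VesselNetwork

    net = VesselNetwork("vein", "LV1")
    e = net.add_tree(np.array([[0.0, 0, 0], [1.0, 0, 0]]), a_root=0.7, subregion=0)
    net.S[e] = 1.0
    st = terminal_diameter_stats([net])
    assert st["min"] == st["q1"] == st["median"] == st["q3"] == st["max"]


def test_lv2_terminals_thinner_than_lv1(small_run):
    forest = small_run["forest"]
    lv1 = terminal_diameter_stats([forest.lv1["artery"]])
    lv2 = terminal_diameter_stats(
        [n for (t, _), n in forest.lv2.items() if t == "artery"]
    )
    assert lv2["median"] < lv1["median"]


# -- whole-path metrics ----------------------------------------------------


def test_straight_path_zero_tortuosity():
    tree = make_tree(
        [-1, 0], [1.0, 1.0], [1.0, 0.8], tips=[[1, 0, 0], [2, 0, 0]]
    )
    pm = path_metrics([tree])
    assert pm.per_terminal.iloc[0]["tortuosity"] == pytest.approx(0.0, abs=1e-12)
    assert pm.per_terminal.iloc[0]["C"] == 2.0


def test_semicircle_tortuosity_closed_form():
    theta = np.linspace(0, np.pi, 201)
    r = 5.0
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), 0 * theta], axis=1)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    parent = [-1] + list(range(199))
    tree = make_tree(
        parent, seglen, np.ones(200), tips=pts[1:], root_pos=pts[0]
    )
    pm = path_metrics([tree])
    tort = pm.per_terminal.iloc[-1]["tortuosity"]
    assert tort == pytest.approx(np.pi / 2 - 1, abs=1e-3)


def test_c_at_least_l_for_all_terminals(small_run):
    trees = merge_levels(small_run["forest"], "artery")
    pm = path_metrics(trees)
    assert (pm.per_terminal["C"] >= pm.per_terminal["L"] - 1e-9).all()
    assert (pm.per_terminal["tortuosity"] >= -1e-12).all()


def test_bifurcation_count_on_known_tree():
    #       0 -- 1 -- terminal
    #         \- 2 -- terminal
    tree = make_tree(
        [-1, 0, 0], [1, 1, 1], [1, 0.8, 0.8],
        tips=[[1, 0, 0], [2, 0, 0], [1, 1, 0]],
    )
    pm = path_metrics([tree])
    assert set(pm.per_terminal["n_bifurcations"]) == {1}


# -- territories -----------------------------------------------------------


def test_root_count_ratios_from_printed_counts():
    counts = {"LACA": 18, "RACA": 18, "LMCA": 33, "RMCA": 41, "LPCA": 8, "RPCA": 11}
    df = root_count_ratios(counts).set_index("label")
    assert df.loc["LACA", "ratio_to_reference"] == pytest.approx(2.25)
    assert df.loc["RACA", "ratio_to_reference"] == pytest.approx(18 / 11, abs=5e-3)
    assert df.loc["LMCA", "ratio_to_reference"] == pytest.approx(33 / 8, abs=5e-3)
    assert df.loc["RMCA", "ratio_to_reference"] == pytest.approx(41 / 11, abs=5e-3)
    assert np.isnan(df.loc["LPCA", "ratio_to_reference"])


def test_territory_areas_sum_to_total(small_run):
    rep = territory_report(small_run["forest"], small_run["lv1"])
    assert rep["area_mm2"].sum() == pytest.approx(
        small_run["surface"].total_area, rel=1e-9
    )
    assert rep["n_roots"].sum() == 6


def test_single_label_degenerate_territory():
    """All roots sharing one label own the whole surface."""
    from mrcvasc.growth import VesselForest
    from mrcvasc.vessels import VesselNetwork
    from mrcvasc.partition import SubregionPartition

    net = VesselNetwork("artery", "LV1")
    e = net.add_tree(np.array([[0.0, 0, 0], [1.0, 0, 0]]), 1.0, 0, label="LMCA")
    net.S[e] = 4.0
    part = SubregionPartition(
        labels=np.zeros(4, dtype=int),
        areas=np.array([4.0]),
        seeds=np.array([0]),
    )
    rep = territory_report(VesselForest(lv1={"artery": net}), part)
    assert rep.iloc[0]["area_mm2"] == 4.0
    assert np.isnan(rep.iloc[0]["ratio_to_reference"])  # no PCA label present


def test_two_pole_territories_split_sphere(sphere20, sphere20_field):
    """Two labelled roots at opposite poles split the area roughly in half."""
    from mrcvasc.growth import grow_level, _root_polyline
    from mrcvasc.growth import VesselForest
    from mrcvasc.partition import partition_subregions
    from mrcvasc.roots import RootEdge

    fractions = []
    for seed in range(5):
        part = partition_subregions(sphere20, 40, 100 + seed)
        roots = []
        for label, pole in (("LMCA", [0, 0, 20.0]), ("LPCA", [0, 0, -20.0])):
            proj, _ = sphere20_field.project_to_surface(np.array(pole, float)[None])
            end = proj[0]
            roots.append(
                RootEdge(end * 1.02, end, 1.0, "artery", label)
            )
        rts = [(_root_polyline(r, sphere20_field), r.radius, r.label) for r in roots]
        net, _ = grow_level(
            rts, part, sphere20, sphere20_field,
            vessel_type="artery", level="LV1", budget=80, limits=(1, 6),
            l_th=25.0, psi_th=1.0, rng=np.random.default_rng(seed),
        )
        rep = territory_report(
            VesselForest(lv1={"artery": net}), part
        ).set_index("label")
        fractions.append(rep.loc["LMCA", "area_mm2"] / sphere20.total_area)
    assert np.mean(np.abs(np.array(fractions) - 0.5)) < 0.15
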