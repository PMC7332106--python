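"""Vascular subregion partitions by seeded region growing.

The surface is divided into N_d edge-connected patches D_i ("vascular
subregions" / vascular units): seed triangles are drawn at random, then grown
over the triangle adjacency graph by a multi-source shortest-hop expansion
(ties broken by lower triangle index, which makes the partition deterministic
for a given seed).  Nested second-level partitions reuse the same routine on
the member triangles of each first-level subregion.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surface import TriSurface


@dataclass
class SubregionPartition:
    """Per-triangle labels i ∈ [0, N_d) with subregion areas |D_i| (mm^2)."""

    labels: np.ndarray  # (F,) int, subregion index per triangle
    areas: np.ndarray  # (N_d,) mm^2
    seeds: np.ndarray  # (N_d,) seed triangle per subregion
    level: str = "LV1"

    @property
    def n_subregions(self) -> int:
        return len(self.areas)

    def members(self, i: int) -> np.ndarray:
        return np.nonzero(self.labels == i)[0]


def _region_grow(
    adjacency: list[list[int]],
    seeds: np.ndarray,
    n_triangles: int,
    triangle_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Multi-source hop-count expansion; ties go to the lower triangle index.

    ``triangle_ids`` maps local indices to global ones so the tie rule stays
    global when growing inside a restricted triangle subset.
    """
    tid = triangle_ids if triangle_ids is not None else np.arange(n_triangles)
    labels = np.full(n_triangles, -1, dtype=np.int64)
    heap: list[tuple[int, int, int, int]] = []
    for lab, s in enumerate(seeds):
        heapq.heappush(heap, (0, int(tid[s]), int(s), lab))
    while heap:
        d, _, t, lab = heapq.heappop(heap)
        if labels[t] != -1:
            continue
        labels[t] = lab
        for nb in adjacency[t]:
            if labels[nb] == -1:
                heapq.heappush(heap, (d + 1, int(tid[nb]), int(nb), lab))
    return labels


def partition_subregions(
    surface: TriSurface,
    n_subregions: int,
    rng: np.random.Generator | int,
    level: str = "LV1",
    _adjacency: list[list[int]] | None = None,
) -> SubregionPartition:
    """Partition the surface into ``n_subregions`` connected patches."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nf = surface.n_triangles
    if not (1 <= n_subregions <= nf):
        raise ValueError(
            f"n_subregions must be in [1, {nf}], got {n_subregions}"
        )
    adj = _adjacency if _adjacency is not None else surface.triangle_adjacency()
    seeds = np.sort(rng.choice(nf, size=n_subregions, replace=False))
    labels = _region_grow(adj, seeds, nf)
    if np.any(labels < 0):
        raise RuntimeError("region growing left unlabeled triangles (mesh not connected?)")
    areas = np.bincount(labels, weights=surface.triangle_areas, minlength=n_subregions)
    return SubregionPartition(labels=labels, areas=areas, seeds=seeds, level=level)


def partition_nested(
    surface: TriSurface,
    lv1: SubregionPartition,
    n_per_parent: int,
    rng: np.random.Generator | int,
) -> dict[int, SubregionPartition]:
    """Second-level partitions, one per LV1 subregion, on its member triangles.

    Each returned partition's ``labels`` is indexed by *local* member-triangle
    position; ``members_of`` the parent gives the global triangle ids in the
    same order.  Subregion count is capped at the member count for tiny
    parents.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    adj_global = surface.triangle_adjacency()
    out: dict[int, SubregionPartition] = {}
    for i in range(lv1.n_subregions):
        tris = lv1.members(i)
        local = {int(t): j for j, t in enumerate(tris)}
        adj = [
            [local[nb] for nb in adj_global[t] if nb in local] for t in tris
        ]
        nd = min(n_per_parent, len(tris))
        seeds = np.sort(rng.choice(len(tris), size=nd, replace=False))
        labels = _region_grow(adj, seeds, len(tris), triangle_ids=tris)
        areas = np.bincount(
            labels, weights=surface.triangle_areas[tris], minlength=nd
        )
        out[i] = SubregionPartition(
            labels=labels, areas=areas, seeds=tris[seeds], level=f"LV2@{i}"
        )
    return out


def export_labels(
    lv1: SubregionPartition,
    lv2: dict[int, SubregionPartition] | None,
    surface: TriSurface,
    path: str,
) -> None:
    """Write the per-triangle label table (triangle_id, lv1_label, lv2_label)."""
    lv2_col = np.full(surface.n_triangles, -1, dtype=np.int64)
    if lv2 is not None:
        for i, part in lv2.items():
            lv2_col[lv1.members(i)] = part.labels
    pd.DataFrame(
        {
            "triangle_id": np.arange(surface.n_triangles),
            "lv1_label": lv1.labels,
            "lv2_label": lv2_col,
        }
    ).to_csv(path, index=False)
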