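"""End-to-end scenario runners and configuration.

Three stock scenarios:

``table1_scaled``
    The desk-scale reference run: a smooth synthetic hemisphere pair of
    ~10^4 mm², 400 coarse (LV1) subregions with ~20 nested fine (LV2)
    subregions each, 12 arterial + 12 venous roots of ~1 mm radius, α = 2 and
    2.4×10^4 total terminals.  This preserves the reference
    parameterization's structural ratios at a scale that runs in minutes.
``nu_sweep``
    The same run at several values of the coarse subregion count N_u,
    probing the insensitivity of Horton's-law parameters to N_u.
``fold_compare``
    Matched-seed runs on a folded vs a smooth surface (same terminal count),
    probing the effect of cortical folding on whole-path tortuosity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import morphometry as mm
from .growth import GrowthConfig, VesselForest, run_mrc
from .partition import SubregionPartition, export_labels, partition_nested, partition_subregions
from .roots import RootEdge, load_roots, save_roots, synthesize_roots
from .sdf import DistanceField, build_distance_field
from .surface import TriSurface, load_surface, make_synthetic_surface
from .vessels import edges_frame, subpoints_frame, write_vtk_polydata


class ConfigError(ValueError):
    """Scenario configuration is malformed."""


@dataclass
class SurfaceSpec:
    path: str | None = None
    semi_axes: tuple[float, float, float] = (34.0, 27.0, 24.0)
    fold_amplitude: float = 0.0
    fold_wavenumber: int = 8
    subdivisions: int = 5

    def build(self) -> TriSurface:
        if self.path is not None:
            return load_surface(self.path)
        return make_synthetic_surface(
            semi_axes=tuple(self.semi_axes),
            fold_amplitude=self.fold_amplitude,
            fold_wavenumber=self.fold_wavenumber,
            subdivisions=self.subdivisions,
        )


@dataclass
class RootSpec:
    path: str | None = None
    artery_labels: dict[str, int] = field(
        default_factory=lambda: {
            "LACA": 2, "RACA": 2, "LMCA": 2, "RMCA": 2, "LPCA": 2, "RPCA": 2
        }
    )
    vein_labels: dict[str, int] = field(
        default_factory=lambda: {f"V{i}": 2 for i in range(6)}
    )
    radius_mean: float = 1.0
    radius_sd: float = 0.2
    min_separation: float = 12.0

    def build(
        self, surface: TriSurface, fieldref: DistanceField, seed: int
    ) -> list[RootEdge]:
        if self.path is not None:
            return load_roots(self.path)
        counts = {("artery", lab): n for lab, n in self.artery_labels.items()}
        counts |= {("vein", lab): n for lab, n in self.vein_labels.items()}
        return synthesize_roots(
            surface,
            fieldref,
            counts,
            seed,
            radius_mean=self.radius_mean,
            radius_sd=self.radius_sd,
            min_separation=self.min_separation,
        )


@dataclass
class ScenarioSpec:
    name: str = "custom"
    surface: SurfaceSpec = field(default_factory=SurfaceSpec)
    roots: RootSpec = field(default_factory=RootSpec)
    growth: GrowthConfig = field(default_factory=lambda: GrowthConfig(n_terminals_total=24_000))
    grid_h: float = 0.5
    grid_margin: float = 3.0
    out_prefix: str = "mrcvasc_out"
    seeds: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ConfigError("seed list must be non-empty")

    def config_hash(self) -> str:
        payload = json.dumps(_spec_to_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _spec_to_dict(spec: ScenarioSpec) -> dict:
    return dataclasses.asdict(spec)


_SECTIONS = {"surface": SurfaceSpec, "roots": RootSpec, "growth": GrowthConfig}


def load_config(path: str) -> ScenarioSpec:
    """Read a YAML/JSON scenario file; unknown keys are rejected."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    kwargs: dict = {}
    top_fields = {f.name for f in dataclasses.fields(ScenarioSpec)}
    for key, val in raw.items():
        if key not in top_fields:
            raise ConfigError(f"{path}: unknown key '{key}'")
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            names = {f.name for f in dataclasses.fields(cls)}
            if not isinstance(val, dict):
                raise ConfigError(f"{path}: section '{key}' must be a mapping")
            for sub in val:
                if sub not in names:
                    raise ConfigError(f"{path}: unknown key '{key}.{sub}'")
            try:
                sub_obj = cls(**val)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{path}: section '{key}': {exc}") from exc
            kwargs[key] = sub_obj
        else:
            kwargs[key] = tuple(val) if key == "seeds" else val
    try:
        return ScenarioSpec(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(spec: ScenarioSpec, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_spec_to_dict(spec), f, sort_keys=True)


# -- building blocks -------------------------------------------------------

_SURFACE_CACHE: dict[tuple, tuple[TriSurface, DistanceField]] = {}


def build_substrate(
    surface_spec: SurfaceSpec, grid_h: float = 0.5, grid_margin: float = 3.0
) -> tuple[TriSurface, DistanceField]:
    """Surface + SDF, cached per process (both are seed-independent)."""
    key = (
        surface_spec.path,
        tuple(surface_spec.semi_axes),
        surface_spec.fold_amplitude,
        surface_spec.fold_wavenumber,
        surface_spec.subdivisions,
        grid_h,
        grid_margin,
    )
    if key not in _SURFACE_CACHE:
        surf = surface_spec.build()
        fieldref = build_distance_field(surf, h=grid_h, margin=grid_margin)
        _SURFACE_CACHE[key] = (surf, fieldref)
    return _SURFACE_CACHE[key]


@dataclass
class RunResult:
    seed: int
    surface: TriSurface
    fieldref: DistanceField
    lv1_partition: SubregionPartition
    lv2_partitions: dict[int, SubregionPartition]
    roots: list[RootEdge]
    forest: VesselForest
    arterial_trees: list[mm.MergedTree]
    strahler: list[mm.StrahlerResult]
    order_table: "object"
    horton: dict[str, mm.HortonFit]
    paths: mm.PathMetrics


def run_single(spec: ScenarioSpec, seed: int) -> RunResult:
    """One full growth + morphometry run for one seed."""
    surf, fieldref = build_substrate(spec.surface, spec.grid_h, spec.grid_margin)
    ss = np.random.SeedSequence([seed, 0x6D7263])
    s_part, s_nest, s_roots = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    lv1 = partition_subregions(surf, spec.growth.n_lv1_subregions, s_part)
    n2 = spec.growth.n_lv2_per_lv1(surf.total_area)
    lv2 = partition_nested(surf, lv1, n2, s_nest)
    roots = spec.roots.build(surf, fieldref, s_roots)
    growth = dataclasses.replace(spec.growth, seed=seed)
    forest = run_mrc(surf, fieldref, lv1, lv2, roots, growth)
    trees = mm.merge_levels(forest, "artery")
    strahler = [mm.strahler_order(t) for t in trees]
    table = mm.pooled_order_table(strahler)
    horton = {q: mm.horton_fit(table, q) for q in ("d", "l", "N_elem")}
    paths = mm.path_metrics(trees)
    return RunResult(
        seed=seed,
        surface=surf,
        fieldref=fieldref,
        lv1_partition=lv1,
        lv2_partitions=lv2,
        roots=roots,
        forest=forest,
        arterial_trees=trees,
        strahler=strahler,
        order_table=table,
        horton=horton,
        paths=paths,
    )


def write_artifacts(result: RunResult, spec: ScenarioSpec, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_roots(result.roots, out / "roots.csv")
    export_labels(result.lv1_partition, result.lv2_partitions, result.surface, out / "subregions.csv")
    nets = result.forest.networks()
    import pandas as pd

    pd.concat([edges_frame(n) for n in nets], ignore_index=True).to_csv(
        out / "edges.csv", index=False
    )
    pd.concat([subpoints_frame(n) for n in result.forest.lv1.values()]).to_csv(
        out / "subpoints_lv1.csv", index=False
    )
    write_vtk_polydata(nets, str(out / "forest.vtk"))
    result.order_table.to_csv(out / "strahler_orders.csv", index=False)
    pd.DataFrame(
        [
            {
                "quantity": q,
                "range": "1-5",
                "a": f.intercept,
                "b": f.slope,
                "R2": f.r_squared,
            }
            for q, f in result.horton.items()
        ]
    ).to_csv(out / "horton_fits.csv", index=False)
    result.paths.per_terminal.to_csv(out / "path_metrics.csv", index=False)
    mm.territory_report(result.forest, result.lv1_partition).to_csv(
        out / "territories.csv", index=False
    )
    log_rows = []
    for ctx, log in result.forest.logs.items():
        for rec in log.insertions:
            log_rows.append(
                {
                    "context": ctx,
                    "step": rec.step,
                    "subregion": rec.subregion,
                    "closest_edge": rec.closest_edge,
                    "distance_mm": rec.distance,
                    "pattern": rec.pattern,
                    "E1": rec.scores[0],
                    "E2": rec.scores[1],
                    "E3": rec.scores[2],
                    "E4": rec.scores[3],
                    "rejections": rec.rejections_d,
                }
            )
    pd.DataFrame(log_rows).to_csv(out / "growth_log.csv", index=False)
    rejections = {
        k: log.rejections_distance for k, log in result.forest.logs.items()
    }
    manifest = {
        "scenario": spec.name,
        "seed": result.seed,
        "config_hash": spec.config_hash(),
        "n_terminals": sum(
            len(n.terminal_ids()) for n in result.forest.lv2.values()
        ),
        "surface_area_mm2": result.surface.total_area,
        "rejections_distance": rejections,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)


def run_scenario(spec: ScenarioSpec, write: bool = True) -> list[RunResult]:
    """Run every seed of a scenario; optionally write one directory per seed."""
    results = []
    for seed in spec.seeds:
        res = run_single(spec, seed)
        if write:
            write_artifacts(res, spec, Path(spec.out_prefix) / f"seed_{seed}")
        results.append(res)
    return results


# -- stock scenarios -------------------------------------------------------


def table1_scaled_spec(
    seeds: tuple[int, ...] = (1, 2, 3),
    n_terminals: int = 24_000,
    n_lv1: int = 400,
    subdivisions: int = 5,
    grid_h: float = 0.5,
    fold_amplitude: float = 0.0,
    out_prefix: str = "mrcvasc_out/table1_scaled",
) -> ScenarioSpec:
    return ScenarioSpec(
        name="table1_scaled",
        surface=SurfaceSpec(
            fold_amplitude=fold_amplitude, subdivisions=subdivisions
        ),
        roots=RootSpec(),
        growth=GrowthConfig(
            n_terminals_total=n_terminals, n_lv1_subregions=n_lv1
        ),
        grid_h=grid_h,
        seeds=seeds,
        out_prefix=out_prefix,
    )


def nu_sweep_specs(
    nu_values: tuple[int, ...] = (200, 400, 800),
    seed: int = 1,
    n_terminals: int = 24_000,
    **kw,
) -> list[ScenarioSpec]:
    """The N_u sensitivity experiment: same total scale, varying N_d(LV1)."""
    return [
        dataclasses.replace(
            table1_scaled_spec(seeds=(seed,), n_terminals=n_terminals, n_lv1=nu, **kw),
            name=f"nu_sweep/{nu}",
        )
        for nu in nu_values
    ]


def fold_compare_specs(
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    fold_amplitude: float = 2.0,
    n_terminals: int = 24_000,
    n_lv1: int = 400,
    **kw,
) -> tuple[ScenarioSpec, ScenarioSpec]:
    """Folded ("actual"-style) vs smooth ("simplified"-style) surface pair at
    matched seeds and equal total terminal count."""
    folded = dataclasses.replace(
        table1_scaled_spec(
            seeds=seeds, n_terminals=n_terminals, n_lv1=n_lv1,
            fold_amplitude=fold_amplitude, **kw
        ),
        name="fold_compare/folded",
    )
    smooth = dataclasses.replace(
        table1_scaled_spec(
            seeds=seeds, n_terminals=n_terminals, n_lv1=n_lv1,
            fold_amplitude=0.0, **kw
        ),
        name="fold_compare/smooth",
    )
    return folded, smooth
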