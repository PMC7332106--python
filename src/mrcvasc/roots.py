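"""Root vessels feeding the surface growth.

Each root edge is a straight segment from an off-surface start position (a
stand-in for a macroscale terminal branch) to an end point on the surface Γ.
The synthetic generator places root ends area-uniformly (optionally with a
minimum mutual separation), assigns major-artery style labels, and draws
mm-scale radii.  Real macroscale terminals, when available as a table, are
extended to the surface along the distance-field direction; extensions longer
than a drop threshold are treated as not supplying this surface and removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sdf import DistanceField
from .surface import TriSurface, sample_barycentric


@dataclass(frozen=True)
class RootEdge:
    start: np.ndarray  # (3,) mm
    end: np.ndarray  # (3,) mm, on/near Γ
    radius: float  # mm
    vessel_type: str  # "artery" | "vein"
    label: str  # e.g. LACA/RACA/LMCA/RMCA/LPCA/RPCA, or synthetic
    origin: str = "image-surrogate"  # or "inherited-from-level"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("root radius must be positive")
        if self.vessel_type not in ("artery", "vein"):
            raise ValueError(f"unknown vessel type {self.vessel_type!r}")
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=float))


def synthesize_roots(
    surface: TriSurface,
    field: DistanceField,
    counts: dict[tuple[str, str], int],
    rng: np.random.Generator | int,
    radius_mean: float = 1.0,
    radius_sd: float = 0.2,
    start_offset: float = 0.8,
    min_separation: float = 0.0,
    max_attempts: int = 10_000,
) -> list[RootEdge]:
    """Draw labelled synthetic roots with ends on the surface.

    ``counts`` maps (vessel_type, label) to the number of roots requested.
    Ends are sampled area-uniformly on Γ (triangle by area, then uniform
    barycentric point, then projected to Γ); starts sit ``start_offset`` mm
    outward along the surface normal direction so that whole root edges stay
    inside the growth shell for the default ψ_th = 1 mm.  Radii are normal
    (mean, sd) truncated at 0.2·mean.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if any(n < 1 for n in counts.values()):
        raise ValueError("at least one root per (type, label) is required")
    roots: list[RootEdge] = []
    placed: list[np.ndarray] = []
    for (vessel_type, label), n in sorted(counts.items()):
        got = 0
        attempts = 0
        while got < n:
            if attempts > max_attempts:
                raise RuntimeError(
                    "could not place roots with the requested minimum separation"
                )
            attempts += 1
            pts, _ = surface.sample_points(1, rng)
            end, _ = field.project_to_surface(pts)
            end = end[0]
            if min_separation > 0 and placed:
                d = np.linalg.norm(np.asarray(placed) - end, axis=1)
                if d.min() < min_separation:
                    continue
            _, direction = field.query(end)
            start = end + start_offset * direction  # outward: ∇ψ points outside
            radius = max(
                float(rng.normal(radius_mean, radius_sd)), 0.2 * radius_mean
            )
            roots.append(
                RootEdge(
                    start=start,
                    end=end,
                    radius=radius,
                    vessel_type=vessel_type,
                    label=label,
                )
            )
            placed.append(end)
            got += 1
    return roots


def extend_roots_to_surface(
    roots: list[RootEdge],
    field: DistanceField,
    drop_threshold: float,
) -> tuple[list[RootEdge], list[RootEdge]]:
    """Extend each root's end straight to Γ; drop over-long extensions.

    Returns (retained, dropped).  A root already on Γ is unchanged.  The
    extension length is the distance from the old end to its projection; if it
    exceeds ``drop_threshold`` (mm) the vessel is considered not to supply
    this surface.
    """
    retained: list[RootEdge] = []
    dropped: list[RootEdge] = []
    for r in roots:
        psi = float(field.psi_at(r.end.reshape(1, 3))[0])
        if abs(psi) <= field.projection_tolerance:
            retained.append(r)
            continue
        proj, _ = field.project_to_surface(r.end.reshape(1, 3))
        ext = float(np.linalg.norm(proj[0] - r.end))
        if ext > drop_threshold:
            dropped.append(r)
        else:
            retained.append(replace(r, end=proj[0]))
    return retained, dropped


def roots_to_frame(roots: list[RootEdge]) -> pd.DataFrame:
    d = [
        {
            "x": r.end[0],
            "y": r.end[1],
            "z": r.end[2],
            "dir_x": (r.end - r.start)[0],
            "dir_y": (r.end - r.start)[1],
            "dir_z": (r.end - r.start)[2],
            "radius_mm": r.radius,
            "type": r.vessel_type,
            "label": r.label,
        }
        for r in roots
    ]
    return pd.DataFrame(d)


def save_roots(roots: list[RootEdge], path: str) -> None:
    roots_to_frame(roots).to_csv(path, index=False)


def load_roots(path: str) -> list[RootEdge]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        end = np.array([row["x"], row["y"], row["z"]])
        direction = np.array([row["dir_x"], row["dir_y"], row["dir_z"]])
        out.append(
            RootEdge(
                start=end - direction,
                end=end,
                radius=float(row["radius_mm"]),
                vessel_type=str(row["type"]),
                label=str(row["label"]),
            )
        )
    return out
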