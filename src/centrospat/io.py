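"""Spot-table and mask I/O, synthetic-image rendering, and run configuration.

The canonical spot table is a CSV with columns ``cell, x, y`` (0-based pixel
coordinates, sub-pixel precision) plus a companion nucleus table with
columns ``cell, center_x, center_y, radius`` (and optionally ``area,
ellipse_a, ellipse_b, ellipse_phi``).  A ``column_map`` option renames
non-canonical headers from other pipelines on ingestion.  Label masks are
16-bit TIFFs with background 0 and one positive label per nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import Ellipse, InvalidParameterError, NucleusRegion, SpotPattern

SPOT_COLUMNS = ("cell", "x", "y")
NUCLEUS_COLUMNS = ("cell", "center_x", "center_y", "radius")


class SchemaError(InvalidParameterError):
    """A table is missing required columns or contains invalid values."""


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def write_spot_table(patterns: list[SpotPattern], spots_path, nuclei_path=None):
    """Write patterns as spot + nucleus CSV tables (cell ids 0..n-1 unless
    the regions carry labels)."""
    spot_rows, nuc_rows = [], []
    for i, p in enumerate(patterns):
        cid = p.region.label if p.region.label is not None else i
        for x, y in p.spots:
            spot_rows.append((cid, x, y))
        e = p.region.ellipse
        nuc_rows.append(
            (
                cid,
                p.region.center[0],
                p.region.center[1],
                p.region.radius,
                p.region.area,
                e.a if e else np.nan,
                e.b if e else np.nan,
                e.phi if e else np.nan,
                p.provenance,
            )
        )
    pd.DataFrame(spot_rows, columns=list(SPOT_COLUMNS)).to_csv(spots_path, index=False)
    if nuclei_path is not None:
        pd.DataFrame(
            nuc_rows,
            columns=[
                "cell",
                "center_x",
                "center_y",
                "radius",
                "area",
                "ellipse_a",
                "ellipse_b",
                "ellipse_phi",
                "provenance",
            ],
        ).to_csv(nuclei_path, index=False)


def read_spot_table(
    spots_path, nuclei_path=None, column_map: dict | None = None
) -> list[SpotPattern]:
    """Read spot (and optional nucleus) CSVs back into SpotPatterns.

    Without a nucleus table, each cell's region is the enclosing circle of
    its spots (centroid center, max spot distance + 1 px radius).
    """
    spots = pd.read_csv(spots_path)
    if column_map:
        spots = spots.rename(columns=column_map)
    _require_columns(spots, SPOT_COLUMNS, "spot table")
    for c in ("x", "y"):
        if not np.issubdtype(spots[c].dtype, np.number):
            raise SchemaError(f"spot column {c!r} is not numeric")
    if spots[["x", "y"]].isna().any().any() or not np.isfinite(
        spots[["x", "y"]].to_numpy()
    ).all():
        raise SchemaError("spot coordinates must be finite")

    nuclei = None
    if nuclei_path is not None:
        nuclei = pd.read_csv(nuclei_path)
        if column_map:
            nuclei = nuclei.rename(columns=column_map)
        _require_columns(nuclei, NUCLEUS_COLUMNS, "nucleus table")
        orphans = set(spots["cell"]) - set(nuclei["cell"])
        if orphans:
            raise SchemaError(f"spot rows reference unknown cell id(s): {sorted(orphans)}")

    patterns = []
    for cid, sub in spots.groupby("cell", sort=False):
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        if nuclei is not None:
            row = nuclei[nuclei["cell"] == cid].iloc[0]
            ellipse = None
            if "ellipse_a" in row and np.isfinite(row.get("ellipse_a", np.nan)):
                ellipse = Ellipse(row["ellipse_a"], row["ellipse_b"], row["ellipse_phi"])
            region = NucleusRegion(
                center=(float(row["center_x"]), float(row["center_y"])),
                radius=float(row["radius"]),
                ellipse=ellipse,
                label=cid,
            )
            prov = str(row["provenance"]) if "provenance" in row else "observed"
        else:
            center = xy.mean(axis=0)
            radius = float(np.linalg.norm(xy - center, axis=1).max() + 1.0)
            region = NucleusRegion(center=tuple(center), radius=radius, label=cid)
            prov = "observed"
        patterns.append(SpotPattern(region, xy, prov))
    return patterns


def read_nucleus_mask(path) -> list[NucleusRegion]:
    """Regions (centroid, equivalent radius, moment ellipse) from a label TIFF."""
    from .models import region_from_mask

    labels = np.asarray(tifffile.imread(path))
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise InvalidParameterError("mask contains no labelled nuclei")
    return [region_from_mask(labels == i, label_value=int(i)) for i in ids]


def write_label_mask(regions: list[NucleusRegion], shape, path):
    """Rasterize circular regions into a 16-bit label TIFF."""
    out = np.zeros(shape, dtype=np.uint16)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, r in enumerate(regions, start=1):
        m = (xx - r.center[0]) ** 2 + (yy - r.center[1]) ** 2 <= r.radius**2
        out[m] = r.label if isinstance(r.label, (int, np.integer)) else i
    tifffile.imwrite(path, out)
    return out


def render_spot_image(
    pattern: SpotPattern, blob_sigma: float = 2.0, shape=(256, 256)
) -> np.ndarray:
    """Render spots as Gaussian blobs on a black 16-bit canvas."""
    h, w = shape
    xy = pattern.spots
    if (xy[:, 0] < 0).any() or (xy[:, 0] > w - 1).any() or (
        xy[:, 1] < 0
    ).any() or (xy[:, 1] > h - 1).any():
        raise InvalidParameterError("spots fall outside the canvas")
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(4 * blob_sigma))
    win = np.arange(-half, half + 1)
    gx, gy = np.meshgrid(win, win)
    for x, y in xy:
        xi, yi = int(round(x)), int(round(y))
        blob = np.exp(-((gx + xi - x) ** 2 + (gy + yi - y) ** 2) / (2 * blob_sigma**2))
        y0, y1 = max(0, yi - half), min(h, yi + half + 1)
        x0, x1 = max(0, xi - half), min(w, xi + half + 1)
        img[y0:y1, x0:x1] += blob[
            y0 - (yi - half) : blob.shape[0] - ((yi + half + 1) - y1),
            x0 - (xi - half) : blob.shape[1] - ((xi + half + 1) - x1),
        ]
    img = img / img.max() if img.max() > 0 else img
    return (img * 60000).astype(np.uint16)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {"generators", "metrics", "benchmark", "models", "output"}

_SECTION_KEYS = {
    "generators": {
        "models",
        "n_spots",
        "min_dist",
        "n_perturbed",
        "shift_range",
        "body_radius",
        "cov_size_range",
        "cov_size_step",
        "region_radius",
        "region_center",
    },
    "metrics": {"k", "r_max", "n_steps", "louvain_seed"},
    "benchmark": {"n_patterns", "removals_max", "reference", "seed"},
    "models": {"n_iter", "burn_in", "n_mc", "n_bins", "seed"},
    "output": {"dir", "prefix"},
}


@dataclass
class RunConfig:
    """Validated YAML configuration for the command-line pipelines."""

    generators: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    benchmark: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise SchemaError(f"unknown config section(s): {sorted(unknown)}")
        for section, keys in _SECTION_KEYS.items():
            bad = set(raw.get(section, {})) - keys
            if bad:
                raise SchemaError(f"unknown key(s) in [{section}]: {sorted(bad)}")
        return cls(**{s: raw.get(s, {}) for s in _KNOWN_SECTIONS})

    def to_yaml(self, path):
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "generators": self.generators,
                    "metrics": self.metrics,
                    "benchmark": self.benchmark,
                    "models": self.models,
                    "output": self.output,
                }
            )
        )

    def generator_configs(self):
        from .core import NucleusRegion
        from .simulators import MODEL_IDS, GeneratorConfig

        g = self.generators
        region = NucleusRegion(
            center=tuple(g.get("region_center", (128.0, 128.0))),
            radius=float(g.get("region_radius", 46.0)),
        )
        kwargs = {
            k: g[k]
            for k in ("n_spots", "min_dist", "n_perturbed", "shift_range", "body_radius")
            if k in g
        }
        names = g.get("models", list(MODEL_IDS))
        return {m: GeneratorConfig(model=m, region=region, **kwargs) for m in names}

    def metric_settings(self):
        from .metrics import MetricSettings, RadiiGrid

        m = self.metrics
        grid = None
        if "r_max" in m or "n_steps" in m:
            grid = RadiiGrid(m.get("r_max", 46.0), m.get("n_steps", 50))
        return MetricSettings(
            k=m.get("k", 10), radii=grid, louvain_seed=m.get("louvain_seed", 0)
        )


def make_fixtures(seed: int = 0, region=None) -> dict:
    """Small deterministic datasets for tests and examples.

    Returns one pattern per generator, a doughnut dataset with known
    (r0, sigma) recorded alongside, and a rendered image of the CSR pattern.
    """
    from .core import DEFAULT_REGION
    from .models import RadialGaussianParams, sample_radially_shifted_gaussian
    from .simulators import default_configs, sample_pattern

    region = region or DEFAULT_REGION
    rng = np.random.default_rng(seed)
    patterns = {
        name: sample_pattern(cfg, rng) for name, cfg in default_configs(region).items()
    }
    doughnut_params = RadialGaussianParams(r0=30.0, sigma=8.0)
    doughnut = [
        sample_radially_shifted_gaussian(doughnut_params, region, 46, rng)
        for _ in range(20)
    ]
    return {
        "patterns": patterns,
        "doughnut_cells": doughnut,
        "doughnut_params": doughnut_params,
        "render": render_spot_image(patterns["CSR"]),
    }
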