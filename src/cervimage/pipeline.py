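"""End-to-end pipeline wiring: configuration, manifests, batch runs.

A run is described by a :class:`RunConfig` (YAML on disk) pointing at a
manifest CSV.  The manifest has one row per acquired image:

    sample_id,image_id,group,boundary_path,<channel columns...>

where each channel column (e.g. ``DAPI``, ``E-cadherin``, ``CD4``,
``CCR5``) holds the path of that channel's image file.  Physical pixel
size and all analysis parameters live in the config, never in code.

Failure semantics: a malformed boundary file or missing image fails
that image only; the run continues, errors are collected, and the CLI
exit status reflects partial failure.  Manual annotation files are the
error-prone input, so fail-fast would discard good data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .depth_profile import (
    SegmentScheme,
    assign_depth_bins,
    double_positive,
    profile_segments,
    threshold_marker,
)
from .geometry import (
    ChannelImage,
    build_epithelium_mask,
    distance_from_boundary,
    measure_thickness,
)
from .stats import mann_whitney

__all__ = [
    "RunConfig",
    "RunError",
    "run_thickness",
    "run_profile",
    "run_simulate",
    "aggregate_per_sample",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable run configuration (YAML round-trip safe)."""

    manifest: str = ""
    pixel_size_um: float = 1.0
    bin_width_um: float = 50.0
    apical_exclusion_um: float = 10.0
    cap_um: float = 300.0
    threshold_method: str = "otsu"
    threshold_params: dict = field(default_factory=dict)
    markers: list = field(default_factory=list)
    double_pairs: list = field(default_factory=list)
    summary_statistic: str = "median"
    output_dir: str = "cervimage_out"
    seed: int = 0
    log_level: str = "INFO"

    @property
    def scheme(self) -> SegmentScheme:
        return SegmentScheme(
            bin_width_um=self.bin_width_um,
            apical_exclusion_um=self.apical_exclusion_um,
            cap_um=self.cap_um,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class RunError:
    """A collected per-image failure."""

    sample_id: str
    image_id: str
    stage: str
    message: str


def _read_manifest(config: RunConfig) -> pd.DataFrame:
    mf = pd.read_csv(config.manifest, dtype=str)
    required = {"sample_id", "image_id", "group", "boundary_path"}
    missing = required - set(mf.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if mf["image_id"].duplicated().any():
        raise ValueError("manifest image_id values must be unique")
    return mf


def _load_channels(row: pd.Series, config: RunConfig, names: list[str]) -> dict[str, ChannelImage]:
    out = {}
    for name in names:
        path = row.get(name)
        if not isinstance(path, str) or not path:
            raise FileNotFoundError(f"manifest row lacks a path for channel {name!r}")
        out[name] = ChannelImage(cio.read_image(path), name, config.pixel_size_um)
    return out


def aggregate_per_sample(per_image: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Pool image-level values to one row per sample (area-weighted mean).

    Multiple sections/ROIs per participant are combined weighting each
    image by its analyzed epithelium area, so a large section counts
    proportionally more than a sliver.
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        w = g["area_mm2"].to_numpy(dtype=float)
        out = {"group": g["group"].iloc[0], "area_mm2": w.sum(), "n_images": len(g)}
        for c in value_cols:
            v = g[c].to_numpy(dtype=float)
            ok = np.isfinite(v) & (w > 0)
            out[c] = float(np.average(v[ok], weights=w[ok])) if ok.any() else np.nan
        return pd.Series(out)

    return per_image.groupby("sample_id").apply(_agg, include_groups=False)


def _group_compare(per_sample: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Mann–Whitney between the two manifest groups for each column."""
    groups = sorted(per_sample["group"].unique())
    rows = []
    if len(groups) == 2:
        ga, gb = groups
        for c in cols:
            a = per_sample.loc[per_sample["group"] == ga, c].dropna().to_numpy()
            b = per_sample.loc[per_sample["group"] == gb, c].dropna().to_numpy()
            try:
                res = mann_whitney(a, b)
                row = res.to_row()
            except ValueError as exc:
                row = dict(test_name="mann_whitney", p_value=np.nan,
                           method_detail=str(exc))
            row["measure"] = c
            row["group_a"], row["group_b"] = ga, gb
            rows.append(row)
    return pd.DataFrame(rows)


def run_thickness(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[RunError]]:
    """Measure layer thicknesses for every manifest image.

    Returns ``(per_image, per_sample, comparisons, errors)``.
    """
    mf = _read_manifest(config)
    rows, errors = [], []
    for _, row in mf.iterrows():
        sid, iid = row["sample_id"], row["image_id"]
        try:
            boundaries = cio.read_boundaries(row["boundary_path"])
            shape_src = next(
                (row[c] for c in mf.columns
                 if c not in ("sample_id", "image_id", "group", "boundary_path")
                 and isinstance(row[c], str) and row[c]),
                None,
            )
            if shape_src is None:
                raise FileNotFoundError("no channel image available to define the grid")
            shape = cio.read_image(shape_src).shape
            mask = build_epithelium_mask(boundaries, shape, config.pixel_size_um)
            res = measure_thickness(boundaries, mask, config.summary_statistic)
            rows.append(dict(
                sample_id=sid, image_id=iid, group=row["group"],
                total_um=res.total_um, ecad_pos_um=res.ecad_pos_um,
                ecad_neg_um=res.ecad_neg_um, area_mm2=mask.area_mm2,
                n_points=res.n_points,
            ))
            logger.info("thickness %s/%s: total=%.1f um", sid, iid, res.total_um)
        except Exception as exc:  # collected, not raised: partial-failure contract
            logger.error("thickness %s/%s failed: %s", sid, iid, exc)
            errors.append(RunError(sid, iid, "thickness", str(exc)))
    per_image = pd.DataFrame(rows)
    cols = ["total_um", "ecad_pos_um", "ecad_neg_um"]
    per_sample = (
        aggregate_per_sample(per_image, cols) if len(per_image) else pd.DataFrame()
    )
    comparisons = _group_compare(per_sample, cols) if len(per_sample) else pd.DataFrame()
    return per_image, per_sample, comparisons, errors


def run_profile(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[RunError]]:
    """Depth-binned marker quantification for every manifest image.

    Returns ``(long_table, per_sample_overall, comparisons, errors)``.
    Double-positive pairs come from ``config.double_pairs`` (list of
    two-marker lists); markers stained in different acquisitions are
    never merged implicitly.
    """
    mf = _read_manifest(config)
    scheme = config.scheme
    long_rows, overall_rows, errors = [], [], []
    for _, row in mf.iterrows():
        sid, iid = row["sample_id"], row["image_id"]
        try:
            boundaries = cio.read_boundaries(row["boundary_path"])
            channels = _load_channels(row, config, list(config.markers))
            shape = next(iter(channels.values())).shape
            mask = build_epithelium_mask(boundaries, shape, config.pixel_size_um)
            depth = distance_from_boundary(mask, boundaries.apical_line, "apical")
            labels = assign_depth_bins(depth, scheme)
            masks = [
                threshold_marker(channels[m], mask, config.threshold_method,
                                 **config.threshold_params)
                for m in config.markers
            ]
            by_name = {m.marker_name: m for m in masks}
            for pair in config.double_pairs:
                a, b = pair
                masks.append(double_positive(by_name[a], by_name[b]))
            prof = profile_segments(masks, labels, mask, scheme)
            long_rows.append(prof.to_frame(sample_id=sid, image_id=iid)
                             .assign(group=row["group"]))
            rec = dict(sample_id=sid, image_id=iid, group=row["group"],
                       area_mm2=mask.area_mm2)
            rec.update({f"{k}_pct": v for k, v in prof.overall_pct.items()})
            overall_rows.append(rec)
        except Exception as exc:
            logger.error("profile %s/%s failed: %s", sid, iid, exc)
            errors.append(RunError(sid, iid, "profile", str(exc)))
    long_table = pd.concat(long_rows, ignore_index=True) if long_rows else pd.DataFrame()
    per_image = pd.DataFrame(overall_rows)
    pct_cols = [c for c in per_image.columns if c.endswith("_pct")]
    per_sample = (
        aggregate_per_sample(per_image, pct_cols) if len(per_image) else pd.DataFrame()
    )
    comparisons = _group_compare(per_sample, pct_cols) if len(per_sample) else pd.DataFrame()
    return long_table, per_sample, comparisons, errors


def run_simulate(spec_dict: dict, outdir, scheme: SegmentScheme | None = None) -> Path:
    """Generate a phantom dataset on disk in the pipeline's own formats.

    Writes one TIFF per channel, the boundary file, truth tables
    (per-segment fractions per marker) and a provenance YAML with the
    spec.  Returns the path of a manifest CSV covering the dataset.
    """
    from .synthetic import PhantomSpec, generate_phantom

    try:
        spec = PhantomSpec(**spec_dict)
    except TypeError as exc:
        raise ValueError(f"invalid phantom spec: {exc}") from exc
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    channels, boundaries, truth = generate_phantom(spec, scheme)

    paths = {}
    for name, ch in channels.items():
        p = outdir / f"{name.replace('/', '_')}.tif"
        cio.write_image(p, ch.pixels)
        paths[name] = str(p)
    bpath = outdir / "boundaries.txt"
    cio.write_boundaries(bpath, boundaries)

    truth_rows = []
    for marker in truth.marker_masks:
        fr = truth.true_bin_fractions(marker)
        for (lo, hi), pct in zip(truth.scheme.intervals(), fr):
            truth_rows.append(dict(marker=marker, bin_lower_um=lo,
                                   bin_upper_um=np.inf if hi is None else hi,
                                   true_fraction_pct=pct))
        truth_rows.append(dict(marker=marker, bin_lower_um=np.nan, bin_upper_um=np.nan,
                               true_fraction_pct=truth.true_overall_fraction(marker)))
    pd.DataFrame(truth_rows).to_csv(outdir / "truth_fractions.csv", index=False)

    prov = dataclasses.asdict(spec)
    prov["marker_bin_fractions"] = {
        k: list(v) for k, v in prov["marker_bin_fractions"].items()
    }
    prov["cell_radius_px"] = list(prov["cell_radius_px"])
    (outdir / "phantom_spec.yaml").write_text(yaml.safe_dump(prov, sort_keys=False))

    manifest = pd.DataFrame([dict(
        sample_id="phantom", image_id="phantom_0", group="A",
        boundary_path=str(bpath), **paths,
    )])
    mpath = outdir / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath
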