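"""Depth-binned quantification of marker-positive area in the epithelium.

The epithelium is partitioned into depth segments counted from the
apical border: a thin apical margin is excluded (background
autofluorescence accumulates at the tissue surface), the remainder is
cut into fixed-width bins, and everything deeper than a cap depth is
pooled into one terminal segment.  With the defaults (50 µm bins, 10 µm
exclusion, 300 µm cap) the segments are [10, 50), [50, 100), ...,
[250, 300), [300, inf).

Marker positivity is pixel-based: a channel is thresholded with an
image-dependent cutoff computed from epithelium pixels only, and the
positively stained area fraction (% of epithelial tissue area) stands in
for cell frequency — appropriate for immune cells with irregular
morphologies where object-level segmentation is unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .geometry import DepthMap, EpitheliumMask, ChannelImage

__all__ = [
    "SegmentScheme",
    "MarkerMask",
    "SegmentProfile",
    "assign_depth_bins",
    "threshold_marker",
    "double_positive",
    "profile_segments",
]

logger = logging.getLogger(__name__)

#: label of pixels outside the epithelium mask
OUTSIDE = -1
#: label of the excluded apical margin
MARGIN = 0


@dataclass(frozen=True)
class SegmentScheme:
    """Depth-binning scheme counted from the apical border.

    ``bin_width_um`` — segment width; ``apical_exclusion_um`` — excluded
    apical margin; ``cap_um`` — depth beyond which all pixels form one
    terminal segment.  ``cap_um`` must be a multiple of ``bin_width_um``.
    """

    bin_width_um: float = 50.0
    apical_exclusion_um: float = 10.0
    cap_um: float = 300.0

    def __post_init__(self) -> None:
        if not (0 <= self.apical_exclusion_um < self.bin_width_um <= self.cap_um):
            raise ValueError(
                "need 0 <= apical_exclusion_um < bin_width_um <= cap_um"
            )
        ratio = self.cap_um / self.bin_width_um
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("cap_um must be an integer multiple of bin_width_um")

    @property
    def n_regular(self) -> int:
        """Number of fixed-width bins (labels 1..n_regular)."""
        return int(round(self.cap_um / self.bin_width_um))

    @property
    def n_labels(self) -> int:
        """Regular bins plus the terminal open-ended bin."""
        return self.n_regular + 1

    def intervals(self) -> list[tuple[float, float | None]]:
        """(lower, upper) of bins 1..n_labels; terminal upper is None."""
        out: list[tuple[float, float | None]] = []
        for k in range(1, self.n_regular + 1):
            lo = self.apical_exclusion_um if k == 1 else (k - 1) * self.bin_width_um
            out.append((lo, k * self.bin_width_um))
        out.append((self.cap_um, None))
        return out


@dataclass
class MarkerMask:
    """Boolean marker-positive pixel mask with its provenance threshold."""

    mask: np.ndarray
    marker_name: str
    threshold_value: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def positive_pixels(self) -> int:
        return int(self.mask.sum())


def assign_depth_bins(depth: DepthMap, scheme: SegmentScheme) -> np.ndarray:
    """Label every epithelium pixel with its depth segment.

    Labels: -1 outside the epithelium, 0 the excluded apical margin
    [0, apical_exclusion_um), 1..K the half-open fixed-width bins, K+1
    the terminal [cap_um, inf) segment.  Requires an apical-referenced
    depth map — depth counted from any other boundary would silently
    invert the segment order.
    """
    if depth.reference != "apical":
        raise ValueError(
            f"assign_depth_bins requires an apical-referenced DepthMap, "
            f"got reference={depth.reference!r}"
        )
    d = depth.depth_um
    labels = np.full(d.shape, OUTSIDE, dtype=int)
    defined = np.isfinite(d)
    dv = d[defined]
    lab = np.floor_divide(dv, scheme.bin_width_um).astype(int) + 1
    lab = np.minimum(lab, scheme.n_labels)
    lab[dv < scheme.apical_exclusion_um] = MARGIN
    labels[defined] = lab
    return labels


def threshold_marker(
    channel: ChannelImage,
    mask: EpitheliumMask,
    method: str = "otsu",
    **params,
) -> MarkerMask:
    """Segment the positively stained area of one marker channel.

    The threshold is computed from epithelium-pixel intensities only
    (image-dependent), and a pixel is positive when its intensity is
    strictly above the threshold.

    Methods
    -------
    ``"otsu"``
        Otsu's between-class-variance maximization (default).  A
        constant-intensity region cannot be split; the mask is then
        all-negative and a warning is logged.
    ``"percentile"``
        Threshold at the given percentile ``q`` of epithelium
        intensities (default 95).
    ``"fixed"``
        Fixed ``threshold`` from params.
    """
    if channel.shape != mask.shape:
        raise ValueError("channel and mask dimensions differ")
    values = channel.pixels[mask.mask]
    if values.size == 0:
        raise ValueError("epithelium mask is empty; cannot compute a threshold")

    if method == "otsu":
        if np.ptp(values) == 0:
            logger.warning(
                "channel %r is constant over the epithelium; Otsu undefined, "
                "returning all-negative mask",
                channel.channel_name,
            )
            thr = float(values[0])
        else:
            thr = float(threshold_otsu(values))
    elif method == "percentile":
        q = float(params.get("q", 95.0))
        thr = float(np.percentile(values, q))
    elif method == "fixed":
        if "threshold" not in params:
            raise ValueError("method 'fixed' requires a 'threshold' parameter")
        thr = float(params["threshold"])
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    pos = mask.mask & (channel.pixels > thr)
    logger.debug("threshold %s on %r -> %.4g", method, channel.channel_name, thr)
    return MarkerMask(mask=pos, marker_name=channel.channel_name, threshold_value=thr)


def double_positive(a: MarkerMask, b: MarkerMask) -> MarkerMask:
    """Pixelwise conjunction of two marker masks (double-positive area)."""
    if a.mask.shape != b.mask.shape:
        raise ValueError("marker masks have different dimensions")
    return MarkerMask(
        mask=a.mask & b.mask,
        marker_name=f"{a.marker_name}+{b.marker_name}+",
        threshold_value=float("nan"),
    )


@dataclass
class SegmentProfile:
    """Positive-area fractions per marker per depth segment.

    ``per_bin_pct[marker]`` holds one percentage per segment (bins
    1..n_labels, apical to basal); NaN marks a segment with zero
    epithelium area (missing, not zero).  ``overall_pct`` uses the full
    epithelium ROI as denominator (total tissue area, margin included);
    ``included_pct`` restricts numerator and denominator to the binned
    region (margin excluded) — the region the per-segment panels cover.
    """

    bins: list[tuple[float, float | None]]
    bin_area_mm2: np.ndarray
    per_bin_pct: dict[str, np.ndarray]
    overall_pct: dict[str, float]
    included_pct: dict[str, float]
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_frame(self, sample_id: str = "", image_id: str = "") -> pd.DataFrame:
        """Long-format table: one row per (marker, segment) plus overall rows."""
        rows = []
        for marker, fracs in self.per_bin_pct.items():
            thr = self.thresholds.get(marker, float("nan"))
            for (lo, hi), area, pct in zip(self.bins, self.bin_area_mm2, fracs):
                rows.append(
                    dict(
                        sample_id=sample_id,
                        image_id=image_id,
                        marker=marker,
                        bin_lower_um=lo,
                        bin_upper_um=np.inf if hi is None else hi,
                        area_mm2=area,
                        positive_fraction_pct=pct,
                        threshold_value=thr,
                    )
                )
            rows.append(
                dict(
                    sample_id=sample_id,
                    image_id=image_id,
                    marker=marker,
                    bin_lower_um=np.nan,
                    bin_upper_um=np.nan,
                    area_mm2=float(self.bin_area_mm2.sum()),
                    positive_fraction_pct=self.overall_pct[marker],
                    threshold_value=thr,
                )
            )
        return pd.DataFrame(rows)


def profile_segments(
    markers: list[MarkerMask],
    labels: np.ndarray,
    mask: EpitheliumMask,
    scheme: SegmentScheme,
) -> SegmentProfile:
    """Per-segment and overall positive-area fractions for each marker.

    Per segment: ``100 * positive_pixels_in_bin / epithelium_pixels_in_bin``.
    Segments without epithelium pixels are NaN.  The overall fraction is
    reported twice: over the full ROI (total tissue area) and over the
    binned (margin-excluded) region.
    """
    if labels.shape != mask.shape:
        raise ValueError("label grid and mask dimensions differ")
    for m in markers:
        if m.mask.shape != mask.shape:
            raise ValueError(f"marker {m.marker_name!r} dimensions differ from mask")
        if np.any(m.mask & ~mask.mask):
            raise ValueError(f"marker {m.marker_name!r} has positives outside the epithelium")

    n = scheme.n_labels
    bin_counts = np.array([(labels == k).sum() for k in range(1, n + 1)], dtype=float)
    total_px = float(mask.mask.sum())
    included_px = float(bin_counts.sum())
    px_to_mm2 = (mask.pixel_size_um / 1000.0) ** 2

    per_bin: dict[str, np.ndarray] = {}
    overall: dict[str, float] = {}
    included: dict[str, float] = {}
    thresholds: dict[str, float] = {}
    for m in markers:
        pos_counts = np.array(
            [(m.mask & (labels == k)).sum() for k in range(1, n + 1)], dtype=float
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            fr = np.where(bin_counts > 0, 100.0 * pos_counts / bin_counts, np.nan)
        per_bin[m.marker_name] = fr
        overall[m.marker_name] = 100.0 * m.positive_pixels / total_px if total_px else np.nan
        included[m.marker_name] = (
            100.0 * pos_counts.sum() / included_px if included_px else np.nan
        )
        thresholds[m.marker_name] = m.threshold_value

    return SegmentProfile(
        bins=scheme.intervals(),
        bin_area_mm2=bin_counts * px_to_mm2,
        per_bin_pct=per_bin,
        overall_pct=overall,
        included_pct=included,
        thresholds=thresholds,
    )
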