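"""Synthetic phantoms and datasets with exact ground truth.

Every measurement stage of the pipeline can be exercised without real
tissue images by generating phantoms that emulate the structure of a
stained ectocervical section:

* a curved epithelial band between an apical (luminal) and a basal
  boundary, with an E-cadherin-positive basal sublayer and an
  E-cadherin-negative superficial sublayer;
* sparse, irregular (star-convex) marker-positive cells whose density
  varies with depth, with a controllable double-positive overlap
  between two marker channels;
* additive Gaussian background noise clipped at zero, and an elevated
  autofluorescence strip along the apical border that makes the apical
  exclusion rule consequential.

Default dimensions mirror the tissue actually analyzed in practice:
about 1.5 mm^2 of epithelium at ~300 µm total thickness with a ~45 µm
E-cadherin-negative layer, and marker area fractions of a few percent.

All generators are pure functions of their spec and seed: the same seed
reproduces output bit-exactly.  Randomness is split into named
substreams (geometry, cells, noise) so that, e.g., cell placement is
stable when only the noise level changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon

from .cervicotype import GARDNERELLA, INERS, NONINERS
from .depth_profile import SegmentScheme, assign_depth_bins
from .geometry import (
    BoundarySet,
    ChannelImage,
    DepthMap,
    EpitheliumMask,
    build_epithelium_mask,
    distance_from_boundary,
)
from .stats import GroupedMeasurements

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_abundance_tables",
    "generate_grouped_measurements",
    "DEFAULT_TAXA",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one tissue phantom.

    Geometry: the apical surface is a sinusoid ``margin + A sin(2 pi
    (x + phase)/period)``; the E-cadherin boundary and basal membrane
    are exact normal-offset curves of it at the E-cadherin-negative and
    total thickness, so the true normal thickness is constant by
    construction.  Set ``sinusoid_amplitude_um = 0`` for parallel-plate
    geometry.

    Markers: ``marker_bin_fractions`` maps a channel name to the target
    positive-area percentage per depth segment (segments 1..n of
    ``scheme``; a shorter list is padded with its last value).  Cells
    are star-convex blobs Poisson-placed within each segment.
    ``double_positive_overlap`` is the probability that a blob of the
    first marker is duplicated into each subsequent marker channel,
    planting double positives at identical pixel locations.
    """

    width_px: int = 2500
    height_px: int = 220
    pixel_size_um: float = 2.0
    apical_margin_um: float = 40.0
    sinusoid_amplitude_um: float = 30.0
    sinusoid_period_um: float = 2000.0
    total_thickness_um: float = 300.0
    ecad_neg_um: float = 45.0
    marker_bin_fractions: dict = field(
        default_factory=lambda: {
            "CD4": (0.5, 3.0, 4.0, 4.0, 3.0, 2.0, 1.5),
            "CCR5": (0.3, 1.5, 1.5, 1.0, 1.0, 0.8, 0.5),
        }
    )
    double_positive_overlap: float = 0.35
    cell_radius_px: tuple[float, float] = (3.0, 8.0)
    cell_irregularity: float = 0.3
    cell_intensity: float = 180.0
    ecad_intensity: float = 150.0
    background_intensity: float = 10.0
    noise_sd: float = 4.0
    autofluor_width_um: float = 10.0
    autofluor_boost: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ecad_neg_um < self.total_thickness_um:
            raise ValueError("need 0 <= ecad_neg_um < total_thickness_um")
        for name, fracs in self.marker_bin_fractions.items():
            if any(not 0 <= f <= 100 for f in fracs):
                raise ValueError(f"marker {name!r}: fractions must be in [0, 100]")
        if not 0 <= self.double_positive_overlap <= 1:
            raise ValueError("double_positive_overlap must be in [0, 1]")
        if self.cell_radius_px[0] <= 0 or self.cell_radius_px[1] < self.cell_radius_px[0]:
            raise ValueError("invalid cell radius range")


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying one phantom."""

    boundaries: BoundarySet
    mask: EpitheliumMask
    depth: DepthMap
    bin_labels: np.ndarray
    scheme: SegmentScheme
    total_thickness_um: float
    ecad_neg_um: float
    marker_masks: dict[str, np.ndarray]

    def true_bin_fractions(self, marker: str) -> np.ndarray:
        """Recount the planted mask: exact positive-area % per segment."""
        m = self.marker_masks[marker]
        n = self.scheme.n_labels
        out = np.full(n, np.nan)
        for k in range(1, n + 1):
            sel = self.bin_labels == k
            denom = sel.sum()
            if denom:
                out[k - 1] = 100.0 * (m & sel).sum() / denom
        return out

    def true_overall_fraction(self, marker: str) -> float:
        """Exact positive-area % over the full epithelium ROI."""
        m = self.marker_masks[marker]
        return 100.0 * float(m.sum()) / float(self.mask.mask.sum())


def _offset_curve(pts: np.ndarray, offset_px: float) -> np.ndarray:
    """Offset a polyline along its (downward-pointing) unit normals."""
    d = np.gradient(pts, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    # normal of tangent (tx, ty) pointing toward increasing y
    nx = -d[:, 1] / norm
    ny = d[:, 0] / norm
    flip = ny < 0
    nx[flip] *= -1
    ny[flip] *= -1
    return pts + offset_px * np.column_stack([nx, ny])


def _star_blob(rng: np.random.Generator, cx: float, cy: float, r0: float,
               irregularity: float, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices of one star-convex polygon blob, clipped to the image."""
    m = 12
    theta = np.linspace(0, 2 * np.pi, m, endpoint=False)
    radii = r0 * (1.0 + irregularity * rng.uniform(-1, 1, size=m))
    xs = cx + radii * np.cos(theta)
    ys = cy + radii * np.sin(theta)
    rr, cc = _draw_polygon(ys, xs, shape=shape)
    return rr, cc


def generate_phantom(
    spec: PhantomSpec, scheme: SegmentScheme | None = None
) -> tuple[dict[str, ChannelImage], BoundarySet, PhantomTruth]:
    """Generate one multi-channel phantom with exact truth.

    Returns ``(channels, boundaries, truth)`` where ``channels`` maps
    channel name (DAPI, E-cadherin and every marker in the spec) to a
    :class:`ChannelImage`.  Deterministic given ``spec.seed``.
    """
    if scheme is None:
        scheme = SegmentScheme()
    px = spec.pixel_size_um
    H, W = spec.height_px, spec.width_px
    t_px = spec.total_thickness_um / px
    margin_px = spec.apical_margin_um / px
    amp_px = spec.sinusoid_amplitude_um / px
    if margin_px + 2 * amp_px + t_px + 3 >= H:
        raise ValueError(
            f"total_thickness_um={spec.total_thickness_um} does not fit the "
            f"{H}px image height at {px} um/px"
        )

    root = np.random.default_rng(spec.seed)
    rng_geom, rng_cells, rng_noise = root.spawn(3)

    # --- geometry: apical sinusoid and its normal-offset curves -------------
    period_px = max(spec.sinusoid_period_um / px, 1.0)
    phase = rng_geom.uniform(0, period_px)
    # extend beyond the image so offset curves still cover the full width,
    # then trim each polyline to its in-bounds vertices (curves are
    # x-monotone, so the trimmed vertex run stays contiguous)
    pad = t_px + 4
    xs = np.arange(2.0 - pad, W - 2.0 + pad, 2.0)
    ya = margin_px + amp_px + amp_px * np.sin(2 * np.pi * (xs + phase) / period_px)
    apical_full = np.column_stack([xs, ya])
    ecad_full = _offset_curve(apical_full, spec.ecad_neg_um / px)
    basal_full = _offset_curve(apical_full, t_px)

    def _trim(curve: np.ndarray) -> np.ndarray:
        keep = (np.rint(curve[:, 0]) >= 0) & (np.rint(curve[:, 0]) <= W - 1)
        return curve[keep]

    apical, ecad, basal = _trim(apical_full), _trim(ecad_full), _trim(basal_full)

    # ROI: a sliver beyond each boundary so the rasterized lines are interior
    roi = np.vstack([_offset_curve(apical, -1.5), _offset_curve(basal, 1.5)[::-1]])
    roi = np.clip(roi, [0.0, 0.0], [W - 1.0, H - 1.0])
    boundaries = BoundarySet(
        roi_polygon=roi, basal_line=basal, ecad_boundary_line=ecad, apical_line=apical
    )
    mask = build_epithelium_mask(boundaries, (H, W), px)
    depth = distance_from_boundary(mask, apical, reference="apical")
    labels = assign_depth_bins(depth, scheme)

    # --- cells: Poisson-placed star blobs per depth segment -----------------
    r_lo, r_hi = spec.cell_radius_px
    mean_blob_area = np.pi * (r_lo**2 + r_lo * r_hi + r_hi**2) / 3.0
    marker_masks: dict[str, np.ndarray] = {}
    blob_registry: list[tuple[np.ndarray, np.ndarray]] = []  # blobs of first marker
    marker_names = list(spec.marker_bin_fractions)
    for mi, name in enumerate(marker_names):
        fracs = list(spec.marker_bin_fractions[name])
        while len(fracs) < scheme.n_labels:
            fracs.append(fracs[-1])
        mmask = np.zeros((H, W), dtype=bool)
        # duplicate first-marker blobs into later channels -> double positives
        if mi > 0:
            for rr, cc in blob_registry:
                if rng_cells.random() < spec.double_positive_overlap:
                    mmask[rr, cc] = True
        for k in range(1, scheme.n_labels + 1):
            sel = np.argwhere((labels == k))
            if len(sel) == 0:
                continue
            target = fracs[k - 1] / 100.0
            if mi > 0:
                # discount the area already planted by duplicated blobs
                planted = (mmask & (labels == k)).sum() / len(sel)
                target = max(0.0, target - planted)
            n_blobs = rng_cells.poisson(target * len(sel) / mean_blob_area)
            if n_blobs == 0:
                continue
            centers = sel[rng_cells.integers(0, len(sel), size=n_blobs)]
            for cy, cx in centers:
                r0 = rng_cells.uniform(r_lo, r_hi)
                rr, cc = _star_blob(rng_cells, cx, cy, r0, spec.cell_irregularity, (H, W))
                keep = mask.mask[rr, cc]
                rr, cc = rr[keep], cc[keep]
                if len(rr) == 0:
                    continue
                mmask[rr, cc] = True
                if mi == 0:
                    blob_registry.append((rr, cc))
        marker_masks[name] = mmask

    # --- render channels -----------------------------------------------------
    strip = mask.mask & (depth.depth_um < spec.autofluor_width_um)

    def _render(signal: np.ndarray) -> np.ndarray:
        img = np.full((H, W), spec.background_intensity, dtype=float)
        img[strip] += spec.autofluor_boost * spec.background_intensity
        img += signal
        if spec.noise_sd > 0:
            img += rng_noise.normal(0.0, spec.noise_sd, size=(H, W))
        return np.clip(img, 0.0, None)

    channels: dict[str, ChannelImage] = {}
    dapi = np.where(mask.mask, 80.0, 0.0)
    channels["DAPI"] = ChannelImage(_render(dapi), "DAPI", px)
    ecad_sig = np.where(
        mask.mask & (depth.depth_um >= spec.ecad_neg_um), spec.ecad_intensity, 0.0
    )
    channels["E-cadherin"] = ChannelImage(_render(ecad_sig), "E-cadherin", px)
    for name in marker_names:
        jitter = 1.0 + 0.15 * rng_noise.uniform(-1, 1, size=(H, W))
        sig = np.where(marker_masks[name], spec.cell_intensity * jitter, 0.0)
        channels[name] = ChannelImage(_render(sig), name, px)

    truth = PhantomTruth(
        boundaries=boundaries,
        mask=mask,
        depth=depth,
        bin_labels=labels,
        scheme=scheme,
        total_thickness_um=spec.total_thickness_um,
        ecad_neg_um=spec.ecad_neg_um,
        marker_masks=marker_masks,
    )
    return channels, boundaries, truth


DEFAULT_TAXA = (
    NONINERS,
    INERS,
    GARDNERELLA,
    "Prevotella",
    "Atopobium",
    "Sneathia",
    "Megasphaera",
    "Streptococcus",
)


def generate_abundance_tables(
    n_per_ct: tuple[int, int, int, int],
    concentration: float = 0.8,
    dominance_threshold: float = 0.5,
    seed: int = 0,
    taxa: tuple[str, ...] = DEFAULT_TAXA,
) -> tuple[pd.DataFrame, pd.Series]:
    """Dirichlet-style compositions with cervicotypes known by construction.

    For CT1–CT3 the intended dominant taxon is drawn above the dominance
    threshold and the remaining mass is spread Dirichlet(concentration)
    over the other taxa.  CT4 compositions are Dirichlet draws rejected
    until the maximum abundance falls below the threshold.

    Returns ``(table, labels)`` with one row per sample, rows summing
    to 1.
    """
    if len(n_per_ct) != 4 or any(n < 0 for n in n_per_ct):
        raise ValueError("n_per_ct must be four non-negative counts")
    if not 0 < dominance_threshold < 0.97:
        raise ValueError("infeasible dominance threshold")
    rng = np.random.default_rng(seed)
    dominant_of = {0: NONINERS, 1: INERS, 2: GARDNERELLA}
    rows, labels, ids = [], [], []
    idx = 0
    for ct_i, n in enumerate(n_per_ct):
        for _ in range(n):
            if ct_i < 3:
                dom = rng.uniform(dominance_threshold + 0.02, 0.97)
                rest = rng.dirichlet(np.full(len(taxa) - 1, concentration)) * (1 - dom)
                comp = np.empty(len(taxa))
                others = [i for i, t in enumerate(taxa) if t != dominant_of[ct_i]]
                comp[taxa.index(dominant_of[ct_i])] = dom
                comp[others] = rest
            else:
                for _try in range(1000):
                    comp = rng.dirichlet(np.full(len(taxa), 1.0))
                    if comp.max() < dominance_threshold - 1e-9:
                        break
                else:
                    raise ValueError(
                        "could not draw a high-diversity composition below the "
                        "dominance threshold; infeasible settings"
                    )
            rows.append(comp)
            labels.append(f"CT{ct_i + 1}")
            ids.append(f"S{idx:04d}")
            idx += 1
    table = pd.DataFrame(rows, index=ids, columns=list(taxa))
    return table, pd.Series(labels, index=ids, name="cervicotype")


def generate_grouped_measurements(
    n_a: int,
    n_b: int,
    effect: float = 0.0,
    distribution: str = "normal",
    loc: float = 12.0,
    scale: float = 8.0,
    detection_limit: float | None = None,
    seed: int = 0,
) -> GroupedMeasurements:
    """Two-group measurement vectors with a known location shift.

    Group B is drawn at ``loc``; group A at ``loc + effect``.  With the
    defaults (loc 12, shift applied by the caller, scale 8) the values
    emulate regulatory-T-cell percentage data (medians around 12–20%).
    ``distribution="lognormal"`` instead emulates cytokine
    concentrations in pg/mL: draws are ``10**Normal(loc, scale)`` —
    analyze them on the log10 scale.  Values below ``detection_limit``
    are flagged (not removed).
    """
    if n_a < 3 or n_b < 3:
        raise ValueError("need at least 3 observations per group")
    rng = np.random.default_rng(seed)
    za = loc + effect + scale * rng.standard_normal(n_a)
    zb = loc + scale * rng.standard_normal(n_b)
    if distribution == "normal":
        va, vb = za, zb
    elif distribution == "lognormal":
        va, vb = 10.0**za, 10.0**zb
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    values = np.concatenate([va, vb])
    groups = np.array(["A"] * n_a + ["B"] * n_b)
    flags = None
    if detection_limit is not None:
        flags = values >= detection_limit
    return GroupedMeasurements(values=values, groups=groups, above_limit=flags)
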