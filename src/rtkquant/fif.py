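"""Molecular brightness from spatial intensity fluctuations.

A membrane image is tiled into small square segments (15x15 pixels by
convention).  Within each segment the mean intensity <I> and variance
sigma^2 of the pixel values report on the oligomeric state of the diffusing
fluorescent species: a unit carrying s fluorophores contributes s-fold more
photons per visit, inflating the variance.  The molecular brightness per
segment is

    analog detector:          eps = (sigma^2 - sigma_D^2) / <I>
    photon-counting detector: eps = sigma^2 / <I> - 1

where sigma_D^2 is the detector noise variance (shot noise is already the
Poisson part of a photon count, hence the "-1").  The two conventions are
not interchangeable: the analog formula removes only the read noise, so
applied to an underlying photon stream it reads one shot-noise unit above
the photon-counting estimate — in practice the analog gain calibration
absorbs that floor.  For a mixture of oligomer
species at per-pixel unit densities mu_s the apparent brightness converges
to the intensity-weighted mean  eps_app = q * sum(mu_s s^2) / sum(mu_s s),
with q the photon yield per fluorophore — the oracle used throughout the
tests.  Distributions of eps across segments, normalized per cell and
averaged across cells, let a population under study be placed between
monomer and dimer reference controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Detector",
    "PHOTON_COUNTING",
    "PhotonImage",
    "SegmentStats",
    "BrightnessDistribution",
    "segment_cell",
    "segment_brightness",
    "brightness_distribution",
    "compare_to_references",
    "apparent_brightness",
]


@dataclass(frozen=True)
class Detector:
    """Detector model: ``photon_counting`` or ``analog`` with noise variance."""

    kind: str
    sigma_d2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("photon_counting", "analog"):
            raise ValueError(f"unknown detector kind {self.kind!r}")
        if self.sigma_d2 < 0:
            raise ValueError("sigma_d2 must be >= 0")


PHOTON_COUNTING = Detector("photon_counting")


@dataclass
class PhotonImage:
    """Integer photon-count image with a boolean cell mask."""

    counts: np.ndarray
    mask: np.ndarray
    detector: Detector = PHOTON_COUNTING

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask shape must match counts shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class SegmentStats:
    """Per-segment first and second moments, and brightness once assigned."""

    cell_id: str
    segment_index: int
    origin: tuple[int, int]
    n_pixels: int
    mean_intensity: float
    variance: float
    brightness: float | None = None
    valid: bool = True

    @property
    def concentration_proxy(self) -> float | None:
        """Intensity / brightness — proportional to units per pixel.

        Undefined (None) for invalid or non-positive-brightness segments.
        """
        if not self.valid or self.brightness is None or self.brightness <= 0:
            return None
        return self.mean_intensity / self.brightness


@dataclass
class BrightnessDistribution:
    """Cell-averaged normalized brightness histogram."""

    bin_edges: np.ndarray
    per_cell_normalized_counts: np.ndarray  # shape (n_cells, n_bins)
    mean_curve: np.ndarray
    standard_error_curve: np.ndarray
    n_cells: int
    cell_ids: list[str] = field(default_factory=list)

    def median_brightness(self) -> float:
        """Median of the cell-averaged distribution (linear interpolation
        within the bin containing the 0.5 quantile of the mean curve)."""
        c = np.cumsum(self.mean_curve)
        c = c / c[-1]
        j = int(np.searchsorted(c, 0.5))
        lo = self.bin_edges[j]
        hi = self.bin_edges[j + 1]
        c_lo = c[j - 1] if j > 0 else 0.0
        frac = (0.5 - c_lo) / max(c[j] - c_lo, 1e-300)
        return float(lo + frac * (hi - lo))


def apparent_brightness(species, photons_per_fluorophore: float) -> float:
    """Law-of-total-variance oracle for a mixture of oligomer species.

    ``species`` is an iterable of (oligomer_size s, mean units per pixel
    mu_s).  Returns eps_app = q * sum(mu s^2) / sum(mu s); raises if the
    mixture carries no intensity.
    """
    num = sum(mu * s * s for s, mu in species)
    den = sum(mu * s for s, mu in species)
    if den == 0:
        raise ValueError("mixture has zero total intensity; brightness undefined")
    return photons_per_fluorophore * num / den


def segment_cell(
    image: PhotonImage,
    segment_size: int = 15,
    cell_id: str = "cell0",
) -> list[SegmentStats]:
    """Tile the masked region into square segments and compute moments.

    Segments are anchored at the origin of the mask bounding box; only
    blocks lying entirely inside the mask are kept, so every segment has the
    same pixel count and variance estimates are comparable.  Variance is the
    unbiased (n-1) estimate.
    """
    if not image.mask.any():
        raise ValueError("mask is empty")
    rows = np.flatnonzero(image.mask.any(axis=1))
    cols = np.flatnonzero(image.mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    stats: list[SegmentStats] = []
    idx = 0
    for r in range(r0, r1 - segment_size + 1, segment_size):
        for c in range(c0, c1 - segment_size + 1, segment_size):
            block_mask = image.mask[r : r + segment_size, c : c + segment_size]
            if not block_mask.all():
                continue
            block = image.counts[r : r + segment_size, c : c + segment_size]
            vals = block.astype(float).ravel()
            stats.append(
                SegmentStats(
                    cell_id=cell_id,
                    segment_index=idx,
                    origin=(int(r), int(c)),
                    n_pixels=vals.size,
                    mean_intensity=float(vals.mean()),
                    variance=float(vals.var(ddof=1)),
                )
            )
            idx += 1
    if not stats:
        warnings.warn(
            "mask smaller than one segment; no segments produced", stacklevel=2
        )
    return stats


def segment_brightness(
    stats: SegmentStats, detector: Detector = PHOTON_COUNTING
) -> SegmentStats:
    """Assign molecular brightness to a segment.

    Photon counting: eps = sigma^2/<I> - 1 (shot noise subtracted as the
    Poisson floor).  Analog: eps = (sigma^2 - sigma_D^2)/<I>.  A segment
    with zero mean intensity has undefined brightness and is flagged
    invalid so downstream distributions exclude it.
    """
    if stats.mean_intensity <= 0:
        return SegmentStats(
            **{**stats.__dict__, "brightness": None, "valid": False}
        )
    if detector.kind == "photon_counting":
        eps = stats.variance / stats.mean_intensity - 1.0
    else:
        eps = (stats.variance - detector.sigma_d2) / stats.mean_intensity
    return SegmentStats(**{**stats.__dict__, "brightness": float(eps), "valid": True})


def default_bins(brightness_values, n_bins: int = 40) -> np.ndarray:
    """Log-spaced bins over the central 99% of positive brightness values."""
    v = np.asarray(brightness_values, dtype=float)
    v = v[v > 0]
    if v.size < 2:
        raise ValueError("need at least two positive brightness values to bin")
    lo, hi = np.percentile(v, [0.5, 99.5])
    lo = max(lo, 1e-6)
    hi = max(hi, lo * 1.001)
    return np.geomspace(lo, hi, n_bins + 1)


def brightness_distribution(
    segments, bins=None, min_segments: int = 10
) -> BrightnessDistribution:
    """Build the per-cell-normalized, cell-averaged brightness histogram.

    Each cell with at least ``min_segments`` valid segments contributes one
    unit-sum histogram over shared bins (out-of-range values are clipped
    into the edge bins so normalization is exact); the distribution reports
    the across-cell mean curve and its standard error SD/sqrt(n_cells).
    Negative-brightness segments (possible from noise) are retained.
    """
    by_cell: dict[str, list[float]] = {}
    for s in segments:
        if s.valid and s.brightness is not None:
            by_cell.setdefault(s.cell_id, []).append(s.brightness)
    by_cell = {k: v for k, v in by_cell.items() if len(v) >= min_segments}
    if not by_cell:
        raise ValueError("no cell has enough valid segments")
    if bins is None:
        pooled = np.concatenate([np.asarray(v) for v in by_cell.values()])
        bins = default_bins(pooled)
    bins = np.asarray(bins, dtype=float)
    n_bins = bins.size - 1
    cell_ids = sorted(by_cell)
    curves = np.empty((len(cell_ids), n_bins))
    eps_width = (bins[-1] - bins[0]) * 1e-12
    for i, cid in enumerate(cell_ids):
        v = np.clip(np.asarray(by_cell[cid]), bins[0], bins[-1] - eps_width)
        h, _ = np.histogram(v, bins=bins)
        curves[i] = h / h.sum()
    mean = curves.mean(axis=0)
    if len(cell_ids) > 1:
        se = curves.std(axis=0, ddof=1) / np.sqrt(len(cell_ids))
    else:
        se = np.zeros(n_bins)
    return BrightnessDistribution(
        bin_edges=bins,
        per_cell_normalized_counts=curves,
        mean_curve=mean,
        standard_error_curve=se,
        n_cells=len(cell_ids),
        cell_ids=cell_ids,
    )


def compare_to_references(
    dist: BrightnessDistribution,
    monomer_ref: BrightnessDistribution,
    dimer_ref: BrightnessDistribution,
    at_tolerance: float = 0.10,
) -> dict:
    """Place a brightness distribution relative to monomer/dimer controls.

    All three distributions must share binning.  Reports the ratio of the
    distribution's median brightness to each control's and a classification
    in {"below monomer", "at monomer", "between", "at dimer", "above dimer"};
    "at" means within ``at_tolerance`` relative of the control median.
    """
    for ref in (monomer_ref, dimer_ref):
        if ref.bin_edges.shape != dist.bin_edges.shape or not np.allclose(
            ref.bin_edges, dist.bin_edges
        ):
            raise ValueError("distributions must share bin edges")
    m = dist.median_brightness()
    m_mono = monomer_ref.median_brightness()
    m_dim = dimer_ref.median_brightness()
    r_mono = m / m_mono
    r_dim = m / m_dim
    if abs(r_mono - 1) <= at_tolerance:
        placement = "at monomer"
    elif abs(r_dim - 1) <= at_tolerance:
        placement = "at dimer"
    elif m < m_mono:
        placement = "below monomer"
    elif m > m_dim:
        placement = "above dimer"
    else:
        placement = "between"
    return {
        "median_brightness": m,
        "ratio_vs_monomer": r_mono,
        "ratio_vs_dimer": r_dim,
        "placement": placement,
    }
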