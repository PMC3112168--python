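"""Punctum detection and the particle statistics built on it.

The pipeline mirrors common ImageJ particle-analysis practice: threshold
(fixed level or local-mean adaptive), label connected components (8-connected
by default), then summarise the resulting particle set as

* a size distribution — counts Np_i of particles per area bin Ap_i,
  expressed as a percentage of the total N_t; and
* a fractional-coverage curve — f_i = Np_i·Ap_i / C_t, the share of the
  total particulate area C_t contributed by each size class, which separates
  "many small particles" from "few large particles" regimes that a bare
  count distribution can conflate.

Raw-image intensity is quantified as the on-cell / off-cell mean ratio S/B,
reported as (S/B)−1 so that zero means "no surface signal above background".
Box scans and contour maps reproduce the profile/level-map visualisations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .containers import (
    FluorescenceImage,
    FractionalCoverageCurve,
    GroupComparison,
    Particle,
    ParticleSet,
    ROI,
    SBResult,
    SizeDistribution,
)
from .stats import compare_groups

__all__ = [
    "threshold_image",
    "label_particles",
    "size_distribution",
    "fractional_coverage",
    "unit_bin_edges",
    "signal_to_background",
    "percent_of_control",
    "PercentOfControl",
    "box_scan",
    "contour_map",
    "compare_groups",
]


def threshold_image(
    img: FluorescenceImage,
    method: str = "adaptive_local",
    level: float | None = None,
    window: int = 15,
    offset: float = 0.0,
) -> np.ndarray:
    """Binary mask of above-threshold pixels.

    ``fixed``: pixel > ``level``.  ``adaptive_local``: pixel > (local mean
    over a ``window``×``window`` square) − ``offset``; a negative offset
    therefore raises the threshold above the local mean.  ``window`` must be
    odd and ≥ 3.
    """
    data = img.data
    if method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
        return data > level
    if method == "adaptive_local":
        if window < 3 or window % 2 == 0:
            raise ValueError("adaptive window must be odd and >= 3")
        local_mean = ndimage.uniform_filter(data, size=window, mode="reflect")
        return data > (local_mean - offset)
    raise ValueError(f"unknown threshold method {method!r}")


def label_particles(
    mask: np.ndarray,
    connectivity: int = 8,
    min_area: float = 1.0,
    intensity: FluorescenceImage | None = None,
) -> ParticleSet:
    """Connected-component particle extraction from a binary mask.

    One particle per component with area ≥ ``min_area`` (pixel count);
    ``connectivity`` is 4 or 8.  If an intensity image is supplied, each
    particle records its peak intensity.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if intensity is not None and intensity.shape != mask.shape:
        raise ValueError("mask and intensity image dimensions differ")
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    props = measure.regionprops(
        labels, intensity_image=None if intensity is None else intensity.data
    )
    particles = []
    for rp in props:
        if rp.area < min_area:
            continue
        cy, cx = rp.centroid
        peak = float(rp.intensity_max) if intensity is not None else 1.0
        particles.append(Particle(x=float(cx), y=float(cy), area=float(rp.area), peak=peak))
    return ParticleSet(particles=particles, shape=mask.shape)


def unit_bin_edges(ps: ParticleSet) -> np.ndarray:
    """Unit (1 px²) bin edges covering [1, Ap′], centred on whole areas."""
    top = int(np.ceil(ps.largest_area))
    return np.arange(0.5, top + 1.0, 1.0)


def _binned(ps: ParticleSet, bin_edges: np.ndarray | None) -> SizeDistribution:
    if ps.n_total == 0:
        raise ValueError("empty particle set")
    edges = unit_bin_edges(ps) if bin_edges is None else np.asarray(bin_edges, dtype=float)
    areas = ps.areas
    if areas.min() < edges[0] or areas.max() > edges[-1]:
        raise ValueError("bin edges must cover [min area, largest area]")
    counts, _ = np.histogram(areas, bins=edges)
    bin_area, _ = np.histogram(areas, bins=edges, weights=areas)
    rep = 0.5 * (edges[:-1] + edges[1:])
    return SizeDistribution(
        bin_edges=edges,
        counts=counts.astype(float),
        rep_areas=rep,
        bin_area=bin_area,
    )


def size_distribution(ps: ParticleSet, bin_edges: np.ndarray | None = None) -> SizeDistribution:
    """Particle-count distribution over area bins (unit bins by default);
    the normalised column Np_i/N_t sums to 100%."""
    return _binned(ps, bin_edges)


def fractional_coverage(
    obj: "ParticleSet | SizeDistribution",
    bin_edges: np.ndarray | None = None,
) -> FractionalCoverageCurve:
    """Fractional coverage f_i = Np_i·Ap_i / C_t per area bin.

    For a particle set the per-bin particulate area is the exact sum of the
    member areas (identical to Np_i·Ap_i at unit bins, and summing to 1
    under any binning); for a model :class:`SizeDistribution` the
    representative-area product is used.
    """
    if isinstance(obj, ParticleSet):
        if obj.c_total <= 0:
            raise ValueError("total particulate area must be positive")
        dist = _binned(obj, bin_edges)
    else:
        dist = obj
    ct = dist.c_total
    if ct <= 0:
        raise ValueError("total particulate area must be positive")
    return FractionalCoverageCurve(
        rep_areas=dist.rep_areas,
        coverage=dist.areas_per_bin / ct,
        c_total=ct,
    )


def signal_to_background(img: FluorescenceImage, on: ROI, off: ROI) -> SBResult:
    """On-cell mean over off-cell mean of a raw (non-background-subtracted)
    image; also exposes (S/B)−1."""
    on_mean = float(on.extract(img).mean())
    off_mean = float(off.extract(img).mean())
    if off_mean == 0:
        raise ZeroDivisionError("off-cell background mean is zero")
    return SBResult(sb=on_mean / off_mean, on_mean=on_mean, off_mean=off_mean)


@dataclass
class PercentOfControl:
    """Treated-group intensity as a percentage of control, with the
    supporting two-sample comparison."""

    percent: int            # rounded for reporting
    percent_raw: float
    comparison: GroupComparison | None


def percent_of_control(
    treated: "np.ndarray | list[float]",
    control: "np.ndarray | list[float]",
) -> PercentOfControl:
    """100 · mean(treated) / mean(control) on (S/B)−1 values, rounded to the
    nearest integer percent for reporting, plus a t-test when both groups
    have n ≥ 2."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 1 or control.size < 1:
        raise ValueError("both groups need at least one value")
    c_mean = control.mean()
    if c_mean == 0:
        raise ZeroDivisionError("control mean is zero")
    pct = 100.0 * treated.mean() / c_mean
    comparison = None
    if treated.size >= 2 and control.size >= 2:
        comparison = compare_groups(
            {"control": control, "treated": treated}, test="t_test"
        )
    return PercentOfControl(
        percent=int(round(pct)), percent_raw=float(pct), comparison=comparison
    )


def box_scan(img: FluorescenceImage, box: ROI, axis: str = "x") -> np.ndarray:
    """1-D intensity profile along ``axis`` within ``box``, averaging across
    the orthogonal axis — the noise-reducing alternative to single-pixel
    line scans."""
    sub = box.extract(img)
    if axis == "x":
        return sub.mean(axis=0)
    if axis == "y":
        return sub.mean(axis=1)
    raise ValueError("axis must be 'x' or 'y'")


def contour_map(
    img: FluorescenceImage,
    n_levels: int = 8,
    out_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Quantised intensity-level map: rescale to ``out_range`` (0–255) then
    split into ``n_levels`` equal bands.  A constant image maps to a single
    band; band index is monotone in input intensity."""
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    lo, hi = out_range
    data = img.data
    span = data.max() - data.min()
    if span == 0:
        return np.zeros(data.shape, dtype=int)
    scaled = (data - data.min()) / span * (hi - lo) + lo
    band_width = (hi - lo) / n_levels
    bands = np.floor((scaled - lo) / band_width).astype(int)
    return np.minimum(bands, n_levels - 1)
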