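"""Model size distributions and the transformations a GPI-cleaving enzyme
should have imposed on surface puncta.

Three binomial-family curves — p⁴, 6p²q² and q⁴ with q = 1−p, the particle
area mapped linearly onto p = Ap/Ap′ — provide archetypal "small-particle",
"intermediate" and "large-particle" size distributions.  Each is scaled so
the total particulate area Σ Np_i·Ap_i equals a common C_t (1×10⁵ px² in the
reference setting), which makes their fractional-coverage curves directly
comparable: equal total coverage, very different apportionment by size.

Two transformations model candidate enzyme effects on a punctate field:

* stripping — every particle loses a fixed area fraction (default 50%),
  particle number N_t held constant, so C_t scales down;
* disassembly — every particle fragments into m smaller puncta of area
  Ap/m, conserving C_t exactly while N_t grows m-fold.

``compare_to_prediction`` quantifies which hypothesis (no effect, or a
transformed prediction) an observed "after" distribution is closer to,
using L1 distance on the normalised counts and on fractional coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import Particle, ParticleSet, SizeDistribution
from .particle_analysis import fractional_coverage

__all__ = [
    "BinomialCurveSpec",
    "binomial_size_curve",
    "apply_stripping",
    "apply_disassembly",
    "compare_to_prediction",
    "DivergenceReport",
    "sample_curve",
]

_TERMS = {
    "p4": lambda p, q: p**4,
    "6p2q2": lambda p, q: 6.0 * p**2 * q**2,
    "q4": lambda p, q: q**4,
}


@dataclass(frozen=True)
class BinomialCurveSpec:
    """A binomial-term size-distribution curve at fixed total area.

    ``term`` is one of ``p4``, ``6p2q2``, ``q4``; ``area_grid`` the particle
    areas (pixel²) at which the curve is evaluated; ``c_total`` the target
    total particulate area the curve is normalised to.
    """

    term: str
    area_grid: np.ndarray
    c_total: float = 1e5

    def __post_init__(self) -> None:
        if self.term not in _TERMS:
            raise ValueError(f"term must be one of {sorted(_TERMS)}")
        grid = np.asarray(self.area_grid, dtype=float)
        if grid.size < 1 or np.any(grid <= 0) or (
            grid.size > 1 and not np.all(np.diff(grid) > 0)
        ):
            raise ValueError("area grid must be positive and strictly increasing")
        if not self.c_total > 0:
            raise ValueError("C_t must be positive")
        object.__setattr__(self, "area_grid", grid)


def _edges_from_grid(grid: np.ndarray) -> np.ndarray:
    """Bin edges midway between grid points (half-spacing at the ends)."""
    if grid.size == 1:
        half = max(grid[0] * 0.5, 0.5)
        return np.array([grid[0] - half, grid[0] + half])
    mids = 0.5 * (grid[:-1] + grid[1:])
    first = grid[0] - (mids[0] - grid[0])
    last = grid[-1] + (grid[-1] - mids[-1])
    return np.concatenate([[max(first, 0.0)], mids, [last]])


def binomial_size_curve(spec: BinomialCurveSpec) -> SizeDistribution:
    """Evaluate the chosen binomial term over the area grid and scale it so
    Σ Np_i·Ap_i = C_t.

    The area axis maps onto the binomial success probability linearly,
    p = Ap/Ap′ with Ap′ the largest grid area.  The returned distribution
    carries expected (continuous) counts; N_t is their sum.
    """
    grid = spec.area_grid
    p = grid / grid.max()
    raw = _TERMS[spec.term](p, 1.0 - p)
    denom = float((raw * grid).sum())
    if denom == 0:
        raise ValueError("degenerate curve: no mass on the area grid")
    counts = raw * (spec.c_total / denom)
    return SizeDistribution(
        bin_edges=_edges_from_grid(grid),
        counts=counts,
        rep_areas=grid,
    )


def sample_curve(dist: SizeDistribution, seed: int = 0) -> SizeDistribution:
    """Seeded Poisson sampling of a continuous expected-count curve into
    integer counts (for stochastic tests)."""
    rng = np.random.default_rng(seed)
    return SizeDistribution(
        bin_edges=dist.bin_edges,
        counts=rng.poisson(dist.counts).astype(float),
        rep_areas=dist.rep_areas,
    )


def apply_stripping(
    obj: "ParticleSet | SizeDistribution", scale: float = 0.5
) -> "ParticleSet | SizeDistribution":
    """Uniformly shrink every particle's area by ``scale`` (default 50%),
    holding the particle count constant; C_t scales by the same factor and
    the distribution shape translates down the area axis."""
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    if isinstance(obj, ParticleSet):
        particles = [
            Particle(x=p.x, y=p.y, area=p.area * scale, peak=p.peak)
            for p in obj.particles
        ]
        return ParticleSet(particles=particles, shape=obj.shape)
    return SizeDistribution(
        bin_edges=obj.bin_edges * scale,
        counts=obj.counts.copy(),
        rep_areas=obj.rep_areas * scale,
        bin_area=None if obj.bin_area is None else obj.bin_area * scale,
    )


def apply_disassembly(ps: ParticleSet, m: int) -> ParticleSet:
    """Fragment every particle into ``m`` puncta of area Ap/m placed tangent
    around the parent centroid; C_t is conserved exactly, N_t becomes m·N_t.

    Fragments smaller than 1 px² trigger a warning (sub-pixel puncta would
    not be resolvable), not an error.
    """
    if not (isinstance(m, (int, np.integer)) and m >= 2):
        raise ValueError("m must be an integer >= 2")
    rows, cols = ps.shape
    if any(p.area / m < 1.0 for p in ps.particles):
        warnings.warn(
            "disassembly produced fragments below 1 px²", stacklevel=2
        )
    fragments: list[Particle] = []
    for p in ps.particles:
        frag_area = p.area / m
        r = math.sqrt(frag_area / math.pi) + 1e-9  # tangent ring radius
        for j in range(m):
            theta = 2.0 * math.pi * j / m
            x = min(max(p.x + r * math.cos(theta), 0.0), cols - 1e-9)
            y = min(max(p.y + r * math.sin(theta), 0.0), rows - 1e-9)
            fragments.append(Particle(x=x, y=y, area=frag_area, peak=p.peak))
    return ParticleSet(particles=fragments, shape=ps.shape)


@dataclass
class DivergenceReport:
    """L1 divergences of an observed "after" distribution from the "before"
    state and from a transformed prediction, and which is closer."""

    d_before_counts: float
    d_prediction_counts: float
    d_before_coverage: float
    d_prediction_coverage: float
    closer: str          # "before" | "prediction"
    verdict: str         # "no_effect" | "effect"


def _rebin(dist: SizeDistribution, edges: np.ndarray) -> np.ndarray:
    """Redistribute a distribution's counts onto a common bin grid by the
    representative area of each source bin; raises if any mass falls
    outside the target grid."""
    occupied = dist.counts > 0
    rep = dist.rep_areas[occupied]
    cnt = dist.counts[occupied]
    if rep.size and (rep.min() < edges[0] or rep.max() > edges[-1]):
        raise ValueError("distributions cannot be rebinned onto a common grid")
    hist, _ = np.histogram(rep, bins=edges, weights=cnt)
    return hist


def _l1(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise ValueError("cannot normalise an empty distribution")
    return float(np.abs(a / sa - b / sb).sum())


def compare_to_prediction(
    observed_before: SizeDistribution,
    observed_after: SizeDistribution,
    predicted_after: SizeDistribution,
    bin_edges: np.ndarray | None = None,
) -> DivergenceReport:
    """Is the observed "after" distribution closer to "no change" or to the
    transformed prediction?

    All three distributions are rebinned onto a common grid (supplied or
    constructed to cover every occupied area), then compared by L1 distance
    on normalised counts and on fractional coverage.  The verdict is
    ``no_effect`` when "after" is at least as close to "before" as to the
    prediction on the count distribution.
    """
    dists = (observed_before, observed_after, predicted_after)
    if bin_edges is None:
        lo = min(d.rep_areas[d.counts > 0].min() for d in dists)
        hi = max(d.rep_areas[d.counts > 0].max() for d in dists)
        bin_edges = np.arange(math.floor(lo) - 0.5, math.ceil(hi) + 1.5, 1.0)
    edges = np.asarray(bin_edges, dtype=float)

    before, after, pred = (_rebin(d, edges) for d in dists)
    rep = 0.5 * (edges[:-1] + edges[1:])

    d_before = _l1(after, before)
    d_pred = _l1(after, pred)
    d_before_cov = _l1(after * rep, before * rep)
    d_pred_cov = _l1(after * rep, pred * rep)

    closer = "before" if d_before <= d_pred else "prediction"
    return DivergenceReport(
        d_before_counts=d_before,
        d_prediction_counts=d_pred,
        d_before_coverage=d_before_cov,
        d_prediction_coverage=d_pred_cov,
        closer=closer,
        verdict="no_effect" if closer == "before" else "effect",
    )
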