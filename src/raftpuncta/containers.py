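"""Shared domain containers used across the pipeline.

Every module of the pipeline (synthetic generators, particle statistics,
redistribution models, I-V fitting, gradient quantification) exchanges data
through the small dataclasses defined here rather than bare arrays, so that
invariants — positive areas, strictly increasing voltage protocols, 15-point
gradient profiles — are checked once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Particle",
    "ParticleSet",
    "FluorescenceImage",
    "ROI",
    "IVRecord",
    "CurrentTrace",
    "SequenceRecord",
    "GradientProfile",
    "BoltzmannParams",
    "SizeDistribution",
    "FractionalCoverageCurve",
    "SBResult",
    "GroupComparison",
]


@dataclass(frozen=True)
class Particle:
    """A single punctum: centroid in pixel coordinates, area in pixel²."""

    x: float
    y: float
    area: float
    peak: float = 1.0

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"particle area must be positive, got {self.area}")


@dataclass
class ParticleSet:
    """A collection of puncta within a rectangular frame.

    ``n_total`` (N_t) is the particle count and ``c_total`` (C_t) the total
    particulate area, Σ Ap_i — the two summary statistics that anchor the
    size-distribution and fractional-coverage representations.
    """

    particles: list[Particle]
    shape: tuple[int, int]  # (rows, cols) of the frame, pixels

    def __post_init__(self) -> None:
        rows, cols = self.shape
        for p in self.particles:
            if not (0 <= p.x < cols and 0 <= p.y < rows):
                raise ValueError(
                    f"particle centroid ({p.x}, {p.y}) outside frame {self.shape}"
                )

    @property
    def n_total(self) -> int:
        return len(self.particles)

    @property
    def c_total(self) -> float:
        return float(sum(p.area for p in self.particles))

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.particles], dtype=float)

    @property
    def largest_area(self) -> float:
        """Ap′, the area of the largest particle in the set."""
        if not self.particles:
            raise ValueError("empty particle set has no largest area")
        return float(max(p.area for p in self.particles))


@dataclass
class FluorescenceImage:
    """2-D single-channel intensity image with pixel metadata.

    Intensities are stored as floats but are expected to live in a 16-bit
    camera range; they must be finite and non-negative.
    """

    data: np.ndarray
    pixel_size_um: float = 0.1
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("image intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, half-open pixel bounds.

    ``label`` follows the on-cell / off-cell convention of raw-image
    signal-to-background measurements; ``box`` is used for box scans.
    """

    label: str  # "on_cell" | "off_cell" | "box"
    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI must be non-empty")

    def validate_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.row0 < 0 or self.col0 < 0 or self.row1 > rows or self.col1 > cols:
            raise ValueError(f"ROI {self} outside frame {shape}")

    def extract(self, img: FluorescenceImage) -> np.ndarray:
        self.validate_within(img.shape)
        return img.data[self.row0 : self.row1, self.col0 : self.col1]


@dataclass
class IVRecord:
    """Per-cell current-density–voltage series (pA/pF vs mV, signed)."""

    cell_id: str
    group: str
    voltages_mv: np.ndarray
    currents_pa_pf: np.ndarray

    def __post_init__(self) -> None:
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.currents_pa_pf = np.asarray(self.currents_pa_pf, dtype=float)
        if self.voltages_mv.shape != self.currents_pa_pf.shape:
            raise ValueError("voltage and current arrays must have equal length")
        if self.voltages_mv.size >= 2 and not np.all(np.diff(self.voltages_mv) > 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass
class CurrentTrace:
    """Whole-cell current trace sampled uniformly in time (ms, pA/pF)."""

    time_ms: np.ndarray
    current_pa_pf: np.ndarray
    rate_khz: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pa_pf = np.asarray(self.current_pa_pf, dtype=float)
        if self.time_ms.shape != self.current_pa_pf.shape:
            raise ValueError("time and current arrays must have equal length")
        if self.time_ms.size >= 2:
            dt = np.diff(self.time_ms)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("trace must be uniformly sampled")


_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SequenceRecord:
    """Protein sequence in 1-letter code, optionally annotating the
    designed GPI-motif region (1-based, inclusive residue span)."""

    id: str
    seq: str
    motif_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        bad = set(self.seq) - _AA20
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GradientProfile:
    """15-fraction sucrose-gradient densitometry profile, top → bottom.

    ``raft_indices`` are the 1-based fraction numbers treated as the buoyant
    (raft) interface; fractions 3–6 by default.
    """

    signals: np.ndarray
    raft_indices: tuple[int, ...] = (3, 4, 5, 6)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape != (15,):
            raise ValueError("gradient profile must have exactly 15 fractions")
        if np.any(self.signals < 0):
            raise ValueError("gradient signals must be non-negative")
        if not all(1 <= i <= 15 for i in self.raft_indices):
            raise ValueError("raft indices must be within 1..15")


@dataclass
class BoltzmannParams:
    """Parameters of the Boltzmann I-V function
    I(V) = g·(V − Vrev) / (1 + exp((V50 − V)/k)).

    Units: g in nS/pF, voltages in mV, currents in pA/pF. ``k`` must be
    positive (activation increases with depolarisation); inward currents are
    negative, so for an inward family Vrev > V50.
    """

    g: float
    v_rev: float
    v50: float
    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("slope factor k must be positive")

    def current(self, v: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(v, dtype=float)
        return self.g * (v - self.v_rev) / (1.0 + np.exp((self.v50 - v) / self.k))

    def imax(self, v_min: float = -30.0, v_max: float = 65.0, n: int = 2001) -> tuple[float, float]:
        """Signed extremum of the curve over the voltage protocol and the
        voltage at which it occurs."""
        grid = np.linspace(v_min, v_max, n)
        i = np.asarray(self.current(grid))
        idx = int(np.argmax(np.abs(i)))
        return float(i[idx]), float(grid[idx])


@dataclass
class SizeDistribution:
    """Binned particle-size distribution.

    ``counts`` (Np_i) may be fractional when the distribution is a model
    curve rather than a tally of detected particles.  ``bin_area`` holds the
    exact summed particulate area per bin when the distribution was built
    from a particle list; otherwise it defaults to Np_i · (representative
    area).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    rep_areas: np.ndarray
    bin_area: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.rep_areas = np.asarray(self.rep_areas, dtype=float)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if self.rep_areas.size != self.counts.size:
            raise ValueError("one representative area per bin required")
        if np.any(self.counts < 0):
            raise ValueError("bin counts must be non-negative")
        if self.bin_area is not None:
            self.bin_area = np.asarray(self.bin_area, dtype=float)

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    @property
    def areas_per_bin(self) -> np.ndarray:
        if self.bin_area is not None:
            return self.bin_area
        return self.counts * self.rep_areas

    @property
    def c_total(self) -> float:
        return float(self.areas_per_bin.sum())

    @property
    def percent(self) -> np.ndarray:
        """Np_i / N_t expressed as a percentage."""
        nt = self.n_total
        if nt == 0:
            raise ValueError("empty distribution has no percentage representation")
        return 100.0 * self.counts / nt

    @property
    def largest_area(self) -> float:
        """Ap′ — the largest occupied representative area."""
        occupied = self.rep_areas[self.counts > 0]
        if occupied.size == 0:
            raise ValueError("empty distribution")
        return float(occupied.max())


@dataclass
class FractionalCoverageCurve:
    """Per-bin share of the total particulate area, f_i = Np_i·Ap_i / C_t."""

    rep_areas: np.ndarray
    coverage: np.ndarray
    c_total: float

    def __post_init__(self) -> None:
        self.rep_areas = np.asarray(self.rep_areas, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.rep_areas.shape != self.coverage.shape:
            raise ValueError("mismatched coverage curve arrays")
        if np.any((self.coverage < -1e-12) | (self.coverage > 1 + 1e-12)):
            raise ValueError("coverage values must lie in [0, 1]")


@dataclass(frozen=True)
class SBResult:
    """Signal-to-background of a raw image: on-cell mean / off-cell mean."""

    sb: float
    on_mean: float
    off_mean: float

    @property
    def sb_minus_1(self) -> float:
        return self.sb - 1.0


@dataclass
class GroupComparison:
    """Summary of a group contrast: means ± SEM, n, test statistic, p."""

    test: str  # "t_test" | "anova_snk"
    means: dict
    sems: dict
    ns: dict
    statistic: float
    pvalue: float
    alpha: float = 0.05
    pairwise: list | None = None  # SNK decisions for ANOVA

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < self.alpha)


def sem(x: Sequence[float] | np.ndarray) -> float:
    """Standard error of the mean, sd/√n (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("SEM requires n >= 2")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))
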