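"""Synthetic study inputs with known ground truth.

This module generates every input the downstream analyses consume:

* punctate surface-labelling fields and rendered fluorescence images
  (many small, bright, well-separated particles over a low background,
  emulating the punctate anti-HA surface staining of α₂δ constructs);
* current-density–voltage families on a −30…+65 mV / 5 mV protocol drawn
  from per-group Boltzmann parameters, including a preset group pair with a
  4-fold peak-current-density enhancement and a −13 mV half-activation
  shift;
* whole-cell current traces with a two-exponential envelope
  A·(1−exp(−t/τ_act))·exp(−t/τ_inact);
* C-terminal protein sequences with an intact GPI-anchoring motif, a
  lysine-containing transmembrane replacement tail, or no motif at all;
* bimodal 15-fraction sucrose-gradient densitometry profiles with a
  configurable raft-signal share (~20% by default).

Every generator draws from a `numpy.random.Generator` seeded from a single
integer, so each dataset is bit-reproducible.  Multi-stage drivers split one
top-level seed with `numpy.random.SeedSequence.spawn`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import (
    BoltzmannParams,
    CurrentTrace,
    FluorescenceImage,
    GradientProfile,
    IVRecord,
    Particle,
    ParticleSet,
    SequenceRecord,
)

__all__ = [
    "generate_particle_field",
    "render_image",
    "generate_iv_dataset",
    "preset_alpha2delta_groups",
    "generate_current_trace",
    "trace_peak_time",
    "generate_sequences",
    "generate_gradient_profile",
    "split_seed",
]


def split_seed(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


# ---------------------------------------------------------------------------
# Punctate fields and rendered images
# ---------------------------------------------------------------------------

class PlacementInfeasibleError(RuntimeError):
    """Raised when rejection sampling cannot place all particles."""


def generate_particle_field(
    n: int,
    frame: tuple[int, int] = (512, 512),
    mean_area: float = 12.0,
    sigma: float = 0.35,
    family: str = "lognormal",
    min_area: float = 6.0,
    min_separation: float = 0.0,
    peak: float = 1000.0,
    seed: int = 0,
    max_attempts_per_particle: int = 100,
) -> ParticleSet:
    """Place ``n`` puncta uniformly at random with a hard-core separation.

    Areas are drawn from a lognormal with mean ``mean_area`` (pixel²) and
    log-sd ``sigma`` (or all fixed at ``mean_area`` for ``family="fixed"``),
    rounded to whole pixels and clipped below at ``min_area`` so each
    particle rasterises to an exact pixel count.  Placement uses rejection
    sampling with a capped budget (``max_attempts_per_particle·n`` draws);
    exceeding it raises :class:`PlacementInfeasibleError`.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    rows, cols = frame

    if family == "lognormal":
        mu = math.log(mean_area) - sigma**2 / 2.0
        areas = rng.lognormal(mu, sigma, size=n)
    elif family == "fixed":
        areas = np.full(n, float(mean_area))
    else:
        raise ValueError(f"unknown size-distribution family {family!r}")
    areas = np.maximum(np.round(areas), round(min_area)).astype(float)

    # keep whole rendered disks (radius + blur allowance) inside the frame
    margin = float(np.sqrt(areas.max() / math.pi)) + 4.0 if n else 0.0
    if n and (rows - 2 * margin <= 0 or cols - 2 * margin <= 0):
        raise PlacementInfeasibleError("frame too small for requested particles")

    xs: list[float] = []
    ys: list[float] = []
    budget = max_attempts_per_particle * max(n, 1)
    attempts = 0
    while len(xs) < n:
        if attempts >= budget:
            raise PlacementInfeasibleError(
                f"placed {len(xs)}/{n} particles in {attempts} attempts; "
                "relax min_separation or enlarge the frame"
            )
        attempts += 1
        x = rng.uniform(margin, cols - margin)
        y = rng.uniform(margin, rows - margin)
        if min_separation > 0 and xs:
            d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
            if np.any(d2 < min_separation**2):
                continue
        xs.append(x)
        ys.append(y)

    particles = [
        Particle(x=xs[i], y=ys[i], area=areas[i], peak=peak) for i in range(n)
    ]
    return ParticleSet(particles=particles, shape=frame)


def _disk_pixels(x: float, y: float, area_px: int, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """The ``area_px`` pixels closest to (x, y) — an exact-area raster disk."""
    rows, cols = shape
    r = math.sqrt(area_px / math.pi) + 2.0
    r0, r1 = max(0, int(y - r)), min(rows, int(y + r) + 2)
    c0, c1 = max(0, int(x - r)), min(cols, int(x + r) + 2)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - y) ** 2 + (xx - x) ** 2
    order = np.argsort(d2, axis=None, kind="stable")[:area_px]
    return yy.ravel()[order], xx.ravel()[order]


def render_image(
    field: ParticleSet,
    psf_sigma: float = 0.8,
    background: float = 100.0,
    poisson_noise: bool = False,
    read_noise_sd: float = 0.0,
    pixel_size_um: float = 0.1,
    seed: int | None = None,
) -> FluorescenceImage:
    """Render a particle field into a fluorescence image.

    Each particle is rasterised as an exact-area disk of uniform value
    ``peak`` (so its integrated intensity above background is area × peak),
    convolved with a Gaussian PSF of width ``psf_sigma``, then offset by a
    flat ``background``.  Noise follows the standard camera model: Poisson
    shot noise on signal + background, then additive Gaussian read noise;
    both are optional.
    """
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be non-negative")
    canvas = np.zeros(field.shape, dtype=float)
    for p in field.particles:
        yy, xx = _disk_pixels(p.x, p.y, int(round(p.area)), field.shape)
        canvas[yy, xx] += p.peak
    if psf_sigma > 0:
        canvas = gaussian_filter(canvas, psf_sigma, mode="constant")
    img = canvas + background

    if poisson_noise or read_noise_sd > 0:
        rng = np.random.default_rng(seed)
        if poisson_noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if read_noise_sd > 0:
            img = img + rng.normal(0.0, read_noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)

    meta = {
        "psf_sigma": psf_sigma,
        "background": background,
        "poisson_noise": poisson_noise,
        "read_noise_sd": read_noise_sd,
        "seed": seed,
        # calibration: integrated blob intensity above background = area × peak
        "intensity_area_calibration": "disk_times_peak",
    }
    return FluorescenceImage(data=img, pixel_size_um=pixel_size_um, meta=meta)


# ---------------------------------------------------------------------------
# I-V families
# ---------------------------------------------------------------------------

PROTOCOL_MV = np.arange(-30.0, 70.0, 5.0)  # −30 … +65 mV in 5 mV steps


def preset_alpha2delta_groups(
    imax_ratio: float = 4.0,
    delta_v50: float = -13.0,
    g_base: float = 0.15,
    v_rev: float = 45.0,
    v50_base: float = 2.0,
    k: float = 6.0,
) -> dict[str, BoltzmannParams]:
    """Boltzmann parameters for the reference contrast between channels
    without and with the auxiliary subunit.

    The "+subunit" group has its half-activation voltage hyperpolarised by
    ``delta_v50`` (−13 mV) and its conductance scaled so the peak current
    density over the protocol is enhanced exactly ``imax_ratio``-fold
    (4-fold) relative to the "−subunit" group.
    """
    minus = BoltzmannParams(g=g_base, v_rev=v_rev, v50=v50_base, k=k)
    plus_shape = BoltzmannParams(g=g_base, v_rev=v_rev, v50=v50_base + delta_v50, k=k)
    scale = imax_ratio * abs(minus.imax()[0]) / abs(plus_shape.imax()[0])
    plus = BoltzmannParams(
        g=g_base * scale, v_rev=v_rev, v50=v50_base + delta_v50, k=k
    )
    return {"minus_a2d": minus, "plus_a2d": plus}


def generate_iv_dataset(
    group_params: dict[str, BoltzmannParams],
    n_cells: int = 10,
    noise_sd: float = 0.5,
    seed: int = 0,
    voltages: np.ndarray | None = None,
    v50_jitter_sd: float = 0.0,
    g_jitter_sigma: float = 0.0,
) -> list[IVRecord]:
    """Simulate per-cell I-V records for each group.

    Each cell's currents follow its group's Boltzmann curve plus i.i.d.
    Gaussian noise of ``noise_sd`` pA/pF.  Optional per-cell jitter applies
    a Gaussian offset to V50 and a lognormal factor to g (both default off,
    keeping zero-noise datasets exactly invertible by the fitter).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    v = PROTOCOL_MV if voltages is None else np.asarray(voltages, dtype=float)
    rng = np.random.default_rng(seed)
    records: list[IVRecord] = []
    for group, params in group_params.items():
        for i in range(n_cells):
            g = params.g
            v50 = params.v50
            if g_jitter_sigma > 0:
                g = g * rng.lognormal(0.0, g_jitter_sigma)
            if v50_jitter_sd > 0:
                v50 = v50 + rng.normal(0.0, v50_jitter_sd)
            cell = BoltzmannParams(g=g, v_rev=params.v_rev, v50=v50, k=params.k)
            i_true = np.asarray(cell.current(v))
            noise = rng.normal(0.0, noise_sd, size=v.size) if noise_sd > 0 else 0.0
            records.append(
                IVRecord(
                    cell_id=f"{group}_{i:02d}",
                    group=group,
                    voltages_mv=v,
                    currents_pa_pf=i_true + noise,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Current traces
# ---------------------------------------------------------------------------

def trace_peak_time(tau_act: float, tau_inact: float) -> float:
    """Time of the noiseless extremum of A(1−e^{−t/τa})e^{−t/τi}:
    t* = τ_act · ln(1 + τ_inact/τ_act)."""
    return tau_act * math.log(1.0 + tau_inact / tau_act)


def generate_current_trace(
    tau_act: float = 2.0,
    tau_inact: float = 50.0,
    amplitude: float = -100.0,
    duration_ms: float = 150.0,
    rate_khz: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> CurrentTrace:
    """A 150 ms depolarising-step current with a two-exponential envelope,
    I(t) = amplitude·(1−exp(−t/τ_act))·exp(−t/τ_inact) + noise."""
    if tau_act <= 0 or tau_inact <= 0:
        raise ValueError("time constants must be positive")
    if tau_inact <= tau_act:
        raise ValueError("tau_inact must exceed tau_act")
    t = np.arange(0.0, duration_ms, 1.0 / rate_khz)
    i = amplitude * (1.0 - np.exp(-t / tau_act)) * np.exp(-t / tau_inact)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=t.size)
    return CurrentTrace(time_ms=t, current_pa_pf=i, rate_khz=rate_khz)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_HYDROPHILIC = "STNQDEKR"   # Kyte–Doolittle < 0
_HYDROPHOBIC = "LLLIVF"     # leucine-rich, Kyte–Doolittle mean ≥ +1.5
_ALL20 = "ACDEFGHIKLMNPQRSTVWY"

# Lysine-containing transmembrane-like replacement plus a 17-residue
# hydrophilic intracellular tail, emulating a type-I reporter's TM+cyto
# region substituted downstream of the ω site.
_TM_REPLACEMENT = "KVVVISAILALVVLTIISLIILIML"
_INTRACELLULAR_17 = "QKKPRNEGDSTRESDSS"


def generate_sequences(
    template: str,
    head_len: int = 30,
    spacer_len: int = 8,
    tail_len: int = 10,
    seq_id: str | None = None,
    seed: int = 0,
) -> SequenceRecord:
    """Design a C-terminal test sequence for the GPI-motif rule engine.

    ``template``:

    * ``"intact_gpi"`` — random head, then ω (small residue) + two small
      residues (ω+1, ω+2) + ≥7 hydrophilic spacer residues + a C-terminal
      leucine-rich hydrophobic stretch.  Satisfies all four motif elements.
    * ``"disrupted_tail"`` — same head and ω, but everything downstream of ω
      replaced by a lysine-containing TM-like segment plus a 17-residue
      hydrophilic intracellular tail (the chimera design), which breaks the
      spacer and terminal-hydrophobic rules.
    * ``"no_motif"`` — random head plus an all-lysine tail; no candidate ω
      can satisfy the spacer + tail rules.
    """
    if spacer_len < 0 or tail_len < 0:
        raise ValueError("lengths must be non-negative")
    rng = np.random.default_rng(seed)
    head = "".join(rng.choice(list(_ALL20), size=head_len))

    if template == "intact_gpi":
        omega_block = "SGA"  # ω = S, ω+1 = G, ω+2 = A
        spacer = "".join(rng.choice(list(_HYDROPHILIC), size=max(spacer_len, 7)))
        tail = "".join(rng.choice(list(_HYDROPHOBIC), size=max(tail_len, 8)))
        seq = head + omega_block + spacer + tail
        motif = (head_len + 1, len(seq))
    elif template == "disrupted_tail":
        seq = head + "S" + _TM_REPLACEMENT + _INTRACELLULAR_17
        motif = (head_len + 1, len(seq))
    elif template == "no_motif":
        seq = head + "K" * max(tail_len, 20)
        motif = None
    else:
        raise ValueError(f"unknown sequence template {template!r}")

    return SequenceRecord(id=seq_id or template, seq=seq, motif_region=motif)


# ---------------------------------------------------------------------------
# Gradient profiles
# ---------------------------------------------------------------------------

def generate_gradient_profile(
    raft_weight: float = 0.2,
    raft_peak: float = 4.0,
    nonraft_peak: float = 11.0,
    width: float = 0.7,
    total: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    raft_indices: tuple[int, ...] = (3, 4, 5, 6),
) -> GradientProfile:
    """Two-component densitometry profile over 15 gradient fractions.

    Each component is a Gaussian over the fraction index, normalised to unit
    mass on the 15-point grid, so the total signal equals ``total`` exactly
    and the raft : non-raft split equals ``raft_weight : 1−raft_weight`` up
    to discretisation (the small component mass falling outside the raft
    index set).

    Noise is Gaussian and signal-proportional, as in film densitometry where
    fluctuations grow with band density: ``noise_sd`` is the standard
    deviation applied at the peak fraction, scaled down linearly with signal
    elsewhere.  Near-empty fractions therefore stay near zero instead of
    being rectified upward by clipping.
    """
    if not 0.0 <= raft_weight <= 1.0:
        raise ValueError("raft_weight must lie in [0, 1]")
    if not (1 <= raft_peak <= 15 and 1 <= nonraft_peak <= 15):
        raise ValueError("peak positions must lie within fractions 1..15")
    x = np.arange(1, 16, dtype=float)

    def component(mu: float) -> np.ndarray:
        w = np.exp(-((x - mu) ** 2) / (2.0 * width**2))
        return w / w.sum()

    profile = total * (
        raft_weight * component(raft_peak)
        + (1.0 - raft_weight) * component(nonraft_peak)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        local_sd = noise_sd * profile / profile.max() if profile.max() > 0 else 0.0
        profile = np.clip(profile + rng.normal(0.0, 1.0, size=15) * local_sd, 0.0, None)
    return GradientProfile(signals=profile, raft_indices=raft_indices)
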