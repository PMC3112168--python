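"""Boltzmann I-V fitting, exponential kinetics and group summaries.

Per-cell current-density–voltage relationships are fitted with

    I(V) = g·(V − Vrev) / (1 + exp((V50 − V)/k)),

the product of a linear driving force and a voltage-dependent activation
gate (k > 0, activation grows with depolarisation; inward currents are
negative).  The peak current density Imax is the signed extremum of the
fitted curve over the protocol range.  Initialisation is deterministic and
protocol-aware — Vrev from the zero crossing of the descending limb, V50
from the half-extremal voltage, k = 5 mV, g from the terminal slope — so a
fit is a pure function of the data.

Activation/inactivation kinetics are quantified by single-exponential fits
to the rising (onset→peak) and decaying (post-peak→end) phases of a trace.

Group contrasts (fold-change in |Imax|, ΔV50, etc.) are summarised as
mean ± SEM with unpaired t-tests against a reference group, starred at the
0.05 / 0.01 / 0.001 tiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .containers import BoltzmannParams, CurrentTrace, IVRecord, sem

__all__ = [
    "boltzmann",
    "fit_boltzmann",
    "BoltzmannFit",
    "peak_current_density",
    "fit_single_exponential",
    "KineticFit",
    "summarize_groups",
    "GroupSummary",
    "FitError",
    "NoPeakError",
]


class FitError(RuntimeError):
    """Non-convergent or degenerate least-squares fit."""


class NoPeakError(ValueError):
    """Trace has no identifiable peak to delimit kinetic phases."""


def boltzmann(v: np.ndarray, g: float, v_rev: float, v50: float, k: float) -> np.ndarray:
    return g * (v - v_rev) / (1.0 + np.exp((v50 - v) / k))


@dataclass
class BoltzmannFit:
    params: BoltzmannParams
    covariance: np.ndarray
    imax: float              # signed extremum of the fitted curve
    v_at_imax: float
    residual_norm: float
    cell_id: str = ""
    group: str = ""


def _initial_guess(v: np.ndarray, i: np.ndarray) -> tuple[float, float, float, float]:
    ext_idx = int(np.argmax(np.abs(i)))
    i_ext = i[ext_idx]

    # Vrev: zero crossing of the descending limb, linearly interpolated
    v_rev = v[-1] + 5.0
    for j in range(ext_idx, len(v) - 1):
        if i[j] == 0.0:
            v_rev = v[j]
            break
        if i[j] * i[j + 1] < 0:
            frac = i[j] / (i[j] - i[j + 1])
            v_rev = v[j] + frac * (v[j + 1] - v[j])
            break

    # V50: voltage at half-extremal current magnitude on the rising limb
    half = abs(i_ext) / 2.0
    v50 = v[ext_idx] - 10.0
    mags = np.abs(i[: ext_idx + 1])
    for j in range(len(mags) - 1):
        if mags[j] <= half <= mags[j + 1]:
            frac = (half - mags[j]) / (mags[j + 1] - mags[j]) if mags[j + 1] > mags[j] else 0.0
            v50 = v[j] + frac * (v[j + 1] - v[j])
            break

    # g from the slope of the final two points (gate ≈ fully open there)
    g0 = abs((i[-1] - i[-2]) / (v[-1] - v[-2])) if len(v) >= 2 else 0.1
    return max(g0, 1e-4), v_rev, v50, 5.0


def fit_boltzmann(rec: IVRecord) -> BoltzmannFit:
    """Deterministic least-squares Boltzmann fit of one cell's I-V record.

    Requires ≥ 6 voltage points.  Raises :class:`FitError` with the initial
    guesses and final residual on non-convergence, or a ``ValueError`` for
    degenerate (all-zero / single-signed-noise) data.
    """
    v = rec.voltages_mv
    i = rec.currents_pa_pf
    if v.size < 6:
        raise ValueError("need at least 6 voltage points to fit")
    if np.allclose(i, 0.0):
        raise ValueError("degenerate data: currents are identically zero")

    p0 = _initial_guess(v, i)
    bounds = ([0.0, -200.0, -200.0, 0.1], [100.0, 200.0, 200.0, 100.0])
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann, v, i, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge (p0={p0}): {exc}") from exc

    params = BoltzmannParams(g=popt[0], v_rev=popt[1], v50=popt[2], k=popt[3])
    imax, v_at = params.imax(v_min=float(v.min()), v_max=float(v.max()))
    resid = float(np.linalg.norm(i - boltzmann(v, *popt)))
    return BoltzmannFit(
        params=params,
        covariance=pcov,
        imax=imax,
        v_at_imax=v_at,
        residual_norm=resid,
        cell_id=rec.cell_id,
        group=rec.group,
    )


def peak_current_density(rec: IVRecord) -> tuple[float, float]:
    """Signed extremum of the *measured* current density over the protocol
    and the command voltage at which it occurs."""
    if rec.currents_pa_pf.size == 0:
        raise ValueError("empty record")
    idx = int(np.argmax(np.abs(rec.currents_pa_pf)))
    return float(rec.currents_pa_pf[idx]), float(rec.voltages_mv[idx])


@dataclass
class KineticFit:
    tau_ms: float
    amplitude: float
    phase: str                  # "activation" | "inactivation"
    window_ms: tuple[float, float]
    residual_norm: float


def _rising(t: np.ndarray, a: float, tau: float) -> np.ndarray:
    return a * (1.0 - np.exp(-t / tau))


def _decaying(t: np.ndarray, a: float, tau: float) -> np.ndarray:
    return a * np.exp(-t / tau)


def fit_single_exponential(
    trace: CurrentTrace,
    phase: str,
    t_skip_ms: float = 0.0,
    decay_start_factor: float = 2.0,
) -> KineticFit:
    """Single-exponential fit of one kinetic phase of a current trace.

    The peak (extremum of |I|) splits the trace: the activation window runs
    from onset (after ``t_skip_ms``, to skip any capacitive transient) to
    the peak and is fitted with A·(1−exp(−t/τ)); the inactivation window
    runs from ``decay_start_factor``·t_peak (where the rising gate has
    essentially saturated) to the end, fitted with A·exp(−t′/τ).

    Because the rising phase is attenuated by the concurrent decay, the
    activation fit holds the decay time constant fixed (estimated first
    from the post-peak phase, when one is available) inside the rising
    model, leaving τ_act as the single free exponential.
    """
    t = trace.time_ms
    i = trace.current_pa_pf
    if np.ptp(i) == 0:
        raise NoPeakError("flat trace has no identifiable peak")
    peak_idx = int(np.argmax(np.abs(i)))
    t_peak = t[peak_idx]

    if phase == "activation":
        if t_peak <= t_skip_ms:
            raise NoPeakError("peak occurs before the activation window opens")
        sel = (t >= t_skip_ms) & (t <= t_peak)
        tau_decay = np.inf
        try:
            tau_decay = fit_single_exponential(
                trace, "inactivation", decay_start_factor=decay_start_factor
            ).tau_ms
        except (NoPeakError, FitError):
            pass

        def model(tt: np.ndarray, a: float, tau: float) -> np.ndarray:
            return _rising(tt, a, tau) * np.exp(-tt / tau_decay)

        p0 = (i[peak_idx], max(t_peak / 3.0, 1e-3))
    elif phase == "inactivation":
        t_start = max(t_peak * decay_start_factor, t_peak)
        sel = t >= t_start
        if sel.sum() < 3:
            raise NoPeakError("too few samples after the peak to fit decay")
        model = _decaying
        t = t - t_start
        p0 = (i[sel][0], max((trace.time_ms[-1] - t_start) / 3.0, 1e-3))
    else:
        raise ValueError("phase must be 'activation' or 'inactivation'")

    try:
        popt, _ = optimize.curve_fit(model, t[sel], i[sel], p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(i[sel] - model(t[sel], *popt)))
    lo, hi = float(trace.time_ms[sel][0]), float(trace.time_ms[sel][-1])
    tau = abs(float(popt[1]))
    return KineticFit(
        tau_ms=tau,
        amplitude=float(popt[0]),
        phase=phase,
        window_ms=(lo, hi),
        residual_norm=resid,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupSummary:
    table: pd.DataFrame          # per-group mean ± SEM rows
    contrasts: pd.DataFrame      # fold-changes / differences vs reference
    reference: str


def summarize_groups(
    fits: dict[str, list[BoltzmannFit]],
    reference: str,
) -> GroupSummary:
    """Per-group mean ± SEM of Imax, V50, Vrev, k and g, plus contrasts
    against ``reference``: |Imax| fold-change, ΔV50, and unpaired t-tests
    starred at the 0.05/0.01/0.001 tiers."""
    if reference not in fits:
        raise ValueError(f"reference group {reference!r} not present")
    for name, group_fits in fits.items():
        if len(group_fits) < 2:
            raise ValueError(f"group {name!r} has n={len(group_fits)} < 2 cells")

    quantities = {
        "imax_pa_pf": lambda f: f.imax,
        "v50_mv": lambda f: f.params.v50,
        "v_rev_mv": lambda f: f.params.v_rev,
        "k_mv": lambda f: f.params.k,
        "g_ns_pf": lambda f: f.params.g,
    }
    rows = []
    values: dict[str, dict[str, np.ndarray]] = {}
    for name, group_fits in fits.items():
        values[name] = {
            q: np.array([getter(f) for f in group_fits])
            for q, getter in quantities.items()
        }
        row: dict[str, object] = {"group": name, "n": len(group_fits)}
        for q in quantities:
            row[f"{q}_mean"] = values[name][q].mean()
            row[f"{q}_sem"] = sem(values[name][q])
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group")

    ref_vals = values[reference]
    contrast_rows = []
    for name in fits:
        if name == reference:
            continue
        row = {
            "group": name,
            "imax_fold_change": abs(values[name]["imax_pa_pf"].mean())
            / abs(ref_vals["imax_pa_pf"].mean()),
            "delta_v50_mv": values[name]["v50_mv"].mean()
            - ref_vals["v50_mv"].mean(),
        }
        for q in quantities:
            _, p = sps.ttest_ind(values[name][q], ref_vals[q], equal_var=True)
            row[f"{q}_p"] = float(p)
            row[f"{q}_flag"] = _stars(float(p))
        contrast_rows.append(row)
    contrasts = pd.DataFrame(contrast_rows)
    if not contrasts.empty:
        contrasts = contrasts.set_index("group")
    return GroupSummary(table=table, contrasts=contrasts, reference=reference)
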