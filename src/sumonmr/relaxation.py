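"""Backbone 15N spin-relaxation analysis: T1, T2 and steady-state hetNOE.

T1 and T2 are obtained per residue by least-squares fitting of a
mono-exponential decay I(t) = I0 * exp(-t/T) to peak intensities recorded
over a series of relaxation delays.  The heteronuclear NOE is the ratio of
cross-peak intensities in the proton-saturated and unsaturated spectra.
Low T1, high T2 and hetNOE values near or below zero mark residues with
large ps-ns backbone motion (flexible tails); high hetNOE marks the rigid
structured core.

Fitting is done in intensity space, not log space: noisy points near or
below zero would be undefined under a log transform.  Standard errors come
from the parameter covariance of the nonlinear fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DecayFitError

logger = logging.getLogger(__name__)

# Relaxation-delay grids (seconds) used for the measurements this module targets.
T1_DELAYS = (0.002, 0.005, 0.01, 0.03, 0.05, 0.1, 0.2, 0.4)
T2_DELAYS = (0.002, 0.008, 0.016, 0.024, 0.032, 0.064, 0.096, 0.2)

HETNOE_FLEXIBLE_CUTOFF = 0.5  # conventional rigidity cutoff for the NOE ratio


@dataclass
class RelaxationSeries:
    """Per-residue intensities across delays (T1/T2) or sat/unsat pairs (hetNOE).

    For decay kinds, ``intensities`` maps residue_id -> array parallel to
    ``delays``.  For hetNOE, it maps residue_id -> (saturated, unsaturated).
    """

    kind: str  # "T1" | "T2" | "hetNOE"
    intensities: dict[int, np.ndarray]
    delays: tuple[float, ...] = ()
    noise_estimate: float = 0.0

    def __post_init__(self):
        if self.kind not in ("T1", "T2", "hetNOE"):
            raise ValueError(f"unknown relaxation kind {self.kind!r}")
        if self.kind != "hetNOE":
            d = np.asarray(self.delays, dtype=float)
            if len(d) < 3 or np.any(np.diff(d) <= 0) or d[0] < 0:
                raise ValueError("delays must be >= 3 non-negative, strictly increasing values")


@dataclass(frozen=True)
class RelaxationResult:
    residue_id: int
    value: float  # T in seconds, or the NOE ratio
    stderr: float
    fit_quality: float = 0.0  # residual 2-norm (decay fits)


def _decay(t, i0, T):
    return i0 * np.exp(-t / T)


def fit_decay(delays, intensities) -> tuple[float, float, tuple[float, float]]:
    """Fit I(t) = I0 * exp(-t/T); returns (T, I0, (T_stderr, I0_stderr)).

    Initialisation is deterministic: I0 starts at the first intensity and T
    at the delay where the intensity is closest to I0/e.  Data that do not
    decay (best T <= 0 or a divergent fit) raise :class:`DecayFitError`.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape or t.size < 3:
        raise ValueError("need >= 3 matching (delay, intensity) points")
    if np.ptp(y) == 0:
        raise ValueError("all intensities equal: nothing to fit")

    i0_guess = y[0]
    if i0_guess == 0:
        i0_guess = y[np.argmax(np.abs(y))]
    t_guess = t[np.argmin(np.abs(y - i0_guess / math.e))]
    if t_guess <= 0:
        t_guess = t[t > 0][0] if np.any(t > 0) else 0.1

    try:
        popt, pcov = curve_fit(
            _decay, t, y, p0=(i0_guess, t_guess), maxfev=10000, method="lm"
        )
    except RuntimeError as exc:
        raise DecayFitError(f"exponential fit did not converge: {exc}") from exc
    i0, T = popt
    if T <= 0 or not np.all(np.isfinite(pcov)):
        raise DecayFitError(f"non-decaying data (fitted T = {T:.4g} s)")
    if T > 100.0 * t.max():
        # T far beyond the sampled delay range: the data carry no decay and
        # the exponential degenerates to a flat line
        raise DecayFitError(f"divergent fit: T = {T:.4g} s with delays up to {t.max()} s")
    perr = np.sqrt(np.diag(pcov))
    return float(T), float(i0), (float(perr[1]), float(perr[0]))


def het_noe(saturated: float, unsaturated: float, noise: float = 0.0) -> tuple[float, float]:
    """hetNOE ratio I_sat/I_unsat with first-order error propagation."""
    if unsaturated == 0:
        raise ValueError("unsaturated intensity must be nonzero")
    ratio = saturated / unsaturated
    if noise == 0.0:
        return ratio, 0.0
    if saturated == 0:
        stderr = abs(noise / unsaturated)
    else:
        stderr = abs(ratio) * math.hypot(noise / saturated, noise / unsaturated)
    return ratio, stderr


def fit_series(series: RelaxationSeries) -> list[RelaxationResult]:
    """Per-residue fit of a whole series; failed decays are logged and skipped."""
    results = []
    for resid in sorted(series.intensities):
        data = series.intensities[resid]
        if series.kind == "hetNOE":
            sat, unsat = float(data[0]), float(data[1])
            ratio, err = het_noe(sat, unsat, series.noise_estimate)
            results.append(RelaxationResult(resid, ratio, err))
        else:
            try:
                T, i0, (t_err, _) = fit_decay(series.delays, data)
            except (DecayFitError, ValueError) as exc:
                logger.warning("residue %d: %s (skipped)", resid, exc)
                continue
            resid_norm = float(
                np.linalg.norm(_decay(np.asarray(series.delays), i0, T) - np.asarray(data))
            )
            results.append(RelaxationResult(resid, T, t_err, resid_norm))
    return results


def flexibility_profile(
    hetnoe_results: list[RelaxationResult],
    cutoff: float = HETNOE_FLEXIBLE_CUTOFF,
) -> dict[int, str]:
    """Classify residues by hetNOE: <= 0 "highly_flexible", < cutoff "flexible", else "rigid"."""
    labels = {}
    for r in hetnoe_results:
        if r.value <= 0:
            labels[r.residue_id] = "highly_flexible"
        elif r.value < cutoff:
            labels[r.residue_id] = "flexible"
        else:
            labels[r.residue_id] = "rigid"
    return labels
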