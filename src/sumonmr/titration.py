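"""Chemical-shift-perturbation titration analysis.

An unlabelled ligand (here typically a SUMO-interacting-motif peptide) is
titrated into a 15N-labelled protein sample and a 1H-15N HSQC is recorded
at every titration point.  In the fast-exchange regime each amide
cross-peak sits at the population-weighted average of its free and bound
positions, so the observed displacement of a peak is proportional to the
bound fraction of the protein.  This module

* computes the weighted chemical shift perturbation (CSP) per residue,
* matches peaks across titration points and flags residues whose peaks
  exchange-broaden out of the spectra,
* calls the binding interface with the mean + 2*SD rule, and
* fits the dissociation constant Kd with the exact 1:1 quadratic
  binding isotherm, with bootstrap uncertainties.

The CSP combines the proton and nitrogen shift changes as

    CSP = sqrt( (dH_free - dH_bound)^2 + ((dN_free - dN_bound)/5)^2 )

with the conventional 1/5 down-weighting of the 15N axis, and the
observed CSP at total concentrations [P]t, [L]t follows

    CSP_obs = CSP_max * f_bound,
    f_bound = ( ([P]t+[L]t+Kd) - sqrt(([P]t+[L]t+Kd)^2 - 4 [P]t [L]t) ) / (2 [P]t).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    AmbiguousMatchError,
    DegenerateDataError,
    FitError,
    PeakMismatchError,
    UnderdeterminedFitError,
)

logger = logging.getLogger(__name__)

NITROGEN_WEIGHT = 5.0  # 15N axis down-scaling in the weighted shift distance
DEFAULT_MATCH_GATE = 0.15  # ppm, weighted distance gate for peak matching


@dataclass(frozen=True)
class Peak:
    """One assigned backbone amide cross-peak."""

    residue_id: int
    delta_h: float  # 1H shift, ppm
    delta_n: float  # 15N shift, ppm
    intensity: float | None = None

    def __post_init__(self):
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_n)):
            raise ValueError("peak shifts must be finite")


@dataclass
class TitrationPoint:
    """Peak list at one (protein_total, ligand_total) condition, in uM."""

    protein_total: float
    ligand_total: float
    peaks: list[Peak]

    def __post_init__(self):
        if self.protein_total < 0 or self.ligand_total < 0:
            raise ValueError("concentrations must be non-negative")
        ids = [p.residue_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError("at most one peak per residue per titration point")

    @property
    def peak_map(self) -> dict[int, Peak]:
        return {p.residue_id: p for p in self.peaks}


@dataclass
class TitrationSeries:
    """Ordered titration points; exactly one must have zero ligand (the reference)."""

    points: list[TitrationPoint]

    @property
    def reference(self) -> TitrationPoint:
        refs = [p for p in self.points if p.ligand_total == 0]
        if not refs:
            raise DegenerateDataError("titration series has no zero-ligand reference point")
        return refs[0]

    @property
    def bound_points(self) -> list[TitrationPoint]:
        return [p for p in self.points if p.ligand_total > 0]


@dataclass(frozen=True)
class CSPRecord:
    """Per-residue CSP between the reference and one endpoint.

    Broadened residues carry no numeric CSP: their peaks disappeared from
    the spectrum, which is qualitative interface evidence but yields no
    measurable displacement.
    """

    residue_id: int
    csp: float | None
    broadened: bool = False

    def __post_init__(self):
        if self.broadened and self.csp is not None:
            raise ValueError("broadened records carry no numeric csp")
        if not self.broadened and (self.csp is None or self.csp < 0):
            raise ValueError("non-broadened records need a csp >= 0")


@dataclass
class InterfaceCall:
    threshold: float  # ppm, mean + multiplier*SD over non-broadened CSPs
    interface_residues: set[int]
    excluded_broadened: set[int]


@dataclass
class BindingFit:
    """Result of fitting the 1:1 isotherm to a titration series."""

    kd: float  # uM
    kd_stderr: float  # bootstrap SD, uM
    kd_ci95: tuple[float, float]  # percentile bootstrap interval, uM
    csp_max: dict[int, float]  # per-residue CSP_max, ppm
    csp_max_stderr: dict[int, float]
    residuals: np.ndarray  # predicted - observed, ppm (residues x bound points)
    fit_mode: str  # "shared" | "per-residue"
    residues_used: tuple[int, ...] = ()
    n_bootstrap: int = 0


def compute_csp(free: Peak, bound: Peak) -> float:
    """Weighted shift distance between the free and bound positions of one residue."""
    if free.residue_id != bound.residue_id:
        raise PeakMismatchError(
            f"cannot pair residue {free.residue_id} with residue {bound.residue_id}"
        )
    return weighted_distance(free.delta_h - bound.delta_h, free.delta_n - bound.delta_n)


def weighted_distance(dh: float, dn: float) -> float:
    return math.hypot(dh, dn / NITROGEN_WEIGHT)


def match_peaks(
    reference: TitrationPoint,
    other: TitrationPoint,
    gate: float = DEFAULT_MATCH_GATE,
) -> tuple[dict[int, Peak], set[int]]:
    """Pair each reference peak with its nearest peak in `other`.

    Assignments usually exist only for the free (reference) spectrum; at
    later titration points peaks have moved, so each reference residue is
    matched to the closest peak in weighted-shift distance within `gate`.
    Residues with no candidate inside the gate are reported as broadened
    (their peak has exchanged out).  Two reference peaks claiming the same
    target is a genuine ambiguity and raises rather than guessing.

    Returns (mapping residue_id -> matched Peak, set of broadened residue_ids).
    """
    mapping: dict[int, Peak] = {}
    broadened: set[int] = set()
    claimed: dict[int, int] = {}  # index into other.peaks -> claiming residue
    for ref_peak in sorted(reference.peaks, key=lambda p: p.residue_id):
        candidates = []  # (distance, candidate residue_id, index)
        for idx, cand in enumerate(other.peaks):
            d = weighted_distance(ref_peak.delta_h - cand.delta_h, ref_peak.delta_n - cand.delta_n)
            if d <= gate:
                candidates.append((d, cand.residue_id, idx))
        if candidates:
            candidates.sort()
            if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
                logger.warning(
                    "peak match tie for residue %d broken by lower candidate residue_id",
                    ref_peak.residue_id,
                )
            best_idx = candidates[0][2]
        else:
            best_idx = None
        if best_idx is None:
            broadened.add(ref_peak.residue_id)
            continue
        if best_idx in claimed:
            raise AmbiguousMatchError(
                f"residues {claimed[best_idx]} and {ref_peak.residue_id} both match the "
                f"same peak at ({other.peaks[best_idx].delta_h:.3f}, "
                f"{other.peaks[best_idx].delta_n:.3f})"
            )
        claimed[best_idx] = ref_peak.residue_id
        mapping[ref_peak.residue_id] = other.peaks[best_idx]
    return mapping, broadened


def track_peaks(
    series: TitrationSeries,
    endpoint: int,
    gate: float = DEFAULT_MATCH_GATE,
) -> tuple[dict[int, Peak], set[int]]:
    """Follow each assigned reference peak through successive titration points.

    Assignments exist only at the zero-ligand reference, and in fast
    exchange peaks move a little at every addition of ligand; chaining
    nearest-neighbour matches point by point follows displacements far
    larger than the single-step gate.  A residue lost at any intermediate
    point stays broadened.  Returns the tracked peak positions at
    ``series.points[endpoint]`` plus the broadened residue set.
    """
    ref_idx = next(i for i, p in enumerate(series.points) if p.ligand_total == 0)
    endpoint = endpoint % len(series.points)
    step = 1 if endpoint >= ref_idx else -1
    path = list(range(ref_idx, endpoint + step, step))

    current = {p.residue_id: p for p in series.points[ref_idx].peaks}
    broadened: set[int] = set()
    for nxt in path[1:]:
        pseudo = TitrationPoint(
            series.points[ref_idx].protein_total,
            0.0,
            [Peak(r, pk.delta_h, pk.delta_n) for r, pk in current.items()],
        )
        mapping, lost = match_peaks(pseudo, series.points[nxt], gate=gate)
        broadened |= lost
        current = {r: pk for r, pk in mapping.items()}
    return current, broadened


def csp_profile(
    series: TitrationSeries,
    endpoint: int = -1,
    gate: float = DEFAULT_MATCH_GATE,
) -> list[CSPRecord]:
    """Per-residue CSP between the zero-ligand reference and `series.points[endpoint]`."""
    ref = series.reference
    tracked, broadened = track_peaks(series, endpoint, gate=gate)
    records = []
    for resid in sorted(ref.peak_map):
        if resid in broadened or resid not in tracked:
            records.append(CSPRecord(resid, None, broadened=True))
        else:
            matched = tracked[resid]
            dh = ref.peak_map[resid].delta_h - matched.delta_h
            dn = ref.peak_map[resid].delta_n - matched.delta_n
            records.append(CSPRecord(resid, weighted_distance(dh, dn)))
    return records


def call_interface(
    records: Iterable[CSPRecord],
    sd_multiplier: float = 2.0,
    sd_ddof: int = 0,
) -> InterfaceCall:
    """Identify the binding interface as residues with CSP above mean + 2*SD.

    The mean and SD are computed over non-broadened records only; residues
    whose peaks broadened out are excluded from the statistics and reported
    separately as qualitative interface candidates.  Population SD
    (``sd_ddof=0``) is the default; the comparison is a strict ``>``.
    """
    records = list(records)
    numeric = [r for r in records if not r.broadened]
    broadened = {r.residue_id for r in records if r.broadened}
    if not numeric:
        raise DegenerateDataError("all residues broadened: no CSP statistics possible")
    if len(numeric) < 3:
        raise DegenerateDataError(
            f"need >= 3 non-broadened records for interface statistics, got {len(numeric)}"
        )
    values = np.array([r.csp for r in numeric])
    threshold = float(values.mean() + sd_multiplier * values.std(ddof=sd_ddof))
    interface = {r.residue_id for r in numeric if r.csp > threshold}
    return InterfaceCall(threshold, interface, broadened)


def fraction_bound(pt: float, lt: float, kd: float) -> float:
    """Bound fraction of the protein for a 1:1 equilibrium at total concentrations pt, lt.

    Exact root of the binding quadratic.  Evaluated in the conjugate form
    2*lt / (s + sqrt(s^2 - 4 pt lt)) with s = pt + lt + kd, which avoids the
    catastrophic cancellation of the textbook (s - sqrt(...))/(2 pt) form
    when kd >> pt, lt.
    """
    if pt <= 0:
        raise ValueError(f"total protein concentration must be > 0, got {pt}")
    if lt < 0 or kd < 0:
        raise ValueError("ligand concentration and Kd must be >= 0")
    if lt == 0:
        return 0.0
    s = pt + lt + kd
    disc = s * s - 4.0 * pt * lt
    # disc >= (pt - lt)^2 + kd terms; clamp tiny negative round-off
    root = math.sqrt(max(disc, 0.0))
    return 2.0 * lt / (s + root)


def predict_csp(pt: float, lt: float, kd: float, csp_max: float) -> float:
    """Observed CSP predicted by the quadratic 1:1 isotherm: CSP_max * f_bound."""
    if csp_max < 0:
        raise ValueError("csp_max must be >= 0")
    return csp_max * fraction_bound(pt, lt, kd)


# ---------------------------------------------------------------------------
# Kd fitting


def _csp_matrix(
    series: TitrationSeries,
    residues: Sequence[int],
    gate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed CSPs for `residues` at every bound point.

    Returns (y, pt, lt) with y of shape (n_residues, n_points).  Raises if a
    selected residue is broadened at any used point, since a vanished peak
    yields no CSP to fit.
    """
    bound_idx = [i for i, p in enumerate(series.points) if p.ligand_total > 0]
    pt = np.array([series.points[i].protein_total for i in bound_idx])
    lt = np.array([series.points[i].ligand_total for i in bound_idx])
    y = np.empty((len(residues), len(bound_idx)))
    for j, i_point in enumerate(bound_idx):
        point = series.points[i_point]
        profile = {r.residue_id: r for r in csp_profile(series, i_point, gate=gate)}
        for i, resid in enumerate(residues):
            rec = profile.get(resid)
            if rec is None or rec.broadened:
                raise DegenerateDataError(
                    f"residue {resid} is broadened/missing at point [L]t={point.ligand_total}; "
                    "exclude it from the fit"
                )
            y[i, j] = rec.csp
    return y, pt, lt


def _fit_shared_kd(
    y: np.ndarray, pt: np.ndarray, lt: np.ndarray, kd_bounds: tuple[float, float]
) -> tuple[float, np.ndarray]:
    """Profiled least squares: for fixed Kd the per-residue CSP_max is linear.

    Minimising over log Kd with CSP_max profiled out reduces the global fit
    to a 1-D bounded search, which is fast and has no multi-start issues.
    """

    def amplitudes(kd: float) -> np.ndarray:
        f = np.array([fraction_bound(p, l, kd) for p, l in zip(pt, lt)])
        denom = float(f @ f)
        if denom == 0.0:
            return np.zeros(y.shape[0]), f
        return np.clip((y @ f) / denom, 0.0, None), f

    def sse(log_kd: float) -> float:
        a, f = amplitudes(math.exp(log_kd))
        r = y - a[:, None] * f[None, :]
        return float((r * r).sum())

    res = minimize_scalar(
        sse,
        bounds=(math.log(kd_bounds[0]), math.log(kd_bounds[1])),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise FitError(f"Kd optimisation failed: {res.message}")
    kd = math.exp(res.x)
    a, _ = amplitudes(kd)
    return kd, a


def fit_kd(
    series: TitrationSeries,
    residues: Iterable[int] | None = None,
    mode: str = "shared",
    n_bootstrap: int = 500,
    seed: int = 0,
    gate: float = DEFAULT_MATCH_GATE,
    kd_bounds: tuple[float, float] = (1e-3, 1e6),
) -> BindingFit | dict[int, BindingFit]:
    """Fit the dissociation constant to the observed CSPs.

    In ``shared`` mode one global Kd and one CSP_max per residue are
    estimated across all selected residues; in ``per-residue`` mode each
    residue is fit independently and a mapping residue -> BindingFit is
    returned.  When `residues` is None, residues whose endpoint CSP exceeds
    half the mean+2SD interface threshold are selected automatically
    (binding-insensitive peaks contribute only noise to the Kd).

    Uncertainties are nonparametric: the bound titration points are
    resampled with replacement `n_bootstrap` times and the fit repeated;
    the Kd standard error is the bootstrap SD and the 95% interval is the
    basic bootstrap interval computed on the log-Kd scale.
    """
    if mode not in ("shared", "per-residue"):
        raise ValueError(f"unknown fit mode {mode!r}")
    if len(series.points) < 3:
        raise UnderdeterminedFitError("need >= 3 titration points to fit a binding curve")

    if residues is None:
        records = csp_profile(series, len(series.points) - 1, gate=gate)
        call = call_interface(records)
        residues = sorted(
            r.residue_id
            for r in records
            if not r.broadened and r.csp > call.threshold / 2.0
        )
        if not residues:
            raise DegenerateDataError("no residue passed the minimum-CSP filter")
    residues = tuple(sorted(residues))

    y, pt, lt = _csp_matrix(series, residues, gate)
    n_obs = y.size
    n_par = 1 + len(residues)
    if mode == "shared" and n_obs < n_par:
        raise UnderdeterminedFitError(
            f"{n_obs} observations cannot constrain {n_par} parameters"
        )
    if mode == "per-residue" and y.shape[1] < 2:
        raise UnderdeterminedFitError("per-residue fits need >= 2 bound points")

    rng = np.random.default_rng(seed)

    def one_fit(ysub: np.ndarray, ptsub: np.ndarray, ltsub: np.ndarray):
        return _fit_shared_kd(ysub, ptsub, ltsub, kd_bounds)

    if mode == "per-residue":
        out: dict[int, BindingFit] = {}
        for i, resid in enumerate(residues):
            out[resid] = _bootstrap_fit(
                y[i : i + 1], pt, lt, (resid,), one_fit, n_bootstrap, rng, "per-residue"
            )
        return out
    return _bootstrap_fit(y, pt, lt, residues, one_fit, n_bootstrap, rng, "shared")


def _bootstrap_fit(y, pt, lt, residues, one_fit, n_bootstrap, rng, mode) -> BindingFit:
    kd, a = one_fit(y, pt, lt)
    f = np.array([fraction_bound(p, l, kd) for p, l in zip(pt, lt)])
    residuals = a[:, None] * f[None, :] - y

    n_pts = y.shape[1]
    kds = np.empty(n_bootstrap)
    amps = np.empty((n_bootstrap, len(residues)))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_pts, size=n_pts)
        kd_b, a_b = one_fit(y[:, idx], pt[idx], lt[idx])
        kds[b] = kd_b
        amps[b] = a_b
    if n_bootstrap:
        kd_stderr = float(kds.std(ddof=1))
        # Basic bootstrap interval on the log scale: Kd is positive and its
        # sampling distribution is right-skewed, so reflecting the log
        # percentiles about the log estimate gives closer-to-nominal
        # coverage than the raw percentile interval at few titration points.
        log_kd = math.log(kd)
        llo, lhi = np.percentile(np.log(kds), [2.5, 97.5])
        ci = (float(math.exp(2 * log_kd - lhi)), float(math.exp(2 * log_kd - llo)))
        a_err = amps.std(axis=0, ddof=1)
    else:
        kd_stderr, ci, a_err = 0.0, (kd, kd), np.zeros(len(residues))
    return BindingFit(
        kd=kd,
        kd_stderr=kd_stderr,
        kd_ci95=ci,
        csp_max={r: float(v) for r, v in zip(residues, a)},
        csp_max_stderr={r: float(v) for r, v in zip(residues, a_err)},
        residuals=residuals,
        fit_mode=mode,
        residues_used=tuple(residues),
        n_bootstrap=n_bootstrap,
    )
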