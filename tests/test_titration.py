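"""Unit and property tests for CSP computation, peak matching and Kd fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from sumonmr.errors import (
    AmbiguousMatchError,
    DegenerateDataError,
    PeakMismatchError,
)
from sumonmr.synthetic import TitrationDesign, default_interface, gen_titration
from sumonmr.titration import (
    CSPRecord,
    Peak,
    TitrationPoint,
    TitrationSeries,
    call_interface,
    compute_csp,
    csp_profile,
    fit_kd,
    fraction_bound,
    match_peaks,
    predict_csp,
)


def equilibrium_bound_fraction(pt, lt, kd):
    """Independent oracle: solve the mass-balance equilibrium numerically.

    Finds the complex concentration PL from (Pt-PL)(Lt-PL) = Kd*PL by
    root bracketing, without using the closed-form quadratic root.
    """
    if lt == 0:
        return 0.0
    f = lambda pl: (pt - pl) * (lt - pl) - kd * pl
    pl = brentq(f, 0.0, min(pt, lt), xtol=1e-16, rtol=1e-15)
    return pl / pt


class TestComputeCsp:
    def test_identical_peaks_give_zero(self):
        p = Peak(3, 8.1, 120.0)
        assert compute_csp(p, p) == 0.0

    @pytest.mark.parametrize(
        "dh, dn, expected",
        [
            (0.1, 0.5, 0.141421),  # sqrt(0.01 + 0.01)
            (0.0, 1.0, 0.2),  # nitrogen-only shift, scaled by 1/5
        ],
    )
    def test_hand_computed_values(self, dh, dn, expected):
        free = Peak(1, 8.0, 120.0)
        bound = Peak(1, 8.0 - dh, 120.0 - dn)
        assert compute_csp(free, bound) == pytest.approx(expected, abs=1e-6)

    def test_residue_mismatch_raises(self):
        with pytest.raises(PeakMismatchError):
            compute_csp(Peak(1, 8.0, 120.0), Peak(2, 8.0, 120.0))

    @given(
        dh=st.floats(-2, 2, allow_nan=False),
        dn=st.floats(-10, 10, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=50)
    def test_symmetric_and_sign_invariant(self, dh, dn):
        free = Peak(1, 8.0, 120.0)
        plus = Peak(1, 8.0 + dh, 120.0 + dn)
        minus = Peak(1, 8.0 - dh, 120.0 - dn)
        assert compute_csp(free, plus) == pytest.approx(compute_csp(plus, free))
        assert compute_csp(free, plus) == pytest.approx(compute_csp(free, minus))


class TestMatchPeaks:
    def make_point(self, peaks, lt=0.0):
        return TitrationPoint(50.0, lt, peaks)

    def test_identity_mapping(self):
        peaks = [Peak(1, 8.0, 120.0), Peak(2, 9.0, 112.0)]
        mapping, broadened = match_peaks(self.make_point(peaks), self.make_point(peaks, 10))
        assert set(mapping) == {1, 2}
        assert broadened == set()

    def test_missing_residue_reported_broadened(self):
        ref = self.make_point([Peak(1, 8.0, 120.0), Peak(2, 9.0, 112.0)])
        other = self.make_point([Peak(1, 8.01, 120.0)], 10)
        mapping, broadened = match_peaks(ref, other)
        assert broadened == {2}
        assert set(mapping) == {1}

    def test_nearest_candidate_chosen_matches_exhaustive_oracle(self, rng):
        # brute force: every ref picks its minimum-distance candidate
        for _ in range(20):
            n = int(rng.integers(2, 7))
            ref_peaks = [
                Peak(i + 1, float(rng.uniform(7, 10)), float(rng.uniform(105, 130)))
                for i in range(n)
            ]
            other_peaks = [
                Peak(i + 1, p.delta_h + float(rng.normal(0, 0.01)),
                     p.delta_n + float(rng.normal(0, 0.05)))
                for i, p in enumerate(ref_peaks)
            ]
            try:
                mapping, broadened = match_peaks(
                    self.make_point(ref_peaks), self.make_point(other_peaks, 10)
                )
            except AmbiguousMatchError:
                continue
            for rp in ref_peaks:
                dists = [
                    math.hypot(rp.delta_h - op.delta_h, (rp.delta_n - op.delta_n) / 5)
                    for op in other_peaks
                ]
                best = int(np.argmin(dists))
                if dists[best] <= 0.15:
                    assert mapping[rp.residue_id] is other_peaks[best]
                else:
                    assert rp.residue_id in broadened

    def test_two_refs_claiming_same_target_raises(self):
        ref = self.make_point([Peak(1, 8.0, 120.0), Peak(2, 8.05, 120.1)])
        other = self.make_point([Peak(1, 8.02, 120.05)], 10)
        with pytest.raises(AmbiguousMatchError, match="1 and 2"):
            match_peaks(ref, other)


class TestCspProfile:
    def test_endpoint_zero_gives_all_zero(self, noiseless_titration):
        _, series = noiseless_titration
        records = csp_profile(series, 0)
        assert all(r.csp == 0.0 for r in records)

    def test_noiseless_matches_generator_closed_form(self, noiseless_titration):
        design, series = noiseless_titration
        records = {r.residue_id: r for r in csp_profile(series, len(series.points) - 1)}
        lt = design.ligand_ratios[-1] * design.protein_total
        fb = fraction_bound(design.protein_total, lt, design.true_kd)
        for resid, (dh, dn) in design.interface_residues.items():
            expected = fb * math.hypot(dh, dn / 5)
            assert records[resid].csp == pytest.approx(expected, rel=1e-9)
        quiet = [r for r in records.values() if r.residue_id not in design.interface_residues]
        assert all(r.csp == pytest.approx(0.0, abs=1e-12) for r in quiet)

    def test_broadened_residue_flagged(self):
        design = TitrationDesign(
            interface_residues={20: (0.2, 1.0)},
            broadened_residues={15: 0.3},
            seed=4,
        )
        series = gen_titration(design)
        records = {r.residue_id: r for r in csp_profile(series, len(series.points) - 1)}
        assert records[15].broadened
        assert records[15].csp is None

    def test_missing_reference_point_raises(self):
        point = TitrationPoint(50.0, 25.0, [Peak(1, 8.0, 120.0)])
        with pytest.raises(DegenerateDataError):
            csp_profile(TitrationSeries([point, point]), 1)


class TestCallInterface:
    def test_hand_computed_threshold(self):
        # mean 0.2, population SD 0.4, threshold 1.0; strict ">" leaves it empty
        records = [CSPRecord(i, v) for i, v in enumerate([0, 0, 0, 0, 1], start=1)]
        call = call_interface(records)
        assert call.threshold == pytest.approx(1.0)
        assert call.interface_residues == set()

    def test_all_equal_gives_empty_interface(self):
        records = [CSPRecord(i, 0.1) for i in range(1, 6)]
        call = call_interface(records)
        assert call.threshold == pytest.approx(0.1)
        assert call.interface_residues == set()

    def test_broadened_excluded_from_stats(self):
        records = [CSPRecord(i, 0.05) for i in range(1, 5)] + [CSPRecord(9, None, True)]
        call = call_interface(records)
        assert call.excluded_broadened == {9}
        assert call.threshold == pytest.approx(0.05)

    def test_order_invariant(self, rng):
        records = [CSPRecord(i + 1, float(v)) for i, v in enumerate(rng.uniform(0, 0.5, 12))]
        forward = call_interface(records)
        backward = call_interface(records[::-1])
        assert forward.threshold == pytest.approx(backward.threshold, rel=1e-12)
        assert forward.interface_residues == backward.interface_residues

    def test_all_broadened_raises(self):
        with pytest.raises(DegenerateDataError):
            call_interface([CSPRecord(i, None, True) for i in range(1, 4)])


class TestPredictCsp:
    def test_zero_ligand_gives_zero(self):
        assert predict_csp(50, 0, 31, 0.2) == 0.0

    def test_stoichiometric_tight_binding_limit(self):
        assert predict_csp(50, 50, 1e-9, 0.2) == pytest.approx(0.2, rel=1e-4)

    def test_hand_computed_value(self):
        # (150 - sqrt(12500)) / 100 * 0.2
        assert predict_csp(50, 50, 50, 0.2) == pytest.approx(0.0763932, abs=1e-7)

    def test_zero_protein_raises(self):
        with pytest.raises(ValueError):
            predict_csp(0, 10, 31, 0.2)

    def test_monotone_in_ligand_and_kd(self):
        lts = np.linspace(1, 500, 40)
        vals = [predict_csp(50, lt, 31, 0.2) for lt in lts]
        assert np.all(np.diff(vals) > 0)
        kds = np.geomspace(0.1, 1e4, 40)
        vals = [predict_csp(50, 100, kd, 0.2) for kd in kds]
        assert np.all(np.diff(vals) < 0)

    def test_agrees_with_numerical_equilibrium_solver(self):
        for pt in np.geomspace(1, 1e3, 7):
            for lt in np.geomspace(0.1, 1e4, 7):
                for kd in np.geomspace(0.01, 1e4, 7):
                    closed = fraction_bound(pt, lt, kd)
                    brute = equilibrium_bound_fraction(pt, lt, kd)
                    assert closed == pytest.approx(brute, rel=1e-10, abs=1e-12)


class TestFitKd:
    def test_noiseless_round_trip(self, noiseless_titration):
        design, series = noiseless_titration
        fit = fit_kd(series, n_bootstrap=0)
        assert fit.kd == pytest.approx(design.true_kd, rel=1e-4)
        for resid, (dh, dn) in design.interface_residues.items():
            if resid in fit.csp_max:
                assert fit.csp_max[resid] == pytest.approx(math.hypot(dh, dn / 5), rel=1e-3)

    def test_per_residue_fits_agree_for_shared_kd_truth(self):
        design = TitrationDesign(
            true_kd=31.0,
            noise_sd=0.002,
            interface_residues={20: (0.2, 1.0), 30: (0.15, 0.8)},
            seed=8,
        )
        series = gen_titration(design)
        fits = fit_kd(series, residues=[20, 30], mode="per-residue", n_bootstrap=200, seed=1)
        kd20, kd30 = fits[20], fits[30]
        joint = math.hypot(kd20.kd_stderr, kd30.kd_stderr)
        assert abs(kd20.kd - kd30.kd) < 3 * joint

    def test_bias_shrinks_with_noise(self):
        errs = []
        for noise in (0.01, 0.001, 0.0001):
            rel = []
            for rep in range(5):
                design = TitrationDesign(
                    true_kd=31.0, noise_sd=noise,
                    interface_residues=default_interface(seed=rep), seed=rep,
                )
                fit = fit_kd(gen_titration(design), n_bootstrap=0)
                rel.append(abs(fit.kd - 31.0) / 31.0)
            errs.append(np.mean(rel))
        assert errs[2] < errs[0]
        assert errs[2] < 1e-2

    def test_too_few_points_raise(self):
        design = TitrationDesign(
            ligand_ratios=(0.0, 1.0), interface_residues={20: (0.2, 1.0)}
        )
        series = gen_titration(design)
        with pytest.raises(Exception):
            fit_kd(series, residues=[20], n_bootstrap=0)

    def test_broadened_residue_rejected(self):
        design = TitrationDesign(
            interface_residues={20: (0.2, 1.0)}, broadened_residues={20: 0.3}, seed=2
        )
        series = gen_titration(design)
        with pytest.raises(DegenerateDataError):
            fit_kd(series, residues=[20], n_bootstrap=0)
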