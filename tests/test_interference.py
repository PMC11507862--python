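"""Shared-peak detection primitives: apex lookup, XICs, smoothing,
co-elution correlation, peak-shape scoring and flag combination."""

import numpy as np
import pytest

from diaforge.chem import Peptidoform
from diaforge.fragments import match_spectrum, theoretical_fragments
from diaforge.interference import (
    Chromatogram,
    NoCoveringWindowError,
    combine_shared,
    correlate_fragments,
    extract_xic,
    locate_apex_spectrum,
    peak_shape_score,
    peptide_centric_shared,
    smooth_chromatogram,
    spectrum_centric_shared,
)
from diaforge.io_formats import PrecursorDetection
from diaforge.spectra import RunData, Spectrum


def ms2_at(rt, mz=(), inten=(), low=380.0, high=420.0):
    return Spectrum(f"scan@{rt}", 2, rt, np.asarray(mz, float), np.asarray(inten, float),
                    isolation_low=low, isolation_high=high,
                    scan_min=150.0, scan_max=1500.0)


def detection(seq="PEPTIDEK", charge=2, apex=10.25, start=10.0, stop=10.5):
    return PrecursorDetection(
        peptidoform=Peptidoform(seq), charge=charge, rt_apex=apex,
        rt_start=start, rt_stop=stop, q_value=0.001, run_id="r",
    )


class TestLocateApex:
    def run_with_scans(self, rts, low=380.0, high=480.0):
        return RunData.from_spectra("r", [ms2_at(rt, low=low, high=high) for rt in rts])

    def test_nearest_scan_wins(self):
        run = self.run_with_scans([10.0, 10.2, 10.4])
        spec = locate_apex_spectrum(run, detection(apex=10.25))
        assert spec.rt == 10.2

    def test_midpoint_tie_breaks_to_earlier_scan(self):
        run = self.run_with_scans([10.0, 10.2])
        spec = locate_apex_spectrum(run, detection(apex=10.1))
        assert spec.rt == 10.0

    def test_uncovered_precursor_raises_with_name(self):
        run = self.run_with_scans([10.0], low=900.0, high=920.0)
        with pytest.raises(NoCoveringWindowError, match="PEPTIDEK"):
            locate_apex_spectrum(run, detection())


class TestSpectrumCentric:
    def test_cross_peptide_claim_flags_both(self):
        pa, pb = Peptidoform("PEPTIDEK"), Peptidoform("LVNELTEFAK")
        ions_a = theoretical_fragments(pa, 2)
        ions_b = theoretical_fragments(pb, 2)
        shared_mz = next(i.mz for i in ions_a if 300.0 < i.mz < 900.0)
        # peptide B's nearest ion forced onto A's first ion via wide tolerance
        diffs = [abs(i.mz - shared_mz) for i in ions_b]
        tol_b = (min(diffs) / shared_mz) * 1e6 * 1.1
        spec = ms2_at(10.0, [shared_mz], [100.0])
        ma = match_spectrum(spec, ions_a, 10.0, peptidoform=pa, precursor_charge=2)
        mb = match_spectrum(spec, ions_b, tol_b, peptidoform=pb, precursor_charge=2)
        flags = spectrum_centric_shared(spec, [ma, mb])
        assert flags[0].any() and flags[1].any()

    def test_single_detection_never_flagged(self):
        pa = Peptidoform("PEPTIDEK")
        ions = theoretical_fragments(pa, 2)
        spec = ms2_at(10.0, [ions[0].mz, ions[2].mz], [10.0, 20.0])
        m = match_spectrum(spec, ions, 10.0, peptidoform=pa, precursor_charge=2)
        assert not spectrum_centric_shared(spec, [m])[0].any()

    def test_disjoint_matches_not_flagged(self):
        pa, pb = Peptidoform("PEPTIDEK"), Peptidoform("LVNELTEFAK")
        ia, ib = theoretical_fragments(pa, 2), theoretical_fragments(pb, 2)
        spec = ms2_at(10.0, sorted([ia[0].mz, ib[4].mz]), [10.0, 20.0])
        ma = match_spectrum(spec, ia, 5.0, peptidoform=pa, precursor_charge=2)
        mb = match_spectrum(spec, ib, 5.0, peptidoform=pb, precursor_charge=2)
        flags = spectrum_centric_shared(spec, [ma, mb])
        assert not flags[0].any() and not flags[1].any()


class TestXic:
    def make_run(self, frag_mz=500.0, pattern=(0, 1, 2, 1, 0)):
        spectra = [
            ms2_at(10.0 + 0.05 * i, [frag_mz] if v else [], [float(v)] if v else [])
            for i, v in enumerate(pattern)
        ]
        return RunData.from_spectra("r", spectra)

    def test_absent_fragment_gives_zero_trace_of_full_length(self):
        run = self.make_run()
        xic = extract_xic(run, 600.0, 10.0, (380.0, 420.0), 10.0, 10.2)
        assert len(xic) == 5 and not xic.intensity.any()

    def test_in_tolerance_peaks_summed_within_scan(self):
        mz = 500.0
        s = ms2_at(10.0, [mz * (1 - 3e-6), mz * (1 + 3e-6)], [5.0, 7.0])
        run = RunData.from_spectra("r", [s])
        xic = extract_xic(run, mz, 10.0, (380.0, 420.0), 9.9, 10.1)
        assert xic.intensity.tolist() == [12.0]

    def test_respects_rt_boundaries(self):
        run = self.make_run()
        xic = extract_xic(run, 500.0, 10.0, (380.0, 420.0), 10.05, 10.15)
        assert len(xic) == 3


class TestSmoothing:
    def test_constant_trace_unchanged_by_sg(self):
        c = Chromatogram(np.linspace(0, 1, 9), np.full(9, 5.0))
        out = smooth_chromatogram(c)
        assert out.intensity == pytest.approx(np.full(9, 5.0))

    def test_short_trace_falls_back_to_wma(self):
        c = Chromatogram(np.arange(5.0), np.array([0.0, 0.0, 10.0, 0.0, 0.0]))
        out = smooth_chromatogram(c, method="savitzky_golay")  # len < window
        assert out.intensity == pytest.approx([0.0, 2.5, 5.0, 2.5, 0.0])

    def test_wma_impulse_matches_hand_convolution(self):
        c = Chromatogram(np.arange(5.0), np.array([0.0, 0.0, 10.0, 0.0, 0.0]))
        out = smooth_chromatogram(c, method="weighted_moving_average")
        assert out.intensity == pytest.approx([0.0, 2.5, 5.0, 2.5, 0.0])

    def test_never_negative(self):
        c = Chromatogram(np.arange(9.0), np.array([0, 0, 0, 50, 0, 0, 0, 0, 0], float))
        assert (smooth_chromatogram(c).intensity >= 0).all()


def brute_force_pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


class TestCorrelate:
    def test_identical_gaussians_aggregate_two(self):
        t = np.linspace(-2, 2, 11)
        g = np.exp(-t**2)
        xics = [Chromatogram(t, g * s) for s in (1.0, 2.0, 0.5)]
        cr = correlate_fragments(xics)
        assert cr.aggregate == pytest.approx([2.0, 2.0, 2.0])
        assert cr.r_to_top == pytest.approx([1.0, 1.0, 1.0])

    def test_anti_phase_trace_has_smallest_aggregate(self):
        t = np.linspace(0, 1, 12)
        g = np.exp(-((t - 0.5) ** 2) / 0.02)
        xics = [Chromatogram(t, g), Chromatogram(t, g * 2),
                Chromatogram(t, g.max() - g)]
        cr = correlate_fragments(xics)
        assert np.argmin(cr.aggregate) == 2
        assert cr.top_fragment in (0, 1)

    def test_matches_brute_force_pearson(self, rng):
        for _ in range(50):
            data = rng.normal(size=(4, 15))
            xics = [Chromatogram(np.arange(15.0), np.abs(row)) for row in data]
            cr = correlate_fragments(xics)
            for i in range(4):
                for j in range(4):
                    if i != j:
                        expect = brute_force_pearson(np.abs(data[i]), np.abs(data[j]))
                        assert cr.pairwise_r[i, j] == pytest.approx(expect, abs=1e-10)

    def test_zero_variance_trace_scores_zero(self):
        t = np.arange(8.0)
        xics = [Chromatogram(t, np.exp(-(t - 4) ** 2)),
                Chromatogram(t, np.exp(-(t - 4) ** 2) * 3),
                Chromatogram(t, np.zeros(8))]
        cr = correlate_fragments(xics)
        assert cr.zero_variance.tolist() == [False, False, True]
        assert cr.aggregate[2] == 0.0


class TestPeakShape:
    def gaussian_set(self, n=4, npts=11):
        t = np.linspace(10.0, 10.5, npts)
        g = np.exp(-0.5 * ((t - 10.25) / 0.06) ** 2)
        return t, [Chromatogram(t, g * (k + 1)) for k in range(n)]

    def test_sharp_gaussian_scores_zero(self):
        t, xics = self.gaussian_set()
        assert peak_shape_score(xics[0], xics, 10.0, 10.5) == 0

    def test_flat_elevated_trace_scores_two(self):
        t, xics = self.gaussian_set()
        flat = Chromatogram(t, np.full_like(t, 3.0))
        assert peak_shape_score(flat, xics + [flat], 10.0, 10.5) == 2

    def test_one_elevated_boundary_scores_one(self):
        t, xics = self.gaussian_set()
        ramp = Chromatogram(t, np.linspace(4.0, 0.0, t.size))
        assert peak_shape_score(ramp, xics + [ramp], 10.0, 10.5) == 1

    def test_empty_trace_scores_zero(self):
        empty = Chromatogram(np.zeros(0), np.zeros(0))
        assert peak_shape_score(empty, [empty], 10.0, 10.5) == 0


class TestPeptideCentricRule:
    def cr_with(self, r_values, top=0):
        from diaforge.interference import CorrelationResult
        r = np.asarray(r_values, float)
        return CorrelationResult(
            pairwise_r=np.eye(len(r)), aggregate=np.zeros(len(r)),
            top_fragment=top, r_to_top=r, zero_variance=np.zeros(len(r), bool),
        )

    def test_below_threshold_is_shared(self):
        flags = peptide_centric_shared(self.cr_with([1.0, 0.79]), [0, 0])
        assert flags.tolist() == [False, True]

    def test_above_threshold_shape_one_not_shared(self):
        flags = peptide_centric_shared(self.cr_with([1.0, 0.95]), [0, 1])
        assert flags.tolist() == [False, False]

    def test_shape_two_shared_despite_high_correlation(self):
        flags = peptide_centric_shared(self.cr_with([1.0, 0.95]), [0, 2])
        assert flags.tolist() == [False, True]

    def test_shape_rule_applies_to_top_fragment_too(self):
        flags = peptide_centric_shared(self.cr_with([1.0, 0.9]), [2, 0])
        assert flags.tolist() == [True, False]


class TestCombine:
    def test_elementwise_or(self):
        a = np.array([[False, True, False]])
        b = np.array([[False, False, True]])
        c = np.array([[False, False, False]])
        assert combine_shared(a, b, c).tolist() == [[False, True, True]]

    def test_commutative_and_idempotent(self, rng):
        grids = [rng.random((3, 4)) > 0.5 for _ in range(3)]
        out = combine_shared(*grids)
        assert np.array_equal(out, combine_shared(grids[2], grids[0], grids[1]))
        assert np.array_equal(out, combine_shared(out, out, out))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            combine_shared(np.zeros((2, 2), bool), np.zeros((2, 3), bool),
                           np.zeros((2, 2), bool))
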