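"""Theoretical fragment enumeration, spectrum matching and normalization."""

import numpy as np
import pytest

from diaforge.chem import Peptidoform, parse_modified_sequence
from diaforge.fragments import (
    FragmentColumnLayout,
    IonConfig,
    NoUsablePeaksError,
    match_spectrum,
    normalize_matrix,
    theoretical_fragments,
)
from diaforge.spectra import Spectrum


def ms2(mz, intensity, scan_min=100.0, scan_max=2000.0):
    return Spectrum(
        "scan=1", 2, 10.0, np.asarray(mz, float), np.asarray(intensity, float),
        isolation_low=400.0, isolation_high=420.0,
        scan_min=scan_min, scan_max=scan_max,
    )


class TestTheoreticalFragments:
    def test_singly_charged_precursor_gets_singly_charged_ions_only(self):
        ions = theoretical_fragments(Peptidoform("AAAA"), 1)
        assert len(ions) == 6
        assert {i.frag_charge for i in ions} == {1}

    def test_multiply_charged_precursor_gets_both_charges(self):
        ions = theoretical_fragments(Peptidoform("PEPTIDE"), 2)
        assert len(ions) == 24  # 6 positions x 2 series x 2 charges

    def test_phospho_loss_only_for_ions_spanning_the_site(self):
        p = parse_modified_sequence("AS(UniMod:21)AK")
        ions = theoretical_fragments(p, 2, IonConfig(phospho_loss=True))
        losses = {(i.series, i.index) for i in ions if i.loss}
        assert losses == {("b", 2), ("b", 3), ("y", 3)}
        assert len(ions) == 18  # 12 regular + 3 loss ions x 2 charges
        # loss m/z sits 97.9769/z below the parent ion
        parent = {(i.series, i.index, i.frag_charge): i.mz for i in ions if not i.loss}
        for i in ions:
            if i.loss:
                assert i.mz == pytest.approx(
                    parent[(i.series, i.index, i.frag_charge)] - 97.976896 / i.frag_charge
                )

    def test_complementary_ions_sum_to_precursor_mass(self):
        p = Peptidoform("LVNELTEFAK")
        ions = {(i.series, i.index): i.mz for i in theoretical_fragments(p, 2) if i.frag_charge == 1}
        L = len(p.sequence)
        for i in range(1, L):
            total = ions[("b", i)] + ions[("y", L - i)]
            assert total == pytest.approx(p.mass() + 2 * 1.007276, abs=1e-4)


class TestColumnLayout:
    def test_cell_bijection_round_trips(self):
        for phospho in (False, True):
            layout = FragmentColumnLayout(phospho_loss=phospho)
            L = 9
            for row in range(L - 1):
                for col in range(layout.n_columns):
                    series, index, charge, loss = layout.ion_key_of(row, col, L)
                    ion_like = type("I", (), {
                        "series": series, "index": index,
                        "frag_charge": charge, "loss": loss,
                    })()
                    assert layout.cell_of(ion_like, L) == (row, col)


class TestMatchSpectrum:
    def setup_method(self):
        self.p = Peptidoform("PEPTIDEK")
        self.ions = theoretical_fragments(self.p, 2)
        self.layout = FragmentColumnLayout()

    def test_exact_peak_carries_intensity(self):
        b2 = next(i for i in self.ions if i.series == "b" and i.index == 2 and i.frag_charge == 1)
        spec = ms2([b2.mz], [123.0])
        m = match_spectrum(spec, self.ions, 10.0, peptidoform=self.p, precursor_charge=2)
        assert m.intensity[self.layout.cell_of(b2, 8)] == 123.0

    def test_peak_outside_tolerance_ignored(self):
        y3 = next(i for i in self.ions if i.series == "y" and i.index == 3 and i.frag_charge == 1)
        spec = ms2([y3.mz * (1 + 25e-6)], [50.0])
        m = match_spectrum(spec, self.ions, 10.0, peptidoform=self.p, precursor_charge=2)
        assert m.intensity[self.layout.cell_of(y3, 8)] == 0.0

    def test_one_peak_claimed_by_two_ions_is_shared(self):
        b4 = next(i for i in self.ions if i.series == "b" and i.index == 4 and i.frag_charge == 1)
        y3 = next(i for i in self.ions if i.series == "y" and i.index == 3 and i.frag_charge == 1)
        fake = Spectrum(
            "scan=1", 2, 10.0,
            np.array([(b4.mz + y3.mz) / 2]), np.array([10.0]),
            isolation_low=400.0, isolation_high=420.0,
            scan_min=100.0, scan_max=2000.0,
        )
        # force both within tolerance by using a wide ppm
        tol = abs(b4.mz - y3.mz) / b4.mz * 1e6
        m = match_spectrum(fake, self.ions, tol, peptidoform=self.p, precursor_charge=2)
        assert m.shared[m.layout.cell_of(b4, 8)]
        assert m.shared[m.layout.cell_of(y3, 8)]
        assert m.mask[m.layout.cell_of(b4, 8)]  # shared implies mask

    def test_out_of_scan_range_ion_masked_not_zeroed(self):
        y1 = next(i for i in self.ions if i.series == "y" and i.index == 1 and i.frag_charge == 1)
        spec = ms2([500.0], [10.0], scan_min=y1.mz + 50.0, scan_max=2000.0)
        m = match_spectrum(spec, self.ions, 10.0, peptidoform=self.p, precursor_charge=2)
        cell = m.layout.cell_of(y1, 8)
        assert m.mask[cell] and not m.matched[cell]

    def test_empty_spectrum_yields_all_zero_matrix(self):
        m = match_spectrum(ms2([], []), self.ions, 10.0,
                           peptidoform=self.p, precursor_charge=2)
        assert m.intensity.sum() == 0 and not m.matched.any()

    def test_invariant_to_peak_order(self, rng):
        mzs = np.array([i.mz for i in self.ions[:6]])
        ints = rng.uniform(10, 100, size=6)
        order = rng.permutation(6)
        a = match_spectrum(ms2(mzs, ints), self.ions, 10.0,
                           peptidoform=self.p, precursor_charge=2)
        b = match_spectrum(ms2(mzs[order], ints[order]), self.ions, 10.0,
                           peptidoform=self.p, precursor_charge=2)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.shared, b.shared)

    def test_equidistant_tie_goes_to_more_intense_peak(self):
        b2 = next(i for i in self.ions if i.series == "b" and i.index == 2 and i.frag_charge == 1)
        delta = b2.mz * 5e-6
        spec = ms2([b2.mz - delta, b2.mz + delta], [5.0, 50.0])
        m = match_spectrum(spec, self.ions, 10.0, peptidoform=self.p, precursor_charge=2)
        assert m.intensity[m.layout.cell_of(b2, 8)] == 50.0


class TestNormalize:
    def test_scales_highest_matched_to_one(self):
        p = Peptidoform("PEPTIDEK")
        ions = theoretical_fragments(p, 2)
        in_range = [i for i in ions if 150.0 < i.mz < 1500.0]
        mzs = sorted(i.mz for i in in_range[:3])
        m = match_spectrum(ms2(mzs, [2.0, 4.0, 8.0]), ions, 10.0,
                           peptidoform=p, precursor_charge=2)
        normalize_matrix(m)
        vals = sorted(m.intensity[m.matched])
        assert vals == pytest.approx([0.25, 0.5, 1.0])
        assert m.intensity[m.matched & ~m.mask].max() == 1.0

    def test_all_zero_matrix_raises(self):
        p = Peptidoform("PEPTIDEK")
        ions = theoretical_fragments(p, 2)
        m = match_spectrum(ms2([], []), ions, 10.0, peptidoform=p, precursor_charge=2)
        with pytest.raises(NoUsablePeaksError):
            normalize_matrix(m)
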