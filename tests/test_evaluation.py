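"""Spearman on unmasked peaks, entrapment FDP bounds, entropy similarity,
NCE calibration."""

import math

import numpy as np
import pytest

from diaforge.evaluation import (
    EntrapmentCounts,
    calibrate_nce,
    count_entrapment_discoveries,
    estimate_fdp,
    generate_entrapment_pairs,
    simulate_discovery_run,
    spearman_unmasked,
    spectral_entropy_similarity,
)
from diaforge.fragments import FragmentColumnLayout
from diaforge.synthetic import make_fragment_examples, true_intensity_rule


def brute_force_spearman(x, y):
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        # average ties
        for val in np.unique(v):
            idx = v == val
            r[idx] = r[idx].mean()
        return r

    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rxm, rym = rx - rx.mean(), ry - ry.mean()
    return float((rxm * rym).sum() / np.sqrt((rxm**2).sum() * (rym**2).sum()))


class TestSpearman:
    def matrix_with(self, intensity, mask):
        ex = make_fragment_examples(1, seed=0)[0]
        m = ex.matrix
        m.intensity = np.asarray(intensity, float)
        m.mask = np.asarray(mask, bool)
        return m

    def test_perfect_agreement(self, rng):
        ex = make_fragment_examples(1, seed=1)[0]
        rho = spearman_unmasked(ex.matrix.intensity.copy(), ex.matrix)
        assert rho == pytest.approx(1.0)

    def test_mask_removes_disagreeing_cell(self):
        ex = make_fragment_examples(1, seed=2)[0]
        pred = ex.matrix.intensity.copy()
        r, c = np.argwhere(~ex.matrix.mask)[0]
        pred[r, c] = 1e6  # wildly wrong but masked
        ex.matrix.mask[r, c] = True
        assert spearman_unmasked(pred, ex.matrix) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        ex = make_fragment_examples(1, seed=3)[0]
        for _ in range(100):
            pred = rng.random(ex.matrix.intensity.shape)
            keep = ~ex.matrix.mask
            expect = brute_force_spearman(pred[keep], ex.matrix.intensity[keep])
            assert spearman_unmasked(pred, ex.matrix) == pytest.approx(expect, abs=1e-10)

    def test_too_few_cells_is_nan(self):
        ex = make_fragment_examples(1, seed=4)[0]
        ex.matrix.mask[:] = True
        ex.matrix.mask[0, 0] = False
        ex.matrix.mask[0, 2] = False
        assert math.isnan(spearman_unmasked(ex.matrix.intensity, ex.matrix))


class TestEntrapmentPairs:
    def test_c_terminus_fixed_and_multiset_preserved(self):
        pairs = generate_entrapment_pairs(["PEPTLDEK", "LVNELTEFAK"], seed=0)
        assert len(pairs) == 2
        for p in pairs:
            assert p.entrapment[-1] == p.target[-1]
            assert sorted(p.entrapment) == sorted(p.target)
            assert p.entrapment != p.target
            assert len(p.entrapment) == len(p.target)

    def test_isoleucine_converted_before_pairing(self):
        pairs = generate_entrapment_pairs(["AIVAK"], seed=0)
        assert pairs[0].target == "ALVAK"
        assert "I" not in pairs[0].entrapment

    def test_deterministic_under_seed(self):
        targets = ["PEPTLDEK", "LVNELTEFAK", "ACDEFGHLK"]
        a = generate_entrapment_pairs(targets, seed=5)
        b = generate_entrapment_pairs(targets, seed=5)
        assert a == b

    def test_homopolymer_skipped(self):
        pairs = generate_entrapment_pairs(["AAAAK", "PEPTLDEK"], seed=0)
        assert [p.target for p in pairs] == ["PEPTLDEK"]


class TestFdp:
    def test_lower_bound_formula(self):
        counts = EntrapmentCounts(n_t=99, n_e=1, n_e_pair_low=0, n_e_pair_both=0, s=1.0)
        assert estimate_fdp(counts, "lower") == pytest.approx(0.01)

    def test_upper_bound_formula(self):
        counts = EntrapmentCounts(n_t=98, n_e=2, n_e_pair_low=1, n_e_pair_both=0, s=1.0)
        assert estimate_fdp(counts, "upper") == pytest.approx(0.03)

    def test_no_discoveries_raises(self):
        counts = EntrapmentCounts(n_t=0, n_e=0, n_e_pair_low=0, n_e_pair_both=0, s=1.0)
        with pytest.raises(ValueError):
            estimate_fdp(counts, "lower")

    def test_lower_never_exceeds_upper(self, rng):
        for _ in range(300):
            counts, _ = simulate_discovery_run(
                n_pairs=200, prop_present=rng.uniform(0.2, 0.8),
                score_cutoff=rng.uniform(0.5, 2.5), rng=rng,
            )
            if counts.n_t + counts.n_e == 0:
                continue
            assert estimate_fdp(counts, "lower") <= estimate_fdp(counts, "upper")

    def test_counting_matches_hand_tally(self):
        t = np.array([2.0, 0.5, np.nan, 3.0])
        e = np.array([1.5, 1.2, 2.0, 0.1])
        c = count_entrapment_discoveries(t, e, s=1.0)
        assert (c.n_t, c.n_e) == (2, 3)
        assert c.n_e_pair_low == 2  # pairs 2 (nan target) and 1 (0.5 < s)
        assert c.n_e_pair_both == 0  # no discovered target scored below its entrapment


class TestEntropySimilarity:
    def test_identical_spectra_give_one(self):
        peaks = [(100.0, 1.0), (200.0, 2.0), (300.0, 0.5)]
        assert spectral_entropy_similarity(peaks, list(peaks)) == pytest.approx(1.0)

    def test_disjoint_spectra_give_zero(self):
        a = [(100.0, 1.0), (200.0, 1.0)]
        b = [(400.0, 1.0), (500.0, 1.0)]
        assert spectral_entropy_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_two_peak_case_matches_hand_computation(self):
        # A = {m1: 1}, B = {m1: 0.5, m2: 0.5} (already normalized)
        a = [(100.0, 1.0)]
        b = [(100.0, 0.5), (200.0, 0.5)]
        s_a = 0.0
        s_b = -2 * 0.5 * math.log(0.5)
        merged = [0.5 + 0.25, 0.25]
        s_ab = -sum(p * math.log(p) for p in merged)
        expect = 1 - (2 * s_ab - s_a - s_b) / math.log(4)
        assert spectral_entropy_similarity(a, b) == pytest.approx(expect, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = [(float(m), float(v)) for m, v in
                 zip(rng.uniform(100, 1000, 5), rng.uniform(0.1, 1, 5))]
            b = [(float(m), float(v)) for m, v in
                 zip(rng.uniform(100, 1000, 4), rng.uniform(0.1, 1, 4))]
            assert spectral_entropy_similarity(a, b) == pytest.approx(
                spectral_entropy_similarity(b, a), abs=1e-12
            )

    def test_empty_spectrum_raises(self):
        with pytest.raises(ValueError):
            spectral_entropy_similarity([], [(100.0, 1.0)])


@pytest.fixture(scope="module")
def nce_examples():
    return make_fragment_examples(30, seed=9, nce=27.0, noise_sigma=0.02)


class TestNceCalibration:
    def rule_predictor(self):
        layout = FragmentColumnLayout()

        def predict(p, charge, nce, instrument):
            return true_intensity_rule(p, charge, nce, layout)

        return predict

    def test_recovers_generating_nce(self, nce_examples):
        grid = list(range(20, 41))
        assert calibrate_nce(self.rule_predictor(), nce_examples, grid) == 27

    def test_single_value_grid(self, nce_examples):
        assert calibrate_nce(self.rule_predictor(), nce_examples, [33.0]) == 33.0

    def test_grid_order_irrelevant(self, nce_examples):
        grid = [35, 27, 20, 31, 24]
        a = calibrate_nce(self.rule_predictor(), nce_examples, grid)
        b = calibrate_nce(self.rule_predictor(), nce_examples, list(reversed(grid)))
        assert a == b == 27
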