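"""Evaluation: unmasked-peak Spearman, entrapment FDP bounds, spectral
entropy similarity and NCE calibration.

FDP (false discovery proportion) is bounded empirically by searching a
combined target + entrapment peptide database. With paired entrapments
(same residue multiset, C-terminal residue fixed, I converted to L), the
counts of entrapment discoveries and of how each compares with its paired
target give a lower bound

    FDP_lower = N_E / (N_T + N_E)

and a paired upper bound

    FDP_upper = (N_E + N_{E>=s>T} + 2 N_{E>T>=s}) / (N_T + N_E),

where N_{E>=s>T} counts discovered entrapments whose paired target missed
the cutoff s and N_{E>T>=s} those whose paired target was discovered but
scored lower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .fragments import AnnotatedFragmentMatrix
from .training_data import TrainingExample


def spearman_unmasked(pred: np.ndarray, obs: AnnotatedFragmentMatrix) -> float:
    """Spearman rank correlation between predicted and observed intensities,
    restricted to unmasked cells. Returns nan (to be excluded from
    summaries) when fewer than 3 unmasked cells exist."""
    keep = ~obs.mask
    if keep.sum() < 3:
        return float("nan")
    rho = spearmanr(pred[keep], obs.intensity[keep]).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# entrapment pairing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntrapmentPair:
    target: str
    entrapment: str


def generate_entrapment_pairs(
    targets: list[str], seed: int, max_attempts: int = 50
) -> list[EntrapmentPair]:
    """Paired entrapment peptides: I->L applied to targets first, then the
    non-C-terminal residues are shuffled (C-terminal residue fixed) until
    the entrapment differs from its own target and every other target.
    Peptides admitting no distinct permutation are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    converted = [t.replace("I", "L") for t in targets]
    target_set = set(converted)
    pairs: list[EntrapmentPair] = []
    for t in converted:
        if len(t) < 3:
            raise ValueError(f"peptide {t!r} too short for entrapment pairing")
        body, cterm = t[:-1], t[-1]
        if len(set(body)) <= 1:
            continue  # homopolymer body: no distinct permutation exists
        entrapment = None
        for _ in range(max_attempts):
            perm = "".join(rng.permutation(list(body))) + cterm
            if perm != t and perm not in target_set:
                entrapment = perm
                break
        if entrapment is None:
            continue
        pairs.append(EntrapmentPair(target=t, entrapment=entrapment))
    return pairs


@dataclass
class EntrapmentCounts:
    n_t: int  # discovered original targets
    n_e: int  # discovered entrapments
    n_e_pair_low: int  # discovered entrapments whose paired target scored < s
    n_e_pair_both: int  # ... whose paired target scored lower but >= s
    s: float

    def __post_init__(self) -> None:
        if min(self.n_t, self.n_e, self.n_e_pair_low, self.n_e_pair_both) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_e_pair_low + self.n_e_pair_both > self.n_e:
            raise ValueError("paired subcounts exceed entrapment discoveries")


def estimate_fdp(counts: EntrapmentCounts, method: str = "upper") -> float:
    """Paired upper bound or combined lower bound on the FDP at cutoff s."""
    denom = counts.n_t + counts.n_e
    if denom == 0:
        raise ValueError("no discoveries: FDP undefined")
    if method == "lower":
        return counts.n_e / denom
    if method == "upper":
        return (counts.n_e + counts.n_e_pair_low + 2 * counts.n_e_pair_both) / denom
    raise ValueError(f"unknown method {method!r}")


def count_entrapment_discoveries(
    target_scores: np.ndarray,
    entrapment_scores: np.ndarray,
    s: float,
) -> EntrapmentCounts:
    """Tally paired discovery counts at cutoff ``s`` (score >= s discovers).

    ``target_scores[i]`` and ``entrapment_scores[i]`` belong to pair i; nan
    marks a peptide that received no score (never discovered).
    """
    t = np.asarray(target_scores, dtype=float)
    e = np.asarray(entrapment_scores, dtype=float)
    if t.shape != e.shape:
        raise ValueError("paired score arrays must align")
    t_disc = np.nan_to_num(t, nan=-np.inf) >= s
    e_disc = np.nan_to_num(e, nan=-np.inf) >= s
    t_eff = np.nan_to_num(t, nan=-np.inf)
    return EntrapmentCounts(
        n_t=int(t_disc.sum()),
        n_e=int(e_disc.sum()),
        n_e_pair_low=int((e_disc & ~t_disc).sum()),
        n_e_pair_both=int((e_disc & t_disc & (t_eff < e)).sum()),
        s=s,
    )


def simulate_discovery_run(
    n_pairs: int,
    prop_present: float,
    score_cutoff: float,
    rng: np.random.Generator,
    sd: float = 1.0,
    separation: float = 1.5,
) -> tuple[EntrapmentCounts, float]:
    """Simulate a search over a paired target+entrapment database with known
    ground truth; returns the counts and the true FDP at the cutoff.

    A fraction of target peptides is truly present and scores
    N(separation, sd); every other candidate — absent targets and all
    entrapments — scores from the null N(0, sd). True false discoveries are
    the null-scored candidates above the cutoff. The default separation is
    moderate, as near a discovery cutoff in practice; for absent-target
    pairs the paired upper bound is exactly tight in expectation, so its
    conservatism (and the bounds' joint coverage) comes from present
    targets occasionally outscored by their entrapment partner.
    """
    present = rng.random(n_pairs) < prop_present
    t_scores = rng.normal(0.0, sd, size=n_pairs)
    t_scores[present] = rng.normal(separation, sd, size=int(present.sum()))
    e_scores = rng.normal(0.0, sd, size=n_pairs)
    counts = count_entrapment_discoveries(t_scores, e_scores, score_cutoff)
    false_disc = int(((t_scores >= score_cutoff) & ~present).sum()) + int(
        (e_scores >= score_cutoff).sum()
    )
    total_disc = counts.n_t + counts.n_e
    true_fdp = false_disc / total_disc if total_disc else float("nan")
    return counts, true_fdp


# ---------------------------------------------------------------------------
# spectral entropy similarity
# ---------------------------------------------------------------------------


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def spectral_entropy_similarity(
    a: list[tuple[float, float]],
    b: list[tuple[float, float]],
    mz_tol: float = 0.01,
) -> float:
    """Unweighted spectral entropy similarity in [0, 1].

    Intensities are normalized to sum 1; peaks of the two spectra are merged
    by m/z within ``mz_tol`` and the half-sum spectrum's Shannon entropy
    S_AB enters 1 - (2 S_AB - S_A - S_B) / ln 4. Identical spectra give 1,
    fully m/z-disjoint spectra give 0.
    """
    if not a or not b:
        raise ValueError("empty spectrum")
    pa = _normalize_peaks(a)
    pb = _normalize_peaks(b)
    s_a = _entropy(np.array([i for _, i in pa]))
    s_b = _entropy(np.array([i for _, i in pb]))
    merged = _merge_peaks(
        [(mz, i / 2.0, 0) for mz, i in pa] + [(mz, i / 2.0, 1) for mz, i in pb], mz_tol
    )
    s_ab = _entropy(np.array(merged))
    sim = 1.0 - (2.0 * s_ab - s_a - s_b) / math.log(4.0)
    return float(np.clip(sim, 0.0, 1.0))


def _normalize_peaks(peaks) -> list[tuple[float, float]]:
    total = sum(i for _, i in peaks)
    if total <= 0:
        raise ValueError("spectrum has no intensity")
    return sorted((float(mz), float(i) / total) for mz, i in peaks)


def _merge_peaks(tagged: list[tuple[float, float, int]], tol: float) -> list[float]:
    """Sum intensities of cross-spectrum peaks within ``tol`` m/z."""
    tagged = sorted(tagged)
    out: list[float] = []
    i = 0
    while i < len(tagged):
        mz, inten, src = tagged[i]
        j = i + 1
        # merge a peak from the other spectrum if adjacent within tolerance
        if j < len(tagged) and tagged[j][2] != src and tagged[j][0] - mz <= tol:
            inten += tagged[j][1]
            j += 1
        out.append(inten)
        i = j
    return out


# ---------------------------------------------------------------------------
# NCE calibration
# ---------------------------------------------------------------------------


def calibrate_nce(
    predictor,
    examples: list[TrainingExample],
    grid: list[float],
    mz_tol: float = 0.01,
) -> float:
    """Pick the NCE maximizing the median entropy similarity between
    predicted and observed intensities, using unshared fragments only.

    ``predictor`` is called as ``predictor(peptidoform, charge, nce,
    instrument) -> grid`` (a fitted
    :class:`~diaforge.models.FragmentIntensityPredictor` works via its
    ``predict_single``). Grid ties resolve to the lowest NCE.
    """
    if not grid:
        raise ValueError("NCE grid must be non-empty")
    predict = getattr(predictor, "predict_single", predictor)
    best_nce, best_median = None, -np.inf
    for nce in sorted(grid):
        sims = []
        for ex in examples:
            pred_grid = predict(ex.peptidoform, ex.charge, nce, ex.instrument)
            m = ex.matrix
            usable = m.matched & ~m.shared & ~m.mask
            obs_peaks, pred_peaks = [], []
            rows, cols = np.nonzero(usable)
            for r, c in zip(rows, cols):
                mz = m.theo_mz[r, c]
                obs_peaks.append((mz, m.intensity[r, c]))
                if pred_grid[r, c] > 0:
                    pred_peaks.append((mz, pred_grid[r, c]))
            if len(obs_peaks) < 2 or not pred_peaks:
                continue
            sims.append(spectral_entropy_similarity(pred_peaks, obs_peaks, mz_tol))
        if sims:
            med = float(np.median(sims))
            if med > best_median:
                best_nce, best_median = nce, med
    if best_nce is None:
        raise ValueError("no example produced a similarity score")
    return best_nce
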