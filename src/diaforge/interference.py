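"""Shared-peak (interference) detection in chimeric DIA spectra.

Two complementary strategies:

* **spectrum-centric** — within one MS2 scan, a peak claimed by fragment ions
  of more than one identified peptidoform is shared;
* **peptide-centric** — fragments whose smoothed extracted ion chromatogram
  (XIC) does not co-elute with the peptide's top-scoring fragment (Pearson r
  below a threshold, default 0.8), or whose peak rises above background at
  both peak boundaries (peak-shape score 2), are shared. This catches
  interference from co-isolated species that were never identified.

The final label is the union of the two strategies plus within-peptide
ambiguous matches flagged during annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .fragments import AnnotatedFragmentMatrix
from .io_formats import PrecursorDetection
from .spectra import RunData, Spectrum, WindowKey


@dataclass
class Chromatogram:
    """Fragment intensity traced over the MS2 cycle grid of one window."""

    rt: np.ndarray  # minutes, ascending
    intensity: np.ndarray  # non-negative
    frag: object | None = None  # cell key or FragmentIon reference

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")

    def __len__(self) -> int:
        return self.rt.size


@dataclass
class CorrelationResult:
    pairwise_r: np.ndarray  # (n, n) symmetric
    aggregate: np.ndarray  # per-fragment sum of r to all others
    top_fragment: int
    r_to_top: np.ndarray
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


class NoCoveringWindowError(ValueError):
    """No isolation window of the run covers the precursor m/z."""


def locate_apex_spectrum(run: RunData, det: PrecursorDetection) -> Spectrum:
    """MS2 scan whose isolation window covers the precursor and whose rt is
    nearest the detection's apex (ties broken toward the earlier scan)."""
    mz = det.peptidoform.mz(det.charge)
    windows = run.windows_covering(mz)
    if not windows:
        raise NoCoveringWindowError(
            f"no isolation window covers {det.peptidoform.proforma()}/{det.charge}+ "
            f"(m/z {mz:.4f})"
        )
    best: Spectrum | None = None
    for w in windows:
        for s in run.ms2_by_window[w]:
            if best is None:
                best = s
                continue
            d_new, d_best = abs(s.rt - det.rt_apex), abs(best.rt - det.rt_apex)
            if d_new < d_best or (d_new == d_best and s.rt < best.rt):
                best = s
    assert best is not None
    return best


def spectrum_centric_shared(
    spec: Spectrum, matrices: list[AnnotatedFragmentMatrix]
) -> list[np.ndarray]:
    """Flag cells whose observed peak is claimed by another peptidoform.

    All matrices must be annotated against ``spec`` (matched peak indices
    refer to its peak list). Returns one boolean flag grid per matrix; the
    caller combines them with the other strategies.
    """
    claimants: dict[int, set[str]] = {}
    for m in matrices:
        key = m.peptidoform.proforma()
        for pk in np.unique(m.matched_peak[m.matched_peak >= 0]):
            claimants.setdefault(int(pk), set()).add(key)
    flags = []
    for m in matrices:
        grid = np.zeros_like(m.shared)
        key = m.peptidoform.proforma()
        rows, cols = np.nonzero(m.matched_peak >= 0)
        for r, c in zip(rows, cols):
            owners = claimants[int(m.matched_peak[r, c])]
            if len(owners - {key}) > 0:
                grid[r, c] = True
        flags.append(grid)
    return flags


def extract_xic(
    run: RunData,
    frag_mz: float,
    tol_ppm: float,
    window: WindowKey,
    rt_start: float,
    rt_stop: float,
) -> Chromatogram:
    """XIC of ``frag_mz`` over the MS2 scans of ``window`` within the peak
    boundaries; per scan, intensities of all peaks within tolerance are
    summed (0 when none)."""
    scans = run.ms2_in_rt_range(window, rt_start, rt_stop)
    tol = frag_mz * tol_ppm * 1e-6
    rts = np.array([s.rt for s in scans])
    vals = np.zeros(len(scans))
    for i, s in enumerate(scans):
        lo = np.searchsorted(s.mz, frag_mz - tol)
        hi = np.searchsorted(s.mz, frag_mz + tol, side="right")
        if hi > lo:
            vals[i] = s.intensity[lo:hi].sum()
    return Chromatogram(rt=rts, intensity=vals)


DEFAULT_WMA_WEIGHTS = (1.0, 2.0, 1.0)


def smooth_chromatogram(
    c: Chromatogram,
    method: str = "savitzky_golay",
    window: int = 7,
    polyorder: int = 2,
    wma_weights: tuple[float, ...] = DEFAULT_WMA_WEIGHTS,
) -> Chromatogram:
    """Savitzky-Golay smoothing (window 7, order 2 by default), falling back
    to a weighted moving average for traces shorter than the SG window.
    Negative smoothed values are clipped to 0."""
    y = c.intensity
    if y.size == 0:
        return Chromatogram(rt=c.rt.copy(), intensity=y.copy(), frag=c.frag)
    if method == "savitzky_golay" and y.size >= window:
        smoothed = savgol_filter(y, window_length=window, polyorder=polyorder)
    elif method in ("savitzky_golay", "weighted_moving_average"):
        w = np.asarray(wma_weights, dtype=float)
        smoothed = np.convolve(y, w / w.sum(), mode="same")
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return Chromatogram(rt=c.rt.copy(), intensity=np.clip(smoothed, 0.0, None), frag=c.frag)


def correlate_fragments(xics: list[Chromatogram]) -> CorrelationResult:
    """Pairwise Pearson r between fragment XICs; the top fragment maximizes
    the aggregate score (sum of r to all others).

    Zero-variance traces contribute r = 0 toward every partner and are
    flagged in ``zero_variance``.
    """
    n = len(xics)
    if n < 2:
        raise ValueError("need at least 2 fragment chromatograms")
    lengths = {len(x) for x in xics}
    if len(lengths) != 1:
        raise ValueError("chromatograms must share one rt grid")
    data = np.stack([x.intensity for x in xics])
    sd = data.std(axis=1)
    zero_var = sd == 0
    r = np.zeros((n, n))
    ok = ~zero_var
    if ok.sum() >= 2:
        sub = np.corrcoef(data[ok])
        r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, 1.0)
    aggregate = r.sum(axis=1) - 1.0
    top = int(np.argmax(aggregate))
    r_to_top = r[:, top].copy()
    r_to_top[top] = 1.0
    return CorrelationResult(
        pairwise_r=r,
        aggregate=aggregate,
        top_fragment=top,
        r_to_top=r_to_top,
        zero_variance=zero_var,
    )


def peak_shape_score(
    c: Chromatogram,
    all_xics: list[Chromatogram],
    rt_start: float,
    rt_stop: float,
    *,
    f_base: float = 0.10,
    f_raised: float = 0.25,
    low_peak_frac: float = 0.5,
    boundary_reference: str = "fragments",
) -> int:
    """Score how strongly a fragment trace stays elevated at the peak
    boundaries (0, 1 or 2 boundaries).

    A boundary meets the criterion when the trace there exceeds both the
    median of the reference intensities at that time point and a fraction
    ``f`` of the trace's own maximum inside the boundaries. ``f`` is 0.10,
    raised to 0.25 when the trace's maximum is below half of the highest
    fragment-trace maximum. ``boundary_reference`` selects the referent for
    the median ("fragments": this peptide's matched fragment XICs — the
    default reading).
    """
    if len(c) == 0:
        return 0
    if boundary_reference != "fragments":
        raise ValueError(f"unknown boundary_reference {boundary_reference!r}")
    i0 = int(np.argmin(np.abs(c.rt - rt_start)))
    i1 = int(np.argmin(np.abs(c.rt - rt_stop)))
    if i1 < i0:
        i0, i1 = i1, i0
    own_max = float(c.intensity[i0 : i1 + 1].max()) if i1 >= i0 else 0.0
    global_max = max((float(x.intensity.max()) for x in all_xics if len(x)), default=0.0)
    f = f_raised if own_max < low_peak_frac * global_max else f_base
    score = 0
    for idx in (i0, i1):
        ref = np.median([x.intensity[idx] for x in all_xics if len(x) > idx])
        v = float(c.intensity[idx])
        if v > ref and v > f * own_max:
            score += 1
    return score


def peptide_centric_shared(
    cr: CorrelationResult,
    shapes: list[int],
    threshold: float = 0.8,
) -> np.ndarray:
    """Shared iff r to the top fragment falls below ``threshold``, or the
    fragment's peak-shape score is 2 (the rule applies to the top fragment
    itself through its shape score)."""
    shapes_arr = np.asarray(shapes)
    if shapes_arr.shape != cr.r_to_top.shape:
        raise ValueError("one shape score per fragment required")
    return (cr.r_to_top < threshold) | (shapes_arr == 2)


def combine_shared(
    spec_flags: np.ndarray,
    pep_flags: np.ndarray,
    ambiguous_flags: np.ndarray,
) -> np.ndarray:
    """Union of the two detection strategies and within-peptide ambiguity."""
    if not (spec_flags.shape == pep_flags.shape == ambiguous_flags.shape):
        raise ValueError("flag grids must be congruent")
    return spec_flags | pep_flags | ambiguous_flags
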