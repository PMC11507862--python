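"""End-to-end assembly: annotate detections, flag interference, build
training examples.

This is the programmatic core behind the CLI's ``prepare`` step; it returns
both the surviving training examples and a per-detection record of which
strategy flagged which cell, so detector performance can be audited against
simulated ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fragments import (
    AnnotatedFragmentMatrix,
    IonConfig,
    match_spectrum,
    theoretical_fragments,
)
from .interference import (
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
from .io_formats import PrecursorDetection
from .spectra import RunData, Spectrum
from .training_data import (
    RTExample,
    Rejection,
    TrainingExample,
    build_fragment_example,
    build_rt_examples,
)

logger = logging.getLogger("diaforge")


@dataclass
class PrepareConfig:
    tol_ppm: float = 10.0
    corr_threshold: float = 0.8
    shared_fraction_max: float = 0.5
    nce: float = 27.0
    instrument: str = "Lumos"
    ion_config: IonConfig = field(default_factory=IonConfig)
    min_fragments_for_xic: int = 3
    min_xic_points: int = 4
    smoothing: str = "savitzky_golay"
    rt_norm_max: float | None = None  # None: use the run's max MS2 RT


@dataclass
class DetectionRecord:
    detection: PrecursorDetection
    spectrum: Spectrum
    matrix: AnnotatedFragmentMatrix
    ambiguous_flags: np.ndarray
    spectrum_centric_flags: np.ndarray
    peptide_centric_flags: np.ndarray
    combined_flags: np.ndarray


@dataclass
class PrepareResult:
    examples: list[TrainingExample]
    rt_examples: list[RTExample]
    records: list[DetectionRecord]
    rejections: dict[str, int]
    shared_stats: dict[str, float]
    rt_norm_max: float


def prepare_training_data(
    run: RunData,
    detections: list[PrecursorDetection],
    cfg: PrepareConfig = PrepareConfig(),
) -> PrepareResult:
    """Annotate every detection at its apex spectrum, flag shared peaks by
    both strategies, and assemble masked training + RT examples."""
    located: list[tuple[PrecursorDetection, Spectrum]] = []
    for det in detections:
        try:
            located.append((det, locate_apex_spectrum(run, det)))
        except NoCoveringWindowError as exc:
            logger.warning("skipping detection: %s", exc)

    # annotate, grouped by apex-spectrum identity for the spectrum-centric pass
    by_scan: dict[str, list[int]] = {}
    matrices: list[AnnotatedFragmentMatrix] = []
    for i, (det, spec) in enumerate(located):
        ions = theoretical_fragments(det.peptidoform, det.charge, cfg.ion_config)
        m = match_spectrum(
            spec,
            ions,
            cfg.tol_ppm,
            peptidoform=det.peptidoform,
            precursor_charge=det.charge,
        )
        matrices.append(m)
        by_scan.setdefault(spec.scan_id, []).append(i)

    ambiguous = [m.shared.copy() for m in matrices]
    spec_flags: list[np.ndarray] = [np.zeros_like(m.shared) for m in matrices]
    for scan_id, idxs in by_scan.items():
        flags = spectrum_centric_shared(located[idxs[0]][1], [matrices[i] for i in idxs])
        for i, f in zip(idxs, flags):
            spec_flags[i] = f

    records: list[DetectionRecord] = []
    examples: list[TrainingExample] = []
    rejections: dict[str, int] = {}
    counters = {"matched": 0, "ambiguous": 0, "spectrum_centric": 0,
                "peptide_centric": 0, "combined": 0}
    for i, (det, spec) in enumerate(located):
        m = matrices[i]
        pep_flags = _peptide_centric_flags(run, det, spec, m, cfg)
        combined = combine_shared(spec_flags[i], pep_flags, ambiguous[i])
        m.apply_shared(combined)
        matched = m.matched
        counters["matched"] += int(matched.sum())
        counters["ambiguous"] += int((ambiguous[i] & matched).sum())
        counters["spectrum_centric"] += int((spec_flags[i] & matched).sum())
        counters["peptide_centric"] += int((pep_flags & matched).sum())
        counters["combined"] += int((combined & matched).sum())
        records.append(
            DetectionRecord(
                detection=det,
                spectrum=spec,
                matrix=m,
                ambiguous_flags=ambiguous[i],
                spectrum_centric_flags=spec_flags[i],
                peptide_centric_flags=pep_flags,
                combined_flags=combined,
            )
        )
        result = build_fragment_example(
            det, m, cfg.shared_fraction_max, nce=cfg.nce, instrument=cfg.instrument
        )
        if isinstance(result, Rejection):
            rejections[result.reason] = rejections.get(result.reason, 0) + 1
        else:
            examples.append(result)

    rt_norm_max = cfg.rt_norm_max if cfg.rt_norm_max is not None else run.max_ms2_rt
    rt_examples = build_rt_examples(
        [det for det, _ in located], rt_norm_max=rt_norm_max
    )
    total_matched = max(counters["matched"], 1)
    shared_stats = {
        "n_detections": float(len(located)),
        "matched_peaks": float(counters["matched"]),
        "shared_fraction_combined": counters["combined"] / total_matched,
        "shared_fraction_spectrum_centric": counters["spectrum_centric"] / total_matched,
        "shared_fraction_peptide_centric": counters["peptide_centric"] / total_matched,
        "shared_fraction_ambiguous": counters["ambiguous"] / total_matched,
    }
    return PrepareResult(
        examples=examples,
        rt_examples=rt_examples,
        records=records,
        rejections=rejections,
        shared_stats=shared_stats,
        rt_norm_max=rt_norm_max,
    )


def _peptide_centric_flags(
    run: RunData,
    det: PrecursorDetection,
    spec: Spectrum,
    m: AnnotatedFragmentMatrix,
    cfg: PrepareConfig,
) -> np.ndarray:
    """XIC-correlation + peak-shape flags on the matrix grid. Degenerate
    inputs (too few fragments or chromatogram points) yield no flags."""
    flags = np.zeros_like(m.shared)
    cells = [
        (r, c)
        for r, c in zip(*np.nonzero(m.matched))
        if m.intensity[r, c] > 0
    ]
    if len(cells) < cfg.min_fragments_for_xic:
        return flags
    window = spec.window
    xics = []
    for r, c in cells:
        xic = extract_xic(
            run, m.theo_mz[r, c], cfg.tol_ppm, window, det.rt_start, det.rt_stop
        )
        xics.append(smooth_chromatogram(xic, method=cfg.smoothing))
    if len(xics[0]) < cfg.min_xic_points:
        return flags
    cr = correlate_fragments(xics)
    shapes = [
        peak_shape_score(x, xics, det.rt_start, det.rt_stop) for x in xics
    ]
    shared = peptide_centric_shared(cr, shapes, cfg.corr_threshold)
    for (r, c), flag in zip(cells, shared):
        flags[r, c] = flag
    return flags
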