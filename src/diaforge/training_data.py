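"""Assembly of masked fragment-intensity and normalized RT training examples.

Spectra dominated by interference are rejected outright: an example whose
base (maximum-intensity matched) peak is shared, or with more than a set
fraction of shared matched peaks (default 50%), carries too little reliable
signal to train on. Surviving spectra are max-normalized and the shared /
out-of-range cells are masked rather than zeroed, so they simply do not
contribute to the loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import Peptidoform
from .fragments import AnnotatedFragmentMatrix, NoUsablePeaksError, normalize_matrix
from .io_formats import PrecursorDetection

DEFAULT_INSTRUMENT = "Lumos"
DEFAULT_NCE = 27.0


@dataclass
class TrainingExample:
    peptidoform: Peptidoform
    charge: int
    nce: float
    instrument: str
    matrix: AnnotatedFragmentMatrix  # normalized, mask = shared | out-of-range


@dataclass
class RTExample:
    peptidoform: Peptidoform
    rt_norm: float  # fraction of the run's RT scale, in [0, 1]
    rt_raw: float  # minutes

    def __post_init__(self) -> None:
        if not 0.0 <= self.rt_norm <= 1.0:
            raise ValueError(f"rt_norm {self.rt_norm} outside [0, 1]")


@dataclass(frozen=True)
class Rejection:
    """Why a spectrum was excluded from training (a value, not an error)."""

    reason: str  # "base_peak_shared" | "shared_fraction" | "no_usable_peaks"
    detail: str = ""


def build_fragment_example(
    det: PrecursorDetection,
    matrix: AnnotatedFragmentMatrix,
    shared_fraction_max: float = 0.5,
    nce: float = DEFAULT_NCE,
    instrument: str = DEFAULT_INSTRUMENT,
) -> TrainingExample | Rejection:
    """Turn an annotated, interference-flagged matrix into a training example.

    Rejects when (a) the maximum-intensity matched peak is shared, or
    (b) shared matched peaks exceed ``shared_fraction_max`` of all matched
    peaks. Otherwise normalizes so the highest usable peak is 1 and keeps
    the mask (shared plus out-of-scan-range cells).
    """
    matched = matrix.matched
    n_matched = int(matched.sum())
    if n_matched == 0:
        return Rejection("no_usable_peaks", "no matched fragments")
    inten = np.where(matched, matrix.intensity, -np.inf)
    base_cell = np.unravel_index(np.argmax(inten), inten.shape)
    if matrix.shared[base_cell]:
        return Rejection("base_peak_shared")
    n_shared = int((matched & matrix.shared).sum())
    frac = n_shared / n_matched
    if frac > shared_fraction_max:
        return Rejection("shared_fraction", f"{frac:.3f} > {shared_fraction_max}")
    try:
        normalize_matrix(matrix)
    except NoUsablePeaksError as exc:
        return Rejection("no_usable_peaks", str(exc))
    return TrainingExample(
        peptidoform=det.peptidoform,
        charge=det.charge,
        nce=nce,
        instrument=instrument,
        matrix=matrix,
    )


def build_rt_examples(
    dets: list[PrecursorDetection],
    rt_norm_max: float | None = None,
    *,
    run_max_ms2_rt: float | None = None,
) -> list[RTExample]:
    """One RT example per distinct peptidoform from a single run.

    Among a peptidoform's charge states, the most confident detection
    (minimum q-value; ties toward the lower charge) supplies the RT, which
    is normalized by ``rt_norm_max`` — the run's maximum MS2 RT unless a
    user value is given.
    """
    if rt_norm_max is None:
        if run_max_ms2_rt is None:
            raise ValueError("rt_norm_max or run_max_ms2_rt must be provided")
        rt_norm_max = run_max_ms2_rt
    run_ids = {d.run_id for d in dets}
    if len(run_ids) > 1:
        raise ValueError(f"RT examples require a single run, got {sorted(run_ids)}")
    best: dict[str, PrecursorDetection] = {}
    for d in dets:
        key = d.peptidoform.proforma()
        cur = best.get(key)
        if cur is None or (d.q_value, d.charge) < (cur.q_value, cur.charge):
            best[key] = d
    examples = []
    for d in best.values():
        if d.rt_apex > rt_norm_max:
            raise ValueError(
                f"RT {d.rt_apex} min exceeds normalization scale {rt_norm_max} min"
            )
        examples.append(
            RTExample(
                peptidoform=d.peptidoform,
                rt_norm=d.rt_apex / rt_norm_max,
                rt_raw=d.rt_apex,
            )
        )
    return examples


def split_train_test(examples: list, test_fraction: float, seed: int):
    """Peptidoform-level train/test split: no sequence on both sides.

    Works for both fragment and RT examples (anything with a
    ``peptidoform``). Deterministic under ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    groups: dict[str, list] = {}
    for ex in examples:
        groups.setdefault(ex.peptidoform.sequence, []).append(ex)
    keys = sorted(groups)
    if len(keys) < 10:
        raise ValueError(f"need at least 10 peptidoforms to split, got {len(keys)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_test = max(1, round(test_fraction * len(keys)))
    test_keys = set(keys[:n_test])
    train, test = [], []
    for key in keys:
        (test if key in test_keys else train).extend(groups[key])
    return train, test


# ---------------------------------------------------------------------------
# columnar serialization (reuse the fragments module's fixed column ordering)
# ---------------------------------------------------------------------------


def examples_to_frame(examples: list[TrainingExample]) -> pd.DataFrame:
    """Long-format table: one row per grid cell, column index following the
    fixed fragment-column layout."""
    rows = []
    for i, ex in enumerate(examples):
        m = ex.matrix
        for r in range(m.intensity.shape[0]):
            for c in range(m.intensity.shape[1]):
                rows.append(
                    {
                        "example": i,
                        "modified_peptide": ex.peptidoform.proforma(),
                        "charge": ex.charge,
                        "nce": ex.nce,
                        "instrument": ex.instrument,
                        "row": r,
                        "col": c,
                        "intensity": m.intensity[r, c],
                        "shared": bool(m.shared[r, c]),
                        "mask": bool(m.mask[r, c]),
                    }
                )
    return pd.DataFrame(rows)


def write_examples_parquet(examples: list[TrainingExample], path: str) -> int:
    df = examples_to_frame(examples)
    df.to_parquet(path, index=False)
    return len(df)


def examples_from_frame(df: pd.DataFrame) -> list[TrainingExample]:
    """Rebuild training examples from the long-format table.

    Theoretical fragment m/z values are regenerated from the peptidoform
    (they are deterministic); matched cells are taken as unmasked cells with
    positive intensity.
    """
    from .chem import parse_modified_sequence
    from .fragments import FragmentColumnLayout, IonConfig, theoretical_fragments

    n_cols = int(df["col"].max()) + 1
    layout = FragmentColumnLayout(phospho_loss=n_cols > 4)
    out: list[TrainingExample] = []
    for _, g in df.groupby("example", sort=True):
        first = g.iloc[0]
        form = parse_modified_sequence(first["modified_peptide"])
        charge = int(first["charge"])
        L = len(form.sequence)
        shape = (L - 1, layout.n_columns)
        intensity = np.zeros(shape)
        shared = np.zeros(shape, dtype=bool)
        mask = np.ones(shape, dtype=bool)
        intensity[g["row"], g["col"]] = g["intensity"]
        shared[g["row"], g["col"]] = g["shared"]
        mask[g["row"], g["col"]] = g["mask"]
        theo = np.full(shape, np.nan)
        ions = theoretical_fragments(
            form, charge, IonConfig(layout.max_frag_charge, layout.phospho_loss)
        )
        for ion in ions:
            theo[layout.cell_of(ion, L)] = ion.mz
        matched = ~mask & (intensity > 0)
        out.append(
            TrainingExample(
                peptidoform=form,
                charge=charge,
                nce=float(first["nce"]),
                instrument=str(first["instrument"]),
                matrix=AnnotatedFragmentMatrix(
                    peptidoform=form,
                    precursor_charge=charge,
                    layout=layout,
                    intensity=intensity,
                    shared=shared,
                    mask=mask,
                    matched_mz=np.where(matched, theo, np.nan),
                    theo_mz=theo,
                    matched_peak=np.where(matched, 0, -1),
                    normalized=True,
                ),
            )
        )
    return out


def read_examples_parquet(path: str) -> list[TrainingExample]:
    return examples_from_frame(pd.read_parquet(path))


def write_rt_examples_tsv(examples: list[RTExample], path: str) -> int:
    df = pd.DataFrame(
        {
            "modified_peptide": [e.peptidoform.proforma() for e in examples],
            "rt_norm": [e.rt_norm for e in examples],
            "rt_raw": [e.rt_raw for e in examples],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def read_rt_examples_tsv(path: str) -> list[RTExample]:
    from .chem import parse_modified_sequence

    df = pd.read_csv(path, sep="\t")
    return [
        RTExample(
            peptidoform=parse_modified_sequence(r["modified_peptide"]),
            rt_norm=float(r["rt_norm"]),
            rt_raw=float(r["rt_raw"]),
        )
        for _, r in df.iterrows()
    ]
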