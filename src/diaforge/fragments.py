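"""Theoretical fragment ions and annotation of chimeric MS2 spectra.

Observed fragment intensities live on a fixed (backbone position x ion
column) grid. Row ``i`` (1-based cleavage ordinal) holds the b_i ion and the
y_(L-i) ion of a length-L peptide; the column axis enumerates
(series, fragment charge, neutral loss) in the fixed order

    b1+, b1+(-98), b2+, b2+(-98), y1+, y1+(-98), y2+, y2+(-98)

(loss columns present only when phospho losses are enabled). This bijection
is the package's on-disk fragment ordering as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import PHOSPHO_LOSS, PROTON, RESIDUE_MASS, WATER, Peptidoform
from .spectra import Spectrum

LOSS_NONE = ""
LOSS_PHOSPHO = "phospho_98"


@dataclass(frozen=True)
class IonConfig:
    """Which fragment ions to generate."""

    max_frag_charge: int = 2
    phospho_loss: bool = False


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    index: int  # 1-based cleavage ordinal within the series
    frag_charge: int
    loss: str  # LOSS_NONE or LOSS_PHOSPHO
    mz: float


class FragmentColumnLayout:
    """Fixed bijection between (series, frag_charge, loss) and column index."""

    def __init__(self, max_frag_charge: int = 2, phospho_loss: bool = False):
        self.max_frag_charge = max_frag_charge
        self.phospho_loss = phospho_loss
        cols: list[tuple[str, int, str]] = []
        for series in ("b", "y"):
            for charge in range(1, max_frag_charge + 1):
                cols.append((series, charge, LOSS_NONE))
                if phospho_loss:
                    cols.append((series, charge, LOSS_PHOSPHO))
        self.columns: tuple[tuple[str, int, str], ...] = tuple(cols)
        self._index = {c: i for i, c in enumerate(cols)}

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column_of(self, series: str, frag_charge: int, loss: str = LOSS_NONE) -> int:
        return self._index[(series, frag_charge, loss)]

    def cell_of(self, ion: FragmentIon, length: int) -> tuple[int, int]:
        """(row, col) grid cell of ``ion`` for a peptide of ``length`` residues."""
        row = ion.index - 1 if ion.series == "b" else length - ion.index - 1
        return row, self.column_of(ion.series, ion.frag_charge, ion.loss)

    def ion_key_of(self, row: int, col: int, length: int) -> tuple[str, int, int, str]:
        """Inverse of :meth:`cell_of`: (series, index, frag_charge, loss)."""
        series, charge, loss = self.columns[col]
        index = row + 1 if series == "b" else length - row - 1
        return series, index, charge, loss

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FragmentColumnLayout)
            and self.columns == other.columns
        )

    def to_dict(self) -> dict:
        return {
            "max_frag_charge": self.max_frag_charge,
            "phospho_loss": self.phospho_loss,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FragmentColumnLayout":
        return cls(**d)


def _prefix_masses(p: Peptidoform) -> np.ndarray:
    """Cumulative residue+mod masses; entry i = mass of residues 1..i."""
    masses = np.array([RESIDUE_MASS[aa] for aa in p.sequence], dtype=float)
    for pos, _, delta in p.mods:
        masses[pos - 1] += delta
    return np.cumsum(masses)


def theoretical_fragments(
    p: Peptidoform,
    precursor_charge: int,
    ion_config: IonConfig = IonConfig(),
) -> list[FragmentIon]:
    """Enumerate b/y ions (optionally with phospho neutral losses).

    Singly charged fragments only for 1+ precursors; singly and doubly
    charged fragments for 2+ and higher. A -97.9769 Da loss variant is added
    for every b/y ion whose residue span contains at least one phospho site.
    """
    L = len(p.sequence)
    if L < 2:
        raise ValueError("peptide must have at least 2 residues")
    if precursor_charge < 1:
        raise ValueError("precursor charge must be >= 1")
    prefix = _prefix_masses(p)
    total = prefix[-1]
    charges = (
        (1,)
        if precursor_charge == 1
        else tuple(range(1, ion_config.max_frag_charge + 1))
    )
    phospho = set(p.phospho_positions()) if ion_config.phospho_loss else set()
    ions: list[FragmentIon] = []
    for i in range(1, L):  # cleavage after residue i
        b_neutral = prefix[i - 1]
        y_neutral = total - prefix[i - 1] + WATER
        b_has_ph = any(pos <= i for pos in phospho)
        y_has_ph = any(pos > i for pos in phospho)
        for z in charges:
            ions.append(FragmentIon("b", i, z, LOSS_NONE, (b_neutral + z * PROTON) / z))
            if b_has_ph:
                ions.append(
                    FragmentIon(
                        "b", i, z, LOSS_PHOSPHO, (b_neutral - PHOSPHO_LOSS + z * PROTON) / z
                    )
                )
            yi = L - i
            ions.append(FragmentIon("y", yi, z, LOSS_NONE, (y_neutral + z * PROTON) / z))
            if y_has_ph:
                ions.append(
                    FragmentIon(
                        "y", yi, z, LOSS_PHOSPHO, (y_neutral - PHOSPHO_LOSS + z * PROTON) / z
                    )
                )
    return ions


class NoUsablePeaksError(ValueError):
    """Annotation produced no matched, unmasked peak to normalize against."""


@dataclass
class AnnotatedFragmentMatrix:
    """Observed fragment intensities of one precursor on the fixed grid.

    ``shared`` marks interfered cells; ``mask`` marks cells excluded from the
    training loss (shared cells, out-of-scan-range ions, and grid cells for
    which no ion was generated). ``shared`` implies ``mask``.
    """

    peptidoform: Peptidoform
    precursor_charge: int
    layout: FragmentColumnLayout
    intensity: np.ndarray  # (L-1, C) non-negative
    shared: np.ndarray  # bool
    mask: np.ndarray  # bool, True = excluded from loss
    matched_mz: np.ndarray  # float, nan where unmatched
    theo_mz: np.ndarray  # float, nan where no ion generated
    matched_peak: np.ndarray  # int, index of matched spectrum peak, -1 if none
    normalized: bool = False

    @property
    def length(self) -> int:
        return len(self.peptidoform.sequence)

    @property
    def matched(self) -> np.ndarray:
        return self.matched_peak >= 0

    def apply_shared(self, flags: np.ndarray) -> None:
        """OR extra shared flags into the matrix, keeping shared => mask."""
        if flags.shape != self.shared.shape:
            raise ValueError("shared-flag grid shape mismatch")
        self.shared |= flags
        self.mask |= flags

    def matched_cells(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.matched)
        return list(zip(rows.tolist(), cols.tolist()))


def match_spectrum(
    spec: Spectrum,
    ions: list[FragmentIon],
    tol_ppm: float = 10.0,
    *,
    peptidoform: Peptidoform,
    precursor_charge: int,
    layout: FragmentColumnLayout | None = None,
) -> AnnotatedFragmentMatrix:
    """Match theoretical ions of one peptidoform against a centroided MS2 scan.

    Each ion takes the nearest peak within ``tol_ppm`` (equidistant peaks:
    the more intense one). Unmatched ions get intensity 0; ions whose m/z
    falls outside the acquired scan range are masked instead. Any observed
    peak claimed by more than one ion of this peptidoform flags all claiming
    cells as shared (a within-peptide ambiguity is interference too).
    """
    if spec.ms_level != 2:
        raise ValueError("match_spectrum requires an MS2 spectrum")
    if layout is None:
        layout = FragmentColumnLayout(
            max_frag_charge=max((i.frag_charge for i in ions), default=2),
            phospho_loss=any(i.loss == LOSS_PHOSPHO for i in ions),
        )
    L = len(peptidoform.sequence)
    shape = (L - 1, layout.n_columns)
    intensity = np.zeros(shape)
    shared = np.zeros(shape, dtype=bool)
    mask = np.ones(shape, dtype=bool)  # cells without a generated ion stay masked
    matched_mz = np.full(shape, np.nan)
    theo_mz = np.full(shape, np.nan)
    matched_peak = np.full(shape, -1, dtype=int)

    scan_min = spec.scan_min if spec.scan_min is not None else -np.inf
    scan_max = spec.scan_max if spec.scan_max is not None else np.inf

    claims: dict[int, list[tuple[int, int]]] = {}
    mz_arr, int_arr = spec.mz, spec.intensity
    for ion in ions:
        cell = layout.cell_of(ion, L)
        theo_mz[cell] = ion.mz
        if not scan_min <= ion.mz <= scan_max:
            continue  # out of acquired range: stays masked
        mask[cell] = False
        pk = _nearest_peak(mz_arr, int_arr, ion.mz, tol_ppm)
        if pk is None:
            continue
        intensity[cell] = int_arr[pk]
        matched_mz[cell] = mz_arr[pk]
        matched_peak[cell] = pk
        claims.setdefault(pk, []).append(cell)

    for cells in claims.values():
        if len(cells) > 1:
            for cell in cells:
                shared[cell] = True
                mask[cell] = True

    return AnnotatedFragmentMatrix(
        peptidoform=peptidoform,
        precursor_charge=precursor_charge,
        layout=layout,
        intensity=intensity,
        shared=shared,
        mask=mask,
        matched_mz=matched_mz,
        theo_mz=theo_mz,
        matched_peak=matched_peak,
    )


def _nearest_peak(
    mz: np.ndarray, intensity: np.ndarray, target: float, tol_ppm: float
) -> int | None:
    if mz.size == 0:
        return None
    tol = target * tol_ppm * 1e-6
    j = np.searchsorted(mz, target)
    cands = [k for k in (j - 1, j) if 0 <= k < mz.size and abs(mz[k] - target) <= tol]
    if not cands:
        return None
    if len(cands) == 1:
        return cands[0]
    d0, d1 = abs(mz[cands[0]] - target), abs(mz[cands[1]] - target)
    if d0 < d1:
        return cands[0]
    if d1 < d0:
        return cands[1]
    # equidistant: prefer the more intense peak
    return max(cands, key=lambda k: intensity[k])


def normalize_matrix(m: AnnotatedFragmentMatrix) -> AnnotatedFragmentMatrix:
    """Scale intensities so the highest matched, unmasked peak equals 1.

    Masked cells' stored values are scaled by the same factor but remain
    masked. Raises :class:`NoUsablePeaksError` when nothing usable matched.
    """
    usable = m.matched & ~m.mask
    if not usable.any() or m.intensity[usable].max() <= 0:
        raise NoUsablePeaksError(
            f"{m.peptidoform.proforma()}/{m.precursor_charge}+: no usable peaks"
        )
    m.intensity = m.intensity / m.intensity[usable].max()
    m.normalized = True
    return m
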