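"""Peptidoform arithmetic: residues, modifications, monoisotopic masses.

A peptidoform is a peptide sequence plus a set of localized modifications.
Masses are monoisotopic throughout; retention times elsewhere in the package
are minutes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

PROTON = 1.007276
WATER = 18.010565
# H3PO4 neutral loss from phosphorylated fragments (nominal "-98 Da")
PHOSPHO_LOSS = 97.976896

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: monoisotopic residue masses (Da), from the Unimod/IUPAC values shipped
#: with pyteomics
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}


@dataclass(frozen=True)
class Modification:
    """A UniMod entry supported by the package."""

    unimod_id: int
    name: str
    delta_mass: float
    targets: str  # residues this mod may sit on


#: minimum supported modification set
MODIFICATIONS: dict[int, Modification] = {
    4: Modification(4, "Carbamidomethyl", 57.021464, "C"),
    21: Modification(21, "Phospho", 79.966331, "STY"),
    35: Modification(35, "Oxidation", 15.994915, "M"),
}


class UnknownModificationError(ValueError):
    """Raised for a modification token outside the supported UniMod set."""


class UnknownResidueError(ValueError):
    """Raised for a residue outside the 20 standard amino acids."""


@dataclass(frozen=True)
class Peptidoform:
    """Peptide sequence with localized modifications.

    ``mods`` is a tuple of ``(position, unimod_id, delta_mass)`` with 1-based
    residue positions; at most one modification per position.
    """

    sequence: str
    mods: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for aa in self.sequence:
            if aa not in STANDARD_RESIDUES:
                raise UnknownResidueError(f"unknown residue {aa!r} in {self.sequence}")
        positions = [p for p, _, _ in self.mods]
        if len(set(positions)) != len(positions):
            raise ValueError("at most one modification per position")
        for p, _, _ in self.mods:
            if not 1 <= p <= len(self.sequence):
                raise ValueError(f"mod position {p} outside 1..{len(self.sequence)}")

    # -- derived quantities -------------------------------------------------

    def mass(self) -> float:
        """Monoisotopic neutral mass in Da."""
        m = WATER + sum(RESIDUE_MASS[aa] for aa in self.sequence)
        return m + sum(d for _, _, d in self.mods)

    def mz(self, charge: int) -> float:
        """Precursor m/z at ``charge``."""
        if charge < 1:
            raise ValueError(f"charge must be >= 1, got {charge}")
        return (self.mass() + charge * PROTON) / charge

    def mod_at(self, position: int) -> int | None:
        """UniMod id at 1-based ``position``, or None."""
        for p, uid, _ in self.mods:
            if p == position:
                return uid
        return None

    def phospho_positions(self) -> tuple[int, ...]:
        return tuple(p for p, uid, _ in self.mods if uid == 21)

    # -- text notation ------------------------------------------------------

    def proforma(self) -> str:
        """DIA-NN style modified-sequence notation, e.g. ``AAC(UniMod:4)K``."""
        out = []
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            uid = self.mod_at(i)
            if uid is not None:
                out.append(f"(UniMod:{uid})")
        return "".join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.proforma()


_MOD_TOKEN = re.compile(r"\(([^)]*)\)")


def parse_modified_sequence(text: str) -> Peptidoform:
    """Parse DIA-NN modified-sequence notation into a :class:`Peptidoform`.

    Supported tokens are parenthesized ``UniMod:<id>`` annotations attached to
    the preceding residue. Unknown tokens raise
    :class:`UnknownModificationError` rather than being skipped.
    """
    sequence: list[str] = []
    mods: list[tuple[int, int, float]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            m = _MOD_TOKEN.match(text, i)
            if m is None:
                raise UnknownModificationError(f"unterminated modification token in {text!r}")
            token = m.group(1)
            if not token.startswith("UniMod:"):
                raise UnknownModificationError(f"unknown modification token {token!r}")
            try:
                uid = int(token.split(":", 1)[1])
            except ValueError as exc:
                raise UnknownModificationError(f"unknown modification token {token!r}") from exc
            if uid not in MODIFICATIONS:
                raise UnknownModificationError(f"unsupported UniMod id {uid}")
            if not sequence:
                raise UnknownModificationError(f"modification token before any residue in {text!r}")
            mods.append((len(sequence), uid, MODIFICATIONS[uid].delta_mass))
            i = m.end()
        else:
            sequence.append(ch)
            i += 1
    return Peptidoform("".join(sequence), tuple(mods))
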