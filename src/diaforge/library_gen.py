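"""In silico digestion, peptidoform enumeration and spectral-library assembly.

Trypsin here cleaves after K/R with no proline suppression ("Trypsin/P").
Peptides containing residues without a defined monoisotopic mass (U, X, ...)
are excluded from digestion output. Libraries keep, per precursor, the top-N
predicted fragments (default 20) inside the configured m/z ranges, rescaled
to max 1, with predicted RT mapped back to the experimental gradient scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .chem import MODIFICATIONS, STANDARD_RESIDUES, Peptidoform
from .fragments import FragmentIon, IonConfig, theoretical_fragments
from .io_formats import ProteinRecord
from .models import FragmentIntensityPredictor, RetentionTimePredictor

logger = logging.getLogger("diaforge")


@dataclass(frozen=True)
class DigestionConfig:
    enzyme: str = "trypsin/p"  # cut after K/R, no proline suppression
    max_missed: int = 1
    length_range: tuple[int, int] = (7, 35)
    nterm_m_excision: bool = False

    def __post_init__(self) -> None:
        if self.length_range[0] < 2:
            raise ValueError("minimum peptide length must be >= 2")


@dataclass(frozen=True)
class DigestedPeptide:
    sequence: str
    missed_cleavages: int


_CLEAVE_AFTER = {"trypsin/p": set("KR"), "trypsin": set("KR")}


def digest(protein: ProteinRecord, cfg: DigestionConfig = DigestionConfig()) -> list[DigestedPeptide]:
    """All tryptic products with at most ``max_missed`` internal cleavage
    sites, within the length range; duplicates within a protein deduplicated
    (first occurrence wins). Peptides containing non-standard residues are
    dropped (logged)."""
    residues = _CLEAVE_AFTER[cfg.enzyme]
    seqs = [protein.sequence]
    if cfg.nterm_m_excision and protein.sequence.startswith("M"):
        seqs.append(protein.sequence[1:])
    lo, hi = cfg.length_range
    seen: set[str] = set()
    out: list[DigestedPeptide] = []
    for seq in seqs:
        # cleavage sites: after each K/R (positions 1..len), plus termini
        sites = [0] + [i + 1 for i, aa in enumerate(seq) if aa in residues]
        if sites[-1] != len(seq):
            sites.append(len(seq))
        for a in range(len(sites) - 1):
            for b in range(a + 1, min(a + 2 + cfg.max_missed, len(sites))):
                pep = seq[sites[a] : sites[b]]
                missed = b - a - 1
                if not lo <= len(pep) <= hi or pep in seen:
                    continue
                if any(aa not in STANDARD_RESIDUES for aa in pep):
                    logger.info("peptide %s contains non-standard residue: excluded", pep)
                    seen.add(pep)
                    continue
                seen.add(pep)
                out.append(DigestedPeptide(pep, missed))
    return out


def enumerate_peptidoforms(
    peptide: str,
    fixed_mods: dict[str, int] | None = None,
    var_mods: dict[str, int] | None = None,
    max_var: int = 0,
    charges: range | tuple[int, ...] = (2, 3, 4),
) -> list[tuple[Peptidoform, int]]:
    """Cross fixed-mod placement, variable-mod combinations (up to
    ``max_var`` per peptide) and the precursor charge range.

    ``fixed_mods``/``var_mods`` map target residue -> UniMod id, e.g.
    ``{"C": 4}`` for carbamidomethyl and ``{"S": 21, "T": 21, "Y": 21}`` for
    phospho.
    """
    fixed_mods = fixed_mods if fixed_mods is not None else {"C": 4}
    var_mods = var_mods or {}
    base: list[tuple[int, int, float]] = []
    for pos, aa in enumerate(peptide, start=1):
        if aa in fixed_mods:
            uid = fixed_mods[aa]
            base.append((pos, uid, MODIFICATIONS[uid].delta_mass))
    var_sites = [
        (pos, var_mods[aa])
        for pos, aa in enumerate(peptide, start=1)
        if aa in var_mods and pos not in {p for p, _, _ in base}
    ]
    mod_sets: list[tuple[tuple[int, int, float], ...]] = []
    for k in range(0, max_var + 1):
        for combo in combinations(var_sites, k):
            mods = tuple(base) + tuple(
                (pos, uid, MODIFICATIONS[uid].delta_mass) for pos, uid in combo
            )
            mod_sets.append(tuple(sorted(mods)))
    out = []
    for mods in mod_sets:
        form = Peptidoform(peptide, mods)
        for z in charges:
            out.append((form, z))
    return out


@dataclass
class SpectralLibraryEntry:
    peptidoform: Peptidoform
    charge: int
    precursor_mz: float
    rt: float  # minutes, experimental scale
    protein_ids: tuple[str, ...]
    fragments: list[tuple[FragmentIon, float]] = field(default_factory=list)


def build_library(
    forms: list[tuple[Peptidoform, int]],
    frag_model: FragmentIntensityPredictor,
    rt_model: RetentionTimePredictor,
    precursor_mz_range: tuple[float, float],
    fragment_mz_range: tuple[float, float],
    top_n: int = 20,
    rt_scale: float = 60.0,
    nce: float = 27.0,
    instrument: str = "Lumos",
    protein_map: dict[str, tuple[str, ...]] | None = None,
    ion_config: IonConfig = IonConfig(),
) -> list[SpectralLibraryEntry]:
    """Predict and assemble library entries for the given peptidoforms.

    Precursors outside ``precursor_mz_range`` are dropped; fragments are
    restricted to ``fragment_mz_range``, ranked by predicted intensity
    (ties broken by series b<y, lower index, lower charge), truncated to
    ``top_n`` and renormalized to max 1. No peak masking applies at
    prediction time. Predicted normalized RT is rescaled by ``rt_scale``
    minutes.
    """
    protein_map = protein_map or {}
    kept = [
        (p, z) for p, z in forms
        if precursor_mz_range[0] <= p.mz(z) <= precursor_mz_range[1]
    ]
    if not kept:
        return []
    layout = frag_model.layout_
    entries: list[SpectralLibraryEntry] = []
    peps = [p for p, _ in kept]
    charges = [z for _, z in kept]
    grids = frag_model.predict(peps, charges, nce, instrument)
    rt_by_form: dict[str, float] = {}
    unique_forms: dict[str, Peptidoform] = {}
    for p in peps:
        unique_forms.setdefault(p.proforma(), p)
    keys = list(unique_forms)
    rts = rt_model.predict([unique_forms[k] for k in keys])
    rt_by_form = dict(zip(keys, rts))
    series_rank = {"b": 0, "y": 1}
    for (p, z), grid in zip(kept, grids):
        ions = theoretical_fragments(p, z, ion_config)
        L = len(p.sequence)
        candidates = []
        for ion in ions:
            if not fragment_mz_range[0] <= ion.mz <= fragment_mz_range[1]:
                continue
            cell = layout.cell_of(ion, L)
            intensity = float(grid[cell])
            if intensity <= 0:
                continue
            candidates.append((ion, intensity))
        if not candidates:
            logger.warning(
                "no fragments in range for %s/%d+: precursor dropped", p.proforma(), z
            )
            continue
        candidates.sort(
            key=lambda t: (
                -t[1],
                series_rank[t[0].series],
                t[0].index,
                t[0].frag_charge,
            )
        )
        top = candidates[:top_n]
        peak = max(i for _, i in top)
        top = [(ion, inten / peak) for ion, inten in top]
        entries.append(
            SpectralLibraryEntry(
                peptidoform=p,
                charge=z,
                precursor_mz=p.mz(z),
                rt=float(rt_by_form[p.proforma()] * rt_scale),
                protein_ids=protein_map.get(p.sequence, ()),
                fragments=top,
            )
        )
    return entries


def peptide_protein_map(
    proteins: list[ProteinRecord], cfg: DigestionConfig = DigestionConfig()
) -> dict[str, tuple[str, ...]]:
    """Map each digested peptide to all parent protein accessions."""
    out: dict[str, list[str]] = {}
    for prot in proteins:
        for pep in digest(prot, cfg):
            parents = out.setdefault(pep.sequence, [])
            if prot.accession not in parents:
                parents.append(prot.accession)
    return {k: tuple(v) for k, v in out.items()}
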