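"""Simulated DIA runs with known fragmentation, RT and interference ground truth.

The generator renders Gaussian elution profiles of tryptic peptides into a
windowed DIA cycle, sums co-isolated fragment contributions into centroided
MS2 peaks, and records, for every rendered fragment peak, whether any other
precursor (identified or anonymous) contributes more than 5% of its
intensity at the apex — the ground-truth interference labels the detector
modules are scored against.

The fragmentation rule is deliberately a smooth closed-form function (not a
neural network) of the cleavage-flanking residues, position, charge and
NCE, so model training has a recoverable target; the RT rule is a logistic
function of mean residue hydrophobicity. Identified peptides co-eluting in
one window are kept m/z-separated so that no sub-threshold cross-matches
blur the labels; interference is injected explicitly as co-eluting
anonymous precursors at a requested rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import MODIFICATIONS, Peptidoform
from .fragments import (
    AnnotatedFragmentMatrix,
    FragmentColumnLayout,
    IonConfig,
    theoretical_fragments,
)
from .io_formats import ProteinRecord, write_detection_report, write_fasta, write_mzml
from .library_gen import DigestionConfig, digest
from .spectra import RunData, Spectrum
from .training_data import RTExample, TrainingExample

# invented, smooth per-residue scales in [0, 1]
CLEAVAGE_PROPENSITY = {
    "G": 0.20, "A": 0.30, "S": 0.25, "P": 0.90, "V": 0.40, "T": 0.30,
    "C": 0.35, "L": 0.50, "I": 0.50, "N": 0.35, "D": 0.60, "Q": 0.40,
    "K": 0.70, "E": 0.55, "M": 0.45, "H": 0.65, "F": 0.50, "R": 0.75,
    "Y": 0.45, "W": 0.55,
}
HYDROPHOBICITY = {
    "G": 0.35, "A": 0.50, "S": 0.30, "P": 0.40, "V": 0.75, "T": 0.40,
    "C": 0.55, "L": 0.90, "I": 0.95, "N": 0.25, "D": 0.30, "Q": 0.30,
    "K": 0.10, "E": 0.35, "M": 0.80, "F": 0.95, "R": 0.15, "H": 0.20,
    "W": 1.00, "Y": 0.70,
}
BASIC_RESIDUES = set("KRH")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def true_intensity_rule(
    p: Peptidoform,
    charge: int,
    nce: float,
    layout: FragmentColumnLayout | None = None,
) -> np.ndarray:
    """Closed-form generating rule for fragment intensities, max-normalized.

    Per cleavage site: a propensity from the flanking residues times a broad
    positional envelope; the b/y balance shifts monotonically with NCE and
    charge; doubly charged fragments scale with the basic-residue content of
    their span; phospho-loss columns carry 60% of their parent ion.
    """
    if layout is None:
        layout = FragmentColumnLayout()
    seq = p.sequence
    L = len(seq)
    grid = np.zeros((L - 1, layout.n_columns))
    frac_y = _sigmoid(0.8 + 0.10 * (nce - 27.0) - 0.4 * (charge - 2))
    phospho = set(p.phospho_positions())
    n_basic_prefix = np.cumsum([aa in BASIC_RESIDUES for aa in seq])
    frag_charges = (1,) if charge == 1 else tuple(range(1, layout.max_frag_charge + 1))
    for i in range(1, L):
        left, right = seq[i - 1], seq[i]
        propensity = np.exp(
            1.2 * CLEAVAGE_PROPENSITY[right] - 0.8 * CLEAVAGE_PROPENSITY[left]
        )
        envelope = np.sin(np.pi * i / L) ** 0.7
        base = propensity * envelope
        for series, inten in (("b", base * (1 - frac_y)), ("y", base * frac_y)):
            n_basic = (
                n_basic_prefix[i - 1]
                if series == "b"
                else n_basic_prefix[-1] - n_basic_prefix[i - 1]
            )
            has_ph = (
                any(pos <= i for pos in phospho)
                if series == "b"
                else any(pos > i for pos in phospho)
            )
            index = i if series == "b" else L - i
            for z in frag_charges:
                value = inten if z == 1 else inten * 0.3 * _sigmoid(2.0 * (n_basic - 1))
                col = layout.column_of(series, z)
                row = index - 1 if series == "b" else L - index - 1
                grid[row, col] = value
                if layout.phospho_loss and has_ph:
                    grid[row, layout.column_of(series, z, "phospho_98")] = 0.6 * value
    m = grid.max()
    return grid / m if m > 0 else grid


def true_rt_rule(p: Peptidoform) -> float:
    """Normalized retention time in [0, 1]: logistic in mean hydrophobicity."""
    h = float(np.mean([HYDROPHOBICITY[aa] for aa in p.sequence]))
    for _, uid, _ in p.mods:
        if uid == 21:
            h -= 0.05 / len(p.sequence) * 10
        elif uid == 35:
            h -= 0.02
    return float(np.clip(0.05 + 0.90 * _sigmoid((h - 0.52) / 0.12), 0.0, 1.0))


@dataclass
class SyntheticConfig:
    n_proteins: int = 80
    protein_length: int = 400
    n_peptides: int = 500
    charge_probs: dict[int, float] = field(default_factory=lambda: {2: 0.7, 3: 0.3})
    window_low: float = 400.0
    window_width: float = 20.0
    n_windows: int = 25
    cycle_s: float = 2.5
    gradient_min: float = 30.0
    peak_sigma_s: float = 6.0
    scan_min: float = 150.0
    scan_max: float = 1500.0
    interference_fraction: float = 0.0
    noise_sigma: float = 0.05  # multiplicative log-normal sigma
    n_noise_peaks: int = 3  # additive floor peaks per MS2 scan
    junk_fraction: float = 0.1  # high-q decoy-like report rows
    nce: float = 27.0
    instrument: str = "Lumos"
    tol_ppm: float = 10.0
    min_rel_intensity: float = 0.01
    rt_jitter_min: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("need at least one isolation window")
        if not 0.0 <= self.interference_fraction < 1.0:
            raise ValueError("interference_fraction must be in [0, 1)")

    @property
    def windows(self) -> list[tuple[float, float]]:
        return [
            (
                self.window_low + i * self.window_width,
                self.window_low + (i + 1) * self.window_width,
            )
            for i in range(self.n_windows)
        ]


@dataclass
class TruthEntry:
    peptidoform: Peptidoform
    charge: int
    apex_min: float
    abundance: float
    true_grid: np.ndarray  # generating rule, max 1
    rendered: np.ndarray  # bool grid: fragment peak present in the run
    interfered: np.ndarray  # bool grid: >5% foreign contribution at apex


@dataclass
class SyntheticGroundTruth:
    layout: FragmentColumnLayout
    entries: dict[tuple[str, int], TruthEntry]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (form, z), e in self.entries.items():
            r_idx, c_idx = np.nonzero(e.rendered)
            for r, c in zip(r_idx, c_idx):
                rows.append(
                    {
                        "modified_peptide": form,
                        "charge": z,
                        "row": int(r),
                        "col": int(c),
                        "true_intensity": float(e.true_grid[r, c]),
                        "interfered": bool(e.interfered[r, c]),
                        "apex_min": e.apex_min,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    run: RunData
    report_rows: list[dict]
    proteins: list[ProteinRecord]
    truth: SyntheticGroundTruth
    config: SyntheticConfig

    def write(self, out_dir: str) -> dict[str, str]:
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "mzml": os.path.join(out_dir, "run.mzML"),
            "report": os.path.join(out_dir, "report.tsv"),
            "fasta": os.path.join(out_dir, "db.fasta"),
            "truth": os.path.join(out_dir, "truth.parquet"),
        }
        write_mzml(self.run, paths["mzml"])
        write_detection_report(self.report_rows, paths["report"])
        write_fasta(self.proteins, paths["fasta"])
        self.truth.to_frame().to_parquet(paths["truth"], index=False)
        return paths


_AA_POOL = list("ACDEFGHILMNPQSTVWYKR")
_AA_WEIGHTS = np.array(
    [6, 2, 5, 6, 4, 6, 2, 5, 9, 2, 4, 5, 4, 7, 6, 7, 1, 3, 11, 11], dtype=float
)
_AA_WEIGHTS /= _AA_WEIGHTS.sum()


def _random_proteins(rng: np.random.Generator, n: int, length: int) -> list[ProteinRecord]:
    return [
        ProteinRecord(
            accession=f"SYN{i:04d}",
            sequence="".join(rng.choice(_AA_POOL, size=length, p=_AA_WEIGHTS)),
        )
        for i in range(n)
    ]


@dataclass
class _Precursor:
    form: Peptidoform
    charge: int
    window: int
    apex: float  # minutes
    sigma: float  # minutes
    abundance: float
    frags: list[tuple[tuple[int, int], float, float]]  # (cell, mz, rel_intensity)
    true_grid: np.ndarray


def simulate_dataset(cfg: SyntheticConfig) -> SimulatedDataset:
    """Render a full DIA run + matching detection report + FASTA + truth."""
    rng = np.random.default_rng(cfg.seed)
    layout = FragmentColumnLayout()
    proteins = _random_proteins(rng, cfg.n_proteins, cfg.protein_length)
    dig_cfg = DigestionConfig()
    peptides: list[str] = []
    seen: set[str] = set()
    for prot in proteins:
        for pep in digest(prot, dig_cfg):
            if pep.sequence not in seen:
                seen.add(pep.sequence)
                peptides.append(pep.sequence)
    rng.shuffle(peptides)

    sigma_min = cfg.peak_sigma_s / 60.0
    span_lo, span_hi = cfg.windows[0][0], cfg.windows[-1][1]
    charges = sorted(cfg.charge_probs)
    charge_p = np.array([cfg.charge_probs[z] for z in charges], dtype=float)
    charge_p /= charge_p.sum()

    accepted: list[_Precursor] = []
    by_window: dict[int, list[_Precursor]] = {}
    leftovers: list[tuple[str, int]] = []
    sep_tol = 3.0 * cfg.tol_ppm * 1e-6  # relative m/z separation among identified
    for seq in peptides:
        if len(accepted) >= cfg.n_peptides:
            leftovers.append((seq, int(rng.choice(charges, p=charge_p))))
            if len(leftovers) > 5 * cfg.n_peptides:
                break
            continue
        charge = int(rng.choice(charges, p=charge_p))
        mods = tuple(
            (i + 1, 4, MODIFICATIONS[4].delta_mass)
            for i, aa in enumerate(seq)
            if aa == "C"
        )
        form = Peptidoform(seq, mods)
        mz = form.mz(charge)
        if not span_lo <= mz < span_hi:
            continue
        w = int((mz - cfg.window_low) // cfg.window_width)
        apex = cfg.gradient_min * true_rt_rule(form) + rng.normal(0, cfg.rt_jitter_min)
        apex = float(np.clip(apex, 4 * sigma_min, cfg.gradient_min - 4 * sigma_min))
        abundance = float(np.exp(rng.normal(np.log(1e5), 0.8)))
        grid = true_intensity_rule(form, charge, cfg.nce, layout)
        ions = theoretical_fragments(form, charge, IonConfig(layout.max_frag_charge))
        frags = []
        for ion in ions:
            cell = layout.cell_of(ion, len(seq))
            rel = grid[cell]
            if rel >= cfg.min_rel_intensity and cfg.scan_min <= ion.mz <= cfg.scan_max:
                frags.append((cell, ion.mz, float(rel)))
        if not frags:
            continue
        # keep identified co-eluters m/z-separated so ground-truth labels stay crisp
        conflict = False
        for other in by_window.get(w, []):
            if abs(other.apex - apex) > 7 * sigma_min:
                continue
            for _, mz_a, _ in frags:
                for _, mz_b, _ in other.frags:
                    if abs(mz_a - mz_b) <= sep_tol * mz_a:
                        conflict = True
                        break
                if conflict:
                    break
            if conflict:
                break
        if conflict:
            continue
        prec = _Precursor(form, charge, w, apex, sigma_min, abundance, frags, grid)
        accepted.append(prec)
        by_window.setdefault(w, []).append(prec)
    if len(accepted) < cfg.n_peptides:
        raise ValueError(
            f"window scheme infeasible: only {len(accepted)} of {cfg.n_peptides} "
            "precursors fit the isolation windows"
        )

    # anonymous co-eluting interferers at the requested per-peak rate
    interferers: list[tuple[int, float, float, float, float]] = []  # (w, mz, apex, sigma, amp)
    injected: dict[int, set[tuple[int, int]]] = {}
    if cfg.interference_fraction > 0:
        for pi, prec in enumerate(accepted):
            for cell, mz, rel in prec.frags:
                if rng.random() >= cfg.interference_fraction:
                    continue
                mz_i = mz * (1.0 + rng.uniform(-6e-6, 6e-6))
                # clearly offset co-eluters: apex 1.2-2.5 peak-sigmas away,
                # intensity comparable to brighter than the target fragment
                shift = rng.choice([-1.0, 1.0]) * rng.uniform(1.2, 2.5) * sigma_min
                amp = prec.abundance * rel * float(np.exp(rng.normal(np.log(1.5), 0.5)))
                sig = sigma_min * rng.uniform(0.8, 1.3)
                interferers.append((prec.window, mz_i, prec.apex + shift, sig, amp))
                injected.setdefault(pi, set()).add(cell)

    # --- render the cycle grid --------------------------------------------
    n_cycles = int(cfg.gradient_min * 60.0 / cfg.cycle_s)
    cycle_min = cfg.cycle_s / 60.0

    def ms2_rt(w: int, c: int) -> float:
        return c * cycle_min + (w + 1) * cycle_min / (cfg.n_windows + 2)

    # peaks[(w, c)] -> list of (mz, intensity, owner)
    peaks: dict[tuple[int, int], list[tuple[float, float, int]]] = {}

    def render(owner: int, w: int, mz: float, apex: float, sig: float, amp: float):
        c_lo = max(0, int((apex - 3.5 * sig) / cycle_min))
        c_hi = min(n_cycles - 1, int((apex + 3.5 * sig) / cycle_min) + 1)
        for c in range(c_lo, c_hi + 1):
            t = ms2_rt(w, c)
            v = amp * np.exp(-0.5 * ((t - apex) / sig) ** 2)
            if v > 0.5:  # detector floor
                peaks.setdefault((w, c), []).append((mz, float(v), owner))

    for pi, prec in enumerate(accepted):
        for cell, mz, rel in prec.frags:
            render(pi, prec.window, mz, prec.apex, prec.sigma, prec.abundance * rel)
    for k, (w, mz, apex, sig, amp) in enumerate(interferers):
        render(-(k + 1), w, mz, apex, sig, amp)

    # --- centroid merge + ground-truth labels -----------------------------
    merged: dict[tuple[int, int], list[tuple[float, float, dict[int, float]]]] = {}
    for key, plist in peaks.items():
        plist.sort()
        out = []
        i = 0
        while i < len(plist):
            mz0, inten, owners = plist[i][0], 0.0, {}
            j = i
            mz_sum = 0.0
            while j < len(plist) and plist[j][0] - mz0 <= mz0 * cfg.tol_ppm * 1e-6:
                mzj, vj, oj = plist[j]
                inten += vj
                mz_sum += mzj * vj
                owners[oj] = owners.get(oj, 0.0) + vj
                j += 1
            out.append((mz_sum / inten, inten, owners))
            i = j
        merged[key] = out

    entries: dict[tuple[str, int], TruthEntry] = {}
    for pi, prec in enumerate(accepted):
        shape = prec.true_grid.shape
        rendered = np.zeros(shape, dtype=bool)
        interfered = np.zeros(shape, dtype=bool)
        c_apex = int(np.argmin(
            [abs(ms2_rt(prec.window, c) - prec.apex) for c in range(n_cycles)]
        ))
        scan = merged.get((prec.window, c_apex), [])
        for cell, mz, rel in prec.frags:
            rendered[cell] = True
            tol = mz * cfg.tol_ppm * 1e-6
            for mz_m, inten, owners in scan:
                if abs(mz_m - mz) <= tol and pi in owners:
                    foreign = inten - owners[pi]
                    if foreign / inten > 0.05:
                        interfered[cell] = True
                    break
        entries[(prec.form.proforma(), prec.charge)] = TruthEntry(
            peptidoform=prec.form,
            charge=prec.charge,
            apex_min=prec.apex,
            abundance=prec.abundance,
            true_grid=prec.true_grid,
            rendered=rendered,
            interfered=interfered,
        )

    # --- noise + spectrum assembly ----------------------------------------
    spectra: list[Spectrum] = []
    scan_counter = 0
    ms1_mz: dict[int, list[tuple[float, float]]] = {}
    for pi, prec in enumerate(accepted):
        mz = prec.form.mz(prec.charge)
        c_lo = max(0, int((prec.apex - 3.5 * prec.sigma) / cycle_min))
        c_hi = min(n_cycles - 1, int((prec.apex + 3.5 * prec.sigma) / cycle_min) + 1)
        for c in range(c_lo, c_hi + 1):
            t = c * cycle_min
            v = prec.abundance * 3.0 * np.exp(-0.5 * ((t - prec.apex) / prec.sigma) ** 2)
            if v > 0.5:
                ms1_mz.setdefault(c, []).append((mz, float(v)))
    for c in range(n_cycles):
        scan_counter += 1
        pk = sorted(ms1_mz.get(c, []))
        spectra.append(
            Spectrum(
                scan_id=f"scan={scan_counter}",
                ms_level=1,
                rt=c * cycle_min,
                mz=np.array([m for m, _ in pk]),
                intensity=np.array([v for _, v in pk]),
                scan_min=cfg.windows[0][0],
                scan_max=cfg.windows[-1][1],
            )
        )
        for w in range(cfg.n_windows):
            scan_counter += 1
            plist = merged.get((w, c), [])
            mz_arr = np.array([m for m, _, _ in plist])
            in_arr = np.array([v for _, v, _ in plist])
            if in_arr.size and cfg.noise_sigma > 0:
                in_arr = in_arr * rng.lognormal(0.0, cfg.noise_sigma, size=in_arr.size)
            if cfg.n_noise_peaks > 0:
                nmz = rng.uniform(cfg.scan_min, cfg.scan_max, size=cfg.n_noise_peaks)
                nint = rng.uniform(1.0, 50.0, size=cfg.n_noise_peaks)
                mz_arr = np.concatenate([mz_arr, nmz])
                in_arr = np.concatenate([in_arr, nint])
            low, high = cfg.windows[w]
            spectra.append(
                Spectrum(
                    scan_id=f"scan={scan_counter}",
                    ms_level=2,
                    rt=ms2_rt(w, c),
                    mz=mz_arr,
                    intensity=in_arr,
                    isolation_low=low,
                    isolation_high=high,
                    scan_min=cfg.scan_min,
                    scan_max=cfg.scan_max,
                )
            )
    run = RunData.from_spectra("synthetic_run", spectra)

    # --- detection report --------------------------------------------------
    report_rows = []
    for prec in accepted:
        report_rows.append(
            {
                "File.Name": "synthetic_run",
                "Modified.Sequence": prec.form.proforma(),
                "Precursor.Charge": prec.charge,
                "RT": round(prec.apex, 4),
                "RT.Start": round(max(0.0, prec.apex - 2.5 * prec.sigma), 4),
                "RT.Stop": round(min(cfg.gradient_min, prec.apex + 2.5 * prec.sigma), 4),
                "Q.Value": round(float(rng.uniform(0.0, 0.002)), 6),
            }
        )
    n_junk = int(round(cfg.junk_fraction * cfg.n_peptides))
    for seq, charge in leftovers[:n_junk]:
        apex = float(rng.uniform(1.0, cfg.gradient_min - 1.0))
        report_rows.append(
            {
                "File.Name": "synthetic_run",
                "Modified.Sequence": seq,
                "Precursor.Charge": charge,
                "RT": round(apex, 4),
                "RT.Start": round(apex - 2.5 * sigma_min, 4),
                "RT.Stop": round(apex + 2.5 * sigma_min, 4),
                "Q.Value": round(float(rng.uniform(0.02, 0.5)), 6),
            }
        )

    truth = SyntheticGroundTruth(layout=layout, entries=entries)
    return SimulatedDataset(
        run=run, report_rows=report_rows, proteins=proteins, truth=truth, config=cfg
    )


# ---------------------------------------------------------------------------
# direct training-example generators (no rendering; for model recovery)
# ---------------------------------------------------------------------------


def _random_tryptic_peptide(rng: np.random.Generator, min_len=7, max_len=30) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(_AA_POOL, size=n - 1, p=_AA_WEIGHTS))
    body = body.replace("K", "A").replace("R", "G")  # keep a single C-terminal site
    return body + ("K" if rng.random() < 0.5 else "R")


def make_fragment_examples(
    n: int,
    seed: int,
    nce: float = 27.0,
    instrument: str = "Lumos",
    noise_sigma: float = 0.05,
    charge_probs: dict[int, float] | None = None,
) -> list[TrainingExample]:
    """Training examples drawn straight from the generating rule plus
    multiplicative log-normal noise (no chromatographic rendering)."""
    rng = np.random.default_rng(seed)
    layout = FragmentColumnLayout()
    charge_probs = charge_probs or {2: 0.7, 3: 0.3}
    charges = sorted(charge_probs)
    p_arr = np.array([charge_probs[z] for z in charges], dtype=float)
    p_arr /= p_arr.sum()
    out: list[TrainingExample] = []
    seen: set[str] = set()
    while len(out) < n:
        seq = _random_tryptic_peptide(rng)
        if seq in seen:
            continue
        seen.add(seq)
        charge = int(rng.choice(charges, p=p_arr))
        form = Peptidoform(seq)
        grid = true_intensity_rule(form, charge, nce, layout)
        noisy = grid * rng.lognormal(0.0, noise_sigma, size=grid.shape)
        generated = grid > 0
        m = noisy[generated].max()
        noisy = noisy / m
        matrix = AnnotatedFragmentMatrix(
            peptidoform=form,
            precursor_charge=charge,
            layout=layout,
            intensity=np.where(generated, noisy, 0.0),
            shared=np.zeros_like(generated),
            mask=~generated,
            matched_mz=np.where(generated, 0.0, np.nan),
            theo_mz=np.where(generated, 0.0, np.nan),
            matched_peak=np.where(generated, 0, -1),
            normalized=True,
        )
        out.append(
            TrainingExample(
                peptidoform=form,
                charge=charge,
                nce=nce,
                instrument=instrument,
                matrix=matrix,
            )
        )
    return out


def make_rt_examples(
    n: int, seed: int, noise_sd: float = 0.01
) -> list[RTExample]:
    """RT examples: the hydrophobicity rule plus Gaussian noise on the
    normalized scale."""
    rng = np.random.default_rng(seed)
    out: list[RTExample] = []
    seen: set[str] = set()
    while len(out) < n:
        seq = _random_tryptic_peptide(rng)
        if seq in seen:
            continue
        seen.add(seq)
        form = Peptidoform(seq)
        rt = float(np.clip(true_rt_rule(form) + rng.normal(0.0, noise_sd), 0.0, 1.0))
        out.append(RTExample(peptidoform=form, rt_norm=rt, rt_raw=rt * 60.0))
    return out
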