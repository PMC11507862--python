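"""Readers and writers for the formats the pipeline touches.

mzML is read through pyteomics; a minimal mzML 1.1.0 writer (64-bit floats,
no compression) is provided so simulated runs round-trip through the same
reader. Detection reports follow the DIA-NN main-report dialect
(tab-separated, one row per precursor per run). Spectral libraries are
written row-per-fragment as TSV and, with identical schema, Parquet.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import fasta as _pfasta

from .chem import Peptidoform, parse_modified_sequence
from .spectra import RunData, Spectrum

if TYPE_CHECKING:  # pragma: no cover
    from .library_gen import SpectralLibraryEntry

logger = logging.getLogger("diaforge")

REQUIRED_REPORT_COLUMNS = (
    "Modified.Sequence",
    "Precursor.Charge",
    "RT",
    "RT.Start",
    "RT.Stop",
    "Q.Value",
    "File.Name",
)

LIBRARY_COLUMNS = (
    "ModifiedPeptide",
    "PeptideSequence",
    "PrecursorCharge",
    "PrecursorMz",
    "Tr_recalibrated",
    "ProteinId",
    "FragmentType",
    "FragmentCharge",
    "FragmentSeriesNumber",
    "FragmentLossType",
    "FragmentMz",
    "LibraryIntensity",
)


@dataclass
class PrecursorDetection:
    """One detected precursor (peptidoform + charge) from a search report."""

    peptidoform: Peptidoform
    charge: int
    rt_apex: float  # minutes
    rt_start: float
    rt_stop: float
    q_value: float
    run_id: str
    site_confidence: float | None = None

    def __post_init__(self) -> None:
        if not self.rt_start <= self.rt_apex <= self.rt_stop:
            raise ValueError(
                f"{self.peptidoform.proforma()}: rt_start <= rt_apex <= rt_stop violated"
            )
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q_value outside [0, 1]")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------


_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_map(elem) -> dict[str, tuple[str, str]]:
    """accession -> (value, unit name) for cvParams directly under ``elem``."""
    out = {}
    for cv in elem.findall(f"{_NS}cvParam"):
        out[cv.get("accession")] = (cv.get("value", ""), cv.get("unitName", ""))
    return out


def read_mzml(path: str, run_id: str | None = None) -> RunData:
    """Load a centroided mzML file into :class:`RunData`.

    Retention times are converted to minutes. Every MS2 scan must carry an
    isolation window; its absence is reported with the offending scan id.
    Binary arrays may be 32- or 64-bit floats, zlib-compressed or not.
    """
    spectra: list[Spectrum] = []
    for _, elem in etree.iterparse(str(path), events=("end",), tag=f"{_NS}spectrum"):
        spectra.append(_parse_spectrum(elem))
        elem.clear(keep_tail=True)
    if run_id is None:
        run_id = str(path)
    return RunData.from_spectra(run_id, spectra)


def _parse_spectrum(elem) -> Spectrum:
    scan_id = elem.get("id", "")
    params = _cv_map(elem)
    if "MS:1000511" not in params:
        raise ValueError(f"scan {scan_id!r}: no ms level recorded")
    ms_level = int(params["MS:1000511"][0])
    rt = scan_min = scan_max = None
    scan_list = elem.find(f"{_NS}scanList")
    if scan_list is not None:
        scan = scan_list.find(f"{_NS}scan")
        if scan is not None:
            sp = _cv_map(scan)
            if "MS:1000016" in sp:
                value, unit = sp["MS:1000016"]
                rt = float(value)
                if unit.lower() in ("second", "seconds", "s"):
                    rt /= 60.0
            sw = scan.find(f"{_NS}scanWindowList/{_NS}scanWindow")
            if sw is not None:
                swp = _cv_map(sw)
                if "MS:1000501" in swp:
                    scan_min = float(swp["MS:1000501"][0])
                if "MS:1000500" in swp:
                    scan_max = float(swp["MS:1000500"][0])
    if rt is None:
        raise ValueError(f"scan {scan_id!r}: no scan start time recorded")
    iso_low = iso_high = None
    if ms_level == 2:
        iso = elem.find(f"{_NS}precursorList/{_NS}precursor/{_NS}isolationWindow")
        if iso is None:
            raise ValueError(f"MS2 scan {scan_id!r} lacks an isolation window")
        ip = _cv_map(iso)
        try:
            target = float(ip["MS:1000827"][0])
            iso_low = target - float(ip["MS:1000828"][0])
            iso_high = target + float(ip["MS:1000829"][0])
        except KeyError as exc:
            raise ValueError(f"MS2 scan {scan_id!r} lacks an isolation window") from exc
    mz = intensity = None
    for bda in elem.findall(f"{_NS}binaryDataArrayList/{_NS}binaryDataArray"):
        bp = _cv_map(bda)
        binary = bda.find(f"{_NS}binary")
        raw = base64.b64decode(binary.text or "")
        if "MS:1000574" in bp:  # zlib compression
            raw = zlib.decompress(raw)
        dtype = np.float32 if "MS:1000521" in bp else np.float64
        arr = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)
        if "MS:1000514" in bp:
            mz = arr
        elif "MS:1000515" in bp:
            intensity = arr
    if mz is None or intensity is None:
        mz = np.zeros(0) if mz is None else mz
        intensity = np.zeros(0) if intensity is None else intensity
    return Spectrum(
        scan_id=scan_id,
        ms_level=ms_level,
        rt=rt,
        mz=mz,
        intensity=intensity,
        isolation_low=iso_low,
        isolation_high=iso_high,
        scan_min=scan_min,
        scan_max=scan_max,
    )


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr.astype(float))).decode()


def write_mzml(run: RunData, path: str) -> None:
    """Write a run as minimal centroided mzML 1.1.0 (no compression)."""
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>\n')
    parts.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        '<cvList count="2">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/'
        'bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>\n"
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
        "</fileContent></fileDescription>\n"
        f'<run id="{escape(run.run_id, {chr(34): "&quot;"})}">\n'
        f'<spectrumList count="{len(run.spectra)}">\n'
    )
    for idx, s in enumerate(run.spectra):
        parts.append(_spectrum_xml(idx, s))
    parts.append("</spectrumList>\n</run>\n</mzML>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))


def _spectrum_xml(index: int, s: Spectrum) -> str:
    mz64, int64 = _b64(s.mz), _b64(s.intensity)
    lines = [
        f'<spectrum index="{index}" id="{escape(s.scan_id)}" '
        f'defaultArrayLength="{s.mz.size}">',
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
    ]
    if s.ms_level == 1:
        lines.append('<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>')
    else:
        lines.append('<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>')
    scan_window = ""
    if s.scan_min is not None and s.scan_max is not None:
        scan_window = (
            '<scanWindowList count="1"><scanWindow>'
            f'<cvParam cvRef="MS" accession="MS:1000501" name="scan window lower limit" '
            f'value="{s.scan_min!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000500" name="scan window upper limit" '
            f'value="{s.scan_max!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            "</scanWindow></scanWindowList>"
        )
    lines.append(
        '<scanList count="1"><scan>'
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
        f'value="{s.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
        f"{scan_window}</scan></scanList>"
    )
    if s.ms_level == 2:
        target = 0.5 * (s.isolation_low + s.isolation_high)
        half = 0.5 * (s.isolation_high - s.isolation_low)
        lines.append(
            '<precursorList count="1"><precursor><isolationWindow>'
            f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" '
            f'value="{target!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" '
            f'value="{half!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" '
            f'value="{half!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            "</isolationWindow></precursor></precursorList>"
        )
    lines.append(
        '<binaryDataArrayList count="2">'
        f'<binaryDataArray encodedLength="{len(mz64)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
        'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
        f"<binary>{mz64}</binary></binaryDataArray>"
        f'<binaryDataArray encodedLength="{len(int64)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
        'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
        f"<binary>{int64}</binary></binaryDataArray>"
        "</binaryDataArrayList>"
    )
    lines.append("</spectrum>\n")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# detection reports
# ---------------------------------------------------------------------------


def parse_detection_report(
    path: str,
    q_max: float = 0.01,
    site_conf_min: float | None = None,
) -> list[PrecursorDetection]:
    """Parse a DIA-NN-dialect main report, filtered at precursor q-value.

    Rows with ``Q.Value`` above ``q_max`` are dropped. When ``site_conf_min``
    is given, rows whose ``PTM.Site.Confidence`` falls below it are dropped
    as well (rows without a recorded confidence are kept).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection report missing required column(s): {missing}")
    df = df[df["Q.Value"] <= q_max]
    has_conf = "PTM.Site.Confidence" in df.columns
    detections: list[PrecursorDetection] = []
    for row in df.itertuples(index=False):
        conf = getattr(row, "PTM_Site_Confidence", None)
        if has_conf:
            conf = row[df.columns.get_loc("PTM.Site.Confidence")]
            conf = None if pd.isna(conf) else float(conf)
        if site_conf_min is not None and conf is not None and conf < site_conf_min:
            continue
        detections.append(
            PrecursorDetection(
                peptidoform=parse_modified_sequence(
                    row[df.columns.get_loc("Modified.Sequence")]
                ),
                charge=int(row[df.columns.get_loc("Precursor.Charge")]),
                rt_apex=float(row[df.columns.get_loc("RT")]),
                rt_start=float(row[df.columns.get_loc("RT.Start")]),
                rt_stop=float(row[df.columns.get_loc("RT.Stop")]),
                q_value=float(row[df.columns.get_loc("Q.Value")]),
                run_id=str(row[df.columns.get_loc("File.Name")]),
                site_confidence=conf,
            )
        )
    return detections


def write_detection_report(rows: Iterable[dict], path: str) -> int:
    """Write a detection report in the dialect :func:`parse_detection_report` reads."""
    df = pd.DataFrame(list(rows))
    missing = [c for c in REQUIRED_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report rows missing required column(s): {missing}")
    df.to_csv(path, sep="\t", index=False)
    return len(df)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> list[ProteinRecord]:
    """Read protein records; sequences are uppercased and '*' stripped.

    Duplicate accessions keep the first occurrence (logged).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for header, seq in _pfasta.read(str(path)):
        accession = header.split()[0]
        if accession.count("|") == 2:  # uniprot-style sp|ACC|NAME headers
            accession = accession.split("|")[1]
        if accession in seen:
            logger.warning("duplicate accession %s: keeping first record", accession)
            continue
        seen.add(accession)
        clean = "".join(seq.split()).upper().rstrip("*")
        if not clean:
            logger.warning("empty sequence for %s: skipped", accession)
            continue
        records.append(ProteinRecord(accession=accession, sequence=clean))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# spectral library output
# ---------------------------------------------------------------------------


def library_to_frame(entries: Iterable["SpectralLibraryEntry"]) -> pd.DataFrame:
    """Flatten library entries to one row per (precursor, fragment)."""
    rows = []
    for e in entries:
        if not e.fragments:
            logger.warning(
                "library entry %s/%d+ has no fragments: skipped",
                e.peptidoform.proforma(),
                e.charge,
            )
            continue
        for ion, intensity in e.fragments:
            rows.append(
                {
                    "ModifiedPeptide": e.peptidoform.proforma(),
                    "PeptideSequence": e.peptidoform.sequence,
                    "PrecursorCharge": e.charge,
                    "PrecursorMz": round(e.precursor_mz, 6),
                    "Tr_recalibrated": round(e.rt, 6),
                    "ProteinId": ";".join(e.protein_ids),
                    "FragmentType": ion.series,
                    "FragmentCharge": ion.frag_charge,
                    "FragmentSeriesNumber": ion.index,
                    "FragmentLossType": ion.loss or "noloss",
                    "FragmentMz": round(ion.mz, 6),
                    "LibraryIntensity": round(intensity, 6),
                }
            )
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library_tsv(entries: Iterable["SpectralLibraryEntry"], path: str) -> int:
    """Write the library as tab-separated rows; returns the row count."""
    df = library_to_frame(entries)
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def write_library_parquet(entries: Iterable["SpectralLibraryEntry"], path: str) -> int:
    """Columnar mirror of :func:`write_library_tsv` (same schema)."""
    df = library_to_frame(entries)
    df.to_parquet(path, index=False)
    return len(df)


def read_library_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
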