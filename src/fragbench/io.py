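"""File surface: MGF spectra, PSM / precursor / prediction tables, reports.

All tables are UTF-8 TSV with a header row and '.' decimal separator.  The
PSM schema is a minimal five-column contract (raw_file, scan, sequence,
modifications, charge) that a MaxQuant msms.txt satisfies after column
renaming; common MaxQuant header spellings are accepted directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .chem import Peptide, enumerate_fragments, layout_keys, parse_peptide
from .errors import DataError, ParseError
from .similarity import LAYOUT_CHARGE1, LAYOUT_CHARGE12, IntensityVector

log = logging.getLogger(__name__)


@dataclass
class SpectrumRecord:
    """One MS/MS spectrum: source file, scan number, peaks sorted by m/z."""

    source_file: str
    scan: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise DataError("m/z and intensity arrays differ in length")
        if (self.intensity < 0).any():
            raise DataError(f"negative intensity in scan {self.scan}")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass(frozen=True)
class PsmRecord:
    """Links one scan to its identified precursor (peptide + charge)."""

    source_file: str
    scan: int
    peptide: Peptide
    charge: int


@dataclass(frozen=True)
class PrecursorRow:
    """Acquisition metadata for one precursor."""

    peptide: Peptide
    charge: int
    nce: float
    instrument: str
    dissociation: str
    mass_analyzer: str

    DISSOCIATIONS = ("HCD", "CID")
    MASS_ANALYZERS = ("FTMS", "ITMS")

    def __post_init__(self):
        if self.dissociation not in self.DISSOCIATIONS:
            raise DataError(f"unknown dissociation {self.dissociation!r}")
        if self.mass_analyzer not in self.MASS_ANALYZERS:
            raise DataError(f"unknown mass analyzer {self.mass_analyzer!r}")
        if not self.nce > 0:
            raise DataError(f"NCE must be positive, got {self.nce}")

    @property
    def key(self):
        return (self.nce, self.dissociation, self.instrument, self.mass_analyzer)


@dataclass
class PredictionTable:
    """Per-method predicted intensity vectors keyed by (proforma, charge)."""

    method_name: str
    entries: dict[tuple[str, int], IntensityVector] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MGF

def read_mgf(path: str | Path) -> Iterator[SpectrumRecord]:
    """Stream spectra from an MGF file.

    Scan numbers come from a ``SCANS=`` header or, failing that, a
    ``scan=<n>`` token inside ``TITLE``.  The source-file name is the first
    TITLE token when one is present (the converter convention
    ``TITLE=file.raw scan=123``), else the MGF file name.  Blocks without a
    scan number are logged and skipped; malformed peak lines abort with the
    line number.
    """
    path = Path(path)
    default_source = path.name
    source = default_source
    in_block = False
    scan: int | None = None
    mzs: list[float] = []
    ints: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block, scan, mzs, ints = True, None, [], []
                source = default_source
            elif line == "END IONS":
                if scan is None:
                    log.warning("%s: block ending at line %d has no scan number; skipped",
                                source, lineno)
                else:
                    if not mzs:
                        log.warning("%s scan %d: empty peak list", source, scan)
                    yield SpectrumRecord(source, scan, np.array(mzs), np.array(ints))
                in_block = False
            elif not in_block:
                continue
            elif "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "SCANS":
                    try:
                        scan = int(float(value))
                    except ValueError as exc:
                        raise ParseError(f"bad SCANS value {value!r}", str(path), lineno) from exc
                elif key == "TITLE":
                    tokens = value.replace('"', " ").split()
                    if tokens and "=" not in tokens[0]:
                        source = tokens[0]
                    if scan is None:
                        for token in tokens:
                            if token.lower().startswith("scan="):
                                try:
                                    scan = int(token.split("=", 1)[1].rstrip(",;"))
                                except ValueError:
                                    pass
            else:
                parts = line.split()
                try:
                    mzs.append(float(parts[0]))
                    ints.append(float(parts[1]))
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"malformed peak line {line!r}", str(path), lineno) from exc


def write_mgf(records: Iterable[SpectrumRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={rec.source_file} scan={rec.scan}\n")
            fh.write(f"SCANS={rec.scan}\n")
            for mz, inten in zip(rec.mz, rec.intensity):
                fh.write(f"{mz:.6f} {inten:.9g}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# PSM table

_PSM_ALIASES = {
    "raw file": "raw_file",
    "raw_file": "raw_file",
    "scan number": "scan",
    "scan": "scan",
    "sequence": "sequence",
    "modifications": "modifications",
    "charge": "charge",
}
PSM_COLUMNS = ("raw_file", "scan", "sequence", "modifications", "charge")

# Search-engine modification spellings mapped to internal names.
_MOD_NAMES = {
    "oxidation": "Oxidation",
    "oxidation (m)": "Oxidation",
    "carbamidomethyl": "Carbamidomethyl",
    "carbamidomethyl (c)": "Carbamidomethyl",
}


def _parse_mod_column(text: str) -> list[tuple[int, str]]:
    """Parse ``"5:Oxidation (M);12:Carbamidomethyl (C)"`` style annotations."""
    text = (text or "").strip()
    if not text or text.lower() == "unmodified":
        return []
    mods = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        pos_str, _, name = token.partition(":")
        name = name.strip()
        try:
            pos = int(pos_str)
        except ValueError as exc:
            raise DataError(f"cannot parse modification token {token!r}") from exc
        canonical = _MOD_NAMES.get(name.lower())
        if canonical is None:
            raise DataError(f"unsupported PTM: {name!r}")
        mods.append((pos, canonical))
    return mods


def read_psm_table(
    path: str | Path, fixed_carbamidomethyl: bool = True
) -> tuple[list[PsmRecord], list[dict]]:
    """Read PSMs; returns (records, excluded-rows-with-reasons).

    Rows carrying unsupported modifications or nonstandard residues (U/O)
    go to the excluded list with a reason instead of being dropped silently.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [_PSM_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"PSM table {path} missing required column(s): {', '.join(missing)}")
    records: list[PsmRecord] = []
    excluded: list[dict] = []
    for idx, row in df.iterrows():
        seq = row["sequence"].strip()
        entry = {"row": int(idx) + 2, "sequence": seq, "scan": row["scan"]}
        if "U" in seq or "O" in seq:
            excluded.append({**entry, "reason": "nonstandard residue"})
            continue
        try:
            mods = _parse_mod_column(row["modifications"])
            peptide = parse_peptide(seq, fixed_carbamidomethyl=False)
            explicit = {p for p, _ in mods}
            if fixed_carbamidomethyl:
                for p, aa in enumerate(peptide.sequence, start=1):
                    if aa == "C" and p not in explicit:
                        mods.append((p, "Carbamidomethyl"))
            peptide = Peptide(peptide.sequence, tuple(mods))
            records.append(
                PsmRecord(row["raw_file"].strip(), int(row["scan"]), peptide, int(row["charge"]))
            )
        except DataError as exc:
            reason = "unsupported PTM" if "PTM" in str(exc) else str(exc)
            excluded.append({**entry, "reason": reason})
    return records, excluded


# ---------------------------------------------------------------------------
# Precursor table

PRECURSOR_COLUMNS = ("sequence", "charge", "nce", "instrument", "dissociation", "mass_analyzer")


def read_precursor_table(path: str | Path) -> dict[tuple[str, int], PrecursorRow]:
    """One precursor per line with sequence/charge/NCE/instrument/DT/MAT."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in PRECURSOR_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"precursor table {path} missing column(s): {', '.join(missing)}")
    out: dict[tuple[str, int], PrecursorRow] = {}
    for _, row in df.iterrows():
        peptide = parse_peptide(row["sequence"].strip())
        pr = PrecursorRow(
            peptide=peptide,
            charge=int(row["charge"]),
            nce=float(row["nce"]),
            instrument=row["instrument"].strip(),
            dissociation=row["dissociation"].strip(),
            mass_analyzer=row["mass_analyzer"].strip(),
        )
        out[(peptide.proforma(), pr.charge)] = pr
    return out


def write_precursor_table(rows: Iterable[PrecursorRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PRECURSOR_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.peptide.proforma()}\t{r.charge}\t{r.nce}\t{r.instrument}"
                f"\t{r.dissociation}\t{r.mass_analyzer}\n"
            )


# ---------------------------------------------------------------------------
# Prediction tables

PREDICTION_COLUMNS = ("sequence", "charge", "series", "ordinal", "fragment_charge", "intensity")


def read_predictions(
    path: str | Path, method_name: str, charges: tuple[int, ...] = (1, 2)
) -> PredictionTable:
    """Assemble a long-format prediction table into canonical-layout vectors.

    Fragment rows absent from the table are zero-filled; duplicate
    (precursor, fragment) rows, negative intensities and out-of-range
    ordinals are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"prediction table {path} missing column(s): {', '.join(missing)}")
    layout = LAYOUT_CHARGE1 if charges == (1,) else LAYOUT_CHARGE12
    table = PredictionTable(method_name)
    vectors: dict[tuple[str, int], np.ndarray] = {}
    peptides: dict[str, Peptide] = {}
    index_cache: dict[int, dict] = {}
    seen: set[tuple[str, int, str, int, int]] = set()
    for _, row in df.iterrows():
        seq = row["sequence"].strip()
        charge = int(row["charge"])
        series = row["series"].strip().lower()
        ordinal = int(row["ordinal"])
        fz = int(row["fragment_charge"])
        intensity = float(row["intensity"])
        if intensity < 0:
            raise DataError(f"negative intensity for {seq}/{charge} {series}{ordinal}^{fz}")
        if fz not in charges:
            raise DataError(f"fragment charge {fz} outside configured coverage {charges}")
        if seq not in peptides:
            peptides[seq] = parse_peptide(seq)
        pep = peptides[seq]
        n = len(pep)
        if not 1 <= ordinal < n:
            raise DataError(
                f"fragment ordinal {ordinal} out of range for {seq} (length {n})"
            )
        dup_key = (seq, charge, series, ordinal, fz)
        if dup_key in seen:
            raise DataError(f"duplicate prediction row for {seq}/{charge} {series}{ordinal}^{fz}")
        seen.add(dup_key)
        if n not in index_cache:
            index_cache[n] = {k: i for i, k in enumerate(layout_keys(n, charges))}
        slot = index_cache[n].get((series, ordinal, fz))
        if slot is None:
            raise DataError(f"unknown fragment {series}{ordinal}^{fz} for {seq}")
        key = (pep.proforma(), charge)
        if key not in vectors:
            vectors[key] = np.zeros(len(charges) * 2 * (n - 1))
        vectors[key][slot] = intensity
    for key, vec in vectors.items():
        table.entries[key] = IntensityVector(vec, layout)
    return table


def write_predictions(table: PredictionTable, path: str | Path,
                      charges: tuple[int, ...] = (1, 2)) -> None:
    """Serialize a prediction table to long-format TSV (zero rows omitted)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for (proforma, charge), vec in table.entries.items():
            pep = parse_peptide(proforma, fixed_carbamidomethyl=False)
            keys = layout_keys(len(pep), charges)
            for key, value in zip(keys, vec.values):
                if value > 0:
                    fh.write(
                        f"{proforma}\t{charge}\t{key.series}\t{key.ordinal}"
                        f"\t{key.charge}\t{value:.10g}\n"
                    )


def match_predictions_by_mz(
    pred_peaks: Iterable[tuple[float, float]],
    peptide: Peptide,
    tol_ppm: float = 20.0,
    charges: tuple[int, ...] = (1, 2),
) -> IntensityVector:
    """Assign m/z-labelled predicted intensities to theoretical b/y slots.

    Each predicted peak goes to the nearest theoretical fragment within
    ``tol_ppm``; peaks matching nothing are dropped with a log message, and
    a peak within tolerance of several fragments is assigned to the nearest
    with a warning.
    """
    frags = enumerate_fragments(peptide, charges)
    theo = np.array([mz for _, mz in frags])
    vec = np.zeros(len(frags))
    for mz, intensity in pred_peaks:
        rel = np.abs(theo - mz) / theo * 1e6
        within = np.nonzero(rel <= tol_ppm)[0]
        if len(within) == 0:
            log.info("predicted peak %.5f outside %g ppm of every theoretical fragment; dropped",
                     mz, tol_ppm)
            continue
        if len(within) > 1:
            log.warning("predicted peak %.5f within tolerance of %d theoretical fragments; "
                        "assigned to nearest", mz, len(within))
        vec[within[np.argmin(rel[within])]] = intensity
    layout = LAYOUT_CHARGE1 if charges == (1,) else LAYOUT_CHARGE12
    return IntensityVector(vec, layout)


# ---------------------------------------------------------------------------
# Annotated PSM store (intermediate output of `fragbench annotate`)

STORE_COLUMNS = ("raw_file", "scan", "sequence", "charge", "nce", "instrument",
                 "dissociation", "mass_analyzer", "layout", "intensities")


def write_annotated_store(annotated, path: str | Path) -> None:
    """Persist annotated PSMs as TSV; intensity vectors are ';'-joined."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(STORE_COLUMNS) + "\n")
        for a in annotated:
            vec = ";".join(f"{v:.8g}" for v in a.experimental.values)
            m = a.precursor_meta
            fh.write(f"{a.psm.source_file}\t{a.psm.scan}\t{a.psm.peptide.proforma()}"
                     f"\t{a.psm.charge}\t{m.nce}\t{m.instrument}\t{m.dissociation}"
                     f"\t{m.mass_analyzer}\t{a.experimental.layout}\t{vec}\n")


def read_annotated_store(path: str | Path):
    """Inverse of :func:`write_annotated_store`."""
    from .annotate import AnnotatedPsm  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in STORE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"annotated store {path} missing column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        peptide = parse_peptide(row["sequence"], fixed_carbamidomethyl=False)
        vec = np.array([float(x) for x in row["intensities"].split(";")])
        meta = PrecursorRow(peptide, int(row["charge"]), float(row["nce"]),
                            row["instrument"], row["dissociation"], row["mass_analyzer"])
        psm = PsmRecord(row["raw_file"], int(row["scan"]), peptide, int(row["charge"]))
        out.append(AnnotatedPsm(psm, meta, IntensityVector(vec, row["layout"])))
    return out


# ---------------------------------------------------------------------------
# Reports

REPORT_COLUMNS = ("method", "stratum", "n_precursors", "q10", "q25", "median",
                  "q75", "q90", "W1_to_experimental", "rank")


def write_report_tsv(rows: Iterable[dict], path: str | Path) -> None:
    """Quantile-report table; similarity statistics printed to 3 decimals."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            cells = []
            for col in REPORT_COLUMNS:
                val = row.get(col, "")
                if isinstance(val, float):
                    cells.append(f"{val:.3f}")
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")


def write_json_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
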