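"""Spectrum annotation, exclusion rules, dataset partitioning.

Turns (spectrum, PSM, precursor metadata) triples into canonical-layout
experimental intensity vectors, applies the all-zero / length / charge
exclusion rules, partitions annotated PSMs into datasets sharing
(NCE, dissociation, instrument, mass analyzer), and builds nonredundant
precursor sets with PSM multiplicities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .chem import Peptide, theoretical_mz_array
from .errors import ConfigError, DataError
from .io import PrecursorRow, PsmRecord, SpectrumRecord
from .similarity import (
    LAYOUT_CHARGE1,
    LAYOUT_CHARGE12,
    IntensityVector,
    restrict_charge1,
)

log = logging.getLogger(__name__)

MODE_CHARGE1 = "charge1_only"
MODE_CHARGE12 = "charge1_and_2"


@dataclass(frozen=True)
class ToleranceSpec:
    """Peak-matching tolerance: ppm (high-resolution) or dalton (ion trap)."""

    mode: str
    value: float

    def __post_init__(self):
        if self.mode not in ("ppm", "dalton"):
            raise ConfigError(f"tolerance mode must be 'ppm' or 'dalton', got {self.mode!r}")
        if not self.value > 0:
            raise ConfigError(f"tolerance value must be positive, got {self.value}")

    @classmethod
    def for_analyzer(cls, mass_analyzer: str, ftms_ppm: float = 20.0,
                     itms_da: float = 0.5) -> "ToleranceSpec":
        if mass_analyzer == "FTMS":
            return cls("ppm", ftms_ppm)
        if mass_analyzer == "ITMS":
            return cls("dalton", itms_da)
        raise ConfigError(f"no default tolerance for mass analyzer {mass_analyzer!r}")

    def window(self, theo_mz: np.ndarray) -> np.ndarray:
        """Absolute Th window around each theoretical m/z."""
        if self.mode == "ppm":
            return theo_mz * self.value * 1e-6
        return np.full_like(theo_mz, self.value)


@dataclass
class AnnotatedPsm:
    """A PSM with its acquisition metadata and experimental intensity vector."""

    psm: PsmRecord
    precursor_meta: PrecursorRow
    experimental: IntensityVector

    @property
    def precursor_id(self) -> tuple[str, int]:
        pid = self.__dict__.get("_pid")
        if pid is None:
            pid = (self.psm.peptide.proforma(), self.psm.charge)
            self.__dict__["_pid"] = pid
        return pid


@dataclass
class Dataset:
    """All annotated PSMs sharing one (NCE, DT, INS, MAT) key."""

    key: tuple
    psms: list[AnnotatedPsm] = field(default_factory=list)
    flagged: bool = False


@dataclass
class PrecursorSet:
    """Distinct precursors of a dataset with their PSM multiplicities."""

    members: set[tuple[str, int]]
    multiplicity: dict[tuple[str, int], int]


@lru_cache(maxsize=65536)
def _theoretical_mz_cached(peptide: Peptide, charges: tuple[int, ...]) -> np.ndarray:
    # Peptide is frozen/hashable; the cached array must never be mutated.
    return theoretical_mz_array(peptide, charges)


def match_peaks(
    spectrum: SpectrumRecord,
    peptide: Peptide,
    charges: tuple[int, ...] = (1, 2),
    tol: ToleranceSpec = ToleranceSpec("ppm", 20.0),
) -> IntensityVector:
    """Experimental intensity vector over the canonical fragment layout.

    Each theoretical fragment independently takes the intensity of the
    nearest experimental peak within tolerance (tie at equal m/z distance:
    higher intensity wins); slots with no matching peak are zero.  An
    experimental peak may serve more than one theoretical fragment.
    """
    charges = tuple(sorted(charges))
    theo = _theoretical_mz_cached(peptide, charges)
    layout = LAYOUT_CHARGE1 if charges == (1,) else LAYOUT_CHARGE12
    vec = np.zeros(len(theo))
    mz, inten = spectrum.mz, spectrum.intensity
    if len(mz) == 0:
        return IntensityVector(vec, layout)
    windows = tol.window(theo)
    # Peaks are sorted; locate each theoretical m/z and inspect neighbours.
    pos = np.searchsorted(mz, theo)
    for k, (t, w) in enumerate(zip(theo, windows)):
        best_d, best_i = None, -1
        for j in (pos[k] - 1, pos[k]):
            if 0 <= j < len(mz):
                d = abs(mz[j] - t)
                if d <= w and (best_d is None or d < best_d
                               or (d == best_d and inten[j] > inten[best_i])):
                    best_d, best_i = d, j
        # Wide dalton windows can span several peaks around the insertion
        # point; scan outward until the window is exceeded.
        j = pos[k] - 2
        while j >= 0 and t - mz[j] <= w:
            d = t - mz[j]
            if best_d is None or d < best_d or (d == best_d and inten[j] > inten[best_i]):
                best_d, best_i = d, j
            j -= 1
        j = pos[k] + 1
        while j < len(mz) and mz[j] - t <= w:
            d = mz[j] - t
            if best_d is None or d < best_d or (d == best_d and inten[j] > inten[best_i]):
                best_d, best_i = d, j
            j += 1
        if best_i >= 0:
            vec[k] = inten[best_i]
    return IntensityVector(vec, layout)


def annotate_psms(
    spectra: dict[tuple[str, int], SpectrumRecord],
    psms: list[PsmRecord],
    precursors: dict[tuple[str, int], PrecursorRow],
    charges: tuple[int, ...] = (1, 2),
    ftms_ppm: float = 20.0,
    itms_da: float = 0.5,
) -> tuple[list[AnnotatedPsm], list[dict]]:
    """Join PSMs to spectra and precursor metadata; annotate each one.

    Returns (annotated, exclusions); a PSM is excluded when its scan is
    missing from the spectra index or its precursor has no metadata row.
    """
    annotated: list[AnnotatedPsm] = []
    exclusions: list[dict] = []
    for psm in psms:
        spectrum = spectra.get((psm.source_file, psm.scan))
        if spectrum is None:
            exclusions.append({"source_file": psm.source_file, "scan": psm.scan,
                               "reason": "scan not found in spectra"})
            continue
        meta = precursors.get((psm.peptide.proforma(), psm.charge))
        if meta is None:
            exclusions.append({"source_file": psm.source_file, "scan": psm.scan,
                               "reason": "precursor not in precursor table"})
            continue
        tol = ToleranceSpec.for_analyzer(meta.mass_analyzer, ftms_ppm, itms_da)
        vec = match_peaks(spectrum, psm.peptide, charges, tol)
        annotated.append(AnnotatedPsm(psm, meta, vec))
    if exclusions:
        log.info("annotation: %d PSM(s) excluded at join stage", len(exclusions))
    return annotated, exclusions


def filter_psms(
    annotated: list[AnnotatedPsm],
    mode: str = MODE_CHARGE12,
    comparability: bool = True,
    max_length: int = 30,
    max_charge: int = 6,
) -> tuple[list[AnnotatedPsm], list[tuple[AnnotatedPsm, str]]]:
    """Apply the all-zero and comparability exclusion rules.

    A PSM is excluded when (a) all configured intensities are zero, (b) in
    charge1_only mode all singly-charged intensities are zero, or (c) the
    comparability filter is on and the peptide is longer than ``max_length``
    or the precursor charge exceeds ``max_charge``.
    """
    if mode not in (MODE_CHARGE1, MODE_CHARGE12):
        raise ConfigError(f"unknown charge-coverage mode {mode!r}")
    kept: list[AnnotatedPsm] = []
    excluded: list[tuple[AnnotatedPsm, str]] = []
    for a in annotated:
        if comparability and len(a.psm.peptide) > max_length:
            excluded.append((a, f"peptide length > {max_length}"))
            continue
        if comparability and a.psm.charge > max_charge:
            excluded.append((a, f"precursor charge > {max_charge}"))
            continue
        if mode == MODE_CHARGE1 and a.experimental.layout == LAYOUT_CHARGE12:
            effective = restrict_charge1(a.experimental)
        else:
            effective = a.experimental
        if effective.is_zero():
            reason = ("all singly-charged intensities zero"
                      if mode == MODE_CHARGE1 else "all intensities zero")
            excluded.append((a, reason))
            continue
        kept.append(a)
    log.info("filter: kept %d, excluded %d of %d PSMs",
             len(kept), len(excluded), len(annotated))
    return kept, excluded


def partition_datasets(
    annotated: list[AnnotatedPsm], min_precursors: int | None = None
) -> list[Dataset]:
    """Group annotated PSMs by (NCE, DT, INS, MAT).

    Datasets whose nonredundant precursor count falls below
    ``min_precursors`` are flagged (not removed) for the caller to exclude.
    """
    by_key: dict[tuple, Dataset] = {}
    for a in annotated:
        ds = by_key.setdefault(a.precursor_meta.key, Dataset(a.precursor_meta.key))
        ds.psms.append(a)
    datasets = [by_key[k] for k in sorted(by_key)]
    if min_precursors is not None:
        for ds in datasets:
            n = len({a.precursor_id for a in ds.psms})
            if n < min_precursors:
                ds.flagged = True
                log.warning("dataset %s has only %d precursors (< %d); flagged",
                            ds.key, n, min_precursors)
    return datasets


def nonredundant_precursors(ds: Dataset) -> PrecursorSet:
    """Distinct (peptide, charge) members of a dataset with PSM counts."""
    multiplicity: dict[tuple[str, int], int] = {}
    for a in ds.psms:
        multiplicity[a.precursor_id] = multiplicity.get(a.precursor_id, 0) + 1
    return PrecursorSet(set(multiplicity), multiplicity)
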