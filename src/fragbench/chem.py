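"""Monoisotopic mass arithmetic and theoretical m/z enumeration for b/y ions.

Covers singly- and doubly-charged b and y fragments of peptides that carry
at most two modification types (methionine oxidation, cysteine
carbamidomethylation).  The canonical fragment layout defined by
:func:`enumerate_fragments` is fixed library-wide: every intensity vector in
the package is ordered b1..b(N-1), y1..y(N-1) at charge 1, then the same
blocks at charge 2 when doubly-charged coverage is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, NamedTuple

import numpy as np

from .errors import DataError

# Standard monoisotopic residue masses (Da), 20 canonical amino acids.
RESIDUE_MASSES = MappingProxyType({
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202841,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767847,
    "C": 103.00918448,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048509,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
})

PROTON = 1.00727646688
WATER = 18.01056468403

MOD_DELTAS = MappingProxyType({
    "Oxidation": 15.99491462,
    "Carbamidomethyl": 57.02146372,
})

# Residue each modification is allowed on.
MOD_TARGETS = MappingProxyType({"Oxidation": "M", "Carbamidomethyl": "C"})

VALID_SERIES = ("b", "y")


class FragmentKey(NamedTuple):
    """Identity of one fragment ion: series ('b'|'y'), ordinal, charge."""

    series: str
    ordinal: int
    charge: int


@dataclass(frozen=True)
class Peptide:
    """A modified peptide: uppercase canonical sequence plus positional mods.

    ``mods`` is a tuple of ``(position, mod_name)`` with 1-based positions.
    Instances validate on construction; invalid peptides raise
    :class:`~fragbench.errors.DataError`.
    """

    sequence: str
    mods: tuple[tuple[int, str], ...] = field(default=())

    def __post_init__(self):
        seq = self.sequence
        if len(seq) < 2:
            raise DataError(f"peptide length must be >= 2, got {len(seq)} ({seq!r})")
        for i, aa in enumerate(seq, start=1):
            if aa not in RESIDUE_MASSES:
                raise DataError(
                    f"unknown residue {aa!r} at position {i} in {seq!r}"
                )
        object.__setattr__(self, "mods", tuple(sorted(self.mods)))
        seen = set()
        for pos, name in self.mods:
            if name not in MOD_DELTAS:
                raise DataError(f"unsupported modification {name!r}")
            if not 1 <= pos <= len(seq):
                raise DataError(
                    f"modification position {pos} outside peptide of length {len(seq)}"
                )
            if seq[pos - 1] != MOD_TARGETS[name]:
                raise DataError(
                    f"{name} not allowed on residue {seq[pos - 1]!r} at position {pos}"
                )
            if pos in seen:
                raise DataError(f"residue at position {pos} carries two modifications")
            seen.add(pos)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_modified(self) -> bool:
        """True when any variable modification (oxidation) is present."""
        return any(name == "Oxidation" for _, name in self.mods)

    def proforma(self) -> str:
        """Serialize to the inline-tag notation, e.g. ``AM[Oxidation]K``."""
        mod_at = dict(self.mods)
        out = []
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            if i in mod_at:
                out.append(f"[{mod_at[i]}]")
        return "".join(out)


def parse_peptide(text: str, fixed_carbamidomethyl: bool = True) -> Peptide:
    """Parse inline-tag notation (``AM[Oxidation]K``) into a :class:`Peptide`.

    With ``fixed_carbamidomethyl`` every cysteine without an explicit tag
    receives Carbamidomethyl, mirroring the usual fixed-modification search
    setting.
    """
    seq: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise DataError(f"unterminated modification tag in {text!r}")
            if not seq:
                raise DataError(f"modification tag before any residue in {text!r}")
            mods.append((len(seq), text[i + 1:end]))
            i = end + 1
        else:
            seq.append(ch)
            i += 1
    sequence = "".join(seq)
    if fixed_carbamidomethyl:
        tagged = {pos for pos, _ in mods}
        for p, aa in enumerate(sequence, start=1):
            if aa == "C" and p not in tagged:
                mods.append((p, "Carbamidomethyl"))
    return Peptide(sequence, tuple(mods))


def _residue_mass_array(peptide: Peptide) -> np.ndarray:
    masses = np.array([RESIDUE_MASSES[aa] for aa in peptide.sequence])
    for pos, name in peptide.mods:
        masses[pos - 1] += MOD_DELTAS[name]
    return masses


def peptide_mono_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas."""
    return float(_residue_mass_array(peptide).sum() + WATER)


def fragment_neutral_mass(peptide: Peptide, key: FragmentKey) -> float:
    """Neutral fragment mass; b = prefix residue sum, y = suffix sum + water."""
    n = len(peptide)
    if not 1 <= key.ordinal < n:
        raise DataError(
            f"fragment ordinal {key.ordinal} invalid for peptide of length {n}"
        )
    if key.series not in VALID_SERIES:
        raise DataError(f"unknown ion series {key.series!r}")
    masses = _residue_mass_array(peptide)
    if key.series == "b":
        return float(masses[: key.ordinal].sum())
    return float(masses[n - key.ordinal:].sum() + WATER)


def fragment_mz(peptide: Peptide, key: FragmentKey) -> float:
    """Theoretical m/z of one fragment: (neutral + z * proton) / z."""
    if key.charge < 1:
        raise DataError(f"fragment charge must be >= 1, got {key.charge}")
    neutral = fragment_neutral_mass(peptide, key)
    return (neutral + key.charge * PROTON) / key.charge


def layout_keys(n: int, charges: Iterable[int] = (1, 2)) -> list[FragmentKey]:
    """Canonical fragment ordering for a peptide of length ``n``.

    b1..b(n-1) then y1..y(n-1), for each requested charge in ascending
    order.  Length is ``|charges| * 2 * (n - 1)``.
    """
    charges = sorted(set(charges))
    if any(z not in (1, 2) for z in charges):
        raise DataError(f"fragment charges restricted to {{1, 2}}, got {charges}")
    keys = []
    for z in charges:
        for series in VALID_SERIES:
            for ordinal in range(1, n):
                keys.append(FragmentKey(series, ordinal, z))
    return keys


def enumerate_fragments(
    peptide: Peptide, charges: Iterable[int] = (1, 2)
) -> list[tuple[FragmentKey, float]]:
    """All b/y fragments in canonical order with their theoretical m/z."""
    masses = _residue_mass_array(peptide)
    n = len(peptide)
    prefix = np.cumsum(masses)
    suffix = np.cumsum(masses[::-1])
    out = []
    for key in layout_keys(n, charges):
        neutral = prefix[key.ordinal - 1] if key.series == "b" else suffix[key.ordinal - 1] + WATER
        out.append((key, float((neutral + key.charge * PROTON) / key.charge)))
    return out


def theoretical_mz_array(peptide: Peptide, charges: Iterable[int] = (1, 2)) -> np.ndarray:
    """Theoretical m/z values in canonical layout order, as a vector."""
    return np.array([mz for _, mz in enumerate_fragments(peptide, charges)])
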