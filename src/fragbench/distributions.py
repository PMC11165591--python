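"""Binned, precursor-weighted similarity distributions and method ranking.

Scores are accumulated into fixed-width (0.001) histograms where each PSM
contributes weight 1/(PSM count of its precursor), so every precursor has
equal impact; distributions from different datasets are combined by adding
bins.  Summaries are weighted quantiles (bin-center convention) and the
W1 distance between unit-normalized binned distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

BIN_WIDTH = 0.001

#: Default peptide-length interval edges for stratified reports: intervals
#: are [7,10], [11,14], ..., [27,30].  Boundaries are configurable and are
#: declared in every report that uses them.
DEFAULT_LENGTH_BINS = (7, 11, 15, 19, 23, 27, 31)

QUANTILE_PROBS = (0.1, 0.25, 0.5, 0.75, 0.9)


@dataclass
class SimilarityDistribution:
    """Weighted histogram over [lo, hi] with fixed bin width.

    Bins are half-open [k*w, (k+1)*w) with the top edge closed, so a score
    equal to ``hi`` lands in the final bin.
    """

    lo: float
    hi: float
    bin_width: float = BIN_WIDTH
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = (self.hi - self.lo) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"range [{self.lo}, {self.hi}] not divisible by bin width {self.bin_width}"
            )
        self.n_bins = int(round(n))
        if self.weights is None:
            self.weights = np.zeros(self.n_bins)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != self.n_bins:
                raise ConfigError("weights length does not match bin count")
            if (self.weights < 0).any():
                raise DataError("negative bin weight")

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())

    @property
    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_index(self, score: float) -> int:
        if not self.lo <= score <= self.hi:
            raise DataError(f"score {score} outside range [{self.lo}, {self.hi}]")
        return min(int((score - self.lo) / self.bin_width), self.n_bins - 1)

    def add(self, score: float, weight: float = 1.0) -> None:
        self.weights[self.bin_index(score)] += weight

    def same_binning(self, other: "SimilarityDistribution") -> bool:
        return (self.lo == other.lo and self.hi == other.hi
                and self.bin_width == other.bin_width)

    def copy(self) -> "SimilarityDistribution":
        return SimilarityDistribution(self.lo, self.hi, self.bin_width, self.weights.copy())


@dataclass(frozen=True)
class QuantileSummary:
    q10: float
    q25: float
    median: float
    q75: float
    q90: float

    def __post_init__(self):
        vals = (self.q10, self.q25, self.median, self.q75, self.q90)
        if any(a > b + 1e-12 for a, b in zip(vals, vals[1:])):
            raise DataError(f"quantiles not monotone: {vals}")


@dataclass
class MethodReport:
    method_name: str
    summary: QuantileSummary
    w1_to_experimental: float | None
    rank: int
    n_precursors: float


def build_distribution(
    scores: Sequence[tuple[float, tuple]],
    multiplicity: Mapping[tuple, int],
    lo: float = 0.0,
    hi: float = 1.0,
    bin_width: float = BIN_WIDTH,
    literal_weighting: bool = False,
) -> SimilarityDistribution:
    """Accumulate (score, precursor_id) pairs into a weighted histogram.

    Default weighting gives each PSM weight 1/multiplicity(precursor) so a
    precursor's total impact is 1 regardless of how many spectra matched it;
    total mass then equals the number of distinct contributing precursors.
    ``literal_weighting`` instead multiplies each PSM by its precursor's
    PSM count (the literal reading of "weighted by the number of PSMs").
    """
    dist = SimilarityDistribution(lo, hi, bin_width)
    if len(scores) == 0:
        return dist
    vals = np.array([s for s, _ in scores], dtype=float)
    if vals.min() < lo or vals.max() > hi:
        bad = vals[(vals < lo) | (vals > hi)][0]
        raise DataError(f"score {bad} outside range [{lo}, {hi}] — upstream metric bug?")
    mults = np.empty(len(scores))
    for i, (_, pid) in enumerate(scores):
        m = multiplicity.get(pid)
        if m is None or m < 1:
            raise DataError(f"precursor {pid} missing valid multiplicity")
        mults[i] = m
    w = mults if literal_weighting else 1.0 / mults
    idx = np.minimum(((vals - lo) / bin_width).astype(int), dist.n_bins - 1)
    np.add.at(dist.weights, idx, w)
    return dist


def combine(distributions: Iterable[SimilarityDistribution]) -> SimilarityDistribution:
    """Add corresponding bins; total mass is additive."""
    distributions = list(distributions)
    if not distributions:
        raise DataError("cannot combine zero distributions")
    out = distributions[0].copy()
    for d in distributions[1:]:
        if not out.same_binning(d):
            raise DataError("cannot combine distributions with different binning")
        out.weights += d.weights
    return out


def quantiles(
    dist: SimilarityDistribution, probs: Sequence[float] = QUANTILE_PROBS
) -> QuantileSummary:
    """Weighted quantiles: center of the bin where the CDF crosses each prob."""
    total = dist.total_mass
    if total <= 0:
        raise DataError("quantiles undefined for an empty distribution")
    cdf = np.cumsum(dist.weights) / total
    centers = dist.centers
    values = []
    for p in probs:
        k = int(np.searchsorted(cdf, p, side="left"))
        values.append(float(centers[min(k, dist.n_bins - 1)]))
    named = dict(zip(sorted(probs), sorted(values)))
    return QuantileSummary(q10=named[0.1], q25=named[0.25], median=named[0.5],
                           q75=named[0.75], q90=named[0.9])


def wasserstein(d1: SimilarityDistribution, d2: SimilarityDistribution) -> float:
    """W1 distance between the unit-normalized binned distributions."""
    if not d1.same_binning(d2):
        raise DataError("W1 requires identical binning")
    if d1.total_mass <= 0 or d2.total_mass <= 0:
        raise DataError("W1 undefined for an empty distribution")
    cdf1 = np.cumsum(d1.weights) / d1.total_mass
    cdf2 = np.cumsum(d2.weights) / d2.total_mass
    return float(d1.bin_width * np.abs(cdf1 - cdf2).sum())


def rank_methods(
    per_method: Mapping[str, tuple[SimilarityDistribution, SimilarityDistribution | None]],
    n_precursors: Mapping[str, float] | None = None,
) -> list[MethodReport]:
    """Rank methods by median, descending; ties broken by q75, then name.

    Each entry maps a method name to (predicted distribution, shared
    experimental distribution or None).  W1 is reported against the
    experimental distribution when available.
    """
    if not per_method:
        raise DataError("rank_methods needs at least one method")
    reports = []
    for name, (pred, exp) in per_method.items():
        summary = quantiles(pred)
        w1 = wasserstein(pred, exp) if exp is not None and exp.total_mass > 0 else None
        n = (n_precursors or {}).get(name, pred.total_mass)
        reports.append(MethodReport(name, summary, w1, rank=0, n_precursors=n))
    reports.sort(key=lambda r: (-r.summary.median, -r.summary.q75, r.method_name))
    for i, r in enumerate(reports, start=1):
        r.rank = i
    for a, b in zip(reports, reports[1:]):
        if a.summary.median == b.summary.median:
            log.info("median tie between %s and %s broken by q75, then name",
                     a.method_name, b.method_name)
    return reports


@dataclass(frozen=True)
class ScoredPsm:
    """One scored PSM with the attributes stratified reports are built on."""

    score: float
    precursor_id: tuple
    charge: int
    length: int
    nce: float
    modified: bool


STRATIFIERS = ("charge", "length_bins", "nce", "ptm_status")


def _stratum_key(rec: ScoredPsm, by: str, length_bins: Sequence[int]):
    if by == "charge":
        return f"z={rec.charge}"
    if by == "nce":
        return f"nce={rec.nce:g}"
    if by == "ptm_status":
        return "modified" if rec.modified else "unmodified"
    if by == "length_bins":
        edges = list(length_bins)
        for a, b in zip(edges, edges[1:]):
            if a <= rec.length < b:
                return f"len={a}-{b - 1}"
        return f"len>={edges[-1]}" if rec.length >= edges[-1] else f"len<{edges[0]}"
    raise ConfigError(f"unknown stratifier {by!r}")


def stratify(
    scored: Sequence[ScoredPsm],
    by: str,
    lo: float = 0.0,
    hi: float = 1.0,
    length_bins: Sequence[int] = DEFAULT_LENGTH_BINS,
    literal_weighting: bool = False,
) -> dict[str, SimilarityDistribution]:
    """Split scored PSMs into disjoint strata and build one distribution each.

    Precursor multiplicities are recomputed within each stratum so the
    equal-precursor-impact weighting holds stratum-locally.
    """
    groups: dict[str, list[ScoredPsm]] = {}
    for rec in scored:
        groups.setdefault(_stratum_key(rec, by, length_bins), []).append(rec)
    out = {}
    for key in sorted(groups):
        recs = groups[key]
        mult: dict[tuple, int] = {}
        for r in recs:
            mult[r.precursor_id] = mult.get(r.precursor_id, 0) + 1
        out[key] = build_distribution(
            [(r.score, r.precursor_id) for r in recs], mult, lo, hi,
            literal_weighting=literal_weighting,
        )
    return out
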