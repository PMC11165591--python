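"""End-to-end evaluation: annotated PSMs + prediction tables -> method reports.

For each dataset the predicted similarity distribution compares every
method's vector against each experimental PSM vector; the experimental
reproducibility distribution compares reference profiles (mean of
L2-normalized replicates) against the replicates of every multi-PSM
precursor.  Dataset distributions are combined by bin addition, then
summarized (quantiles, W1 to the experimental distribution) and ranked by
median, descending.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .annotate import (
    MODE_CHARGE1,
    MODE_CHARGE12,
    AnnotatedPsm,
    partition_datasets,
)
from .distributions import (
    MethodReport,
    ScoredPsm,
    SimilarityDistribution,
    build_distribution,
    combine,
    quantiles,
    rank_methods,
    stratify,
)
from .errors import ConfigError, DataError, UndefinedSimilarityError
from .io import PredictionTable
from .similarity import (
    METRIC_RANGES,
    METRICS,
    IntensityVector,
    reference_profile,
    restrict_charge1,
)

log = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    metric: str
    method_reports: list[MethodReport]
    method_dists: dict[str, SimilarityDistribution]
    experimental_dist: SimilarityDistribution | None
    experimental_summary: object | None
    scored: dict[str, list[ScoredPsm]]
    skipped: dict[str, int] = field(default_factory=dict)

    def report_rows(self, stratifiers: tuple[str, ...] = ()) -> list[dict]:
        rows = []
        for r in self.method_reports:
            rows.append({
                "method": r.method_name, "stratum": "overall",
                "n_precursors": round(r.n_precursors, 3),
                "q10": r.summary.q10, "q25": r.summary.q25,
                "median": r.summary.median, "q75": r.summary.q75,
                "q90": r.summary.q90,
                "W1_to_experimental": (r.w1_to_experimental
                                       if r.w1_to_experimental is not None else ""),
                "rank": r.rank,
            })
        if self.experimental_dist is not None and self.experimental_summary is not None:
            s = self.experimental_summary
            rows.append({
                "method": "experimental", "stratum": "overall",
                "n_precursors": round(self.experimental_dist.total_mass, 3),
                "q10": s.q10, "q25": s.q25, "median": s.median,
                "q75": s.q75, "q90": s.q90,
                "W1_to_experimental": 0.0, "rank": "",
            })
        lo, hi = METRIC_RANGES[self.metric]
        for by in stratifiers:
            for method, recs in self.scored.items():
                for stratum, dist in stratify(recs, by, lo, hi).items():
                    if dist.total_mass <= 0:
                        continue
                    s = quantiles(dist)
                    rows.append({
                        "method": method, "stratum": f"{by}:{stratum}",
                        "n_precursors": round(dist.total_mass, 3),
                        "q10": s.q10, "q25": s.q25, "median": s.median,
                        "q75": s.q75, "q90": s.q90,
                        "W1_to_experimental": "", "rank": "",
                    })
        return rows

    def to_summary(self) -> dict:
        out = {"metric": self.metric, "methods": {}, "skipped_psms": self.skipped}
        for r in self.method_reports:
            out["methods"][r.method_name] = {
                "rank": r.rank,
                "median": round(r.summary.median, 6),
                "q10": round(r.summary.q10, 6), "q25": round(r.summary.q25, 6),
                "q75": round(r.summary.q75, 6), "q90": round(r.summary.q90, 6),
                "w1_to_experimental": (round(r.w1_to_experimental, 6)
                                       if r.w1_to_experimental is not None else None),
                "n_precursors": round(r.n_precursors, 3),
            }
        if self.experimental_summary is not None:
            s = self.experimental_summary
            out["experimental"] = {
                "median": round(s.median, 6), "q10": round(s.q10, 6),
                "q25": round(s.q25, 6), "q75": round(s.q75, 6),
                "q90": round(s.q90, 6),
                "n_precursors": round(self.experimental_dist.total_mass, 3),
            }
        return out


def _effective(vec: IntensityVector, mode: str) -> IntensityVector:
    return restrict_charge1(vec) if mode == MODE_CHARGE1 else vec


def run_evaluation(
    annotated: list[AnnotatedPsm],
    predictions: dict[str, PredictionTable],
    metric: str = "angle",
    mode: str = MODE_CHARGE12,
    literal_weighting: bool = False,
    min_precursors: int | None = None,
) -> EvaluationResult:
    """Score every (method, PSM) pair and build combined distributions.

    Raises on a prediction whose vector layout disagrees with the
    annotation layout; PSMs for which a metric is undefined (all-zero or
    zero-variance vectors) are skipped with a counted reason.
    """
    if metric not in METRICS:
        raise ConfigError(f"unknown metric {metric!r}")
    if not predictions:
        raise ConfigError("at least one prediction table is required")
    score_fn = METRICS[metric]
    lo, hi = METRIC_RANGES[metric]
    datasets = [ds for ds in partition_datasets(annotated, min_precursors)
                if not ds.flagged]
    method_parts: dict[str, list[SimilarityDistribution]] = {m: [] for m in predictions}
    exp_parts: list[SimilarityDistribution] = []
    scored: dict[str, list[ScoredPsm]] = {m: [] for m in predictions}
    skipped: dict[str, int] = {}

    for ds in datasets:
        for method, table in predictions.items():
            pairs = []
            for a in ds.psms:
                pred = table.entries.get(a.precursor_id)
                if pred is None:
                    skipped[f"{method}: no prediction"] = \
                        skipped.get(f"{method}: no prediction", 0) + 1
                    continue
                exp_vec = _effective(a.experimental, mode)
                pred_vec = _effective(pred, mode)
                if len(pred_vec) != len(exp_vec):
                    raise DataError(
                        f"layout mismatch for precursor {a.precursor_id} in method "
                        f"{method}: predicted length {len(pred_vec)} vs "
                        f"experimental {len(exp_vec)}")
                try:
                    s = score_fn(pred_vec, exp_vec)
                except UndefinedSimilarityError as exc:
                    skipped[f"{method}: {exc.code}"] = \
                        skipped.get(f"{method}: {exc.code}", 0) + 1
                    continue
                pairs.append((s, a.precursor_id))
                scored[method].append(ScoredPsm(
                    score=s, precursor_id=a.precursor_id, charge=a.psm.charge,
                    length=len(a.psm.peptide), nce=a.precursor_meta.nce,
                    modified=a.psm.peptide.is_modified))
            # multiplicities restricted to precursors that actually scored
            part_mult = Counter(pid for _, pid in pairs)
            method_parts[method].append(
                build_distribution(pairs, part_mult, lo, hi,
                                   literal_weighting=literal_weighting))

        by_prec: dict[tuple, list[IntensityVector]] = {}
        for a in ds.psms:
            by_prec.setdefault(a.precursor_id, []).append(_effective(a.experimental, mode))
        exp_pairs = []
        for pid, vecs in by_prec.items():
            if len(vecs) < 2:
                continue
            try:
                ref = reference_profile(vecs)
            except UndefinedSimilarityError as exc:
                skipped[f"experimental: {exc.code}"] = \
                    skipped.get(f"experimental: {exc.code}", 0) + 1
                continue
            for v in vecs:
                try:
                    exp_pairs.append((score_fn(ref, v), pid))
                except UndefinedSimilarityError as exc:
                    skipped[f"experimental: {exc.code}"] = \
                        skipped.get(f"experimental: {exc.code}", 0) + 1
        exp_mult = Counter(pid for _, pid in exp_pairs)
        exp_parts.append(build_distribution(exp_pairs, exp_mult, lo, hi,
                                            literal_weighting=literal_weighting))

    method_dists = {m: combine(parts) for m, parts in method_parts.items()}
    exp_dist = combine(exp_parts) if exp_parts else None
    have_exp = exp_dist is not None and exp_dist.total_mass > 0
    if not have_exp:
        log.warning("no precursor with >= 2 PSMs; experimental distribution absent")
    reports = rank_methods(
        {m: (d, exp_dist if have_exp else None) for m, d in method_dists.items()})
    return EvaluationResult(
        metric=metric,
        method_reports=reports,
        method_dists=method_dists,
        experimental_dist=exp_dist if have_exp else None,
        experimental_summary=quantiles(exp_dist) if have_exp else None,
        scored=scored,
        skipped=skipped,
    )
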