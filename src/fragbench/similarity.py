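"""Per-PSM similarity metrics and reference experimental profiles.

Two metrics are provided: Pearson correlation and the normalized angle
``alpha = 1 - 2*theta/pi`` where ``theta`` is the angle between the two
non-negative intensity vectors.  Both are scale-free; no normalization is
applied before metric evaluation.  Reference profiles for experimental
reproducibility are means of L2-normalized replicate vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import LayoutMismatchError, UndefinedSimilarityError

LAYOUT_CHARGE1 = "charge1"
LAYOUT_CHARGE12 = "charge1+2"


@dataclass(frozen=True)
class IntensityVector:
    """Non-negative intensities over the canonical fragment layout.

    ``layout`` tags the charge coverage: ``charge1`` vectors have length
    2*(N-1), ``charge1+2`` vectors 4*(N-1) for a peptide of length N.
    """

    values: np.ndarray
    layout: str = LAYOUT_CHARGE12

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("intensity vector must be one-dimensional")
        if (vals < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.layout not in (LAYOUT_CHARGE1, LAYOUT_CHARGE12):
            raise ValueError(f"unknown layout {self.layout!r}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def peptide_length(self) -> int:
        block = 2 if self.layout == LAYOUT_CHARGE1 else 4
        return len(self.values) // block + 1

    def is_zero(self) -> bool:
        return not self.values.any()


def _as_array(u) -> np.ndarray:
    if isinstance(u, IntensityVector):
        return u.values
    return np.asarray(u, dtype=float)


def _check_layouts(u, v) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(u, IntensityVector) and isinstance(v, IntensityVector):
        if u.layout != v.layout:
            raise LayoutMismatchError(f"layouts differ: {u.layout} vs {v.layout}")
    a, b = _as_array(u), _as_array(v)
    if a.shape != b.shape:
        raise LayoutMismatchError(f"vector lengths differ: {len(a)} vs {len(b)}")
    return a, b


def normalized_angle(u, v) -> float:
    """Normalized angle in [0, 1]; 1 = parallel, 0 = orthogonal.

    theta is evaluated with the numerically stable two-argument form
    ``2*atan2(|x - y|, |x + y|)`` on the unit-normalized vectors, which is
    exact for identical vectors where plain ``arccos`` loses ~1e-8 (the
    arccos argument would otherwise need clamping to [-1, 1] against
    floating-point overshoot).  All-zero vectors are rejected: callers must
    filter first.
    """
    a, b = _check_layouts(u, v)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError(
            "normalized angle undefined for all-zero vector", code="all_zero"
        )
    x, y = a / na, b / nb
    theta = 2.0 * np.arctan2(np.linalg.norm(x - y), np.linalg.norm(x + y))
    theta = min(float(theta), np.pi / 2)
    return 1.0 - 2.0 * theta / np.pi


def pearson(u, v) -> float:
    """Sample Pearson correlation over paired slots."""
    a, b = _check_layouts(u, v)
    da, db = a - a.mean(), b - b.mean()
    sa, sb = np.linalg.norm(da), np.linalg.norm(db)
    if sa == 0 or sb == 0:
        raise UndefinedSimilarityError(
            "Pearson undefined for zero-variance vector", code="zero_variance"
        )
    return float(np.clip(np.dot(da, db) / (sa * sb), -1.0, 1.0))


METRICS = {"angle": normalized_angle, "pearson": pearson}

#: Score range per metric, used downstream for distribution binning.
METRIC_RANGES = {"angle": (0.0, 1.0), "pearson": (-1.0, 1.0)}


def reference_profile(replicates: Sequence) -> IntensityVector:
    """Mean of L2-normalized replicate vectors for one precursor.

    Requires at least two nonzero replicates; precursors with a single PSM
    are ineligible for the experimental reproducibility distribution.
    """
    if len(replicates) < 2:
        raise UndefinedSimilarityError(
            f"reference profile needs >= 2 replicates, got {len(replicates)}",
            code="too_few_replicates",
        )
    layout = (
        replicates[0].layout
        if isinstance(replicates[0], IntensityVector)
        else LAYOUT_CHARGE12
    )
    arrays = []
    for r in replicates:
        a = _as_array(r)
        norm = np.linalg.norm(a)
        if norm == 0:
            raise UndefinedSimilarityError(
                "reference profile undefined with an all-zero replicate",
                code="all_zero",
            )
        arrays.append(a / norm)
    return IntensityVector(np.mean(arrays, axis=0), layout)


def restrict_charge1(u: IntensityVector) -> IntensityVector:
    """Return the charge-1 block of a charge1+2 vector; identity on charge1."""
    if u.layout == LAYOUT_CHARGE1:
        return u
    half = len(u.values) // 2
    return IntensityVector(u.values[:half].copy(), LAYOUT_CHARGE1)
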