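"""Potency-bin-wise confidence analysis and training-set modification.

Model confidence is rarely uniform across the potency range: a model can be
over-confident for weakly and highly potent compounds yet under-confident
in the well-populated intermediate range, while whole-set calibration
metrics average this structure away. This module stratifies the fraction of
test compounds falling within x standard deviations of their prediction by
TRUE pIC50 bin and labels each bin over-/under-confident against the
normal-reference coverage (68.27% at x = 1).

It also implements the two training-set modifications used to probe how
calibration depends on the label distribution, defined on three potency
bins pIC50 <= 5.5, (5.5, 7.5], > 7.5:

* **balanced** — minority-sample every bin down to the smallest bin's count;
* **reduced** — delete the central (intermediate-potency) bin entirely.

Modification applies to training data only; test sets stay untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import stream
from .types import ActivityClass, PredictionSet
from .uq_metrics import expected_coverage

#: boundaries of the three modification bins on the pIC50 scale
MODIFICATION_EDGES = (5.5, 7.5)


@dataclass(frozen=True)
class BinScheme:
    """Left-open/right-closed potency bins; values outside the range are
    clamped into the terminal bins."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing, length >= 2")

    @classmethod
    def equal_width(cls, lo: float = 4.0, hi: float = 10.0, n_bins: int = 12) -> "BinScheme":
        return cls(edges=tuple(np.linspace(lo, hi, n_bins + 1)))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, pic50: np.ndarray) -> np.ndarray:
        """Bin index per compound; bin b covers (edges[b], edges[b+1]]."""
        inner = np.asarray(self.edges[1:-1])
        idx = np.searchsorted(inner, np.asarray(pic50, dtype=float), side="left")
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class BinnedConfidence:
    """Per-potency-bin coverage at x standard deviations."""

    scheme: BinScheme
    sd_multiple: float
    counts: np.ndarray
    fractions: np.ndarray  # NaN for empty bins
    expected: float
    labels: list[Optional[str]]  # "over-confident" / "under-confident" / None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.scheme.edges[:-1],
                "bin_hi": self.scheme.edges[1:],
                "count": self.counts,
                "fraction_within": self.fractions,
                "expected": self.expected,
                "label": self.labels,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def binwise_coverage(
    ps: PredictionSet, scheme: BinScheme | None = None, x: float = 1.0
) -> BinnedConfidence:
    """Fraction of compounds within x*sigma, stratified by true-pIC50 bin.

    A bin is labelled over-confident when its observed fraction falls below
    the normal reference 2*Phi(x)-1 (the model under-predicted its
    uncertainty there), under-confident when above. Empty bins get count 0
    and no label.
    """
    if not ps.has_variance:
        raise ValueError("bin-wise coverage needs predicted variances")
    scheme = scheme or BinScheme.equal_width()
    ref = expected_coverage(x)
    within = np.abs(ps.errors) < x * np.sqrt(ps.variance)
    bins = scheme.assign(ps.y_true)
    counts = np.bincount(bins, minlength=scheme.n_bins)
    hits = np.bincount(bins, weights=within.astype(float), minlength=scheme.n_bins)
    with np.errstate(invalid="ignore"):
        fractions = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    labels: list[Optional[str]] = []
    for c, f in zip(counts, fractions):
        if c == 0:
            labels.append(None)
        elif f < ref:
            labels.append("over-confident")
        elif f > ref:
            labels.append("under-confident")
        else:
            labels.append(None)
    return BinnedConfidence(
        scheme=scheme,
        sd_multiple=x,
        counts=counts,
        fractions=fractions,
        expected=ref,
        labels=labels,
    )


@dataclass(frozen=True)
class ModificationScheme:
    """Training-set modification mode over the three fixed potency bins."""

    mode: str = "original"  # {"original", "balanced", "reduced"}
    edges: tuple[float, float] = MODIFICATION_EDGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("original", "balanced", "reduced"):
            raise ValueError(f"unknown modification mode {self.mode!r}")
        if len(self.edges) != 2 or not self.edges[0] < self.edges[1]:
            raise ValueError("modification needs exactly two increasing edges")

    def bin_of(self, pic50: np.ndarray) -> np.ndarray:
        """0 = low (<= lo), 1 = central (lo, hi], 2 = high (> hi)."""
        lo, hi = self.edges
        p = np.asarray(pic50, dtype=float)
        return np.where(p <= lo, 0, np.where(p <= hi, 1, 2))


def balance_training_set(train: ActivityClass, scheme: ModificationScheme) -> ActivityClass:
    """Minority-sample each potency bin down to the smallest bin's count.

    The smallest bin is kept whole; the others are sampled uniformly without
    replacement, deterministically given ``scheme.seed``. Fails explicitly
    if any bin is empty (balancing is then undefined). Output preserves the
    input compound order.
    """
    bins = scheme.bin_of(train.pic50)
    counts = np.bincount(bins, minlength=3)
    if np.any(counts == 0):
        raise ValueError(f"cannot balance: empty potency bin (counts {counts.tolist()})")
    m = int(counts.min())
    rng = stream(scheme.seed, "balance")
    keep: list[np.ndarray] = []
    for b in range(3):
        idx = np.flatnonzero(bins == b)
        keep.append(idx if len(idx) == m else rng.choice(idx, size=m, replace=False))
    order = np.sort(np.concatenate(keep))
    return train.subset(order, class_id=f"{train.class_id}-balanced")


def reduce_training_set(train: ActivityClass, scheme: ModificationScheme | None = None) -> ActivityClass:
    """Delete the central potency bin (lo, hi] from the training set.

    A compound exactly at the lower edge belongs to the low bin and is
    retained; one exactly at the upper edge sits in the central bin and is
    removed. An empty result is permitted.
    """
    scheme = scheme or ModificationScheme(mode="reduced")
    keep = np.flatnonzero(scheme.bin_of(train.pic50) != 1)
    return train.subset(keep, class_id=f"{train.class_id}-reduced")


def modify_training_set(train: ActivityClass, scheme: ModificationScheme) -> ActivityClass:
    if scheme.mode == "original":
        return train
    if scheme.mode == "balanced":
        return balance_training_set(train, scheme)
    return reduce_training_set(train, scheme)
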