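"""Shared containers: activity classes and prediction sets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class SignalModel:
    """The latent linear bit-weight law behind a synthetic activity class.

    Recorded so the Bayes-optimal predictor (``intercept + F[:, bits] @
    weights`` before clipping) can be evaluated exactly.
    """

    bits: np.ndarray          # signal bit positions, shape (n_signal,)
    weights: np.ndarray       # weights on those bits, shape (n_signal,)
    intercept: float
    noise_sd: float

    def predict(self, fingerprints: np.ndarray) -> np.ndarray:
        return self.intercept + fingerprints[:, self.bits].astype(float) @ self.weights


@dataclass
class ActivityClass:
    """Compounds of one target: binary fingerprints plus pIC50 labels.

    Fingerprints are a dense uint8 (n_compounds, n_bits) 0/1 matrix; pIC50 is
    on the log-molar scale (higher = more potent).
    """

    class_id: str
    compound_ids: list[str]
    fingerprints: np.ndarray
    pic50: np.ndarray
    signal: Optional[SignalModel] = None

    def __post_init__(self) -> None:
        self.fingerprints = np.asarray(self.fingerprints, dtype=np.uint8)
        self.pic50 = np.asarray(self.pic50, dtype=float)
        if self.fingerprints.ndim != 2:
            raise ValueError("fingerprints must be a 2-D bit matrix")
        n = self.fingerprints.shape[0]
        if len(self.compound_ids) != n or self.pic50.shape != (n,):
            raise ValueError("compound_ids, fingerprints and pic50 lengths differ")
        if not np.all(np.isfinite(self.pic50)):
            raise ValueError("non-finite pIC50 label")
        if len(set(self.compound_ids)) != n:
            raise ValueError("compound_ids must be unique")

    def __len__(self) -> int:
        return self.fingerprints.shape[0]

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]

    def subset(self, indices: Sequence[int], class_id: str | None = None) -> "ActivityClass":
        idx = np.asarray(indices, dtype=int)
        return ActivityClass(
            class_id=class_id or self.class_id,
            compound_ids=[self.compound_ids[i] for i in idx],
            fingerprints=self.fingerprints[idx],
            pic50=self.pic50[idx],
            signal=self.signal,
        )

    def subset_ids(self, ids: Sequence[str], class_id: str | None = None) -> "ActivityClass":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        return self.subset([pos[c] for c in ids], class_id=class_id)


@dataclass
class PredictionSet:
    """Per test compound: true label, predicted mean, predicted variance.

    ``variance`` is None for single-model controls that provide no
    uncertainty estimate; metrics that need it must signal unavailability.
    """

    y_true: np.ndarray
    y_pred: np.ndarray
    variance: Optional[np.ndarray] = None
    compound_ids: Optional[list[str]] = None
    model: str = ""
    split: str = ""

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if self.y_true.shape != self.y_pred.shape:
            raise ValueError("y_true and y_pred lengths differ")
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if self.variance.shape != self.y_true.shape:
                raise ValueError("variance length differs")
            if np.any(self.variance < 0):
                raise ValueError("negative predicted variance")

    def __len__(self) -> int:
        return self.y_true.shape[0]

    @property
    def errors(self) -> np.ndarray:
        return self.y_pred - self.y_true

    @property
    def has_variance(self) -> bool:
        return self.variance is not None

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids if self.compound_ids is not None else [""] * n,
                "y_true": self.y_true,
                "y_pred": self.y_pred,
                "variance": self.variance if self.variance is not None else np.full(n, np.nan),
                "model": self.model,
                "split": self.split,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionSet":
        df = pd.read_csv(path)
        var = df["variance"].to_numpy(dtype=float)
        return cls(
            y_true=df["y_true"].to_numpy(dtype=float),
            y_pred=df["y_pred"].to_numpy(dtype=float),
            variance=None if np.all(np.isnan(var)) else var,
            compound_ids=[str(c) for c in df["compound_id"]],
            model=str(df["model"].iloc[0]) if len(df) else "",
            split=str(df["split"].iloc[0]) if len(df) else "",
        )

    def tagged(self, model: str | None = None, split: str | None = None) -> "PredictionSet":
        return replace(
            self,
            model=self.model if model is None else model,
            split=self.split if split is None else split,
        )
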