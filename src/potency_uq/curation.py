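"""Numeric curation rules for raw IC50 activity records.

Mirrors the standard ChEMBL-style curation of large activity classes:
a strict molecular-mass cut-off, an inclusive potency window (default
10 pM - 10 uM), and replicate aggregation on the log scale with a tenfold
span rule. Structural-alert filtering (PAINS, medicinal-chemistry rules,
aggregators) runs published external filter sets; only a delegation hook
is provided here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple, Optional

import pandas as pd


@dataclass(frozen=True)
class RawActivityRecord:
    compound_id: str
    target_id: str
    potency_molar: float  # IC50 in molar units, > 0
    mol_mass: Optional[float] = None  # Daltons
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.potency_molar > 0:
            raise ValueError(f"potency_molar must be > 0, got {self.potency_molar}")


@dataclass(frozen=True)
class CurationConfig:
    """Numeric filter settings.

    ``max_mass`` is a strict upper bound (a compound of exactly 1000 Da is
    removed). ``potency_window`` is inclusive at both ends. ``require_mass``
    drops records lacking a molecular mass; set False to let them pass.
    ``aggregation_span`` is the maximum max/min fold-range within which
    replicate measurements of one compound-target pair are averaged rather
    than discarded.
    """

    max_mass: float = 1000.0
    potency_window: tuple[float, float] = (1e-11, 1e-5)  # 10 pM .. 10 uM
    aggregation_span: float = 10.0
    require_mass: bool = True

    def validate(self) -> None:
        lo, hi = self.potency_window
        if not lo < hi:
            raise ValueError("potency_window low bound must be below high bound")
        if self.max_mass <= 0:
            raise ValueError("max_mass must be positive")
        if self.aggregation_span <= 1:
            raise ValueError("aggregation_span must exceed 1")


class AggregatedRecord(NamedTuple):
    compound_id: str
    target_id: str
    pic50: float


def pic50_from_molar(potency_molar: float) -> float:
    """pIC50 = -log10(IC50 / M)."""
    if not potency_molar > 0:
        raise ValueError("potency must be positive")
    return -math.log10(potency_molar)


def filter_records(
    records: Iterable[RawActivityRecord], config: CurationConfig | None = None
) -> list[RawActivityRecord]:
    """Apply the mass and potency-window filters, preserving order."""
    config = config or CurationConfig()
    config.validate()
    lo, hi = config.potency_window
    kept = []
    for rec in records:
        if rec.mol_mass is None:
            if config.require_mass:
                continue
        elif not rec.mol_mass < config.max_mass:
            continue
        if not lo <= rec.potency_molar <= hi:
            continue
        kept.append(rec)
    return kept


def aggregate_replicates(
    records: Iterable[RawActivityRecord], aggregation_span: float = 10.0
) -> list[AggregatedRecord]:
    """Collapse replicate measurements per (compound, target) pair.

    Groups whose potencies span more than ``aggregation_span``-fold are
    discarded entirely; the rest emit one row whose pIC50 is the arithmetic
    mean of the replicate pIC50 values (equivalently the geometric mean of
    the molar potencies — averaging is done on the log scale because the
    span criterion itself is a log-scale rule). Singletons pass through.
    Group order follows first occurrence.
    """
    if aggregation_span <= 1:
        raise ValueError("aggregation_span must exceed 1")
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        groups.setdefault((rec.compound_id, rec.target_id), []).append(rec.potency_molar)
    out = []
    for (cid, tid), potencies in groups.items():
        if max(potencies) / min(potencies) > aggregation_span:
            continue
        pic50 = sum(pic50_from_molar(p) for p in potencies) / len(potencies)
        out.append(AggregatedRecord(cid, tid, pic50))
    return out


def apply_alert_hook(
    records: Iterable[RawActivityRecord],
    predicate: Callable[[RawActivityRecord], bool] | None = None,
) -> list[RawActivityRecord]:
    """Delegate structural-alert filtering to a user-supplied keep-predicate.

    Identity when ``predicate`` is None. Exceptions raised by the predicate
    propagate annotated with the offending record's compound id.
    """
    records = list(records)
    if predicate is None:
        return records
    kept = []
    for rec in records:
        try:
            keep = predicate(rec)
        except Exception as exc:
            raise RuntimeError(
                f"alert predicate failed on compound {rec.compound_id!r}"
            ) from exc
        if keep:
            kept.append(rec)
    return kept


def curate(
    records: Iterable[RawActivityRecord],
    config: CurationConfig | None = None,
    alert_predicate: Callable[[RawActivityRecord], bool] | None = None,
) -> list[AggregatedRecord]:
    """Full numeric curation: filters, alert hook, replicate aggregation."""
    config = config or CurationConfig()
    filtered = filter_records(records, config)
    filtered = apply_alert_hook(filtered, alert_predicate)
    return aggregate_replicates(filtered, config.aggregation_span)


# ---------------------------------------------------------------------------
# delimited-text interchange

_COLUMNS = ["compound_id", "target_id", "potency_molar", "mol_mass", "smiles"]


def read_raw_records_csv(path) -> list[RawActivityRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        mass = getattr(row, "mol_mass", None)
        smiles = getattr(row, "smiles", None)
        records.append(
            RawActivityRecord(
                compound_id=str(row.compound_id),
                target_id=str(row.target_id),
                potency_molar=float(row.potency_molar),
                mol_mass=None if mass is None or pd.isna(mass) else float(mass),
                smiles=None if smiles is None or pd.isna(smiles) else str(smiles),
            )
        )
    return records


def write_raw_records_csv(records: Iterable[RawActivityRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "target_id": r.target_id,
                "potency_molar": r.potency_molar,
                "mol_mass": r.mol_mass,
                "smiles": r.smiles,
            }
            for r in records
        ],
        columns=_COLUMNS,
    ).to_csv(path, index=False)


def write_curated_csv(records: Iterable[AggregatedRecord], path) -> None:
    """Write curated pIC50 rows (`compound_id,target_id,pic50`)."""
    pd.DataFrame(records, columns=["compound_id", "target_id", "pic50"]).to_csv(
        path, index=False
    )
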