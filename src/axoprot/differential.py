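"""Fold-change classification of proteins into shared vs predominant classes.

The comparative rule: a protein detected in both tissues with a
flagella/cilia quantity ratio (f/c) strictly greater than five-fold in either
direction, or detected exclusively in one tissue, is "predominant" there;
everything else is shared. Predominant proteins fall into three groups —
found exclusively in one tissue, represented by a different isoform in each
tissue, or present in both but strongly enriched in one.

Exclusive detection is reported with the dash sentinel ("-"), never as
infinity, matching how comparative tables print an undetected side. Ratios
are kept at full precision internally; reports round half-even to two
decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_EVEN, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "EXCLUSIVE_SENTINEL",
    "Klass",
    "Group",
    "DifferentialRecord",
    "fold_change",
    "classify",
    "group_assign",
    "build_record",
    "summarize",
    "format_ratio",
]

EXCLUSIVE_SENTINEL = "-"
FoldChange = Union[float, str]


class Klass(str, Enum):
    FLAGELLA_PREDOMINANT = "flagella_predominant"
    CILIA_PREDOMINANT = "cilia_predominant"
    SHARED = "shared"


class Group(str, Enum):
    EXCLUSIVE = "exclusive"
    ISOFORM_DIFFERENTIAL = "isoform_differential"
    ENRICHED = "enriched"
    NOT_APPLICABLE = "not_applicable"


def _check_pair(q_flagella: float, q_cilia: float) -> None:
    if q_flagella < 0 or q_cilia < 0:
        raise ValueError("quantities must be non-negative")
    if q_flagella == 0 and q_cilia == 0:
        raise ValueError("a record with zero quantity in both tissues cannot exist")


def fold_change(q_flagella: float, q_cilia: float) -> FoldChange:
    """Flagella/cilia quantity ratio, or the dash sentinel for exclusive detection."""
    _check_pair(q_flagella, q_cilia)
    if q_flagella == 0 or q_cilia == 0:
        return EXCLUSIVE_SENTINEL
    return q_flagella / q_cilia


def format_ratio(fc: FoldChange) -> str:
    """Render a ratio for reports: half-even rounding to two decimals."""
    if fc == EXCLUSIVE_SENTINEL:
        return EXCLUSIVE_SENTINEL
    return str(Decimal(repr(float(fc))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def classify(q_flagella: float, q_cilia: float, threshold: float = 5.0) -> Klass:
    """Predominance call for one protein's tissue quantity pair.

    Strictly more than ``threshold``-fold enrichment (or exclusive detection)
    on either side is predominant there; a ratio of exactly ``threshold`` is
    shared, by the strict "more than five-times" reading of the rule.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    _check_pair(q_flagella, q_cilia)
    if q_cilia == 0:
        return Klass.FLAGELLA_PREDOMINANT
    if q_flagella == 0:
        return Klass.CILIA_PREDOMINANT
    ratio = q_flagella / q_cilia
    if ratio > threshold:
        return Klass.FLAGELLA_PREDOMINANT
    if ratio < 1.0 / threshold:
        return Klass.CILIA_PREDOMINANT
    return Klass.SHARED


@dataclass(frozen=True)
class DifferentialRecord:
    """One protein's comparative row: quantities, ratio, class and group."""

    protein_id: str
    category: str
    q_flagella: float
    q_cilia: float
    fc_ratio: FoldChange
    klass: Klass
    group: Group = Group.NOT_APPLICABLE


def group_assign(record: DifferentialRecord, isoform_partner_detected: bool = False
                 ) -> Group:
    """Predominance-group assignment for a classified record.

    Exclusive detection with an isoform partner detected in the other tissue
    is the isoform-differential group; exclusive without a partner is the
    uniquely-found group; predominant but detected on both sides is the
    enriched group; shared records get no group.
    """
    if record.klass is Klass.SHARED:
        return Group.NOT_APPLICABLE
    exclusive = record.q_flagella == 0 or record.q_cilia == 0
    if exclusive:
        return Group.ISOFORM_DIFFERENTIAL if isoform_partner_detected else Group.EXCLUSIVE
    return Group.ENRICHED


def build_record(
    protein_id: str,
    q_flagella: float,
    q_cilia: float,
    category: str = "",
    threshold: float = 5.0,
    isoform_partner_detected: bool = False,
) -> DifferentialRecord:
    """Compute ratio, class and group for one quantity pair."""
    rec = DifferentialRecord(
        protein_id=protein_id,
        category=category,
        q_flagella=q_flagella,
        q_cilia=q_cilia,
        fc_ratio=fold_change(q_flagella, q_cilia),
        klass=classify(q_flagella, q_cilia, threshold),
    )
    return replace(rec, group=group_assign(rec, isoform_partner_detected))


@dataclass(frozen=True)
class Summary:
    counts: Mapping[str, int]  # per klass value
    by_category: Mapping[tuple[str, str], int]  # (klass value, category) -> count
    table: pd.DataFrame


def summarize(records: Sequence[DifferentialRecord]) -> Summary:
    """Counts per class and category plus a report-shaped table.

    Rows are ordered by (category, descending dominant-side quantity); the
    class counts are an exact partition of the input.
    """
    counts = {k.value: 0 for k in Klass}
    by_cat: dict[tuple[str, str], int] = {}
    for r in records:
        counts[r.klass.value] += 1
        key = (r.klass.value, r.category)
        by_cat[key] = by_cat.get(key, 0) + 1
    assert sum(counts.values()) == len(records)

    def dominant(r: DifferentialRecord) -> float:
        return max(r.q_flagella, r.q_cilia)

    ordered = sorted(records, key=lambda r: (r.category, -dominant(r), r.protein_id))
    table = pd.DataFrame(
        {
            "category": [r.category for r in ordered],
            "q_flagella": [r.q_flagella for r in ordered],
            "q_cilia": [r.q_cilia for r in ordered],
            "fc": [format_ratio(r.fc_ratio) for r in ordered],
            "protein": [r.protein_id for r in ordered],
            "klass": [r.klass.value for r in ordered],
            "group": [r.group.value for r in ordered],
        }
    )
    return Summary(counts=counts, by_category=by_cat, table=table)
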