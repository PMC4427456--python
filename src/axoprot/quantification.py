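"""2DE spot quantification: ppm normalization, cross-gel matching, consensus.

Replicate gel spot maps (spot position = isoelectric point × apparent
molecular weight, with a densitometric quantity) are normalized per gel to
parts-per-million of total spot quantity, matched across gels by a
deterministic agglomerative rule in (pI, log10 MW) space, averaged over the
replicates in which each spot was detected, and optionally divided by
molecular mass so quantities approximate molar rather than mass abundance.

The cross-gel matcher replaces interactive gel-analysis software with an
explicit, reproducible rule: spots cluster when they lie within a pI
tolerance and a log-MW tolerance of the cluster centroid, candidate links
being consumed in ascending normalized distance, with at most one member
per gel per cluster. Matched clusters receive special spot numbers (SSPs)
ordered by position, so the labelling is invariant to input file order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spot",
    "SpotMap",
    "SpotCluster",
    "SpotConsensus",
    "normalize_ppm",
    "match_spots_across_gels",
    "average_replicates",
    "mass_normalize",
]

TISSUES = ("flagella", "cilia")
PPM_TOTAL = 1e6


@dataclass(frozen=True)
class Spot:
    """One detected gel spot: local id, pI (pH), apparent MW (kDa), quantity."""

    spot_id: str
    pi: float
    mw_kda: float
    quantity: float

    def __post_init__(self) -> None:
        if not (3.0 <= self.pi <= 10.0):
            raise ValueError(f"spot {self.spot_id}: pI {self.pi} outside the gel range [3, 10]")
        if self.mw_kda <= 0:
            raise ValueError(f"spot {self.spot_id}: MW must be positive")
        if self.quantity < 0 or math.isnan(self.quantity):
            raise ValueError(f"spot {self.spot_id}: quantity must be non-negative")


@dataclass(frozen=True)
class SpotMap:
    """All spots detected on one gel, labelled by tissue of origin."""

    gel_id: str
    tissue: str
    spots: tuple[Spot, ...]

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        ids = [s.spot_id for s in self.spots]
        if len(ids) != len(set(ids)):
            raise ValueError(f"gel {self.gel_id}: duplicate spot ids")

    @property
    def total_quantity(self) -> float:
        return sum(s.quantity for s in self.spots)


@dataclass(frozen=True)
class SpotCluster:
    """A cross-gel consensus spot with its SSP label and member spots per gel."""

    ssp: str
    pi: float
    mw_kda: float
    members: Mapping[str, Spot]  # gel_id -> member spot


@dataclass(frozen=True)
class SpotConsensus:
    clusters: tuple[SpotCluster, ...]
    gel_tissues: Mapping[str, str]  # gel_id -> tissue

    def gels_per_tissue(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tissue in self.gel_tissues.values():
            out[tissue] = out.get(tissue, 0) + 1
        return out


def normalize_ppm(spotmap: SpotMap) -> SpotMap:
    """Express each spot quantity as ppm of the gel's total quantity.

    The normalized quantities sum to 1e6 per gel by construction; an all-zero
    gel is rejected because it has no denominator.
    """
    total = spotmap.total_quantity
    if total <= 0:
        raise ValueError(f"gel {spotmap.gel_id}: total quantity is zero, cannot normalize")
    spots = tuple(replace(s, quantity=s.quantity / total * PPM_TOTAL) for s in spotmap.spots)
    return replace(spotmap, spots=spots)


def _spot_key(gel_id: str, spot: Spot) -> tuple:
    # input-order-independent tie-break key
    return (spot.pi, spot.mw_kda, gel_id, spot.spot_id)


class _Cluster:
    __slots__ = ("entries",)

    def __init__(self, entry: tuple[str, Spot]):
        self.entries: list[tuple[str, Spot]] = [entry]

    def centroid(self) -> tuple[float, float]:
        pis = [s.pi for _, s in self.entries]
        logmws = [math.log10(s.mw_kda) for _, s in self.entries]
        return (sum(pis) / len(pis), sum(logmws) / len(logmws))

    def gels(self) -> set[str]:
        return {g for g, _ in self.entries}


def match_spots_across_gels(
    maps: Sequence[SpotMap],
    pi_tol: float = 0.2,
    logmw_tol: float = 0.04,
) -> SpotConsensus:
    """Cluster spots across replicate gels and assign SSP labels.

    Candidate links between spots of *different* gels with normalized
    distance d = max(|ΔpI|/pi_tol, |Δlog10 MW|/logmw_tol) ≤ 1 are processed
    in ascending d (ties broken on position, then gel and spot ids, so the
    result is independent of input order). Two clusters merge only if no gel
    would contribute two spots and every member stays within tolerance of
    the merged centroid. SSPs are assigned in (pI, MW) order.
    """
    if not maps:
        raise ValueError("need at least one spot map")
    if pi_tol <= 0 or logmw_tol <= 0:
        raise ValueError("tolerances must be positive")
    gel_ids = [m.gel_id for m in maps]
    if len(gel_ids) != len(set(gel_ids)):
        raise ValueError("duplicate gel ids")

    entries = [(m.gel_id, s) for m in sorted(maps, key=lambda m: m.gel_id)
               for s in sorted(m.spots, key=lambda s: _spot_key(m.gel_id, s))]
    clusters: dict[int, _Cluster] = {i: _Cluster(e) for i, e in enumerate(entries)}
    owner = list(range(len(entries)))  # entry index -> cluster key

    pis = np.array([s.pi for _, s in entries])
    logmws = np.array([math.log10(s.mw_kda) for _, s in entries])
    gels = [g for g, _ in entries]

    links = []
    for i in range(len(entries)):
        dpi = np.abs(pis[i + 1:] - pis[i]) / pi_tol
        dmw = np.abs(logmws[i + 1:] - logmws[i]) / logmw_tol
        d = np.maximum(dpi, dmw)
        # two spots both within tolerance of a shared centroid can be up to
        # 2x the tolerance apart pairwise, so links are proposed out to d=2;
        # the centroid check at merge time is what enforces membership
        for off in np.nonzero(d <= 2.0)[0]:
            j = i + 1 + off
            if gels[i] == gels[j]:
                continue
            ki, kj = sorted((_spot_key(*entries[i]), _spot_key(*entries[j])))
            links.append((float(d[off]), ki, kj, i, j))
    links.sort()

    for _, _, _, i, j in links:
        a, b = owner[i], owner[j]
        if a == b:
            continue
        ca, cb = clusters[a], clusters[b]
        if ca.gels() & cb.gels():
            continue
        merged = ca.entries + cb.entries
        cpi = sum(s.pi for _, s in merged) / len(merged)
        cmw = sum(math.log10(s.mw_kda) for _, s in merged) / len(merged)
        ok = all(
            abs(s.pi - cpi) < pi_tol and abs(math.log10(s.mw_kda) - cmw) < logmw_tol
            for _, s in merged
        )
        if not ok:
            continue
        ca.entries = merged
        del clusters[b]
        for k, o in enumerate(owner):
            if o == b:
                owner[k] = a

    finished = []
    for c in clusters.values():
        cpi, clmw = c.centroid()
        finished.append((cpi, 10.0 ** clmw, c))
    finished.sort(key=lambda t: (t[0], t[1], _spot_key(*t[2].entries[0])))
    width = max(4, len(str(len(finished))))
    out = tuple(
        SpotCluster(
            ssp=f"SSP{i:0{width}d}",
            pi=cpi,
            mw_kda=mw,
            members={g: s for g, s in c.entries},
        )
        for i, (cpi, mw, c) in enumerate(finished, start=1)
    )
    gel_tissues = {m.gel_id: m.tissue for m in maps}
    return SpotConsensus(clusters=out, gel_tissues=gel_tissues)


def average_replicates(
    consensus: SpotConsensus,
    min_detected: int = 2,
) -> pd.DataFrame:
    """Per-SSP mean ppm quantity per tissue, with the detection-consensus rule.

    A spot's tissue quantity is the mean over the replicates in which it was
    detected; detection in fewer than ``min_detected`` replicates of a tissue
    is treated as absence (quantity 0), paralleling the identification rule
    that a protein must be found at least twice to count. Quantities are
    never imputed.

    Returns a table with columns ``ssp, pi, mw_kda`` and, per tissue,
    ``q_<tissue>`` (mean ppm) and ``n_<tissue>`` (replicates detected).
    """
    per_tissue = consensus.gels_per_tissue()
    for tissue, n in per_tissue.items():
        if n < min_detected:
            raise ValueError(
                f"tissue {tissue!r} has {n} replicate gels, fewer than min_detected={min_detected}"
            )
    rows = []
    for c in consensus.clusters:
        row: dict[str, object] = {"ssp": c.ssp, "pi": c.pi, "mw_kda": c.mw_kda}
        for tissue in sorted(per_tissue):
            qs = [s.quantity for g, s in c.members.items()
                  if consensus.gel_tissues[g] == tissue]
            n = len(qs)
            row[f"n_{tissue}"] = n
            row[f"q_{tissue}"] = float(np.mean(qs)) if n >= min_detected else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def mass_normalize(ppm_quantity: float, protein_mw_kda: float) -> float:
    """Divide a ppm quantity by molecular mass in kDa (a molar-abundance proxy).

    Dividing both tissues' quantities by the same molecular mass leaves every
    within-protein tissue ratio unchanged; it only reweights proteins of
    different sizes against each other.
    """
    if protein_mw_kda <= 0 or math.isnan(protein_mw_kda):
        raise ValueError("molecular mass must be positive")
    return ppm_quantity / protein_mw_kda
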