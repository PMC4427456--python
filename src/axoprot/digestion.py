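"""In-silico proteolysis: tryptic peptides and theoretical PMF peak lists.

Trypsin is shipped with the classic Keil rule — cleave C-terminal to K or R
except when the next residue is proline — switchable off for the permissive
variant. Peptides carry 0-based half-open coordinates into their parent and
a missed-cleavage count; the zero-missed set tiles the parent exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .physchem import MassMode, ResidueMassTable, default_mass_table, peptide_mass

__all__ = ["Peptide", "DigestParams", "cleavage_sites", "digest", "theoretical_peak_list"]

# Enzyme rules: residues cut after, and residues that block the cut when they
# follow the site (the Keil proline exception for trypsin).
_ENZYMES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "trypsin": (frozenset("KR"), frozenset("P")),
}


@dataclass(frozen=True, order=True)
class Peptide:
    """A proteolytic fragment of a parent protein.

    ``start``/``end`` are 0-based half-open coordinates in the parent;
    ``mass`` is [M+H]+ monoisotopic by default (see :class:`DigestParams`).
    """

    start: int
    end: int
    sequence: str
    missed_cleavages: int
    mass: float


@dataclass(frozen=True)
class DigestParams:
    """Digestion and mass settings shared across the PMF stages.

    ``charge_state=1`` with ``mass_mode="mono"`` yields [M+H]+ monoisotopic
    masses, the dominant species in MALDI-TOF peptide spectra. ``mass_range``
    is the instrument window applied by :func:`theoretical_peak_list`
    (700–4000 Da, a typical MALDI acquisition window).
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 1
    proline_rule: bool = True
    min_length: int = 1
    mass_mode: MassMode = "mono"
    charge_state: int = 1
    mass_range: tuple[float, float] = (700.0, 4000.0)


def cleavage_sites(sequence: str, enzyme: str = "trypsin", proline_rule: bool = True
                   ) -> list[int]:
    """Internal cut positions as boundary indices (cut between i-1 and i).

    The chain termini are not cleavage sites; a terminal K/R therefore
    contributes no site.
    """
    try:
        cut_after, blocked_by = _ENZYMES[enzyme]
    except KeyError:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; available rules: {sorted(_ENZYMES)}"
        ) from None
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in cut_after:
            if proline_rule and sequence[i + 1] in blocked_by:
                continue
            sites.append(i + 1)
    return sites


def digest(
    sequence: str,
    enzyme: str = "trypsin",
    max_missed_cleavages: int = 1,
    *,
    proline_rule: bool = True,
    min_length: int = 1,
    mass_mode: MassMode = "mono",
    charge_state: int = 1,
    table: ResidueMassTable | None = None,
) -> list[Peptide]:
    """All peptides with 0..``max_missed_cleavages`` retained internal sites.

    Returned in (start, end) order; deterministic. Terminal peptides count
    only their retained *internal* sites. Peptides shorter than ``min_length``
    are dropped (default keeps everything).
    """
    if not sequence:
        raise ValueError("protein sequence must be non-empty")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be non-negative")
    table = table or default_mass_table()
    sites = cleavage_sites(sequence, enzyme, proline_rule)
    bounds = [0, *sites, len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            if end - start < min_length:
                continue
            frag = sequence[start:end]
            peptides.append(
                Peptide(
                    start=start,
                    end=end,
                    sequence=frag,
                    missed_cleavages=j - i - 1,
                    mass=peptide_mass(frag, mass_mode, charge_state, table),
                )
            )
    return peptides


def theoretical_peak_list(
    sequence: str,
    params: DigestParams = DigestParams(),
    table: ResidueMassTable | None = None,
) -> list[tuple[float, Peptide]]:
    """Digest ``sequence`` and return in-window (mass, peptide) pairs, mass-ascending.

    Distinct peptides with coinciding masses are retained as separate entries.
    """
    lo, hi = params.mass_range
    if lo > hi:
        raise ValueError(f"inverted mass range ({lo}, {hi})")
    peps = digest(
        sequence,
        enzyme=params.enzyme,
        max_missed_cleavages=params.max_missed_cleavages,
        proline_rule=params.proline_rule,
        min_length=params.min_length,
        mass_mode=params.mass_mode,
        charge_state=params.charge_state,
        table=table,
    )
    entries = [(p.mass, p) for p in peps if lo <= p.mass <= hi]
    entries.sort(key=lambda mp: (mp[0], mp[1].start, mp[1].end))
    return entries
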