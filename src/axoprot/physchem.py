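"""Peptide and protein physical chemistry: masses and isoelectric points.

These are the physical primitives underneath both peptide-mass-fingerprint
identification and the synthetic 2DE gel simulator: monoisotopic and average
masses for tryptic peptides and whole chains, and Henderson–Hasselbalch
isoelectric-point prediction for the first (isoelectric focusing) gel
dimension.

The residue-mass and pKa tables are shipped as plain-text data files and can
be overridden with a file path, so the constants every downstream number
depends on are pinned and inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

__all__ = [
    "PROTON_MASS",
    "WATER_MONO",
    "WATER_AVERAGE",
    "CARBAMIDOMETHYL_CYS",
    "ResidueMassTable",
    "PkaTable",
    "default_mass_table",
    "default_pka_table",
    "peptide_mass",
    "protein_mw",
    "net_charge",
    "isoelectric_point",
]

MassMode = Literal["mono", "average"]

#: Mass of a proton (Da); the [M+H]+ ion of a peptide weighs neutral + this.
PROTON_MASS = 1.00727646688
#: Mass of one water molecule (Da), released per condensed peptide bond.
WATER_MONO = 18.0105646863
WATER_AVERAGE = 18.01528

#: Fixed modification for iodoacetamide-alkylated cysteine (+57.02146 Da).
#: Off by default: alkylation must be declared, never assumed.
CARBAMIDOMETHYL_CYS: Mapping[str, float] = {"C": 57.02146}


class UnknownResidueError(ValueError):
    """A sequence contains a character outside the residue table."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"unknown residue {residue!r} at position {position}; "
            "nonstandard codes (B, Z, X, U, ...) are rejected rather than "
            "silently averaged"
        )


def _validate_sequence(sequence: str, known: Mapping[str, object]) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, aa in enumerate(sequence):
        if aa not in known:
            raise UnknownResidueError(aa, i)


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue monoisotopic/average masses plus the water and proton constants.

    ``residue_mass`` maps one-letter codes to ``(monoisotopic, average)`` Da.
    ``fixed_mods`` maps residue codes to a mass delta added on every occurrence
    (e.g. carbamidomethyl-Cys).
    """

    residue_mass: Mapping[str, tuple[float, float]]
    water_mass: tuple[float, float] = (WATER_MONO, WATER_AVERAGE)
    proton_mass: float = PROTON_MASS
    fixed_mods: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residue_mass)
        if missing:
            raise ValueError(f"residue table missing standard residues: {sorted(missing)}")
        for aa, (mono, avg) in self.residue_mass.items():
            if mono <= 0 or avg <= 0:
                raise ValueError(f"non-positive mass for residue {aa!r}")
            if mono > avg:
                raise ValueError(
                    f"monoisotopic mass exceeds average mass for residue {aa!r}"
                )

    @classmethod
    def from_file(cls, path: str | Path, fixed_mods: Mapping[str, float] | None = None
                  ) -> "ResidueMassTable":
        """Load a table from a whitespace-delimited file: code, mono Da, average Da."""
        masses: dict[str, tuple[float, float]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, mono, avg = line.split()
            masses[code] = (float(mono), float(avg))
        return cls(residue_mass=masses, fixed_mods=dict(fixed_mods or {}))

    def with_fixed_mods(self, mods: Mapping[str, float]) -> "ResidueMassTable":
        """Return a copy carrying ``mods`` as fixed modifications."""
        return replace(self, fixed_mods=dict(mods))


@dataclass(frozen=True)
class PkaTable:
    """Ionisable-group pKa values and charge signs for pI prediction.

    Acids (D, E, C, Y and the C-terminus) carry sign −1, bases (H, K, R and the
    N-terminus) +1; the default values are the Bjellqvist set.
    """

    nterm_pka: float
    cterm_pka: float
    sidechain_pka: Mapping[str, float]
    charge_sign: Mapping[str, int]

    def __post_init__(self) -> None:
        for aa in "DECY":
            if self.charge_sign.get(aa, -1) != -1:
                raise ValueError(f"acidic residue {aa} must carry sign -1")
        for aa in "HKR":
            if self.charge_sign.get(aa, +1) != +1:
                raise ValueError(f"basic residue {aa} must carry sign +1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PkaTable":
        nterm = cterm = None
        side: dict[str, float] = {}
        sign: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            group, pka, s = line.split()
            if group == "nterm":
                nterm = float(pka)
            elif group == "cterm":
                cterm = float(pka)
            else:
                side[group] = float(pka)
                sign[group] = int(s)
        if nterm is None or cterm is None:
            raise ValueError("pKa file must define nterm and cterm entries")
        return cls(nterm_pka=nterm, cterm_pka=cterm, sidechain_pka=side, charge_sign=sign)


@lru_cache(maxsize=1)
def default_mass_table() -> ResidueMassTable:
    """The shipped standard residue-mass table (no fixed modifications)."""
    path = resources.files("axoprot") / "data" / "residue_masses.tsv"
    return ResidueMassTable.from_file(str(path))


@lru_cache(maxsize=1)
def default_pka_table() -> PkaTable:
    """The shipped Bjellqvist pKa table."""
    path = resources.files("axoprot") / "data" / "pka_bjellqvist.tsv"
    return PkaTable.from_file(str(path))


def peptide_mass(
    sequence: str,
    mode: MassMode = "mono",
    charge_state: int = 0,
    table: ResidueMassTable | None = None,
) -> float:
    """Mass of a peptide in Da.

    ``charge_state=0`` returns the neutral mass (residues + one water + fixed
    modifications). For z ≥ 1 returns the m/z of the protonated ion,
    ``(neutral + z·proton) / z``; the MALDI default z=1 gives [M+H]+.
    """
    table = table or default_mass_table()
    _validate_sequence(sequence, table.residue_mass)
    if mode not in ("mono", "average"):
        raise ValueError(f"mode must be 'mono' or 'average', got {mode!r}")
    if charge_state < 0:
        raise ValueError("charge_state must be a non-negative integer")
    idx = 0 if mode == "mono" else 1
    mass = table.water_mass[idx]
    for aa in sequence:
        mass += table.residue_mass[aa][idx]
        mass += table.fixed_mods.get(aa, 0.0)
    if charge_state == 0:
        return mass
    return (mass + charge_state * table.proton_mass) / charge_state


def protein_mw(sequence: str, table: ResidueMassTable | None = None) -> float:
    """Average-mass molecular weight of a whole chain in Da.

    This is the denominator used when spot quantities are normalized by
    molecular mass before tissues are compared.
    """
    return peptide_mass(sequence, mode="average", charge_state=0, table=table)


def net_charge(sequence: str, ph: float, pka: PkaTable | None = None) -> float:
    """Net charge Q(pH) of a polypeptide by the Henderson–Hasselbalch model.

    Q = Σ over ionisable groups of sign · 1/(1 + 10^(sign·(pH − pKa))),
    strictly decreasing in pH.
    """
    pka = pka or default_pka_table()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    groups: list[tuple[int, float]] = [(+1, pka.nterm_pka), (-1, pka.cterm_pka)]
    for aa in sequence:
        if aa in pka.sidechain_pka:
            groups.append((pka.charge_sign[aa], pka.sidechain_pka[aa]))
    return sum(s / (1.0 + 10.0 ** (s * (ph - p))) for s, p in groups)


def isoelectric_point(
    sequence: str,
    pka: PkaTable | None = None,
    table: ResidueMassTable | None = None,
    tol: float = 1e-3,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Q(pH) is strictly decreasing so the root is unique; bisection runs to a
    bracket width of ``tol`` (default 1e-3 pH units).
    """
    table = table or default_mass_table()
    _validate_sequence(sequence, table.residue_mass)
    lo, hi = 0.0, 14.0
    # Refine past the bracket tolerance until |Q| is genuinely small; long
    # chains have a steep Q so a fixed bracket width alone does not bound |Q|.
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if hi - lo <= tol and abs(q) < 1e-2:
            break
        if q > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
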