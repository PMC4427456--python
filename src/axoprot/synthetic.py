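"""Ground-truthed synthetic data for the comparative 2DE/PMF pipeline.

The generator emulates the statistical structure of a two-tissue comparative
gel study: a proteome of random sequences containing isoform pairs that
differ by a few substitutions (guaranteeing diagnostic tryptic peptides),
per-tissue abundance profiles covering shared, enriched and exclusive
proteins with the heavily-exclusive composition seen in real predominance
tables, triplicate gels per tissue with multiplicative lognormal intensity
noise, positional jitter and low-quantity spot dropout, and MALDI spectra
with incomplete peptide detection, ppm-scale mass error and contaminant
peaks.

Every output is a pure function of its parameters and an integer seed; the
global seed fans out to fixed per-component streams so the proteome, the
gels and each spectrum are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .differential import Group, Klass, classify
from .digestion import DigestParams
from .physchem import isoelectric_point, protein_mw
from .pmf import PeakList, Tolerance, diagnostic_peptides
from .quantification import Spot, SpotMap

__all__ = [
    "ProteinTruth",
    "GroundTruth",
    "DropoutRecord",
    "SpectrumTruth",
    "generate_proteome",
    "simulate_gels",
    "simulate_spectra",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# fixed seed-stream offsets per component
_STREAM_PROTEOME = 0
_STREAM_GELS = 1
_STREAM_SPECTRA = 2

# Default class mix, echoing the composition of a real two-tissue comparison
# (a slim majority shared; predominant proteins mostly tissue-exclusive, with
# a minority of finite-ratio enriched rows; flagella-predominant outnumbering
# cilia-predominant).
DEFAULT_CLASS_MIX: Mapping[str, float] = {
    "shared": 0.55,
    "flagella_exclusive": 0.22,
    "cilia_exclusive": 0.10,
    "flagella_enriched": 0.08,
    "cilia_enriched": 0.05,
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class ProteinTruth:
    """True state of one synthetic protein (quantities on the ppm scale)."""

    protein_id: str
    abundance_flagella: float
    abundance_cilia: float
    klass: Klass
    group: Group
    isoform_partner: str | None
    pi: float
    mw_kda: float


@dataclass(frozen=True)
class DropoutRecord:
    gel_id: str
    protein_id: str
    raw_quantity: float


@dataclass(frozen=True)
class SpectrumTruth:
    spot_id: str
    source_protein: str
    detected_masses: tuple[float, ...]
    mass_errors_ppm: tuple[float, ...]
    n_contaminants: int


@dataclass
class GroundTruth:
    """Everything needed to score a pipeline run against the simulation."""

    seed: int
    proteins: dict[str, ProteinTruth]
    dropouts: list[DropoutRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": t.protein_id,
                "abundance_flagella": t.abundance_flagella,
                "abundance_cilia": t.abundance_cilia,
                "klass": t.klass.value,
                "group": t.group.value,
                "isoform_partner": t.isoform_partner or "",
                "pi": round(t.pi, 4),
                "mw_kda": round(t.mw_kda, 4),
            }
            for t in self.proteins.values()
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(RESIDUES[i] for i in rng.integers(0, len(RESIDUES), size=length))


def _gene_id(rng: np.random.Generator, used: set[str]) -> str:
    # identifiers shaped like tunicate KH gene models
    while True:
        arm = rng.choice(["C", "L"])
        chrom = int(rng.integers(1, 15)) if arm == "C" else int(rng.integers(100, 160))
        num = int(rng.integers(1, 1000))
        tag = rng.choice(["SL1-1", "ND1-1", "nonSL1-1"])
        gid = f"KH.{arm}{chrom}.{num}.v1.A.{tag}"
        if gid not in used:
            used.add(gid)
            return gid


def _mutate(rng: np.random.Generator, sequence: str, n_subs: int) -> str:
    """Apply n point substitutions, never to the same position twice and never
    swapping to a residue of identical monoisotopic mass (I↔L)."""
    seq = list(sequence)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        old = seq[pos]
        forbidden = {old, "I" if old == "L" else "L" if old == "I" else ""}
        choices = [aa for aa in RESIDUES if aa not in forbidden]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def _isoform_pair(
    rng: np.random.Generator,
    length_range: tuple[int, int],
    n_subs: int,
    diag_params: DigestParams,
    diag_tol: Tolerance,
    max_tries: int = 200,
) -> tuple[str, str]:
    """A sequence pair differing by exactly ``n_subs`` substitutions with at
    least one diagnostic tryptic mass on each side."""
    for _ in range(max_tries):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        a = _random_sequence(rng, length)
        b = _mutate(rng, a, n_subs)
        ua, ub, _ = diagnostic_peptides(a, b, diag_params, diag_tol)
        if ua and ub:
            return a, b
    raise ValueError(
        f"could not place a diagnostic peptide within {max_tries} attempts; "
        f"length_range={length_range} may be too short to host an in-window tryptic peptide"
    )


def _class_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n proteins to the class mix."""
    raw = {k: n * v for k, v in mix.items()}
    counts = {k: int(math.floor(x)) for k, x in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def generate_proteome(
    n_proteins: int = 60,
    n_isoform_pairs: int = 3,
    substitutions_per_pair: int = 2,
    length_range: tuple[int, int] = (200, 450),
    seed: int = 0,
    class_mix: Mapping[str, float] = DEFAULT_CLASS_MIX,
    abundance_median: float = 5000.0,
    abundance_log_sigma: float = 1.2,
    digest_params: DigestParams = DigestParams(),
    tolerance: Tolerance = Tolerance(100.0, "ppm"),
) -> tuple[dict[str, str], GroundTruth]:
    """Generate a synthetic proteome with isoform pairs and true abundances.

    Isoform pair members are placed exclusively in opposite tissues (the
    mutually-exclusive-isoform structure); the remaining proteins are split
    between shared, exclusive and >5-fold-enriched classes by ``class_mix``.
    Per-tissue abundances are lognormal
    (median ``abundance_median`` ppm, log-sd ``abundance_log_sigma``) and each
    tissue is renormalized to 1e6 ppm; the recorded true class is computed
    from the final normalized abundances, so truth and data cannot disagree.
    """
    if substitutions_per_pair < 1:
        raise ValueError(
            "substitutions_per_pair must be >= 1: identical isoforms admit no diagnostic peptide"
        )
    if 2 * n_isoform_pairs > n_proteins:
        raise ValueError("2 * n_isoform_pairs must not exceed n_proteins")
    if length_range[0] > length_range[1] or length_range[0] < 20:
        raise ValueError("length_range must be (lo, hi) with lo >= 20")
    rng = _rng(seed, _STREAM_PROTEOME)

    used_ids: set[str] = set()
    proteome: dict[str, str] = {}
    partner: dict[str, str | None] = {}
    side_of: dict[str, str] = {}  # class key per protein

    for _ in range(n_isoform_pairs):
        a_seq, b_seq = _isoform_pair(rng, length_range, substitutions_per_pair,
                                     digest_params, tolerance)
        a_id, b_id = _gene_id(rng, used_ids), _gene_id(rng, used_ids)
        proteome[a_id] = a_seq
        proteome[b_id] = b_seq
        partner[a_id], partner[b_id] = b_id, a_id
        side_of[a_id] = "cilia_exclusive"
        side_of[b_id] = "flagella_exclusive"

    n_rest = n_proteins - 2 * n_isoform_pairs
    counts = _class_counts(n_rest, class_mix)
    rest_classes = [k for k, c in counts.items() for _ in range(c)]
    for klass_key in rest_classes:
        pid = _gene_id(rng, used_ids)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        proteome[pid] = _random_sequence(rng, length)
        partner[pid] = None
        side_of[pid] = klass_key

    # per-tissue abundances before renormalization
    qf: dict[str, float] = {}
    qc: dict[str, float] = {}
    mu = math.log(abundance_median)
    for pid in proteome:
        base = float(rng.lognormal(mu, abundance_log_sigma))
        kind = side_of[pid]
        if kind == "shared":
            r = float(np.exp(rng.uniform(math.log(1 / 3), math.log(3))))
        elif kind.endswith("enriched"):
            r = float(np.exp(rng.uniform(math.log(6.5), math.log(60))))
            if kind.startswith("cilia"):
                r = 1.0 / r
        elif kind == "flagella_exclusive":
            qf[pid], qc[pid] = base, 0.0
            continue
        else:  # cilia_exclusive
            qf[pid], qc[pid] = 0.0, base
            continue
        qf[pid] = base * math.sqrt(r)
        qc[pid] = base / math.sqrt(r)

    sf, sc = sum(qf.values()), sum(qc.values())
    for pid in proteome:
        qf[pid] = qf[pid] / sf * 1e6
        qc[pid] = qc[pid] / sc * 1e6

    proteins: dict[str, ProteinTruth] = {}
    for pid, seq in proteome.items():
        klass = classify(qf[pid], qc[pid])
        exclusive = qf[pid] == 0 or qc[pid] == 0
        if klass is Klass.SHARED:
            group = Group.NOT_APPLICABLE
        elif exclusive and partner[pid] is not None:
            group = Group.ISOFORM_DIFFERENTIAL
        elif exclusive:
            group = Group.EXCLUSIVE
        else:
            group = Group.ENRICHED
        proteins[pid] = ProteinTruth(
            protein_id=pid,
            abundance_flagella=qf[pid],
            abundance_cilia=qc[pid],
            klass=klass,
            group=group,
            isoform_partner=partner[pid],
            pi=isoelectric_point(seq),
            mw_kda=protein_mw(seq) / 1000.0,
        )
    return proteome, GroundTruth(seed=seed, proteins=proteins)


def simulate_gels(
    proteome: Mapping[str, str],
    truth: GroundTruth,
    n_replicates: int = 3,
    noise_sigma: float = 0.2,
    dropout_quantity: float = 100.0,
    jitter_pi: float = 0.05,
    jitter_logmw: float = 0.01,
    seed: int = 0,
) -> list[SpotMap]:
    """Simulate replicate 2DE gels for both tissues.

    Per gel, each protein with non-zero abundance in that tissue yields a
    spot at its true (pI, MW) position perturbed by Gaussian pI jitter and
    lognormal MW jitter, with raw quantity = true abundance × a lognormal
    factor of log-sd ``noise_sigma``. Spots whose noisy quantity falls below
    ``dropout_quantity`` are omitted from that gel and recorded in
    ``truth.dropouts``. Spot ids equal source protein ids so truth-derived
    identification maps are trivial; real spot tables carry arbitrary ids.
    """
    if noise_sigma < 0 or dropout_quantity < 0:
        raise ValueError("noise_sigma and dropout_quantity must be non-negative")
    rng = _rng(seed, _STREAM_GELS)
    truth.dropouts = []
    maps: list[SpotMap] = []
    order = sorted(proteome)
    for tissue in ("cilia", "flagella"):
        for rep in range(1, n_replicates + 1):
            gel_id = f"{tissue}_rep{rep}"
            spots = []
            for pid in order:
                t = truth.proteins[pid]
                abundance = t.abundance_cilia if tissue == "cilia" else t.abundance_flagella
                if abundance == 0:
                    continue
                pi = float(np.clip(t.pi + rng.normal(0.0, jitter_pi) if jitter_pi > 0
                                   else t.pi, 3.0, 10.0))
                mw = t.mw_kda * 10.0 ** (rng.normal(0.0, jitter_logmw) if jitter_logmw > 0
                                         else 0.0)
                qty = abundance * (float(rng.lognormal(0.0, noise_sigma))
                                   if noise_sigma > 0 else 1.0)
                if qty < dropout_quantity:
                    truth.dropouts.append(DropoutRecord(gel_id, pid, qty))
                    continue
                spots.append(Spot(spot_id=pid, pi=pi, mw_kda=mw, quantity=qty))
            maps.append(SpotMap(gel_id=gel_id, tissue=tissue, spots=tuple(spots)))
    return maps


def simulate_spectra(
    sequence: str,
    detection_prob: float = 0.7,
    mass_error_ppm_sigma: float = 25.0,
    n_contaminants: int = 5,
    seed: int = 0,
    params: DigestParams = DigestParams(),
    spot_id: str = "spot",
    source_protein: str = "",
    replicate_id: str = "",
) -> tuple[PeakList, SpectrumTruth]:
    """Simulate a MALDI peak list for one protein.

    Each theoretical in-window peptide mass is retained with probability
    ``detection_prob``, perturbed by Gaussian relative mass error of
    ``mass_error_ppm_sigma`` ppm; ``n_contaminants`` peaks are drawn
    uniformly over the mass window. Intensities are lognormal, contaminants
    systematically weaker than true peaks.
    """
    if not (0.0 < detection_prob <= 1.0):
        raise ValueError("detection_prob must be in (0, 1]")
    from .digestion import theoretical_peak_list  # local import avoids cycle at module load

    rng = _rng(seed, _STREAM_SPECTRA)
    theo = [m for m, _ in theoretical_peak_list(sequence, params)]
    mz, inten, errors, detected = [], [], [], []
    for m in theo:
        if rng.random() > detection_prob:
            continue
        err_ppm = float(rng.normal(0.0, mass_error_ppm_sigma)) if mass_error_ppm_sigma > 0 else 0.0
        mz.append(m * (1.0 + err_ppm * 1e-6))
        inten.append(float(rng.lognormal(math.log(100.0), 0.5)))
        errors.append(err_ppm)
        detected.append(m)
    lo, hi = params.mass_range
    for _ in range(n_contaminants):
        mz.append(float(rng.uniform(lo, hi)))
        inten.append(float(rng.lognormal(math.log(20.0), 0.5)))
    peaklist = PeakList.from_arrays(spot_id=spot_id, mz=mz, intensity=inten,
                                    replicate_id=replicate_id)
    strue = SpectrumTruth(
        spot_id=spot_id,
        source_protein=source_protein,
        detected_masses=tuple(detected),
        mass_errors_ppm=tuple(errors),
        n_contaminants=n_contaminants,
    )
    return peaklist, strue
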