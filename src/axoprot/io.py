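"""File formats: FASTA proteomes, MALDI peak lists, 2DE spot tables.

Peak lists come in two plain-text flavours: a minimal MGF dialect
(BEGIN IONS / TITLE=... / one "m/z intensity" row per peak / END IONS, no
precursor fields, as produced for PMF work) and bare two-column
whitespace-delimited text. The format is auto-detected by extension
(``.mgf`` vs anything else), overridable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pmf import PeakList
from .quantification import Spot, SpotMap

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peaklist",
    "write_peaklist",
    "read_spot_tables",
    "write_spot_tables",
]

SPOT_COLUMNS = ["gel_id", "tissue", "spot_id", "pi", "mw_kda", "quantity"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id, in file order."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()]
    SeqIO.write(recs, str(path), "fasta")


def _detect_format(path: Path) -> Literal["mgf", "txt"]:
    return "mgf" if path.suffix.lower() == ".mgf" else "txt"


def read_peaklist(
    path: str | Path,
    format: Literal["mgf", "txt", None] = None,
    spot_id: str | None = None,
    replicate_id: str = "",
) -> PeakList:
    """Read one spectrum; ``spot_id`` defaults to TITLE (MGF) or the file stem."""
    path = Path(path)
    fmt = format or _detect_format(path)
    title = None
    mz, inten = [], []
    lines = path.read_text().splitlines()
    if fmt == "mgf":
        inside = False
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                inside = True
            elif line == "END IONS":
                break
            elif inside and "=" in line:
                key, _, val = line.partition("=")
                if key.strip().upper() == "TITLE":
                    title = val.strip()
            elif inside:
                fields = line.split()
                mz.append(float(fields[0]))
                inten.append(float(fields[1]) if len(fields) > 1 else 0.0)
    else:
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            mz.append(float(fields[0]))
            inten.append(float(fields[1]) if len(fields) > 1 else 0.0)
    sid = spot_id or title or path.stem
    return PeakList.from_arrays(spot_id=sid, mz=mz, intensity=inten,
                                replicate_id=replicate_id)


def write_peaklist(peaklist: PeakList, path: str | Path,
                   format: Literal["mgf", "txt", None] = None) -> None:
    path = Path(path)
    fmt = format or _detect_format(path)
    rows = [f"{mz:.5f} {inten:.4f}" for mz, inten in peaklist.peaks]
    if fmt == "mgf":
        body = "\n".join(["BEGIN IONS", f"TITLE={peaklist.spot_id}", *rows, "END IONS", ""])
    else:
        body = "\n".join(rows) + "\n"
    path.write_text(body)


def read_spot_tables(path: str | Path) -> list[SpotMap]:
    """Read a spot-table TSV (one row per spot, possibly many gels) into SpotMaps."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    maps = []
    for (gel_id, tissue), sub in df.groupby(["gel_id", "tissue"], sort=True):
        spots = tuple(
            Spot(spot_id=str(r.spot_id), pi=float(r.pi), mw_kda=float(r.mw_kda),
                 quantity=float(r.quantity))
            for r in sub.itertuples()
        )
        maps.append(SpotMap(gel_id=str(gel_id), tissue=str(tissue), spots=spots))
    return maps


def write_spot_tables(maps: Iterable[SpotMap], path: str | Path) -> None:
    rows = [
        {"gel_id": m.gel_id, "tissue": m.tissue, "spot_id": s.spot_id,
         "pi": round(s.pi, 4), "mw_kda": round(s.mw_kda, 4), "quantity": s.quantity}
        for m in maps
        for s in m.spots
    ]
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, sep="\t", index=False)
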