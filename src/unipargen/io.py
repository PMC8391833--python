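"""Readers and writers for the plain-text formats used throughout the package.

Sequences travel as FASTA, STR haplotype tables and sample metadata as
tab-separated text with ``NA`` for missing values, distance matrices as
square TSV with matching header row/column, and haplotype networks as
GraphML. Every writer round-trips losslessly through its reader.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_SEQ_ALPHABET = set("ACGTN-")


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata carried through every analysis.

    ``language_family`` and ``country`` are the two grouping variables used
    for hierarchical AMOVA (language first, then geography).
    """

    sample_id: str
    population: str
    country: str
    language_family: str
    sex_marker: str = "mtDNA"  # "mtDNA" or "Y"


@dataclasses.dataclass(frozen=True)
class StrPanel:
    """Ordered Y-STR locus panel shared by all haplotypes in one analysis."""

    locus_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.locus_names) < 1:
            raise ValueError("panel must contain at least one locus")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("locus names must be unique")

    def __len__(self) -> int:
        return len(self.locus_names)


@dataclasses.dataclass(frozen=True)
class StrHaplotype:
    """Vector of integer repeat counts over an ordered locus panel."""

    sample_id: str
    alleles: tuple[int, ...]
    panel: StrPanel
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.panel):
            raise ValueError(
                f"{self.sample_id}: {len(self.alleles)} alleles for "
                f"{len(self.panel)}-locus panel"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs, order preserved.

    Sequences are upper-cased; duplicate ids and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(f"{path}: {rec.id}: invalid characters {sorted(bad)}")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_metadata(path: str | Path) -> dict[str, SampleMeta]:
    """Read a sample metadata TSV keyed by sample_id.

    Enforces that a population maps to exactly one country and one
    language family.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    required = {"sample_id", "population", "country", "language_family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    for col in ("country", "language_family"):
        per_pop = df.groupby("population")[col].nunique()
        if (per_pop > 1).any():
            pop = per_pop[per_pop > 1].index[0]
            raise ValueError(f"{path}: population {pop!r} maps to multiple {col} values")
    out = {}
    for row in df.itertuples(index=False):
        out[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            population=row.population,
            country=row.country,
            language_family=row.language_family,
            sex_marker=getattr(row, "sex_marker", "mtDNA"),
        )
    return out


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(m) for m in metas])
    df.to_csv(path, sep="\t", index=False)


def read_str_table(
    path: str | Path,
    panel: StrPanel | None = None,
    meta: dict[str, SampleMeta] | None = None,
    allow_intermediate: bool = False,
    intermediate_round: str = "floor",
) -> tuple[list[StrHaplotype], list[str]]:
    """Read a Y-STR haplotype table (sample_id + one column per locus).

    Returns ``(complete, excluded_ids)``: rows with any ``NA`` at a panel
    locus are excluded and listed by id so no sample is dropped silently.
    Non-integer ("intermediate") alleles such as 12.2 are an error unless
    ``allow_intermediate`` is set, in which case they are mapped to an
    integer by the stated convention ("floor" or "round").
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: first column must be 'sample_id'")
    loci = [c for c in df.columns if c != "sample_id"]
    if panel is None:
        panel = StrPanel(tuple(loci))
    else:
        missing = set(panel.locus_names) - set(loci)
        if missing:
            raise ValueError(f"{path}: panel loci absent from table: {sorted(missing)}")
    complete: list[StrHaplotype] = []
    excluded: list[str] = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        alleles: list[int] = []
        ok = True
        for locus in panel.locus_names:
            raw = row[locus]
            if pd.isna(raw) or raw == "NA":
                ok = False
                continue
            try:
                val = int(raw)
            except ValueError:
                try:
                    fval = float(raw)
                except ValueError:
                    raise ValueError(
                        f"{path}: sample {sid!r}, locus {locus}: "
                        f"non-numeric allele {raw!r}"
                    ) from None
                if not allow_intermediate:
                    raise ValueError(
                        f"{path}: sample {sid!r}, locus {locus}: intermediate "
                        f"allele {raw!r} (pass allow_intermediate to map it)"
                    )
                val = int(np.floor(fval)) if intermediate_round == "floor" else int(round(fval))
            alleles.append(val)
        if ok:
            complete.append(
                StrHaplotype(
                    sample_id=sid,
                    alleles=tuple(alleles),
                    panel=panel,
                    meta=None if meta is None else meta.get(sid),
                )
            )
        else:
            excluded.append(sid)
    return complete, excluded


def write_str_table(haplotypes: Sequence[StrHaplotype], path: str | Path) -> None:
    if not haplotypes:
        raise ValueError("no haplotypes to write")
    panel = haplotypes[0].panel
    rows = []
    for h in haplotypes:
        if h.panel.locus_names != panel.locus_names:
            raise ValueError("mixed panels in one table")
        rows.append({"sample_id": h.sample_id, **dict(zip(panel.locus_names, h.alleles))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_distance_matrix(
    matrix: np.ndarray, labels: Sequence[str], path: str | Path
) -> None:
    """Write a square symmetric zero-diagonal matrix as labelled TSV."""
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} labels")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(matrix), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_distance_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), [str(x) for x in df.index]


def write_network_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
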