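"""Readers and writers for the external formats.

Everything on disk is plain text: FASTA for sequences (with a sidecar
metadata TSV carrying isolation years — headers in public sequence records
are too unreliable to parse dates from), a minimal GFF3 for ORF
annotations, CSV for the binary infection matrix, TSV for spacer catalogs
and hit tables, and JSON for analysis results.

All external coordinates are 1-based inclusive on the forward strand.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtils import validate_dna

ROLE_PHAGE = "phage_genome"
ROLE_LOCUS = "crispr_locus"


@dataclass
class DatedSequenceRecord:
    """A sequence (phage genome or CRISPR locus amplicon) with its isolation year."""

    id: str
    sequence: str
    isolation_year: int
    isolation_source: Optional[str] = None
    role: str = ROLE_PHAGE

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.sequence = validate_dna(self.sequence, name=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfAnnotation:
    """A predicted ORF on a phage genome; start/end 1-based inclusive, forward strand."""

    genome_id: str
    orf_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"ORF {self.orf_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"ORF {self.orf_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# metadata sidecar


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar TSV (columns: id, year, source, role), indexed by id."""
    meta = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "year"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
    if meta["id"].duplicated().any():
        dups = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"metadata {path}: duplicate ids {dups}")
    return meta.set_index("id")


def write_metadata(records: Iterable[DatedSequenceRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "year": r.isolation_year,
            "source": r.isolation_source or "",
            "role": r.role,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_with_metadata(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[DatedSequenceRecord]:
    """Read a FASTA file and attach isolation years from the metadata TSV.

    Records come back in file order with uppercased sequences (N allowed).
    Every FASTA id must have a metadata row; a missing row is an error
    naming the offending id.
    """
    meta = read_metadata(metadata_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise KeyError(f"FASTA id {rec.id!r} has no row in metadata {metadata_path}")
        row = meta.loc[rec.id]
        source = row.get("source")
        role = row.get("role", ROLE_PHAGE)
        records.append(
            DatedSequenceRecord(
                id=rec.id,
                sequence=str(rec.seq),
                isolation_year=int(row["year"]),
                isolation_source=None if pd.isna(source) or source == "" else str(source),
                role=str(role) if isinstance(role, str) and role else ROLE_PHAGE,
            )
        )
    return records


def write_fasta(records: Iterable[DatedSequenceRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (minimal: seqid, start, end, strand, ID attribute)


def read_orf_annotations(path: str | Path) -> list[OrfAnnotation]:
    """Parse ORF features from a GFF3-compatible table.

    Only seqid, start, end, strand and the ID attribute are consumed; other
    columns and feature types pass through unfiltered except comment lines.
    """
    orfs: list[OrfAnnotation] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _, _, start, end, _, strand, _, attrs = fields[:9]
            orf_id = ""
            for chunk in attrs.split(";"):
                if chunk.startswith("ID="):
                    orf_id = chunk[3:]
            if not orf_id:
                orf_id = f"{seqid}_orf{lineno}"
            key = (seqid, orf_id)
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate ORF id {orf_id!r} on {seqid}")
            seen.add(key)
            orfs.append(OrfAnnotation(seqid, orf_id, int(start), int(end), strand))
    return orfs


def write_orf_annotations(orfs: Iterable[OrfAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(
                f"{o.genome_id}\tcrisprcoev\tCDS\t{o.start}\t{o.end}\t.\t{o.strand}\t.\tID={o.orf_id}\n"
            )


# ---------------------------------------------------------------------------
# infection matrix CSV (phages as rows, bacteria as columns, 1 = plaque)


def read_infection_matrix_csv(
    path: str | Path,
    phage_years: dict[str, int],
    bacterium_years: dict[str, int],
):
    """Read an all-against-all plaque matrix; returns an InfectionMatrix.

    The study design is complete, so a missing or non-binary cell is an
    error, not an NA.
    """
    from .timeshift import InfectionMatrix  # late import to avoid a cycle

    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        bad = [(str(r), str(c)) for r, c in zip(*df.isna().values.nonzero())]
        raise ValueError(f"infection matrix {path}: missing cells at {bad[:5]}")
    values = df.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise ValueError(f"infection matrix {path}: cells must be 0 or 1")
    df = df.astype(int)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return InfectionMatrix(
        outcomes=df,
        phage_years=pd.Series({p: phage_years[p] for p in df.index}),
        bacterium_years=pd.Series({b: bacterium_years[b] for b in df.columns}),
    )


def write_infection_matrix_csv(matrix, path: str | Path) -> None:
    matrix.outcomes.to_csv(path)


# ---------------------------------------------------------------------------
# spacer catalog TSVs


def write_catalog_tsv(catalog, pool_path: str | Path, arrays_path: str | Path) -> None:
    """Write the global pool (locus, label, sequence, conserved) and the
    per-isolate arrays (isolate, locus, position, label)."""
    with open(pool_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["locus", "label", "sequence", "conserved"])
        for locus, pool in catalog.pools.items():
            for label, seq in pool.items():
                flag = int(label in catalog.conserved.get(locus, set()))
                w.writerow([locus, label, seq, flag])
    with open(arrays_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["isolate", "locus", "position", "label"])
        for isolate, per_locus in catalog.arrays.items():
            for locus, labels in per_locus.items():
                for pos, label in enumerate(labels, start=1):
                    w.writerow([isolate, locus, pos, label])


def read_catalog_tsv(pool_path: str | Path, arrays_path: str | Path, years: dict[str, int]):
    """Rebuild a SpacerCatalog from its two TSVs plus isolate years."""
    from .catalog import SpacerCatalog

    pool_df = pd.read_csv(pool_path, sep="\t", dtype=str)
    arrays_df = pd.read_csv(arrays_path, sep="\t", dtype={"position": int})
    pools: dict[str, dict[str, str]] = {}
    conserved: dict[str, set[str]] = {}
    for _, row in pool_df.iterrows():
        pools.setdefault(row["locus"], {})[row["label"]] = row["sequence"]
        conserved.setdefault(row["locus"], set())
        if int(row["conserved"]):
            conserved[row["locus"]].add(row["label"])
    arrays: dict[str, dict[str, list[str]]] = {}
    for _, row in arrays_df.sort_values(["isolate", "locus", "position"]).iterrows():
        arrays.setdefault(str(row["isolate"]), {}).setdefault(row["locus"], []).append(row["label"])
    variable = {
        locus: set(pool) - conserved.get(locus, set()) for locus, pool in pools.items()
    }
    return SpacerCatalog(
        pools=pools,
        arrays=arrays,
        years={i: years[i] for i in arrays},
        conserved=conserved,
        variable=variable,
    )


# ---------------------------------------------------------------------------
# hit tables and JSON results


HIT_COLUMNS = [
    "spacer_label",
    "genome_id",
    "start",
    "end",
    "strand",
    "mismatches",
    "region",
    "coding_strand_hit",
    "quadrant",
    "downstream_flank",
]


def write_hit_table(hits, path: str | Path) -> None:
    rows = []
    for h in hits:
        d = dataclasses.asdict(h)
        rows.append({c: d.get(c) for c in HIT_COLUMNS})
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
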