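"""Readers and writers for the external formats the pipeline consumes.

Formats
-------
FASTA
    Protein and CDS sequences, via Bio.SeqIO.  Sequences are uppercased and
    stripped of gaps and whitespace on read.
Repeat-annotation TSV
    One row per repeat with columns ``accession``, ``gene_id``,
    ``organism_id``, ``category``, ``repeat_index``, ``start``, ``end``,
    ``score``, ``sequence``, ``labels``.  ``labels`` is a run-length string
    like ``Lda:6,Sa:7,Lab:5,...`` expanding to one structural tag per
    residue.  This dialect is defined by this package (WDSP's native output
    schema is not reproduced here); :func:`write_repeat_table` emits it and
    external annotations are converted to it at the boundary.
GFF3 / 6-column TSV gene tables
    1-based inclusive coordinates throughout (GFF3 convention).  The TSV
    dialect is ``gene_id  contig  start  end  strand  product`` with header.
Proteome TSV
    ``organism_id  category  n_proteins  n_wd40`` with header.

All readers are deterministic and never mutate their inputs.
"""

from __future__ import annotations

import logging
import urllib.parse
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .model import (
    FormatError,
    GeneRecord,
    ProteomeRecord,
    RepeatUnit,
    ValidationError,
    WD40Protein,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_repeat_table",
    "write_repeat_table",
    "read_gene_table",
    "write_gene_table",
    "read_proteome_table",
    "write_proteome_table",
]

logger = logging.getLogger(__name__)

REPEAT_TABLE_COLUMNS = [
    "accession",
    "gene_id",
    "organism_id",
    "category",
    "repeat_index",
    "start",
    "end",
    "score",
    "sequence",
    "labels",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence); uppercase, gaps/whitespace
    removed, file order preserved.  Empty files yield an empty list with a
    warning."""
    path = Path(path)
    try:
        records = [
            (rec.id, str(rec.seq).upper().replace("-", "").replace(".", "").replace(" ", ""))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:  # e.g. sequence data before the first header
        raise FormatError(f"{path}: malformed FASTA ({exc})") from exc
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = 60
) -> None:
    """Write (id, sequence) records as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _expand_labels(rle: str, accession: str) -> tuple[str, ...]:
    labels: list[str] = []
    for chunk in rle.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            tag, count = chunk.split(":")
            labels.extend([tag] * int(count))
        except ValueError as exc:
            raise FormatError(
                f"{accession}: malformed label run {chunk!r} (expected TAG:COUNT)"
            ) from exc
    return tuple(labels)


def _compress_labels(labels: Sequence[str]) -> str:
    runs: list[tuple[str, int]] = []
    for tag in labels:
        if runs and runs[-1][0] == tag:
            runs[-1] = (tag, runs[-1][1] + 1)
        else:
            runs.append((tag, 1))
    return ",".join(f"{tag}:{n}" for tag, n in runs)


def read_repeat_table(
    path: str | Path,
    sequences: Optional[Mapping[str, str]] = None,
) -> list[WD40Protein]:
    """Read the repeat-annotation TSV into proteins with populated repeats.

    ``sequences`` optionally maps accession to the full protein sequence
    (e.g. from :func:`read_fasta`); without it the protein sequence is
    reconstructed from the repeat segments with ``X`` filling unannotated
    positions.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REPEAT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    proteins: list[WD40Protein] = []
    for accession, group in df.groupby("accession", sort=False):
        group = group.sort_values("start", key=lambda s: s.astype(int))
        first = group.iloc[0]
        repeats = [
            RepeatUnit(
                parent_id=str(accession),
                index=int(row.repeat_index),
                start=int(row.start),
                end=int(row.end),
                sequence=row.sequence,
                labels=_expand_labels(row.labels, str(accession)),
                score=float(row.score),
            )
            for row in group.itertuples()
        ]
        if sequences is not None and accession in sequences:
            seq = sequences[str(accession)]
        else:
            length = max(r.end for r in repeats)
            chars = ["X"] * length
            for r in repeats:
                chars[r.start - 1 : r.end] = list(r.sequence)
            seq = "".join(chars)
        proteins.append(
            WD40Protein(
                accession=str(accession),
                gene_id=str(first.gene_id),
                organism_id=str(first.organism_id),
                category=str(first.category),
                sequence=seq,
                repeats=repeats,
            )
        )
    if not proteins:
        raise ValidationError(f"{path}: no repeat rows (proteins need >= 1 repeat)")
    logger.info("%s: read %d proteins", path, len(proteins))
    return proteins


def write_repeat_table(path: str | Path, proteins: Iterable[WD40Protein]) -> None:
    rows = []
    for p in proteins:
        for r in p.repeats:
            rows.append(
                {
                    "accession": p.accession,
                    "gene_id": p.gene_id,
                    "organism_id": p.organism_id,
                    "category": p.category,
                    "repeat_index": r.index,
                    "start": r.start,
                    "end": r.end,
                    "score": r.score,
                    "sequence": r.sequence,
                    "labels": _compress_labels(r.labels),
                }
            )
    pd.DataFrame(rows, columns=REPEAT_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


_GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def _gff_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in raw.strip().split(";"):
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = urllib.parse.unquote(value.strip())
    return out


def read_gene_table(
    path: str | Path,
    format: str = "tsv",
    product_attribute: str = "product",
    feature_types: Sequence[str] = ("gene", "CDS"),
) -> list[GeneRecord]:
    """Read gene records from GFF3 or the 6-column TSV dialect.

    GFF3: rows whose feature type is in ``feature_types`` become records; a
    gene with both ``gene`` and ``CDS`` rows is taken from the ``gene`` row.
    The product comes from ``product_attribute`` (falling back to ``Name``),
    the id from ``ID`` or ``locus_tag``.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["gene_id", "contig", "start", "end", "strand", "product"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        return [
            GeneRecord(
                gene_id=row.gene_id,
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                product="" if pd.isna(row.product) else str(row.product),
            )
            for row in df.itertuples()
        ]
    if format != "gff3":
        raise FormatError(f"unknown gene-table format {format!r}")
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS, dtype=str
    )
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for row in df.itertuples():
        if row.type not in feature_types:
            continue
        attrs = _gff_attributes(row.attributes)
        gene_id = attrs.get("ID") or attrs.get("locus_tag")
        if gene_id is None:
            raise FormatError(f"{path}: feature without ID/locus_tag attribute")
        gene_id = gene_id.removeprefix("gene:").removeprefix("cds:")
        if gene_id in seen:
            continue  # gene row takes precedence over its CDS row
        seen.add(gene_id)
        records.append(
            GeneRecord(
                gene_id=gene_id,
                contig=row.seqid,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                product=attrs.get(product_attribute, attrs.get("Name", "")),
            )
        )
    return records


def write_gene_table(path: str | Path, genes: Iterable[GeneRecord]) -> None:
    """Write gene records in the 6-column TSV dialect."""
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "contig": g.contig,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product": g.product,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_proteome_table(path: str | Path) -> list[ProteomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["organism_id", "category", "n_proteins", "n_wd40"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        ProteomeRecord(
            organism_id=row.organism_id,
            category=row.category,
            n_proteins=int(row.n_proteins),
            n_wd40=int(row.n_wd40),
        )
        for row in df.itertuples()
    ]


def write_proteome_table(path: str | Path, records: Iterable[ProteomeRecord]) -> None:
    pd.DataFrame(
        [
            {
                "organism_id": r.organism_id,
                "category": r.category,
                "n_proteins": r.n_proteins,
                "n_wd40": r.n_wd40,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
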