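"""File-format readers and writers.

All in-memory intervals in this package are 1-based inclusive (GFF style;
``size = end - start + 1``).  BED6 and bedGraph files are converted to their
native 0-based half-open convention at this boundary and nowhere else.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_COLUMNS = ["gene_id", "start", "end", "strand"]
READ_COLUMNS = ["start", "end", "strand"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> tuple[str, str]:
    """Read a single-contig FASTA; returns (contig_name, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one contig in {path}, found {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_fasta(path: str | os.PathLike, name: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Parse gene models from GFF3 into a sorted DataFrame.

    Columns: gene_id, start, end, strand (+ program if the annotation carries
    a ground-truth ``program`` attribute).  Coordinates stay 1-based inclusive.
    """
    import gffutils

    empty = pd.DataFrame(columns=GENE_COLUMNS)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return empty

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        row = {
            "gene_id": gene_id,
            "start": int(feat.start),
            "end": int(feat.end),
            "strand": feat.strand,
        }
        if "program" in feat.attributes:
            row["program"] = feat.attributes["program"][0]
        rows.append(row)
    # a gene may be represented by both a gene and a CDS line; keep one
    df = pd.DataFrame(rows).drop_duplicates(subset="gene_id")
    return df.sort_values("start", kind="stable").reset_index(drop=True)


def write_gff3(path: str | os.PathLike, genes: pd.DataFrame, chrom: str,
               feature_type: str = "gene", source: str = "predaseq") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            if hasattr(row, "program"):
                attrs += f";program={row.program}"
            fh.write(
                f"{chrom}\t{source}\t{feature_type}\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED6 (alignments, TSS calls)

def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED6 into 1-based inclusive start/end with name, score, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "score": float, "strand": str},
    )
    df["start"] = df["start"] + 1  # BED is 0-based half-open
    return df


def write_bed6(path: str | os.PathLike, intervals: pd.DataFrame, chrom: str,
               name: str | Iterable[str] = ".", score=0) -> None:
    """Write 1-based inclusive intervals (start/end/strand columns) as BED6."""
    out = pd.DataFrame({
        "chrom": chrom,
        "start": intervals["start"].to_numpy() - 1,
        "end": intervals["end"].to_numpy(),
        "name": intervals["name"] if "name" in intervals else name,
        "score": intervals["score"] if "score" in intervals else score,
        "strand": intervals["strand"].to_numpy(),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph (per-position 5' end counts, per strand)

def write_bedgraph(path: str | os.PathLike, positions: np.ndarray,
                   values: np.ndarray, chrom: str) -> None:
    """Write single-base records; ``positions`` are 1-based."""
    pos = np.asarray(positions, dtype=np.int64)
    out = pd.DataFrame({
        "chrom": chrom, "start": pos - 1, "end": pos,
        "value": np.asarray(values),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    """Read single-base bedGraph records into (position, value), 1-based."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if len(df) and not (df["end"] - df["start"] == 1).all():
        raise ValueError(f"{path}: expected single-base bedGraph records")
    return pd.DataFrame({"position": df["start"] + 1, "value": df["value"]})


# ---------------------------------------------------------------------------
# coverage

def coverage_from_reads(reads: pd.DataFrame, genome_length: int,
                        strand: str | None = None) -> np.ndarray:
    """Per-base read coverage as an array indexed 1..genome_length.

    Index 0 is unused padding.  ``strand`` restricts to reads of one strand;
    the default is strand-blind (unstranded mRNA-seq protocol).
    """
    if strand is not None:
        reads = reads[reads["strand"] == strand]
    diff = np.zeros(genome_length + 2, dtype=np.int64)
    starts = reads["start"].to_numpy()
    ends = reads["end"].to_numpy()
    np.add.at(diff, np.clip(starts, 1, genome_length), 1)
    np.add.at(diff, np.clip(ends + 1, 1, genome_length + 1), -1)
    cov = np.cumsum(diff)[: genome_length + 1]
    cov[0] = 0
    return cov


# ---------------------------------------------------------------------------
# sequences

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_table(path: str | os.PathLike, df: pd.DataFrame,
                metadata: dict | None = None) -> None:
    """Write a TSV with ``# key: value`` metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
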