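"""Transcription-start-site calling from paired TAP(+)/TAP(-) 5'-end tracks.

A genomic position is called as a TSS when it is supported by at least
``min_reads`` TAP(+) read starts, shows at least ``min_enrichment``-fold
depth-normalized enrichment in TAP(+) over TAP(-), and lies upstream of an
annotated gene on the same strand.  Nearby redundant calls are collapsed to
the best-supported position, calls are extended over downstream co-oriented
genes into operons, and 50-base promoter sequences are extracted 5'->3'
relative to transcription.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TSS_COLUMNS = ["position", "strand", "raw_plus", "raw_minus",
               "enrichment", "gene_id", "distance_to_start"]


@dataclass
class FivePrimeTrack:
    """Per-(position, strand) 5'-end read-start counts for one treatment.

    ``counts`` columns: position (1-based), strand, count.
    """

    counts: pd.DataFrame
    treatment: str = "TAP_plus"
    total_reads: int = field(default=0)

    def __post_init__(self):
        if len(self.counts) and (self.counts["count"] < 0).any():
            raise ValueError("negative 5'-end counts")
        self.total_reads = int(self.counts["count"].sum()) if len(self.counts) else 0

    def lookup(self) -> dict:
        """(position, strand) -> count."""
        if not len(self.counts):
            return {}
        return {(int(p), s): int(c) for p, s, c in
                zip(self.counts["position"], self.counts["strand"], self.counts["count"])}

    @classmethod
    def from_bedgraphs(cls, fwd_path: str | os.PathLike, rev_path: str | os.PathLike,
                       treatment: str) -> "FivePrimeTrack":
        from . import io as pio
        frames = []
        for path, strand in ((fwd_path, "+"), (rev_path, "-")):
            df = pio.read_bedgraph(path)
            frames.append(pd.DataFrame({"position": df["position"],
                                        "strand": strand, "count": df["value"]}))
        counts = pd.concat(frames, ignore_index=True)
        counts = counts.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)
        return cls(counts=counts.astype({"position": np.int64, "count": np.int64}),
                   treatment=treatment)


def call_tss(tap_plus: FivePrimeTrack, tap_minus: FivePrimeTrack,
             annotation: pd.DataFrame | None, min_reads: int = 5,
             min_enrichment: float = 3.0, max_upstream: int = 300) -> pd.DataFrame:
    """Call TSS positions from the paired tracks.

    Enrichment is computed on depth-normalized counts with a pseudocount of
    one read added to the TAP(-) raw count:
    ``(raw_plus/total_plus) / ((raw_minus+1)/total_minus)``.  A call must lie
    within ``max_upstream`` bases 5' of some gene start on the same strand,
    or inside that gene's first three codons (annotation slack).  Each call is
    assigned the nearest such gene.  With ``annotation=None`` the upstream
    requirement is skipped and every enriched position is returned unassigned
    (gene_id None) — the form the intergenic sRNA stage consumes.
    Returns calls sorted by position.
    """
    if tap_plus.total_reads == 0 or tap_minus.total_reads == 0:
        raise ValueError("both 5'-end tracks must contain reads")
    minus_lookup = tap_minus.lookup()

    gene_start = {}
    if annotation is not None:
        for g in annotation.itertuples(index=False):
            gene_start[g.gene_id] = (g.start, g.strand) if g.strand == "+" else (g.end, g.strand)

    plus_starts = np.array(sorted(v[0] for v in gene_start.values() if v[1] == "+"))
    plus_ids = sorted((v[0], k) for k, v in gene_start.items() if v[1] == "+")
    minus_starts = np.array(sorted(v[0] for v in gene_start.values() if v[1] == "-"))
    minus_ids = sorted((v[0], k) for k, v in gene_start.items() if v[1] == "-")

    rows = []
    for rec in tap_plus.counts.itertuples(index=False):
        raw_plus = int(rec.count)
        if raw_plus < min_reads:
            continue
        raw_minus = minus_lookup.get((int(rec.position), rec.strand), 0)
        enrichment = ((raw_plus / tap_plus.total_reads)
                      / ((raw_minus + 1) / tap_minus.total_reads))
        if enrichment < min_enrichment:
            continue
        if annotation is None:
            gene_id, dist = None, 0
        else:
            gene_id, dist = _nearest_downstream_gene(
                int(rec.position), rec.strand, plus_starts, plus_ids,
                minus_starts, minus_ids, max_upstream)
            if gene_id is None:
                continue
        rows.append({"position": int(rec.position), "strand": rec.strand,
                     "raw_plus": raw_plus, "raw_minus": int(raw_minus),
                     "enrichment": enrichment, "gene_id": gene_id,
                     "distance_to_start": dist})
    calls = pd.DataFrame(rows, columns=TSS_COLUMNS)
    return calls.sort_values("position", kind="stable").reset_index(drop=True)


def assign_genes(calls: pd.DataFrame, annotation: pd.DataFrame,
                 max_upstream: int = 300) -> pd.Series:
    """Gene assignment (or None) for arbitrary (position, strand) calls.

    Same rule as :func:`call_tss`: the nearest gene whose start lies within
    ``max_upstream`` bases downstream on the same strand (3-codon slack).
    """
    gene_start = {}
    for g in annotation.itertuples(index=False):
        gene_start[g.gene_id] = (g.start, g.strand) if g.strand == "+" else (g.end, g.strand)
    plus_starts = np.array(sorted(v[0] for v in gene_start.values() if v[1] == "+"))
    plus_ids = sorted((v[0], k) for k, v in gene_start.items() if v[1] == "+")
    minus_starts = np.array(sorted(v[0] for v in gene_start.values() if v[1] == "-"))
    minus_ids = sorted((v[0], k) for k, v in gene_start.items() if v[1] == "-")
    assigned = [
        _nearest_downstream_gene(int(rec.position), rec.strand, plus_starts,
                                 plus_ids, minus_starts, minus_ids, max_upstream)[0]
        for rec in calls.itertuples(index=False)
    ]
    return pd.Series(assigned, index=calls.index, dtype=object)


def _nearest_downstream_gene(pos, strand, plus_starts, plus_ids,
                             minus_starts, minus_ids, max_upstream):
    """Nearest gene whose upstream window [start-max_upstream, start+8] (strand
    oriented) contains ``pos``; returns (gene_id, clipped distance) or (None, None)."""
    slack = 8  # first three codons
    if strand == "+":
        if len(plus_starts) == 0:
            return None, None
        i = int(np.searchsorted(plus_starts, pos - slack, side="left"))
        if i == len(plus_starts):
            return None, None
        start = plus_starts[i]
        if start - pos > max_upstream:
            return None, None
        return plus_ids[i][1], max(0, int(start - pos))
    if len(minus_starts) == 0:
        return None, None
    i = int(np.searchsorted(minus_starts, pos + slack, side="right")) - 1
    if i < 0:
        return None, None
    start = minus_starts[i]
    if pos - start > max_upstream:
        return None, None
    return minus_ids[i][1], max(0, int(pos - start))


def deduplicate(calls: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Collapse runs of nearby same-strand calls to the best-supported one.

    Within a run where consecutive same-strand positions differ by at most
    ``window``, only the call with maximal TAP(+) support survives; ties go
    to the most 5' position (smallest on +, largest on -).
    """
    kept = []
    for strand, sub in calls.groupby("strand", sort=True):
        sub = sub.sort_values("position", kind="stable")
        run: list = []
        prev = None
        for rec in sub.itertuples():
            if prev is not None and rec.position - prev > window:
                kept.append(_best_of_run(run, strand))
                run = []
            run.append(rec)
            prev = rec.position
        if run:
            kept.append(_best_of_run(run, strand))
    if not kept:
        return calls.iloc[0:0].copy()
    out = pd.DataFrame([r._asdict() for r in kept]).drop(columns="Index", errors="ignore")
    return out.sort_values("position", kind="stable").reset_index(drop=True)


def _best_of_run(run, strand):
    best = run[0]
    for rec in run[1:]:
        if rec.raw_plus > best.raw_plus:
            best = rec
        elif rec.raw_plus == best.raw_plus and strand == "-" and rec.position > best.position:
            best = rec  # most 5' on the minus strand is the larger coordinate
    return best


def assign_operons(calls: pd.DataFrame, annotation: pd.DataFrame,
                   coverage: np.ndarray, max_gap: int = 50,
                   connect_frac: float = 0.25) -> dict:
    """Extend each TSS call over downstream co-oriented genes into an operon.

    Starting from the call's assigned gene, the operon grows gene-by-gene
    while the next gene is co-oriented, lacks its own TSS call, and either
    its intergenic gap is at most ``max_gap`` or the gap's minimum coverage
    is at least ``connect_frac`` of the upstream gene's mean coverage.
    Returns {(position, strand): [gene_id, ...]}.
    """
    anno = annotation.sort_values("start", kind="stable").reset_index(drop=True)
    idx_of = {g: i for i, g in enumerate(anno["gene_id"])}
    has_tss = set(calls["gene_id"])
    operons = {}
    for rec in calls.itertuples(index=False):
        if rec.gene_id not in idx_of:
            warnings.warn(f"TSS at {rec.position}{rec.strand} has no downstream gene; excluded")
            continue
        members = [rec.gene_id]
        i = idx_of[rec.gene_id]
        step = 1 if rec.strand == "+" else -1
        while True:
            j = i + step
            if j < 0 or j >= len(anno):
                break
            cur, nxt = anno.iloc[i], anno.iloc[j]
            if nxt["strand"] != rec.strand or nxt["gene_id"] in has_tss:
                break
            if rec.strand == "+":
                gap_lo, gap_hi = cur["end"] + 1, nxt["start"] - 1
            else:
                gap_lo, gap_hi = nxt["end"] + 1, cur["start"] - 1
            gap = gap_hi - gap_lo + 1
            if gap > max_gap:
                gap_cov = coverage[gap_lo: gap_hi + 1].min() if gap > 0 else 0
                mean_cov = coverage[cur["start"]: cur["end"] + 1].mean()
                if gap_cov < connect_frac * mean_cov:
                    break
            members.append(nxt["gene_id"])
            i = j
        operons[(rec.position, rec.strand)] = members
    return operons


def extract_promoters(calls: pd.DataFrame, genome: str,
                      upstream_len: int = 50) -> dict:
    """50-base promoter sequence per call, 5'->3' relative to transcription.

    Plus strand: bases [pos-upstream_len, pos-1]; minus strand: reverse
    complement of [pos+1, pos+upstream_len].  Calls too close to the contig
    edge are skipped with a warning.
    """
    from .io import reverse_complement

    promoters = {}
    L = len(genome)
    for rec in calls.itertuples(index=False):
        pos = int(rec.position)
        if rec.strand == "+":
            if pos - upstream_len < 1:
                warnings.warn(f"TSS at {pos}+ too close to contig start; promoter skipped")
                continue
            seq = genome[pos - upstream_len - 1: pos - 1]
        else:
            if pos + upstream_len > L:
                warnings.warn(f"TSS at {pos}- too close to contig end; promoter skipped")
                continue
            seq = reverse_complement(genome[pos: pos + upstream_len])
        promoters[(pos, rec.strand)] = seq
    return promoters
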