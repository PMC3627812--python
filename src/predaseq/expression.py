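"""Per-ORF expression calling and phase classification.

Reads overlapping each ORF by at least one base are counted (strand-blind by
default, matching the unstranded mRNA-seq protocol; a read spanning two genes
increments both).  Counts are normalized to RPKM (reads per kilobase of gene
model per million mapped reads); a gene is called expressed in a condition
when its RPKM exceeds 50.  Differential expression between the two
conditions is assessed with a one-degree-of-freedom goodness-of-fit chi-square
on the paired RPKM values, Bonferroni-corrected over the tested genes, and
each gene is assigned one of six phase categories from its expression flags
and a 5-fold dominance rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

EXPRESSION_THRESHOLD = 50.0   # RPKM above which a gene counts as expressed
DOMINANCE_FOLD = 5.0          # minimum fold for AP-/GP-dominant calls

CATEGORIES = ("AP_only", "GP_only", "AP_dominant", "GP_dominant", "shared", "silent")


# ---------------------------------------------------------------------------
# counting and normalization

def count_reads(alignments: pd.DataFrame, annotation: pd.DataFrame,
                stranded: bool = False) -> pd.Series:
    """Reads overlapping each gene by >= 1 base (1-based inclusive intervals).

    Genes must be sorted and non-overlapping.  Returns a Series indexed by
    gene_id.  ``stranded=True`` restricts to reads on the gene's strand.
    """
    anno = annotation.sort_values("start", kind="stable").reset_index(drop=True)
    g_start = anno["start"].to_numpy(dtype=np.int64)
    g_end = anno["end"].to_numpy(dtype=np.int64)
    if len(anno) and ((g_end - g_start + 1) <= 0).any():
        bad = anno.loc[(g_end - g_start + 1) <= 0, "gene_id"].tolist()
        raise ValueError(f"non-positive gene length: {bad}")
    counts = np.zeros(len(anno), dtype=np.int64)
    if len(anno) and len(alignments):
        r_start = alignments["start"].to_numpy(dtype=np.int64)
        r_end = alignments["end"].to_numpy(dtype=np.int64)
        if stranded:
            strands = anno["strand"].to_numpy()
            for strand in ("+", "-"):
                mask = alignments["strand"].to_numpy() == strand
                gsel = strands == strand
                sub = _overlap_counts(r_start[mask], r_end[mask],
                                      g_start[gsel], g_end[gsel])
                counts[gsel] += sub
        else:
            counts = _overlap_counts(r_start, r_end, g_start, g_end)
    return pd.Series(counts, index=anno["gene_id"].to_numpy(), name="count")


def _overlap_counts(r_start, r_end, g_start, g_end) -> np.ndarray:
    """Per-region overlap counts for sorted non-overlapping regions."""
    counts = np.zeros(len(g_start), dtype=np.int64)
    if len(g_start) == 0 or len(r_start) == 0:
        return counts
    base = np.searchsorted(g_end, r_start, side="left")
    k = 0
    while True:
        j = base + k
        valid = j < len(g_start)
        jj = np.where(valid, j, 0)
        valid &= (g_start[jj] <= r_end) & (g_end[jj] >= r_start)
        if not valid.any():
            break
        np.add.at(counts, j[valid], 1)
        k += 1
    return counts


def rpkm(count, gene_length, total_mapped):
    """Reads per kilobase of gene model per million mapped reads.

    ``count * 1e9 / (gene_length * total_mapped)``; accepts scalars or arrays.
    """
    gene_length = np.asarray(gene_length, dtype=float)
    total = float(total_mapped)
    if np.any(gene_length <= 0):
        raise ValueError("gene_length must be positive")
    if total <= 0:
        raise ValueError("total_mapped must be positive")
    out = np.asarray(count, dtype=float) * 1e9 / (gene_length * total)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# differential test

def chi2_differential(rpkm_ap, rpkm_gp, n_tests: int = 1):
    """1-df goodness-of-fit chi-square on a pair of RPKM values.

    Observed (a, b) against expected ((a+b)/2, (a+b)/2), i.e.
    ``chi2 = (a-b)^2/(a+b)``; p from the chi-square(1) upper tail,
    Bonferroni-adjusted as ``min(1, p * n_tests)``.  A zero pair returns
    p = 1.  Accepts scalars or arrays; returns (p_raw, p_adj).
    """
    a = np.asarray(rpkm_ap, dtype=float)
    b = np.asarray(rpkm_gp, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("RPKM values must be non-negative")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(total > 0, (a - b) ** 2 / np.where(total > 0, total, 1.0), 0.0)
    p_raw = np.where(total > 0, stats.chi2.sf(chi2, df=1), 1.0)
    p_adj = np.minimum(1.0, p_raw * n_tests)
    if a.ndim == 0:
        return float(p_raw), float(p_adj)
    return p_raw, p_adj


# ---------------------------------------------------------------------------
# classification

def classify(rpkm_ap: float, rpkm_gp: float,
             threshold: float = EXPRESSION_THRESHOLD,
             fold: float = DOMINANCE_FOLD) -> str:
    """Phase category of one gene from its RPKM pair.

    Expressed means RPKM strictly above ``threshold``; a gene expressed in
    both conditions is dominant when one RPKM is at least ``fold`` times the
    other, otherwise shared.
    """
    exp_ap = rpkm_ap > threshold
    exp_gp = rpkm_gp > threshold
    if not exp_ap and not exp_gp:
        return "silent"
    if exp_ap and not exp_gp:
        return "AP_only"
    if exp_gp and not exp_ap:
        return "GP_only"
    if rpkm_ap >= fold * rpkm_gp:
        return "AP_dominant"
    if rpkm_gp >= fold * rpkm_ap:
        return "GP_dominant"
    return "shared"


def build_table(ap_alignments: pd.DataFrame, gp_alignments: pd.DataFrame,
                annotation: pd.DataFrame, total_ap: int | None = None,
                total_gp: int | None = None,
                threshold: float = EXPRESSION_THRESHOLD,
                fold: float = DOMINANCE_FOLD) -> pd.DataFrame:
    """Full per-gene expression table (one row per annotated gene).

    ``total_ap``/``total_gp`` are the per-condition mapped-read totals used
    as RPKM denominators; they default to the alignment counts supplied.
    The Bonferroni family is the set of genes with at least one read in
    either condition.
    """
    anno = annotation.sort_values("start", kind="stable").reset_index(drop=True)
    count_ap = count_reads(ap_alignments, anno)
    count_gp = count_reads(gp_alignments, anno)
    total_ap = int(total_ap) if total_ap is not None else len(ap_alignments)
    total_gp = int(total_gp) if total_gp is not None else len(gp_alignments)
    lengths = (anno["end"] - anno["start"] + 1).to_numpy()

    rpkm_ap = rpkm(count_ap.to_numpy(), lengths, total_ap)
    rpkm_gp = rpkm(count_gp.to_numpy(), lengths, total_gp)
    tested = (count_ap.to_numpy() + count_gp.to_numpy()) > 0
    n_tests = max(1, int(tested.sum()))
    p_raw, p_adj = chi2_differential(rpkm_ap, rpkm_gp, n_tests)

    table = pd.DataFrame({
        "gene_id": anno["gene_id"],
        "length": lengths,
        "count_ap": count_ap.to_numpy(),
        "count_gp": count_gp.to_numpy(),
        "rpkm_ap": rpkm_ap,
        "rpkm_gp": rpkm_gp,
        "expressed_ap": rpkm_ap > threshold,
        "expressed_gp": rpkm_gp > threshold,
        "p_raw": p_raw,
        "p_adj": p_adj,
    })
    table["category"] = [classify(a, b, threshold, fold)
                         for a, b in zip(rpkm_ap, rpkm_gp)]
    table.attrs["n_tests"] = n_tests
    table.attrs["total_ap"] = total_ap
    table.attrs["total_gp"] = total_gp
    return table


def summarize(records: pd.DataFrame | dict) -> dict:
    """Category counts and percentages of expressed genes.

    Accepts a full expression table or a {category: count} mapping.
    Percentages (nearest integer) are over expressed genes, i.e. all
    categories except silent; with nothing expressed they are reported as 0.
    """
    if isinstance(records, pd.DataFrame):
        counts = records["category"].value_counts().to_dict()
    else:
        counts = dict(records)
    counts = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    total = sum(counts.values())
    expressed = total - counts["silent"]
    percent = {}
    for cat in CATEGORIES:
        if cat == "silent":
            continue
        percent[cat] = int(round(100.0 * counts[cat] / expressed)) if expressed else 0
    return {"counts": counts, "percent_of_expressed": percent,
            "total_genes": total, "total_expressed": expressed}


# ---------------------------------------------------------------------------
# GC content

def gc_content(sequence: str) -> float:
    """Fraction of G/C among unambiguous bases (case-insensitive)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    denom = gc + at
    return gc / denom if denom else float("nan")


def gc3_content(coding_sequence: str) -> float:
    """GC fraction at third codon positions of a coding sequence."""
    if not coding_sequence:
        raise ValueError("empty sequence")
    if len(coding_sequence) % 3:
        raise ValueError("coding sequence length must be divisible by 3")
    return gc_content(coding_sequence[2::3])


def compare_gc(ap_values, gp_values) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between two sets of GC fractions."""
    a = np.asarray(ap_values, dtype=float)
    b = np.asarray(gp_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def nearest_int_fold(numerator: float, denominator: float) -> int:
    """Nearest-integer fold ratio, as printed in summary tables."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(round(numerator / denominator))
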