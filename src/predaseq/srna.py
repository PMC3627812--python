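"""Intergenic attack-phase sRNA discovery.

Intergenic regions are screened for >4-fold AP-over-GP expression with a
Bonferroni-corrected chi-square test, apparent long 5'UTRs (expression
connected to a downstream expressed gene) are discarded, transcript
boundaries are fixed from the TSS calls (5' end and strand) and from the
whole-transcriptome coverage (3' end), and the differential test is repeated
on the refined coordinates.  A local ORF-content filter flags candidates
that look protein-coding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expression import chi2_differential, count_reads, rpkm

logger = logging.getLogger(__name__)

FOLD_THRESHOLD = 4.0   # minimum AP/GP fold for the intergenic screen
P_ADJ_THRESHOLD = 0.05

STOP_CODONS = {"TAA", "TAG", "TGA"}


def intergenic_regions(annotation: pd.DataFrame, genome_length: int,
                       min_len: int = 50) -> pd.DataFrame:
    """Complement of the merged gene intervals within [1, genome_length]."""
    regions = []
    pos = 1
    if len(annotation):
        anno = annotation.sort_values("start", kind="stable")
        for row in anno.itertuples(index=False):
            if row.start > pos:
                regions.append((pos, row.start - 1))
            pos = max(pos, row.end + 1)
    if pos <= genome_length:
        regions.append((pos, genome_length))
    df = pd.DataFrame(regions, columns=["start", "end"])
    return df[(df["end"] - df["start"] + 1) >= min_len].reset_index(drop=True)


def fold_with_floor(rpkm_ap: float, rpkm_gp: float, length: int,
                    total_gp: int) -> float:
    """AP/GP RPKM ratio with an epsilon floor of one GP read's RPKM.

    The floor keeps folds finite when the GP signal is zero while preserving
    the ranking of strongly AP-specific candidates.
    """
    eps = 1e9 / (length * total_gp)
    return rpkm_ap / max(rpkm_gp, eps)


def screen_regions(regions: pd.DataFrame, ap_alignments: pd.DataFrame,
                   gp_alignments: pd.DataFrame, totals: tuple[int, int],
                   fold_threshold: float = FOLD_THRESHOLD,
                   p_adj_threshold: float = P_ADJ_THRESHOLD) -> pd.DataFrame:
    """Differential screen of intergenic regions; keeps AP-enriched ones.

    ``totals`` are the per-condition mapped-read totals (RPKM denominators).
    Bonferroni corrects over all screened regions.  Retains regions with
    fold > ``fold_threshold`` and adjusted p <= ``p_adj_threshold``.
    """
    total_ap, total_gp = totals
    regions = regions.sort_values("start", kind="stable").reset_index(drop=True)
    named = regions.copy()
    named["gene_id"] = [f"region{i:05d}" for i in range(len(named))]
    count_ap = count_reads(ap_alignments, named).to_numpy()
    count_gp = count_reads(gp_alignments, named).to_numpy()
    lengths = (regions["end"] - regions["start"] + 1).to_numpy()
    rpkm_ap = rpkm(count_ap, lengths, total_ap)
    rpkm_gp = rpkm(count_gp, lengths, total_gp)
    n_tests = max(1, len(regions))
    _, p_adj = chi2_differential(rpkm_ap, rpkm_gp, n_tests)
    p_adj = np.atleast_1d(p_adj)

    out = regions.copy()
    out["length"] = lengths
    out["count_ap"] = count_ap
    out["count_gp"] = count_gp
    out["rpkm_ap"] = rpkm_ap
    out["rpkm_gp"] = rpkm_gp
    out["fold"] = [fold_with_floor(a, g, l, total_gp)
                   for a, g, l in zip(np.atleast_1d(rpkm_ap), np.atleast_1d(rpkm_gp), lengths)]
    out["p_adj"] = p_adj
    keep = (out["fold"] > fold_threshold) & (out["p_adj"] <= p_adj_threshold)
    return out[keep].reset_index(drop=True)


def exclude_utr_readthrough(candidates: pd.DataFrame, coverage: np.ndarray,
                            annotation: pd.DataFrame, expressed_ap: set,
                            connect_frac: float = 0.25) -> pd.DataFrame:
    """Discard candidates whose expression is connected to a downstream gene.

    A candidate is a putative long 5'UTR (and dropped) when, on its strand,
    the coverage between its 3' end and the next downstream same-strand gene
    start never falls below ``connect_frac`` times the candidate's mean
    coverage AND that gene is AP-expressed.  Candidates without a strand call
    yet are tested on both strands.
    """
    anno = annotation.sort_values("start", kind="stable").reset_index(drop=True)
    keep_rows = []
    for row in candidates.itertuples(index=False):
        strands = [row.strand] if "strand" in candidates.columns else ["+", "-"]
        readthrough = any(
            _connected_downstream(row, s, coverage, anno, expressed_ap, connect_frac)
            for s in strands
        )
        if readthrough:
            logger.info("candidate %d-%d dropped: 5'UTR read-through", row.start, row.end)
        else:
            keep_rows.append(row)
    if not keep_rows:
        return candidates.iloc[0:0].copy()
    return pd.DataFrame(keep_rows).drop(columns="Index", errors="ignore").reset_index(drop=True)


def _connected_downstream(row, strand, coverage, anno, expressed_ap, connect_frac):
    """Coverage never dips between the candidate's expression peak and the
    downstream same-strand gene start (candidate edges may abut the gene, so
    the scan starts at the covered footprint, not the region boundary)."""
    region = coverage[row.start: row.end + 1]
    mean_cov = region.mean()
    if mean_cov == 0:
        return False
    peak_pos = row.start + int(np.argmax(region))
    if strand == "+":
        downstream = anno[(anno["strand"] == "+") & (anno["start"] > row.end)]
        if not len(downstream):
            return False
        gene = downstream.iloc[0]
        lo, hi = peak_pos, gene["start"] - 1
    else:
        downstream = anno[(anno["strand"] == "-") & (anno["end"] < row.start)]
        if not len(downstream):
            return False
        gene = downstream.iloc[-1]
        lo, hi = gene["end"] + 1, peak_pos
    if gene["gene_id"] not in expressed_ap:
        return False
    if hi < lo:
        return True
    return coverage[lo: hi + 1].min() >= connect_frac * mean_cov


def refine_boundaries(candidate, tss_calls: pd.DataFrame, coverage: np.ndarray,
                      end_frac: float = 0.1, persistence: int = 20,
                      tss_slack: int = 50) -> dict | None:
    """Fix a candidate's 5' end from the TSS data and its 3' end from coverage.

    The start is the strongest TSS call inside the raw region or within
    ``tss_slack`` nt upstream of it (strand taken from that call); the end is
    the last position downstream of the start with coverage at least
    ``end_frac`` of the candidate's peak, scanning until coverage stays below
    that floor for ``persistence`` consecutive bases.  RPKM, fold and the
    chi-square test are then recomputed on the refined interval by
    :func:`rescreen_interval`.  Returns None (with a logged reason) when no
    qualifying TSS exists or the refined interval is empty.
    """
    lo, hi = int(candidate.start), int(candidate.end)

    in_window = []
    for rec in tss_calls.itertuples(index=False):
        pos = int(rec.position)
        if rec.strand == "+" and lo - tss_slack <= pos <= hi:
            in_window.append(rec)
        elif rec.strand == "-" and lo <= pos <= hi + tss_slack:
            in_window.append(rec)
    if not in_window:
        logger.info("candidate %d-%d dropped: no qualifying TSS", lo, hi)
        return None
    tss = max(in_window, key=lambda r: r.raw_plus)
    start5 = int(tss.position)
    strand = tss.strand

    step = 1 if strand == "+" else -1
    region_lo, region_hi = min(lo, start5), max(hi, start5)
    peak = coverage[region_lo: region_hi + 1].max()
    if peak <= 0:
        logger.info("candidate %d-%d dropped: no coverage from TSS", lo, hi)
        return None
    floor = end_frac * peak
    end3 = None
    below = 0
    pos = start5
    while 1 <= pos <= len(coverage) - 1:
        if coverage[pos] >= floor:
            end3 = pos
            below = 0
        else:
            below += 1
            if below >= persistence:
                break
        pos += step
    if end3 is None or (end3 - start5) * step <= 0:
        logger.info("candidate %d-%d dropped: refined end at or before start", lo, hi)
        return None

    start, end = (start5, end3) if strand == "+" else (end3, start5)
    length = end - start + 1
    return {"start": start, "end": end, "strand": strand, "size": length,
            "tss_position": start5, "tss_support": int(tss.raw_plus)}


def rescreen_interval(start: int, end: int, ap_alignments: pd.DataFrame,
                      gp_alignments: pd.DataFrame, totals: tuple[int, int],
                      n_tests: int) -> dict:
    """Counts, RPKM, fold and adjusted p on one (refined) interval."""
    total_ap, total_gp = totals
    region = pd.DataFrame({"gene_id": ["x"], "start": [start], "end": [end],
                           "strand": ["+"]})
    count_ap = int(count_reads(ap_alignments, region).iloc[0])
    count_gp = int(count_reads(gp_alignments, region).iloc[0])
    length = end - start + 1
    r_ap = rpkm(count_ap, length, total_ap)
    r_gp = rpkm(count_gp, length, total_gp)
    _, p_adj = chi2_differential(r_ap, r_gp, max(1, n_tests))
    return {"count_ap": count_ap, "count_gp": count_gp, "rpkm_ap": r_ap,
            "rpkm_gp": r_gp,
            "fold": fold_with_floor(r_ap, r_gp, length, total_gp),
            "p_adj": float(p_adj)}


def orf_filter(sequence: str, max_orf_aa: int = 50) -> bool:
    """True (flag for exclusion) when the sense strand holds a closed ORF of
    at least ``max_orf_aa`` codons (ATG..stop, any frame, stop excluded)."""
    seq = sequence.upper()
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i: i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in STOP_CODONS and start is not None:
                if (i - start) // 3 >= max_orf_aa:
                    return True
                start = None
    return False


def annotate_promoter(candidate, motif, promoters: dict) -> bool:
    """True iff the candidate's 50-base promoter contains the two-box motif.

    ``promoters`` maps (tss_position, strand) -> promoter sequence.  The
    candidate must carry a TSS (refined start); its absence is an error.
    """
    from .motif import scan

    key = (int(candidate["tss_position"]), candidate["strand"])
    if key not in promoters:
        raise ValueError(f"candidate has no promoter sequence at {key}")
    if motif is None:
        return False
    return scan(promoters[key], motif) is not None


def discover_srnas(annotation: pd.DataFrame, genome: str,
                   ap_alignments: pd.DataFrame, gp_alignments: pd.DataFrame,
                   tss_calls: pd.DataFrame, totals: tuple[int, int],
                   expressed_ap: set, motif=None,
                   min_len: int = 50, fold_threshold: float = FOLD_THRESHOLD,
                   end_frac: float = 0.1, connect_frac: float = 0.25,
                   max_orf_aa: int = 50) -> pd.DataFrame:
    """End-to-end intergenic sRNA discovery; returns the final candidate table.

    ``tss_calls`` should be the annotation-free enriched-position set
    (``call_tss(..., annotation=None)``): intergenic transcripts are by
    definition not upstream of a gene.  Columns mirror the summary-table
    layout: name, start, end, strand, size, rpkm_ap, rpkm_gp, fold (nearest
    integer reported separately), p_adj, has_tss, fliA_promoter,
    orf_filtered.  Candidates failing the refined re-screen, the
    read-through rule or lacking a TSS are dropped; ORF-bearing candidates
    are kept but flagged.
    """
    from .io import reverse_complement
    from .tss import assign_genes, extract_promoters

    # enriched positions explained as a gene promoter are mRNA TSSs, not sRNAs
    if len(tss_calls):
        tss_calls = tss_calls[assign_genes(tss_calls, annotation).isna()].reset_index(drop=True)

    genome_length = len(genome)
    regions = intergenic_regions(annotation, genome_length, min_len=min_len)
    screened = screen_regions(regions, ap_alignments, gp_alignments, totals,
                              fold_threshold=fold_threshold)
    coverage = _coverage(ap_alignments, genome_length)
    screened = exclude_utr_readthrough(screened, coverage, annotation,
                                       expressed_ap, connect_frac=connect_frac)
    n_tests = max(1, len(regions))
    rows = []
    for cand in screened.itertuples(index=False):
        refined = refine_boundaries(cand, tss_calls, coverage, end_frac=end_frac)
        if refined is None:
            continue
        stats = rescreen_interval(refined["start"], refined["end"],
                                  ap_alignments, gp_alignments, totals, n_tests)
        if stats["fold"] <= fold_threshold or stats["p_adj"] > P_ADJ_THRESHOLD:
            logger.info("refined candidate %d-%d dropped on re-screen",
                        refined["start"], refined["end"])
            continue
        seq = genome[refined["start"] - 1: refined["end"]]
        if refined["strand"] == "-":
            seq = reverse_complement(seq)
        fliA = False
        if motif is not None:
            own_call = pd.DataFrame({"position": [refined["tss_position"]],
                                     "strand": [refined["strand"]]})
            promoters = extract_promoters(own_call, genome)
            if promoters:
                fliA = annotate_promoter(refined, motif, promoters)
        rows.append({
            "start": refined["start"], "end": refined["end"],
            "strand": refined["strand"], "size": refined["size"],
            "rpkm_ap": stats["rpkm_ap"], "rpkm_gp": stats["rpkm_gp"],
            "fold": stats["fold"], "p_adj": stats["p_adj"],
            "has_tss": True, "fliA_promoter": bool(fliA),
            "orf_filtered": orf_filter(seq, max_orf_aa=max_orf_aa),
            "sequence": seq,
        })
    out = pd.DataFrame(rows, columns=["start", "end", "strand", "size", "rpkm_ap",
                                      "rpkm_gp", "fold", "p_adj", "has_tss",
                                      "fliA_promoter", "orf_filtered", "sequence"])
    out = out.sort_values("start", kind="stable").reset_index(drop=True)
    out.insert(0, "name", [f"APsRNA{i + 1}" for i in range(len(out))])
    return out


def _coverage(reads: pd.DataFrame, genome_length: int) -> np.ndarray:
    from .io import coverage_from_reads
    return coverage_from_reads(reads, genome_length)
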