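"""Synthetic dual-phase transcriptome bundles with known ground truth.

Generates a toy predatory-bacterium genome in which attack-phase (AP) and
growth-phase (GP) transcriptional programs are planted explicitly: genes are
laid out in program-homogeneous clusters, every non-silent gene gets a
transcription start site (TSS) 20-150 nt upstream of its first codon, a
fraction of AP promoters carries the two-box sigma-28 element
(TTAAG-N16-CCGATA, -10 box ending 7 nt before the TSS), and intergenic small
RNAs with extreme AP/GP fold differences are planted between gene clusters.

Whole-transcriptome alignments are drawn multinomially over transcripts with
uniform read starts, and the paired TAP(+)/TAP(-) 5'-end tracks put
Poisson-distributed counts at every planted TSS (enriched in TAP(+)) and at
processed 5' ends (equal in both libraries).

Expected expression is parameterized directly in RPKM units.  Because all
reads map to transcripts, each condition's RPKM values are constrained to
sum (weighted by length) to 1e9; planted fold changes are therefore made
exact in expectation by scaling the condition-exclusive gene sets until the
two conditions carry equal transcript mass.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .tss import FivePrimeTrack

CHROM = "synth1"

PROGRAMS = ("AP_only", "GP_only", "AP_dominant", "GP_dominant", "shared", "silent")

#: two-box promoter element planted in motif-bearing promoters
MOTIF_BOX35 = "TTAAG"
MOTIF_BOX10 = "CCGATA"
MOTIF_SPACER = 16
#: gap between the 3' end of the -10 box and the TSS (canonical discriminator)
DISCRIMINATOR = 7

_DEFAULT_FRACTIONS = {
    # category counts 353 / 1557 / 114 / 66 / 250 among 2340 expressed genes,
    # with 65% of the genome expressed (=> 3600 genes total, 1260 silent)
    "AP_only": 353 / 3600,
    "GP_only": 1557 / 3600,
    "AP_dominant": 114 / 3600,
    "GP_dominant": 66 / 3600,
    "shared": 250 / 3600,
    "silent": 1260 / 3600,
}


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic bundle.

    Defaults emulate the study design at desk scale: 36 bp reads, two
    unstranded whole-transcriptome libraries, paired TAP(+)/TAP(-) 5'-end
    tracks with 10-fold primary-end enrichment, two-thirds of AP promoters
    carrying the two-box element, and eight planted intergenic sRNAs spanning
    16- to 5300-fold AP/GP differences.
    """

    genome_length: int = 100_000
    n_genes: int = 90
    program_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    mean_gene_length: int = 650
    read_length: int = 36
    library_size_ap: int = 500_000
    library_size_gp: int = 500_000
    tap_plus_depth: int = 130_000
    tap_minus_depth: int = 100_000
    tss_enrichment_factor: float = 10.0
    processed_site_rate: float = 20.0  # non-TSS 5' ends per kb
    motif_fraction: float = 0.66
    srna_motif_fraction: float = 3 / 8
    n_srnas: int = 8
    srna_fold_range: tuple = (16.0, 5300.0)
    gc_ap: float = 0.52
    gc_gp: float = 0.49
    stray_read_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.program_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"program_fractions sum to {total}, expected 1")
        if set(self.program_fractions) - set(PROGRAMS):
            raise ValueError(f"unknown programs: {set(self.program_fractions) - set(PROGRAMS)}")
        if self.read_length >= self.mean_gene_length:
            raise ValueError("read_length must be smaller than mean_gene_length")
        if self.library_size_ap <= 0 or self.library_size_gp <= 0:
            raise ValueError("library sizes must be positive")
        if self.tap_plus_depth < 0 or self.tap_minus_depth < 0:
            raise ValueError("track depths must be non-negative")
        if not (0 <= self.motif_fraction <= 1):
            raise ValueError("motif_fraction must be a fraction")


@dataclass
class GroundTruth:
    """Planted truth for one bundle.

    ``genes`` holds the gene models (1-based inclusive) with their program;
    ``true_tss`` rows are (position, strand, gene_ids, has_motif);
    ``true_srnas`` rows are (name, start, end, strand, fold, has_motif);
    ``rpkm_ap``/``rpkm_gp`` map every transcript (gene or sRNA) to its
    expected RPKM in each condition.
    """

    genes: pd.DataFrame
    gene_programs: dict
    true_tss: pd.DataFrame
    true_srnas: pd.DataFrame
    rpkm_ap: dict
    rpkm_gp: dict

    def transcripts(self) -> pd.DataFrame:
        """All transcribed units (genes + sRNAs) as one interval table."""
        gene_part = self.genes[["gene_id", "start", "end", "strand"]].rename(
            columns={"gene_id": "name"})
        if len(self.true_srnas):
            srna_part = self.true_srnas[["name", "start", "end", "strand"]]
            return pd.concat([gene_part, srna_part], ignore_index=True)
        return gene_part

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "gene_programs": self.gene_programs,
            "true_tss": self.true_tss.to_dict(orient="records"),
            "true_srnas": self.true_srnas.to_dict(orient="records"),
            "rpkm_ap": self.rpkm_ap,
            "rpkm_gp": self.rpkm_gp,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        gene_cols = ["gene_id", "start", "end", "strand", "program"]
        tss_cols = ["position", "strand", "gene_ids", "has_motif"]
        srna_cols = ["name", "start", "end", "strand", "fold", "has_motif"]
        return cls(
            genes=pd.DataFrame(payload["genes"], columns=gene_cols),
            gene_programs=payload["gene_programs"],
            true_tss=pd.DataFrame(payload["true_tss"], columns=tss_cols),
            true_srnas=pd.DataFrame(payload["true_srnas"], columns=srna_cols),
            rpkm_ap=payload["rpkm_ap"],
            rpkm_gp=payload["rpkm_gp"],
        )


# ---------------------------------------------------------------------------
# helpers

def _rng(spec: SimulationSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, spec.seed])


def _program_counts(fractions: dict, n: int) -> dict:
    """Largest-remainder apportionment of n genes over programs."""
    raw = {p: fractions.get(p, 0.0) * n for p in PROGRAMS}
    counts = {p: int(math.floor(v)) for p, v in raw.items()}
    short = n - sum(counts.values())
    for p in sorted(PROGRAMS, key=lambda p: raw[p] - counts[p], reverse=True)[:short]:
        counts[p] += 1
    return counts


def _log_uniform(rng, low, high, size=None):
    return np.exp(rng.uniform(np.log(low), np.log(high), size))


def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    bases = np.array(list("ACGT"))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bases[rng.choice(4, size=length, p=p)]


# ---------------------------------------------------------------------------
# genome generation

def generate_genome(spec: SimulationSpec) -> tuple[str, pd.DataFrame, GroundTruth]:
    """Build genome sequence, annotation, and ground truth.

    Returns ``(genome_sequence, annotation, truth)``.  The annotation is a
    DataFrame (gene_id, start, end, strand, program); serialize it without the
    program column for blind analysis runs.
    """
    spec.validate()
    rng = _rng(spec, 1)
    L = spec.genome_length

    empty_genes = pd.DataFrame(columns=["gene_id", "start", "end", "strand", "program"])
    empty_tss = pd.DataFrame(columns=["position", "strand", "gene_ids", "has_motif"])
    empty_srna = pd.DataFrame(columns=["name", "start", "end", "strand", "fold", "has_motif"])
    if spec.n_genes == 0:
        seq = "".join(_random_seq(rng, L, 0.5))
        truth = GroundTruth(empty_genes, {}, empty_tss, empty_srna, {}, {})
        return seq, empty_genes, truth

    # --- program multiset, clustered into program-homogeneous runs
    counts = _program_counts(spec.program_fractions, spec.n_genes)
    remaining = dict(counts)
    clusters: list[tuple[str, int, str]] = []  # (program, run_length, strand)
    while sum(remaining.values()) > 0:
        progs = [p for p in PROGRAMS if remaining[p] > 0]
        weights = np.array([remaining[p] for p in progs], dtype=float)
        prog = progs[rng.choice(len(progs), p=weights / weights.sum())]
        run = int(min(rng.integers(3, 11), remaining[prog]))
        strand = "+" if rng.random() < 0.5 else "-"
        clusters.append((prog, run, strand))
        remaining[prog] -= run

    # --- gene lengths (codon multiples)
    lengths = rng.gamma(8.0, spec.mean_gene_length / 8.0, size=spec.n_genes)
    lengths = np.clip(lengths, max(150, spec.read_length + 30), 4 * spec.mean_gene_length)
    lengths = (np.round(lengths / 3).astype(int) * 3)

    # --- sRNA slots interleaved between clusters
    srna_lengths = rng.integers(100, 451, size=spec.n_srnas)
    slot_after = set()
    if spec.n_srnas > 0 and len(clusters) > 1:
        k = min(spec.n_srnas, len(clusters) - 1)
        slot_after = set(rng.choice(len(clusters) - 1, size=k, replace=False))

    # --- walk left to right; gaps leave room for one promoter each
    gene_rows, srna_rows = [], []
    pos = 250  # leading margin keeps first promoter on the contig
    gi = si = 0
    prev_strand = None
    for ci, (prog, run, strand) in enumerate(clusters):
        for j in range(run):
            if prev_strand == "-" and strand == "+" and j == 0:
                gap = int(rng.integers(430, 601))  # two promoters share this gap
            else:
                gap = int(rng.integers(210, 401))
            start = pos + gap
            end = start + int(lengths[gi]) - 1
            gene_rows.append({
                "gene_id": f"g{gi + 1:04d}", "start": start, "end": end,
                "strand": strand, "program": prog,
            })
            pos = end
            prev_strand = strand
            gi += 1
        if ci in slot_after and si < spec.n_srnas:
            gap = int(rng.integers(210, 401))
            slen = int(srna_lengths[si])
            s_start = pos + gap + 80
            s_end = s_start + slen - 1
            srna_rows.append({
                "name": f"srna{si + 1:02d}", "start": s_start, "end": s_end,
                "strand": "+" if rng.random() < 0.5 else "-",
            })
            pos = s_end + 80
            prev_strand = None
            si += 1
    # leftover sRNAs (fewer cluster boundaries than requested) go at the tail
    while si < spec.n_srnas:
        gap = int(rng.integers(210, 401))
        slen = int(srna_lengths[si])
        s_start = pos + gap + 80
        s_end = s_start + slen - 1
        srna_rows.append({"name": f"srna{si + 1:02d}", "start": s_start,
                          "end": s_end, "strand": "+" if rng.random() < 0.5 else "-"})
        pos = s_end + 80
        si += 1

    needed = pos + 250
    if needed > L:
        raise ValueError(
            f"cannot place {spec.n_genes} genes and {spec.n_srnas} sRNAs: "
            f"layout needs {needed} bases but genome_length is {L}")

    genes = pd.DataFrame(gene_rows)
    srnas = pd.DataFrame(srna_rows, columns=["name", "start", "end", "strand"])

    # --- genome sequence: background, then program-specific gene composition
    gc_mid = 0.5 * (spec.gc_ap + spec.gc_gp)
    seq = _random_seq(rng, L, 0.5)
    gc_of = {"AP_only": spec.gc_ap, "AP_dominant": spec.gc_ap,
             "GP_only": spec.gc_gp, "GP_dominant": spec.gc_gp,
             "shared": gc_mid, "silent": gc_mid}
    for row in genes.itertuples(index=False):
        glen = row.end - row.start + 1
        seq[row.start - 1: row.end] = _random_seq(rng, glen, gc_of[row.program])

    # --- expression levels (expected RPKM, exact in expectation; see module docstring)
    rpkm_ap, rpkm_gp = _draw_levels(genes, srnas, spec, rng)

    # --- plant TSSs and promoters
    tss_rows = []
    for row in genes.itertuples(index=False):
        if row.program == "silent":
            continue
        d = int(rng.integers(20, 151))
        tss = row.start - d if row.strand == "+" else row.end + d
        is_ap = row.program in ("AP_only", "AP_dominant")
        has_motif = bool(is_ap and rng.random() < spec.motif_fraction)
        if has_motif:
            _plant_motif(seq, tss, row.strand)
        tss_rows.append({"position": int(tss), "strand": row.strand,
                         "gene_ids": [row.gene_id], "has_motif": has_motif})
    for row in srnas.itertuples(index=False):
        tss = row.start if row.strand == "+" else row.end
        has_motif = bool(rng.random() < spec.srna_motif_fraction)
        if has_motif:
            _plant_motif(seq, tss, row.strand)
        tss_rows.append({"position": int(tss), "strand": row.strand,
                         "gene_ids": [row.name], "has_motif": has_motif})
    true_tss = pd.DataFrame(tss_rows, columns=["position", "strand", "gene_ids", "has_motif"])
    true_tss = true_tss.sort_values("position", kind="stable").reset_index(drop=True)

    # --- planted sRNA folds (expected RPKM ratio)
    if len(srnas):
        srnas = srnas.copy()
        srnas["fold"] = [rpkm_ap[n] / rpkm_gp[n] for n in srnas["name"]]
        srnas["has_motif"] = [
            bool(true_tss.loc[[n in ids for ids in true_tss["gene_ids"]], "has_motif"].iloc[0])
            for n in srnas["name"]
        ]
    else:
        srnas = empty_srna

    truth = GroundTruth(
        genes=genes,
        gene_programs=dict(zip(genes["gene_id"], genes["program"])),
        true_tss=true_tss,
        true_srnas=srnas,
        rpkm_ap=rpkm_ap,
        rpkm_gp=rpkm_gp,
    )
    _check_label_consistency(truth)
    return "".join(seq), genes, truth


def _plant_motif(seq: np.ndarray, tss: int, strand: str,
                 spacer: int = MOTIF_SPACER) -> None:
    """Write TTAAG-N{spacer}-CCGATA into the promoter of ``tss`` (1-based)."""
    if strand == "+":
        b10_start = tss - DISCRIMINATOR - len(MOTIF_BOX10)  # -10 box ends 7 nt before TSS
        b35_start = b10_start - spacer - len(MOTIF_BOX35)
        seq[b35_start - 1: b35_start - 1 + 5] = list(MOTIF_BOX35)
        seq[b10_start - 1: b10_start - 1 + 6] = list(MOTIF_BOX10)
    else:
        b10_end = tss + DISCRIMINATOR + len(MOTIF_BOX10)
        b35_end = b10_end + spacer + len(MOTIF_BOX35)
        seq[b10_end - 6: b10_end] = list(pio.reverse_complement(MOTIF_BOX10))
        seq[b35_end - 5: b35_end] = list(pio.reverse_complement(MOTIF_BOX35))


def _draw_levels(genes: pd.DataFrame, srnas: pd.DataFrame, spec: SimulationSpec,
                 rng: np.random.Generator) -> tuple[dict, dict]:
    """Expected RPKM per transcript per condition.

    Raw levels are drawn per program with margins well clear of the
    classification thresholds (expression > 50 RPKM, 5-fold dominance), then
    the condition-exclusive gene sets are scaled so both conditions carry
    equal raw transcript mass; a final common factor maps raw mass to the
    1e9 RPKM-mass constraint, preserving every planted fold exactly.
    """
    ap, gp = {}, {}
    for row in genes.itertuples(index=False):
        prog = row.program
        if prog == "AP_only":
            ap[row.gene_id], gp[row.gene_id] = float(_log_uniform(rng, 300, 3000)), 0.0
        elif prog == "GP_only":
            ap[row.gene_id], gp[row.gene_id] = 0.0, float(_log_uniform(rng, 300, 3000))
        elif prog == "AP_dominant":
            weak = float(_log_uniform(rng, 250, 600))
            ap[row.gene_id] = weak * float(_log_uniform(rng, 8, 30))
            gp[row.gene_id] = weak
        elif prog == "GP_dominant":
            weak = float(_log_uniform(rng, 250, 600))
            ap[row.gene_id] = weak
            gp[row.gene_id] = weak * float(_log_uniform(rng, 8, 30))
        elif prog == "shared":
            a = float(_log_uniform(rng, 450, 1500))
            ap[row.gene_id], gp[row.gene_id] = a, a * float(_log_uniform(rng, 0.55, 1.8))
        else:  # silent
            ap[row.gene_id], gp[row.gene_id] = 0.0, 0.0
    for row in srnas.itertuples(index=False):
        a = float(_log_uniform(rng, 4e3, 2e5))
        fold = float(_log_uniform(rng, *spec.srna_fold_range))
        ap[row.name], gp[row.name] = a, a / fold

    lengths = dict(zip(genes["gene_id"], genes["end"] - genes["start"] + 1))
    lengths.update(zip(srnas["name"], srnas["end"] - srnas["start"] + 1))

    mass_ap = sum(ap[t] * lengths[t] for t in ap)
    mass_gp = sum(gp[t] * lengths[t] for t in gp)
    target = max(mass_ap, mass_gp)
    ap_only = set(genes.loc[genes["program"] == "AP_only", "gene_id"])
    gp_only = set(genes.loc[genes["program"] == "GP_only", "gene_id"])
    for side, mass, excl, levels in (("AP", mass_ap, ap_only, ap),
                                     ("GP", mass_gp, gp_only, gp)):
        if mass >= target or target == 0:
            continue
        excl_mass = sum(levels[t] * lengths[t] for t in excl)
        if excl_mass <= 0:
            warnings.warn(
                f"no {side}-exclusive transcript mass to balance conditions; "
                "planted folds will carry a common multiplicative bias")
            continue
        scale = 1.0 + (target - mass) / excl_mass
        for t in excl:
            levels[t] *= scale

    # common raw->RPKM factor (both conditions now carry mass `target`)
    if target > 0:
        k = 1e9 / target
        ap = {t: v * k for t, v in ap.items()}
        gp = {t: v * k for t, v in gp.items()}
    return ap, gp


def _check_label_consistency(truth: GroundTruth) -> None:
    from .expression import classify
    for row in truth.genes.itertuples(index=False):
        cat = classify(truth.rpkm_ap[row.gene_id], truth.rpkm_gp[row.gene_id])
        if cat != row.program:
            warnings.warn(
                f"planted program of {row.gene_id} ({row.program}) disagrees with its "
                f"expected-RPKM category ({cat}); check spec levels/fractions")


# ---------------------------------------------------------------------------
# whole-transcriptome alignments

def simulate_alignments(genome: str, truth: GroundTruth,
                        spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate AP and GP read alignments (1-based inclusive intervals).

    Read counts are multinomial over transcripts with probabilities
    proportional to expected RPKM x length; starts are uniform within each
    transcript so every read lies fully inside it.  An optional stray-read
    fraction is scattered uniformly over the genome.
    """
    spec.validate()
    rng = _rng(spec, 2)
    out = []
    tx = truth.transcripts()
    for levels, n_reads in ((truth.rpkm_ap, spec.library_size_ap),
                            (truth.rpkm_gp, spec.library_size_gp)):
        out.append(_simulate_one_library(tx, levels, n_reads, spec, rng))
    return out[0], out[1]


def _simulate_one_library(tx: pd.DataFrame, levels: dict, n_reads: int,
                          spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    rl = spec.read_length
    L = spec.genome_length
    n_stray = int(round(n_reads * spec.stray_read_rate))
    n_tx_reads = n_reads - n_stray

    starts_list, strands_list = [], []
    if len(tx):
        lens = (tx["end"] - tx["start"] + 1).to_numpy(dtype=float)
        weights = np.array([levels.get(n, 0.0) for n in tx["name"]]) * lens
        if weights.sum() > 0:
            p = weights / weights.sum()
            counts = rng.multinomial(n_tx_reads, p)
            for (row, cnt) in zip(tx.itertuples(index=False), counts):
                if cnt == 0:
                    continue
                hi = max(row.start, row.end - rl + 1)
                starts_list.append(rng.integers(row.start, hi + 1, size=cnt))
                strands_list.append(np.full(cnt, row.strand))
    if n_stray > 0:
        starts_list.append(rng.integers(1, L - rl + 2, size=n_stray))
        strands_list.append(np.where(rng.random(n_stray) < 0.5, "+", "-"))

    if not starts_list:
        return pd.DataFrame(columns=["start", "end", "strand"])
    starts = np.concatenate(starts_list)
    strands = np.concatenate(strands_list)
    order = np.argsort(starts, kind="stable")
    return pd.DataFrame({
        "start": starts[order].astype(np.int64),
        "end": (starts[order] + rl - 1).astype(np.int64),
        "strand": strands[order],
    })


# ---------------------------------------------------------------------------
# 5'-end tracks

def simulate_5prime_tracks(truth: GroundTruth,
                           spec: SimulationSpec) -> tuple[FivePrimeTrack, FivePrimeTrack]:
    """Paired TAP(+)/TAP(-) per-position 5'-end count tracks.

    Every planted TSS receives Poisson counts enriched ``tss_enrichment_factor``
    fold in TAP(+); processed sites receive equal expected counts in both
    libraries.  Per-track intensities are scaled so expected totals match the
    requested depths.
    """
    spec.validate()
    rng = _rng(spec, 3)
    L = spec.genome_length
    n_proc = int(round(spec.processed_site_rate * L / 1000.0))
    if len(truth.true_tss) == 0 and n_proc == 0:
        raise ValueError("no TSSs planted and processed_site_rate is 0: tracks would be empty")

    tss_pos = truth.true_tss["position"].to_numpy(dtype=np.int64)
    tss_strand = truth.true_tss["strand"].to_numpy()
    taken = set(zip(tss_pos.tolist(), tss_strand.tolist()))

    proc_pos = rng.integers(1, L + 1, size=n_proc)
    proc_strand = np.where(rng.random(n_proc) < 0.5, "+", "-")
    keep = np.array([(int(p), s) not in taken for p, s in zip(proc_pos, proc_strand)],
                    dtype=bool) if n_proc else np.zeros(0, dtype=bool)
    proc_pos, proc_strand = proc_pos[keep], proc_strand[keep]

    pos = np.concatenate([tss_pos, proc_pos])
    strand = np.concatenate([tss_strand, proc_strand])
    base = rng.uniform(1.0, 3.0, size=len(pos))  # per-site intensity heterogeneity
    is_tss = np.zeros(len(pos), dtype=bool)
    is_tss[: len(tss_pos)] = True

    w_plus = np.where(is_tss, base * spec.tss_enrichment_factor, base)
    w_minus = base
    tracks = []
    for weights, depth, treatment in ((w_plus, spec.tap_plus_depth, "TAP_plus"),
                                      (w_minus, spec.tap_minus_depth, "TAP_minus")):
        if depth <= 0 or weights.sum() == 0:
            counts = np.zeros(len(pos), dtype=np.int64)
        else:
            lam = weights / weights.sum() * depth
            counts = rng.poisson(lam)
        nz = counts > 0
        df = pd.DataFrame({"position": pos[nz], "strand": strand[nz],
                           "count": counts[nz]})
        df = df.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)
        tracks.append(FivePrimeTrack(counts=df, treatment=treatment))
    return tracks[0], tracks[1]


# ---------------------------------------------------------------------------
# bundle serialization

BUNDLE_FILES = {
    "genome": "genome.fa",
    "annotation": "annotation.gff3",
    "annotation_truth": "annotation.truth.gff3",
    "ap_reads": "ap.bed",
    "gp_reads": "gp.bed",
    "tap_plus_fwd": "tap_plus.fwd.bedgraph",
    "tap_plus_rev": "tap_plus.rev.bedgraph",
    "tap_minus_fwd": "tap_minus.fwd.bedgraph",
    "tap_minus_rev": "tap_minus.rev.bedgraph",
    "ground_truth": "ground_truth.json",
}


def write_bundle(spec: SimulationSpec, outdir: str | os.PathLike) -> dict:
    """Generate a full bundle and serialize it; returns the file map."""
    os.makedirs(outdir, exist_ok=True)
    genome, genes, truth = generate_genome(spec)
    ap_reads, gp_reads = simulate_alignments(genome, truth, spec)
    tap_plus, tap_minus = simulate_5prime_tracks(truth, spec)

    paths = {k: os.path.join(outdir, v) for k, v in BUNDLE_FILES.items()}
    pio.write_fasta(paths["genome"], CHROM, genome)
    pio.write_gff3(paths["annotation"], genes[["gene_id", "start", "end", "strand"]], CHROM)
    pio.write_gff3(paths["annotation_truth"], genes, CHROM)
    pio.write_bed6(paths["ap_reads"], ap_reads, CHROM)
    pio.write_bed6(paths["gp_reads"], gp_reads, CHROM)
    for track, key in ((tap_plus, "tap_plus"), (tap_minus, "tap_minus")):
        for strand, suffix in (("+", "fwd"), ("-", "rev")):
            sub = track.counts[track.counts["strand"] == strand]
            pio.write_bedgraph(paths[f"{key}_{suffix}"], sub["position"].to_numpy(),
                               sub["count"].to_numpy(), CHROM)
    truth.to_json(paths["ground_truth"])
    with open(os.path.join(outdir, "spec.json"), "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=1, default=list)
    return paths
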