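"""Pipeline orchestration and static report rendering.

``run_all`` executes expression calling, TSS/promoter mapping, motif
discovery and sRNA detection against files on disk, serializing every
stage's tables (with reproducibility metadata headers) and a static HTML
report with a per-gene AP/GP expression track.
"""

from __future__ import annotations

import base64
import dataclasses
import hashlib
import io as _io
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import expression as xpr
from . import io as pio
from . import motif as mtf
from . import srna as srn
from . import tss as tssmod

logger = logging.getLogger("predaseq")

_PARAM_DEFAULTS = {
    "expression_threshold": 50.0,
    "dominance_fold": 5.0,
    "tss_min_reads": 5,
    "tss_min_enrichment": 3.0,
    "tss_max_upstream": 300,
    "dedup_window": 5,
    "operon_max_gap": 50,
    "operon_connect_frac": 0.25,
    "promoter_len": 50,
    "motif_spacer_min": 14,
    "motif_spacer_max": 18,
    "motif_n_iter": 20,
    "srna_min_len": 50,
    "srna_fold_threshold": 4.0,
    "srna_end_frac": 0.1,
    "srna_connect_frac": 0.25,
    "srna_max_orf_aa": 50,
}


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    genome: str
    annotation: str
    ap_reads: str
    gp_reads: str
    tap_plus_fwd: str
    tap_plus_rev: str
    tap_minus_fwd: str
    tap_minus_rev: str
    outdir: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def param(self, name):
        return self.params.get(name, _PARAM_DEFAULTS[name])

    def metadata(self) -> dict:
        fields = dataclasses.asdict(self)
        fields.pop("outdir")  # where results land must not change what they are
        payload = json.dumps(fields, sort_keys=True, default=str)
        overrides = {k: v for k, v in self.params.items()
                     if k in _PARAM_DEFAULTS and v != _PARAM_DEFAULTS[k]}
        return {
            "tool": f"predaseq {__version__}",
            "config_hash": hashlib.md5(payload.encode()).hexdigest(),
            "seed": self.seed,
            "overrides": json.dumps(overrides, sort_keys=True) or "{}",
        }

    @classmethod
    def from_bundle(cls, bundle_dir: str, outdir: str, seed: int = 0,
                    params: dict | None = None) -> "RunConfig":
        from .simulate import BUNDLE_FILES
        paths = {k: os.path.join(bundle_dir, v) for k, v in BUNDLE_FILES.items()}
        return cls(genome=paths["genome"], annotation=paths["annotation"],
                   ap_reads=paths["ap_reads"], gp_reads=paths["gp_reads"],
                   tap_plus_fwd=paths["tap_plus_fwd"], tap_plus_rev=paths["tap_plus_rev"],
                   tap_minus_fwd=paths["tap_minus_fwd"], tap_minus_rev=paths["tap_minus_rev"],
                   outdir=outdir, seed=seed, params=params or {})


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(f"stage '{stage}' needs missing input: {path}")
    return path


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of result objects and table paths."""
    os.makedirs(config.outdir, exist_ok=True)
    meta = config.metadata()
    out = lambda name: os.path.join(config.outdir, name)

    # ---- inputs
    _, genome = pio.read_fasta(_require(config.genome, "expression"))
    annotation = pio.read_gff3(_require(config.annotation, "expression"))
    if not len(annotation):
        raise ValueError(f"annotation {config.annotation} contains no genes")
    ap_reads = pio.read_bed6(_require(config.ap_reads, "expression"))
    gp_reads = pio.read_bed6(_require(config.gp_reads, "expression"))
    chrom = ap_reads["chrom"].iloc[0] if len(ap_reads) else "chr"

    # ---- expression
    logger.info("[expression] counting %d + %d reads over %d genes",
                len(ap_reads), len(gp_reads), len(annotation))
    table = xpr.build_table(ap_reads, gp_reads, annotation,
                            threshold=config.param("expression_threshold"),
                            fold=config.param("dominance_fold"))
    summary = xpr.summarize(table)
    pio.write_table(out("expression.tsv"), table, meta)
    with open(out("program_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)

    # ---- coverage tracks
    L = len(genome)
    cov_ap = pio.coverage_from_reads(ap_reads, L)
    cov_gp = pio.coverage_from_reads(gp_reads, L)
    for cov, name in ((cov_ap, "coverage_ap.bedgraph"), (cov_gp, "coverage_gp.bedgraph")):
        nz = np.nonzero(cov[1:])[0] + 1
        pio.write_bedgraph(out(name), nz, cov[nz], chrom)

    # ---- TSS + promoters
    tap_plus = tssmod.FivePrimeTrack.from_bedgraphs(
        _require(config.tap_plus_fwd, "tss"), _require(config.tap_plus_rev, "tss"),
        "TAP_plus")
    tap_minus = tssmod.FivePrimeTrack.from_bedgraphs(
        _require(config.tap_minus_fwd, "tss"), _require(config.tap_minus_rev, "tss"),
        "TAP_minus")
    calls = tssmod.call_tss(tap_plus, tap_minus, annotation,
                            min_reads=config.param("tss_min_reads"),
                            min_enrichment=config.param("tss_min_enrichment"),
                            max_upstream=config.param("tss_max_upstream"))
    calls = tssmod.deduplicate(calls, window=config.param("dedup_window"))
    expressed_any = set(table.loc[table["category"] != "silent", "gene_id"])
    calls = calls[calls["gene_id"].isin(expressed_any)].reset_index(drop=True)
    operons = tssmod.assign_operons(calls, annotation, cov_ap,
                                    max_gap=config.param("operon_max_gap"),
                                    connect_frac=config.param("operon_connect_frac"))
    promoters = tssmod.extract_promoters(calls, genome,
                                         upstream_len=config.param("promoter_len"))
    logger.info("[tss] %d calls after deduplication and curation", len(calls))

    # ---- motif discovery on AP-specific promoters
    ap_specific = set(table.loc[table["category"].isin(["AP_only", "AP_dominant"]),
                                "gene_id"])
    ap_keys = [(int(r.position), r.strand) for r in calls.itertuples(index=False)
               if r.gene_id in ap_specific]
    ap_promoters = [promoters[k] for k in ap_keys if k in promoters]
    motif = None
    if len(ap_promoters) >= 20:
        motif = mtf.discover(ap_promoters,
                             spacer_range=(config.param("motif_spacer_min"),
                                           config.param("motif_spacer_max")),
                             n_iter=config.param("motif_n_iter"))
    if motif is not None:
        mtf.write_meme(motif, out("motif.meme"))
        pio.write_table(out("motif_logo.tsv"), mtf.logo_matrix(motif), meta)
        frac, percent = mtf.prevalence(ap_promoters, motif)
        logger.info("[motif] consensus %s-N%d-%s in %d%% of AP promoters",
                    *motif.consensus()[:1], motif.modal_spacer(),
                    motif.consensus()[1], percent)
    else:
        frac, percent = 0.0, 0
        logger.info("[motif] no motif discovered (%d AP promoters)", len(ap_promoters))

    # ---- TSS table (with motif status and operon gene lists)
    motif_status = []
    for rec in calls.itertuples(index=False):
        key = (int(rec.position), rec.strand)
        hit = (motif is not None and key in promoters
               and mtf.scan(promoters[key], motif) is not None)
        motif_status.append(hit)
    tss_table = calls.copy()
    tss_table["operon_genes"] = [",".join(operons.get((int(r.position), r.strand), []))
                                 for r in calls.itertuples(index=False)]
    tss_table["promoter"] = [promoters.get((int(r.position), r.strand), "")
                             for r in calls.itertuples(index=False)]
    tss_table["has_motif"] = motif_status
    pio.write_table(out("tss.tsv"), tss_table, meta)
    bed = calls.rename(columns={"position": "start"}).assign(
        end=lambda d: d["start"], name="TSS", score=lambda d: d["raw_plus"])
    pio.write_bed6(out("tss.bed"), bed, chrom)

    # ---- sRNA discovery
    expressed_ap = set(table.loc[table["expressed_ap"], "gene_id"])
    totals = (table.attrs["total_ap"], table.attrs["total_gp"])
    # intergenic transcripts are not upstream of genes: use the raw enriched set
    enriched = tssmod.deduplicate(
        tssmod.call_tss(tap_plus, tap_minus, None,
                        min_reads=config.param("tss_min_reads"),
                        min_enrichment=config.param("tss_min_enrichment")),
        window=config.param("dedup_window"))
    srnas = srn.discover_srnas(
        annotation, genome, ap_reads, gp_reads, enriched, totals, expressed_ap,
        motif=motif,
        min_len=config.param("srna_min_len"),
        fold_threshold=config.param("srna_fold_threshold"),
        end_frac=config.param("srna_end_frac"),
        connect_frac=config.param("srna_connect_frac"),
        max_orf_aa=config.param("srna_max_orf_aa"))
    report_srnas = srnas.drop(columns=["sequence"]).copy()
    report_srnas["fold_nearest_int"] = [
        xpr.nearest_int_fold(a, max(g, 1e-300)) if g > 0 else int(round(f))
        for a, g, f in zip(srnas["rpkm_ap"], srnas["rpkm_gp"], srnas["fold"])]
    pio.write_table(out("srna.tsv"), report_srnas, meta)
    if len(srnas):
        pio.write_bed6(out("srna.bed"), srnas, chrom)
        with open(out("srna.fa"), "w") as fh:
            for rec in srnas.itertuples(index=False):
                fh.write(f">{rec.name} {rec.start}-{rec.end}({rec.strand})\n{rec.sequence}\n")
    logger.info("[srna] %d candidates emitted", len(srnas))

    # ---- HTML report
    _render_html(out("report.html"), table, summary, motif, percent, report_srnas,
                 tss_table, meta)

    return {"expression": table, "summary": summary, "tss": tss_table,
            "operons": operons, "promoters": promoters, "motif": motif,
            "motif_prevalence_percent": percent, "srnas": srnas,
            "paths": {n: out(n) for n in ("expression.tsv", "tss.tsv", "srna.tsv",
                                          "program_summary.json", "report.html")}}


def _expression_figure(table: pd.DataFrame) -> str:
    """Per-gene AP/GP RPKM track (log scale) as a base64 PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(10, 4), sharex=True)
    x = np.arange(len(table))
    for ax, col, label, color in ((axes[0], "rpkm_ap", "AP", "#c0392b"),
                                  (axes[1], "rpkm_gp", "GP", "#2980b9")):
        ax.bar(x, np.maximum(table[col], 0.1), color=color, width=1.0)
        ax.set_yscale("log")
        ax.set_ylabel(f"{label} RPKM")
    axes[1].set_xlabel("gene index along genome")
    fig.tight_layout()
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=90)
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def _render_html(path, table, summary, motif, motif_percent, srnas, tss_table, meta):
    png = _expression_figure(table)
    counts = summary["counts"]
    pct = summary["percent_of_expressed"]
    rows = "".join(
        f"<tr><td>{c}</td><td>{counts[c]}</td>"
        f"<td>{pct.get(c, '')}</td></tr>" for c in counts)
    if motif is not None:
        c35, c10 = motif.consensus()
        motif_html = (f"<p>Two-box element <b>{c35}-N{motif.modal_spacer()}-{c10}</b> "
                      f"found in {motif_percent}% of AP-specific promoters.</p>")
    else:
        motif_html = "<p>No two-box element discovered.</p>"
    srna_html = srnas.to_html(index=False) if len(srnas) else "<p>No sRNA candidates.</p>"
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>predaseq report</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:2px 8px}}</style></head><body>
<h1>Dual-phase transcriptome report</h1>
<p><small>{meta['tool']} | config {meta['config_hash']} | seed {meta['seed']}</small></p>
<h2>Per-gene expression (AP vs GP)</h2>
<img src="data:image/png;base64,{png}" alt="per-gene expression track"/>
<h2>Phase categories</h2>
<table><tr><th>category</th><th>genes</th><th>% of expressed</th></tr>{rows}</table>
<p>{summary['total_expressed']} of {summary['total_genes']} genes expressed.</p>
<h2>Promoter motif</h2>{motif_html}
<p>{len(tss_table)} TSS calls.</p>
<h2>Intergenic AP-specific sRNAs</h2>{srna_html}
</body></html>"""
    with open(path, "w") as fh:
        fh.write(html)
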