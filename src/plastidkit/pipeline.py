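"""End-to-end analysis orchestration and report-table output.

Stages run in dependency order: structure → codon statistics → bias
diagnostics → divergence (needs an alignment) → substitution rates (needs
at least two genomes).  A stage failure is recorded in the run manifest and
skips only the stages that depend on it.  All outputs are TSV/BED/JSON
(UTF-8, Unix newlines, fixed column order), so re-running an identical
configuration reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .bias import enc_curve_table, neutrality_fit, pr2_coordinates
from .codon import (
    build_cai_weights,
    compute_rscu,
    count_codons,
    summarize_usage,
)
from ._genetics import ALL_CODONS
from .diversity import call_hotspots, per_region_pi, read_alignment, window_pi
from .genome import (
    GenomeRecord,
    detect_inverted_repeats,
    extract_cds,
    junction_report,
    read_genbank,
    region_gc,
    unique_cds_features,
)
from .rates import assign_gene_sets, geneset_rates, pairwise_rates_table

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("plastidkit")


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Window/step/threshold defaults are the field-standard plastome scan
    settings: 400 bp windows, 200 bp step, hotspot threshold π > 0.10.
    """

    genome_paths: list[str] = field(default_factory=list)
    alignment_path: str | None = None
    window: int = 400
    step: int = 200
    pi_threshold: float = 0.10
    ir_min_len: int = 10_000
    include_stops_in_rscu: bool = True
    seed: int = 0
    outdir: str = "plastidkit_out"


def _fmt(x, nd=4) -> str:
    if x is None:
        return "NA"
    return f"{x:.{nd}f}"


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _structure_stage(genomes, cfg, outdir):
    rows, jrows = [], []
    for g in genomes:
        if g.partition is None:
            g.partition = detect_inverted_repeats(g, min_len=cfg.ir_min_len)
        gc = region_gc(g)
        L = g.length
        p = g.partition
        rows.append([
            g.id, str(L),
            str(p.lsc.length(L)) if p else "NA",
            str(p.irb.length(L) + p.ira.length(L)) if p else "NA",
            str(p.ssc.length(L)) if p else "NA",
            _fmt(gc.total), _fmt(gc.lsc), _fmt(gc.ir), _fmt(gc.ssc),
        ])
        if p is not None:
            for j in junction_report(g):
                jrows.append([g.id, j.junction, j.gene_name,
                              str(j.bases_in_ir), str(j.distance)])
    _write_tsv(outdir / "partition.tsv",
               ["species", "total_bp", "lsc_bp", "ir_bp", "ssc_bp",
                "gc_total", "gc_lsc", "gc_ir", "gc_ssc"], rows)
    _write_tsv(outdir / "junctions.tsv",
               ["species", "junction", "gene", "bases_in_ir", "distance"],
               jrows)


def _codon_stage(genomes, cfg, outdir):
    """Returns per-species and per-gene summaries for the bias stage."""
    species_rows, gene_rows = [], []
    rscu_cols: dict[str, dict[str, float]] = {}
    summaries, per_gene = {}, {}
    for g in genomes:
        cdss = []
        for f in unique_cds_features(g):
            cdss.append(extract_cds(g, f))
        sets = assign_gene_sets([c.gene_name for c in cdss])
        photo = [c for c in cdss if sets[c.gene_name] in ("psa", "psb", "rbcL")]
        weights = build_cai_weights(photo or cdss,
                                    description="photosynthesis genes")
        summary = summarize_usage(cdss, weights=weights, label=g.id)
        summaries[g.id] = summary
        species_rows.append([
            g.id, _fmt(summary.gc, 3), _fmt(summary.gc1, 3),
            _fmt(summary.gc2, 3), _fmt(summary.gc3, 3), _fmt(summary.cai, 3),
            _fmt(summary.t3s, 3), _fmt(summary.c3s, 3), _fmt(summary.a3s, 3),
            _fmt(summary.g3s, 3), _fmt(summary.gc3s, 3), _fmt(summary.enc, 2),
        ])
        gene_summaries = []
        for c in cdss:
            try:
                s = summarize_usage([c], weights=weights, label=c.gene_name)
            except ValueError:
                continue
            gene_summaries.append(s)
            gene_rows.append([
                g.id, c.gene_name, sets[c.gene_name], _fmt(s.gc, 3),
                _fmt(s.gc1, 3), _fmt(s.gc2, 3), _fmt(s.gc3, 3), _fmt(s.cai, 3),
                _fmt(s.t3s, 3), _fmt(s.c3s, 3), _fmt(s.a3s, 3), _fmt(s.g3s, 3),
                _fmt(s.gc3s, 3), _fmt(s.enc, 2),
            ])
        per_gene[g.id] = gene_summaries
        table = count_codons(cdss)
        rscu = compute_rscu(table, include_stops=cfg.include_stops_in_rscu)
        rscu_cols[g.id] = dict(rscu.rscu)
    _write_tsv(outdir / "codon_usage.tsv",
               ["species", "GC", "GC1", "GC2", "GC3", "CAI", "T3S", "C3S",
                "A3S", "G3S", "GC3S", "ENC"], species_rows)
    _write_tsv(outdir / "per_gene_usage.tsv",
               ["species", "gene_name", "gene_set", "GC", "GC1", "GC2", "GC3",
                "CAI", "T3S", "C3S", "A3S", "G3S", "GC3S", "ENC"], gene_rows)
    ids = [g.id for g in genomes]
    rscu_rows = [[c] + [_fmt(rscu_cols[i].get(c), 3) for i in ids]
                 for c in ALL_CODONS]
    _write_tsv(outdir / "rscu_matrix.tsv", ["codon"] + ids, rscu_rows)
    return summaries, per_gene


def _bias_stage(summaries, per_gene, outdir):
    pr2_rows, neut_rows, curve_rows = [], [], []
    for sp, summary in summaries.items():
        pt = pr2_coordinates(summary)
        if pt is not None:
            pr2_rows.append([sp, _fmt(pt.gc_bias, 3), _fmt(pt.at_bias, 3)])
        points = [(s.gc12, s.gc3) for s in per_gene[sp]]
        try:
            fit = neutrality_fit(points)
            neut_rows.append([sp, _fmt(fit.slope), _fmt(fit.intercept),
                              _fmt(fit.r2), str(fit.n_genes)])
        except ValueError as exc:
            log.warning("neutrality fit failed for %s: %s", sp, exc)
        for pt2 in enc_curve_table(per_gene[sp]):
            curve_rows.append([sp, pt2.label, _fmt(pt2.gc3s), _fmt(pt2.enc_observed, 2),
                               _fmt(pt2.enc_expected, 2), _fmt(pt2.deviation)])
    _write_tsv(outdir / "pr2.tsv", ["label", "gc_bias", "at_bias"], pr2_rows)
    _write_tsv(outdir / "neutrality.tsv",
               ["species", "slope", "intercept", "r2", "n_genes"], neut_rows)
    _write_tsv(outdir / "enc_curve.tsv",
               ["species", "gene", "gc3s", "enc_observed", "enc_expected",
                "deviation"], curve_rows)


def _divergence_stage(aln, genomes, cfg, outdir):
    windows = window_pi(aln, window=cfg.window, step=cfg.step)
    wrows = [[str(w.start + 1), str(w.end), str(w.valid_sites), _fmt(w.pi, 5)]
             for w in windows]
    _write_tsv(outdir / "windows.tsv",
               ["start", "end", "valid_sites", "pi"], wrows)
    annotation = genomes[0].features if genomes else None
    hotspots = call_hotspots(windows, threshold=cfg.pi_threshold,
                             annotation=annotation)
    with open(outdir / "hotspots.bed", "w", newline="\n") as fh:
        for h in hotspots:
            name = h.label or "hotspot"
            fh.write(f"{aln.labels[0]}\t{h.start}\t{h.end}\t{name}\t"
                     f"{h.peak_pi:.5f}\n")
    part = genomes[0].partition if genomes else None
    if part is not None:
        pi_lsc, pi_ir, pi_ssc = per_region_pi(aln, part)
        _write_tsv(outdir / "region_pi.tsv", ["region", "pi"],
                   [["LSC", _fmt(pi_lsc, 5)], ["IR", _fmt(pi_ir, 5)],
                    ["SSC", _fmt(pi_ssc, 5)]])


def _rates_stage(genomes, outdir):
    rates = geneset_rates(genomes)
    rows = [[gs, _fmt(r.dn), _fmt(r.ds), _fmt(r.omega),
             _fmt(r.n_sites, 1), _fmt(r.s_sites, 1), str(r.pairs_used)]
            for gs, r in sorted(rates.items())]
    _write_tsv(outdir / "rates.tsv",
               ["gene_set", "dn", "ds", "omega", "n_sites", "s_sites",
                "pairs_used"], rows)
    prows = [[gs, a, b, _fmt(r.dn), _fmt(r.ds), _fmt(r.omega)]
             for gs, a, b, r in pairwise_rates_table(genomes)]
    _write_tsv(outdir / "rates_pairs.tsv",
               ["gene_set", "species_a", "species_b", "dn", "ds", "omega"],
               prows)


def run_all(
    config: RunConfig, genomes: list[GenomeRecord] | None = None
) -> dict:
    """Run every applicable stage; returns the run manifest (also written).

    ``genomes`` may be passed directly (e.g. synthetic records); otherwise
    they are read from ``config.genome_paths``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = [read_genbank(p) for p in config.genome_paths]
    if not genomes:
        raise ValueError("run_all: no genomes")
    manifest: dict = {
        "package": "plastidkit",
        "version": __version__,
        "config": asdict(config),
        "inputs": {p: _sha256(p) for p in config.genome_paths},
        "stages": {},
    }
    if config.alignment_path:
        manifest["inputs"][config.alignment_path] = _sha256(config.alignment_path)

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3)
            }
            log.info("stage %s: ok (%.1fs)", name, time.perf_counter() - t0)
            return result
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            log.error("stage %s failed: %s", name, exc)
            return None

    run_stage("structure", _structure_stage, genomes, config, outdir)
    codon_out = run_stage("codon_stats", _codon_stage, genomes, config, outdir)
    if codon_out is not None:
        run_stage("bias_analysis", _bias_stage, *codon_out, outdir)
    else:
        manifest["stages"]["bias_analysis"] = {
            "status": "skipped", "reason": "codon_stats failed"
        }
    if config.alignment_path:
        aln = read_alignment(config.alignment_path)
        run_stage("divergence", _divergence_stage, aln, genomes, config, outdir)
    else:
        manifest["stages"]["divergence"] = {
            "status": "skipped", "reason": "no alignment provided"
        }
    if len(genomes) >= 2:
        run_stage("subst_rates", _rates_stage, genomes, outdir)
    else:
        manifest["stages"]["subst_rates"] = {
            "status": "skipped", "reason": "fewer than 2 genomes"
        }
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
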