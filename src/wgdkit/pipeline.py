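"""End-to-end orchestration: simulate/load -> hits -> duplicate classes ->
Ks -> peaks -> dating -> shared-WGD test -> telomeres -> fractionation ->
retention -> report.

Each stage writes its own TSV/JSON/BED output so that every number in the
final report can be re-derived from stage files, and a fixed seed gives an
identical report (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as wio
from .kaks import ka_ks_batch
from .models import rank_index
from .peaks import (KsSample, fit_ks_mixture, extract_peaks,
                    estimate_wgd_age, test_shared_wgd, DEFAULT_KS_RANGE)
from .retention import (PangeneRow, classify_retention, fractionation_profile,
                        fractionation_bias_test)
from .simulate import SimConfig, simulate_clade, write_genomes, kmer_hits, \
    pangene_table
from .synteny import chain_anchors, classify_duplicates, syntenic_depth_ratio
from .telomere import TelomereScanConfig, scan_genome


@dataclass
class PipelineConfig:
    """Every stage's knobs in one validated bundle."""

    sim: SimConfig = field(default_factory=SimConfig)
    # telomere scan windows sized for the simulator's ~50 kb chromosomes;
    # real genomes use the TelomereScanConfig default of 1 Mb
    scan: TelomereScanConfig = field(
        default_factory=lambda: TelomereScanConfig(window=10_000))
    min_block: int = 5
    max_gap: int = 25
    tandem_gap: int = 1
    proximal_gap: int = 10
    ks_range: tuple[float, float] = DEFAULT_KS_RANGE
    k_max: int = 5
    min_ks_sample: int = 50
    calib_peak_ks: float | None = None  # None => matched to sim syn_rate
    calib_age_my: float = 35.0
    shared_tolerance: float = 0.02
    fractionation_window: int = 25
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if self.min_block < 2 or self.k_max < 1:
            raise ValueError("min_block >= 2 and k_max >= 1 required")
        if self.ks_range[0] <= 0 or self.ks_range[0] >= self.ks_range[1]:
            raise ValueError("ks_range must be 0 < lo < hi")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


REPORT_SCHEMA = {
    "provenance": dict,
    "simulation": dict,
    "telomeres": dict,
    "duplicates": dict,
    "ks_paralog": dict,
    "ks_ortholog": dict,
    "dating": dict,
    "synteny_depth": dict,
    "fractionation": dict,
    "retention": dict,
    "files": dict,
}


def validate_report(report: dict) -> None:
    """Check the report against the published key/type schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report section {key!r} is not a {typ.__name__}")
    for path in report["files"].values():
        if not Path(path).exists():
            raise ValueError(f"report lists missing file {path}")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full analysis on a simulated clade and write a report.

    Returns the report dict (also written to ``report.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    sim = config.sim

    # --- simulate and persist genomes -------------------------------------
    result = simulate_clade(sim)
    manifest = write_genomes(result, outdir / "genomes")
    for sp, d in manifest.items():
        for kind, p in d.items():
            files[f"genome_{sp}_{kind}"] = p

    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": asdict(config),
        },
        "simulation": {
            "species": list(result.genes),
            "genes_per_species": {sp: len(g) for sp, g in result.genes.items()},
            "true_wgd_age_my": sim.wgd_age,
            "true_ortholog_split_my": sim.speciation_ages[1],
            "expected_wgd_ks": (None if sim.wgd_age is None
                                else 2 * sim.syn_rate * sim.wgd_age),
        },
    }

    # --- telomeres on the focal (ingA) genome -----------------------------
    windows, statuses = scan_genome(result.chromosomes["ingA"], config.scan)
    bed = outdir / "telomere_windows.bed"
    status_tsv = outdir / "telomere_status.tsv"
    wio.write_windows_bed(windows, bed)
    wio.write_contig_status_tsv(statuses, status_tsv)
    files["telomere_windows_bed"] = str(bed)
    files["telomere_status_tsv"] = str(status_tsv)
    report["telomeres"] = {
        "n_windows_retained": sum(1 for w in windows if w.retained),
        "contigs": {s.scaffold: s.classification for s in statuses},
        "n_both_ends": sum(1 for s in statuses
                           if s.classification == "both_ends"),
    }

    # --- within-genome duplicates on ingA ---------------------------------
    cds_a = result.cds_dict("ingA")
    ranks_a = rank_index(result.genes["ingA"])
    hits_self = kmer_hits(cds_a)
    hits_path = outdir / "ingA_self_hits.tsv"
    wio.write_hit_table(hits_self, hits_path)
    files["ingA_self_hits"] = str(hits_path)
    blocks = chain_anchors(hits_self, ranks_a, min_block=config.min_block,
                           max_gap=config.max_gap)
    pairs = classify_duplicates(hits_self, ranks_a, blocks,
                                tandem_gap=config.tandem_gap,
                                proximal_gap=config.proximal_gap)
    blocks_tsv = outdir / "ingA_blocks.tsv"
    pairs_tsv = outdir / "ingA_dup_pairs.tsv"
    wio.write_blocks_tsv(blocks, blocks_tsv)
    wio.write_pairs_tsv(pairs, pairs_tsv)
    files["ingA_blocks"] = str(blocks_tsv)
    files["ingA_dup_pairs"] = str(pairs_tsv)
    mode_counts: dict[str, int] = {}
    for p in pairs:
        mode_counts[p.mode] = mode_counts.get(p.mode, 0) + 1
    report["duplicates"] = {"n_blocks": len(blocks), "modes": mode_counts}

    # --- Ks of WGD-classified paralog pairs -------------------------------
    wgd_pairs = [(p.gene_a, p.gene_b) for p in pairs if p.mode == "wgd"]
    ks_df = ka_ks_batch(wgd_pairs, cds_a)
    ks_tsv = outdir / "ingA_wgd_ks.tsv"
    ks_df.to_csv(ks_tsv, sep="\t", index=False)
    files["ingA_wgd_ks"] = str(ks_tsv)
    paralog_sample = KsSample.from_values(
        ks_df.loc[~ks_df.saturated, "ks"], "paralog", config.ks_range)
    report["ks_paralog"] = {"n_pairs": len(wgd_pairs),
                            "n_usable": len(paralog_sample)}
    youngest_peak = None
    if len(paralog_sample) >= config.min_ks_sample:
        fit, all_fits = fit_ks_mixture(
            paralog_sample, (1, config.k_max), seed=config.seed,
            min_n=config.min_ks_sample)
        peaks = extract_peaks(fit)
        youngest_peak = peaks.peaks[0]
        fit_json = outdir / "ingA_ks_fit.json"
        wio.write_json({"best": fit.to_dict(),
                        "all": [f.to_dict() for f in all_fits]}, fit_json)
        files["ingA_ks_fit"] = str(fit_json)
        report["ks_paralog"].update({
            "k_selected": fit.k,
            "peaks": peaks.peaks,
            "weights": peaks.weights,
            "youngest_peak": youngest_peak,
        })

    # --- cross-species ortholog Ks (ingA vs ingB syntenic anchors) --------
    cds_b = result.cds_dict("ingB")
    ranks_ab = {**ranks_a, **rank_index(result.genes["ingB"])}
    hits_cross = kmer_hits(cds_a, cds_b)
    blocks_ab = chain_anchors(hits_cross, ranks_ab,
                              min_block=config.min_block,
                              max_gap=config.max_gap)
    ortho_pairs = sorted({tuple(sorted((a.gene_a, a.gene_b)))
                          for b in blocks_ab for a in b.anchors})
    ortho_df = ka_ks_batch(ortho_pairs, {**cds_a, **cds_b})
    ortho_tsv = outdir / "ingA_ingB_ortholog_ks.tsv"
    ortho_df.to_csv(ortho_tsv, sep="\t", index=False)
    files["ortholog_ks"] = str(ortho_tsv)
    ortho_sample = KsSample.from_values(
        ortho_df.loc[~ortho_df.saturated, "ks"], "ortholog", config.ks_range)
    report["ks_ortholog"] = {"n_pairs": len(ortho_pairs),
                             "n_usable": len(ortho_sample)}
    divergence_peak = None
    if len(ortho_sample) >= config.min_ks_sample:
        ofit, _ = fit_ks_mixture(ortho_sample, (1, min(3, config.k_max)),
                                 seed=config.seed,
                                 min_n=config.min_ks_sample)
        opeaks = extract_peaks(ofit)
        # divergence peak = heaviest component (the bulk of orthologs)
        divergence_peak = opeaks.peaks[int(np.argmax(opeaks.weights))]
        report["ks_ortholog"].update({
            "k_selected": ofit.k,
            "peaks": opeaks.peaks,
            "divergence_peak": divergence_peak,
        })

    # --- dating + shared-WGD verdict --------------------------------------
    report["dating"] = {}
    if youngest_peak is not None:
        calib_peak = config.calib_peak_ks
        if calib_peak is None:
            # calibration matched to the simulation's clock
            calib_peak = 2.0 * sim.syn_rate * config.calib_age_my
        cal = estimate_wgd_age(youngest_peak, calib_peak, config.calib_age_my)
        report["dating"] = {
            "wgd_peak_ks": youngest_peak,
            "calib_peak_ks": calib_peak,
            "calib_age_my": config.calib_age_my,
            "age_my": cal.age_my,
            "syn_rate_per_year": cal.syn_rate_per_year,
        }
        if divergence_peak is not None:
            report["dating"]["shared_wgd_verdict"] = test_shared_wgd(
                youngest_peak, divergence_peak, config.shared_tolerance)

    # --- syntenic depth of ingA against the unduplicated out1 -------------
    cds_ref = result.cds_dict("out1")
    ranks_ref = rank_index(result.genes["out1"])
    hits_ref = kmer_hits(cds_ref, cds_a)
    blocks_ref = chain_anchors(hits_ref, {**ranks_ref, **ranks_a},
                               min_block=config.min_block,
                               max_gap=config.max_gap)
    hist, modal = syntenic_depth_ratio(blocks_ref, ranks_ref)
    report["synteny_depth"] = {
        "histogram": {str(k): v for k, v in sorted(hist.items())},
        "modal_depth": modal,
        "quota": f"{modal}:1",
    }

    # --- fractionation profile of ingA homoeologs vs out1 -----------------
    ortho_map: dict[str, list[str]] = {}
    for b in blocks_ref:
        for a in b.anchors:
            ref_gene, qry_gene = ((a.gene_a, a.gene_b)
                                  if a.gene_a in ranks_ref
                                  else (a.gene_b, a.gene_a))
            ortho_map.setdefault(ref_gene, []).append(ranks_a[qry_gene][0])
    ref_order = [(g.gene_id, g.scaffold) for g in result.genes["out1"]]
    fwindows = fractionation_profile(ref_order, ortho_map,
                                     window=config.fractionation_window)
    frac_tsv = outdir / "fractionation_windows.tsv"
    wio.write_fractionation_tsv(fwindows, frac_tsv)
    files["fractionation_windows"] = str(frac_tsv)
    report["fractionation"] = {"n_windows": len(fwindows)}
    if len(fwindows) >= 5:
        p, m1, m2 = fractionation_bias_test(fwindows)
        report["fractionation"].update({
            "sign_test_p": p,
            "mean_retention_1": m1,
            "mean_retention_2": m2,
            "biased": p < 0.01,
        })

    # --- pangene retention classes ----------------------------------------
    pg = pangene_table(result)
    pg_tsv = outdir / "pangenes.tsv"
    pg.to_csv(pg_tsv, sep="\t", index=False)
    files["pangenes"] = str(pg_tsv)
    rows = [PangeneRow(r.pangene, int(r.out1), int(r.out2),
                       int(r.ingA), int(r.ingB))
            for r in pg.itertuples()]
    classes, totals = classify_retention(rows)
    class_tsv = outdir / "retention_classes.tsv"
    with open(class_tsv, "w") as fh:
        fh.write("pangene\tclass\n")
        for r, c in zip(rows, classes):
            fh.write(f"{r.pangene}\t{c.value}\n")
    files["retention_classes"] = str(class_tsv)
    report["retention"] = {"totals": totals, "n_pangenes": len(rows)}

    report["files"] = files
    report_path = outdir / "report.json"
    wio.write_json(report, report_path)
    validate_report(report)
    return report
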