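"""End-to-end orchestration: simulate -> scan -> annotate -> quantify -> report.

A single structured config (YAML-compatible nested dict) drives every
stage; unknown keys are rejected and the effective, defaults-merged config
is written next to the outputs. Every filter chain reports a funnel of
accept/reject counts, the primary debugging surface for this kind of
pipeline. Given a seed, a full run is deterministic and the report is
byte-identical across reruns.
"""

from __future__ import annotations

import copy
import json
import logging
import os
from collections import Counter
from typing import Any, Sequence

import yaml

from . import abundance as ab
from . import annotate as an
from . import numts as nm
from . import simulate as sim
from . import sva as sv
from .align import ExactMatcher
from .io import ensure_dir, write_bed, write_fasta, write_fastq
from .records import GenomicInterval, SeqRecord
from .simulate import (
    PlantParams,
    RdaParams,
    ToyGenomeSpec,
    mt_gene_map,
)

log = logging.getLogger("senomob")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "genome": {
        "n_chroms": 2,
        "chrom_length": 50_000,
        "gc_fraction": 0.5,
        "mt_length": 16_559,
        "n_germline_sva": 8,
        "n_germline_numt": 5,
        "n_alu": 20,
        "n_line": 6,
        "n_ltr": 4,
        "n_satellite": 2,
        "n_genes": 3,
    },
    "events": {
        "n_de_novo_sva": 6,
        "n_de_novo_numt": 6,
        "mt_len_range": [40, 400],
        "microhomology_range": [0, 5],
        "tsd_range": [4, 20],
        "hexamer_repeat_range": [30, 50],
        "truncation_5p_max": 0,
        "repeat_target_bias": 0.0,
    },
    "wgs": {
        "coverage": 20,
        "read_len": 150,
        "mt_copy_number": 5,
        "error_rate": 0.0,
        "n_replicates": 2,
    },
    "rda": {
        "n_replicates": 3,
        "adaptor": sim.DEFAULT_RDA_ADAPTOR,
        "flank_len": 80,
        "head_len": 120,
        "subtraction_efficiency": 0.99,
        "amplification": 50,
    },
    "aluscan": {"max_amplicon": 5_000, "copies": 2},
    "numt_scan": {
        "min_mt_len": 30,
        "max_mt_len": 130,
        "min_flank": 20,
        "min_query_cov": 0.95,
        "merge_window": 100,
    },
    "sva_call": {
        "exclusion_window": 100,
        "collapse_tolerance": 20,
        "min_hexamer_repeats": 3,
    },
    "abundance": {"tile_len": 1000, "min_identity": 1.0},
    "annotate": {"midpoint_rule": True, "consensus_window": 10},
}


def merge_config(user: dict[str, Any] | None) -> dict[str, Any]:
    """Merge a user config over the defaults, rejecting unknown keys."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    if not user:
        return merged

    def merge(dst: dict, src: dict, path: str) -> None:
        for key, value in src.items():
            if key not in dst:
                raise ValueError(f"unknown config key {path}{key!r}")
            if isinstance(dst[key], dict):
                if not isinstance(value, dict):
                    raise ValueError(f"config key {path}{key!r} must be a mapping")
                merge(dst[key], value, f"{path}{key}.")
            else:
                dst[key] = value

    merge(merged, user, "")
    return merged


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def aggregate(values: Sequence[int]) -> int:
    """Exact integer sum of per-replicate/per-dataset counts."""
    return int(sum(int(v) for v in values))


def _recover_numts(calls, truth, window: int):
    de_novo = [ev for ev in truth if ev.kind == "de_novo_numt"]
    recovered = set()
    false_calls = 0
    for call in calls:
        matched = False
        for i, ev in enumerate(de_novo):
            if call.chrom == ev.chrom and (
                call.start - window <= ev.ref_point <= call.end + window
            ):
                recovered.add(i)
                matched = True
        if not matched:
            false_calls += 1
    return len(recovered), len(de_novo), false_calls


def _recover_svas(calls, truth, tolerance: int):
    de_novo = [ev for ev in truth if ev.kind == "de_novo_sva"]
    recovered = set()
    false_calls = 0
    for call in calls:
        matched = False
        for i, ev in enumerate(de_novo):
            if call.chrom == ev.chrom and abs(call.position - ev.ref_point) <= tolerance:
                recovered.add(i)
                matched = True
        if not matched:
            false_calls += 1
    return len(recovered), len(de_novo), false_calls


def run_all(config: dict[str, Any] | None = None, outdir: str = "senomob_run") -> dict[str, Any]:
    """Run the whole pipeline on a simulated two-sample design.

    Returns the summary report (also written as report.json/report.txt in
    ``outdir`` together with all intermediate artifacts).
    """
    cfg = merge_config(config)
    ensure_dir(outdir)
    with open(os.path.join(outdir, "effective_config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    seed = int(cfg["seed"])
    g = cfg["genome"]
    spec = ToyGenomeSpec(seed=seed, **{k: v for k, v in g.items()})
    log.info("stage simulate: building toy genome (seed=%d)", seed)
    toy = sim.make_toy_genome(spec)
    ev = cfg["events"]
    params = PlantParams(
        mt_len_range=tuple(ev["mt_len_range"]),
        microhomology_range=tuple(ev["microhomology_range"]),
        tsd_range=tuple(ev["tsd_range"]),
        hexamer_repeat_range=tuple(ev["hexamer_repeat_range"]),
        truncation_5p_max=ev["truncation_5p_max"],
        repeat_target_bias=ev["repeat_target_bias"],
    )
    sen = sim.plant_de_novo_events(
        toy, ev["n_de_novo_sva"], ev["n_de_novo_numt"], params, seed=seed + 1
    )
    toy.write(outdir)
    write_fasta(sen.records, os.path.join(outdir, "senescent.fa"))
    sim.write_truth(sen.truth, os.path.join(outdir, "truth.bed"))

    w = cfg["wgs"]
    sp = cfg["numt_scan"]
    scan_params = nm.ScanParams(
        min_mt_len=sp["min_mt_len"],
        max_mt_len=sp["max_mt_len"],
        min_flank=sp["min_flank"],
        min_query_cov=sp["min_query_cov"],
        merge_window=sp["merge_window"],
    )
    scanner = nm.NumtScanner(toy.mt, scan_params.min_mt_len)
    min_span = max(8, int(scan_params.min_query_cov * scan_params.min_flank))
    nuclear_matcher = ExactMatcher(toy.chroms, min_len=min_span)

    def scan(reads, label):
        result = nm.scan_sample(
            reads,
            toy.chroms,
            toy.mt,
            scan_params,
            label=label,
            scanner=scanner,
            nuclear_matcher=nuclear_matcher,
        )
        log.info("funnel %s: %s", label, json.dumps(result.funnel, sort_keys=True))
        return result

    numt_calls: dict[str, list[nm.NumtCall]] = {}
    funnels: dict[str, dict[str, int]] = {}
    wgs_reads: dict[str, list[SeqRecord]] = {}
    for rep in range(w["n_replicates"]):
        label = f"WGS{rep + 1}"
        reads_sen = sim.simulate_wgs(
            sen.chroms,
            sen.mt,
            w["coverage"],
            w["read_len"],
            w["mt_copy_number"],
            w["error_rate"],
            seed=seed + 10 + rep,
            id_prefix=f"{label.lower()}_sen",
        )
        reads_prol = sim.simulate_wgs(
            toy.chroms,
            toy.mt,
            w["coverage"],
            w["read_len"],
            w["mt_copy_number"],
            w["error_rate"],
            seed=seed + 20 + rep,
            id_prefix=f"{label.lower()}_prol",
        )
        wgs_reads[f"{label}_sen"] = reads_sen
        wgs_reads[f"{label}_prol"] = reads_prol
        write_fastq(reads_sen, os.path.join(outdir, f"{label.lower()}_senescent.fastq"))
        res_sen = scan(reads_sen, label)
        res_prol = scan(reads_prol, f"{label}_prol")
        funnels[f"{label}_sen"] = res_sen.funnel
        funnels[f"{label}_prol"] = res_prol.funnel
        numt_calls[label] = nm.call_de_novo(
            res_sen, res_prol, toy.numt, toy.mt.length, scan_params.merge_window
        )

    al = cfg["aluscan"]
    sen_repeats = [sen.lift(iv) for iv in toy.repeats]
    alu_sen = sim.simulate_aluscan(
        sen.chroms, sen_repeats, al["max_amplicon"], w["read_len"],
        copies=al["copies"], seed=seed + 40,
    )
    alu_prol = sim.simulate_aluscan(
        toy.chroms, toy.repeats, al["max_amplicon"], w["read_len"],
        copies=al["copies"], seed=seed + 41,
    )
    res_sen = scan(alu_sen, "AluScan")
    res_prol = scan(alu_prol, "AluScan_prol")
    funnels["AluScan_sen"] = res_sen.funnel
    funnels["AluScan_prol"] = res_prol.funnel
    numt_calls["AluScan"] = nm.call_de_novo(
        res_sen, res_prol, toy.numt, toy.mt.length, scan_params.merge_window
    )
    all_numt_calls = [c for calls in numt_calls.values() for c in calls]
    write_bed(nm.calls_to_bed(all_numt_calls), os.path.join(outdir, "numt_calls.bed"))
    with open(os.path.join(outdir, "numt_calls.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tmt_start\tmt_end\tsupport\tdataset\tmicrohomology_len\n")
        for c in sorted(all_numt_calls, key=lambda c: (c.chrom, c.start)):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.mt_start}\t{c.mt_end}\t"
                f"{c.support}\t{c.dataset}\t{c.microhomology_len}\n"
            )
    composition = nm.mito_composition(
        all_numt_calls, mt_gene_map(toy.mt.id, toy.mt.length), toy.mt.length
    )

    r = cfg["rda"]
    sc = cfg["sva_call"]
    rda_params = RdaParams(
        adaptor=r["adaptor"],
        flank_len=r["flank_len"],
        head_len=r["head_len"],
        subtraction_efficiency=r["subtraction_efficiency"],
        amplification=r["amplification"],
        read_len=w["read_len"],
    )
    sva_calls: dict[str, list[sv.InsertionCall]] = {}
    for rep in range(r["n_replicates"]):
        label = f"Sen_{rep + 1}"
        reads = sim.simulate_rda(sen, toy, rda_params, seed=seed + 30 + rep)
        write_fastq(reads, os.path.join(outdir, f"rda_{label.lower()}.fastq"))
        flanks = []
        rda_funnel: dict[str, int] = {"reads_total": len(reads)}
        for read in reads:
            parsed = sv.parse_amplicon(
                read, r["adaptor"], min_hexamer_repeats=sc["min_hexamer_repeats"]
            )
            if isinstance(parsed, sv.Rejection):
                rda_funnel[f"reads_{parsed.reason}"] = (
                    rda_funnel.get(f"reads_{parsed.reason}", 0) + 1
                )
            else:
                flanks.append(parsed)
        rda_funnel["flank_reads"] = len(flanks)
        calls = sv.call_insertions(
            flanks,
            toy.chroms,
            toy.sva,
            exclusion_window=sc["exclusion_window"],
            collapse_tolerance=sc["collapse_tolerance"],
            replicate=label,
            nuclear_matcher=nuclear_matcher,
            funnel=rda_funnel,
        )
        log.info("funnel RDA %s: %s", label, json.dumps(rda_funnel, sort_keys=True))
        funnels[f"RDA_{label}"] = rda_funnel
        sva_calls[label] = calls
        write_bed(sv.calls_to_bed(calls), os.path.join(outdir, f"sva_calls_{label.lower()}.bed"))
    summaries = sv.summarize(sva_calls)
    venn = (
        sv.replicate_overlap(sva_calls, tolerance=sc["collapse_tolerance"])
        if len(sva_calls) >= 2
        else {}
    )

    ann = cfg["annotate"]
    target_sites = [c.interval for calls in sva_calls.values() for c in calls]
    numt_sites = [c.interval for c in all_numt_calls]
    labels_per_rep = [
        an.annotate_sites(
            [c.interval for c in calls], toy.genes, toy.repeats, ann["midpoint_rule"]
        )
        for calls in sva_calls.values()
        if calls
    ]
    annotation = (
        an.summarize_fractions(labels_per_rep).fraction_pct if labels_per_rep else {}
    )
    numt_labels = (
        an.annotate_sites(numt_sites, toy.genes, toy.repeats, ann["midpoint_rule"])
        if numt_sites
        else []
    )
    cleavage_inputs = []
    for calls in sva_calls.values():
        for c in calls:
            chrom_seq = toy.chroms[c.chrom]
            lo = max(0, c.position - 30)
            cleavage_inputs.append((chrom_seq[lo : c.position + 30], c.position - lo))
    cleavage_fraction, _ = an.scan_cleavage_consensus(
        cleavage_inputs, window=ann["consensus_window"]
    )

    q = cfg["abundance"]
    tiles = ab.tile(toy.mt, q["tile_len"])
    profile = ab.abundance_profile(
        wgs_reads.get("WGS1_sen", []),
        wgs_reads.get("WGS1_prol", []),
        tiles,
        min_identity=q["min_identity"],
    )
    profile.to_csv(os.path.join(outdir, "mt_tile_profile.tsv"), sep="\t", index=False)

    n_rec, n_truth, n_false = _recover_numts(
        all_numt_calls, sen.truth, scan_params.merge_window
    )
    sva_all_calls = [c for calls in sva_calls.values() for c in calls]
    s_rec, s_truth, s_false = _recover_svas(
        sva_all_calls, sen.truth, sc["collapse_tolerance"]
    )

    report = {
        "sva": {
            "per_replicate": [
                {"replicate": s.replicate, "total": s.total, "unique": s.unique}
                for s in summaries
            ],
            "grand_total": aggregate([s.total for s in summaries]),
            "grand_unique": aggregate([s.unique for s in summaries]),
            "venn": {"+".join(sorted(k)): v for k, v in venn.items()},
        },
        "numt": {
            "per_dataset": {label: len(calls) for label, calls in numt_calls.items()},
            "total": aggregate([len(calls) for calls in numt_calls.values()]),
            "mito_composition_pct": {k: v["pct"] for k, v in composition.items()},
            "target_annotation": dict(sorted(Counter(numt_labels).items())),
        },
        "annotation_fraction_pct": annotation,
        "cleavage_consensus_fraction": cleavage_fraction,
        "abundance": profile.to_dict(orient="records"),
        "recovery": {
            "numt_recovered": n_rec,
            "numt_planted": n_truth,
            "numt_false_calls": n_false,
            "sva_recovered": s_rec,
            "sva_planted": s_truth,
            "sva_false_calls": s_false,
        },
        "funnels": funnels,
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_text_report(report, os.path.join(outdir, "report.txt"))
    return report


def _write_text_report(report: dict[str, Any], path: str) -> None:
    lines = ["senomob pipeline report", "======================", ""]
    sva = report["sva"]
    lines.append("De novo SVA insertions (RDA readout)")
    for row in sva["per_replicate"]:
        lines.append(
            f"  {row['replicate']}: total={row['total']} unique={row['unique']}"
        )
    lines.append(
        f"  aggregate: total={sva['grand_total']} unique={sva['grand_unique']}"
    )
    numt = report["numt"]
    lines.append("De novo numts")
    for label, n in numt["per_dataset"].items():
        lines.append(f"  {label}: {n}")
    lines.append(f"  aggregate: {numt['total']}")
    rec = report["recovery"]
    lines.append("Truth recovery")
    lines.append(
        f"  numts: {rec['numt_recovered']}/{rec['numt_planted']} recovered, "
        f"{rec['numt_false_calls']} false calls"
    )
    lines.append(
        f"  SVAs:  {rec['sva_recovered']}/{rec['sva_planted']} recovered, "
        f"{rec['sva_false_calls']} false calls"
    )
    if rec["numt_planted"] == 0 and rec["sva_planted"] == 0:
        lines.append("  (no de novo events were planted; zero calls expected)")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
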