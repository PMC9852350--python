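"""End-to-end orchestration with deterministic seeding and a
machine-readable run report.

Stage order: simulate (synthetic mode) -> counts -> FPKM -> presence
calls -> assembly-consensus filter -> Venn partition -> family
assignment -> mobility classification -> haustorium mediation ->
transfer summary -> downstream stats -> recovery metrics against the
truth table.  The ORF screen annotates the report but does not filter
mobility calls by default (``orf_strict=True`` drops non-coding
candidates before classification).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import expression, homology, mobility, orf_screen, stats, synthetic_data
from .io_formats import RunConfig, read_tally_table
from .mobility import MobilityCall, TransferSummary


def worked_example_tallies() -> dict[str, float]:
    """The packaged printed-tally fixture for arithmetic-only checks."""
    path = resources.files("xenotraffic.data") / "worked_example_tallies.tsv"
    return read_tally_table(str(path))


def evaluate_against_truth(
    calls: Sequence[MobilityCall],
    truth: pd.DataFrame,
) -> dict:
    """Per-direction sensitivity, precision, false-discovery proportion
    and the full (true mobility x called direction) confusion table."""
    truth_mob = truth["mobility"]
    confusion: dict[str, dict[str, int]] = {}
    for call in calls:
        if call.unigene_id not in truth_mob.index:
            raise ValueError(f"call id {call.unigene_id!r} absent from truth table")
        t = str(truth_mob.loc[call.unigene_id])
        confusion.setdefault(t, {}).setdefault(call.direction, 0)
        confusion[t][call.direction] += 1
    metrics: dict[str, dict] = {"confusion": confusion, "per_direction": {}}
    for direction in ("CD_to_HC", "HC_to_CD"):
        n_true = int((truth_mob == direction).sum())
        n_called = sum(1 for c in calls if c.direction == direction)
        tp = confusion.get(direction, {}).get(direction, 0)
        fp = n_called - tp
        sensitivity = tp / n_true if n_true else None
        precision = tp / n_called if n_called else None
        fdp = fp / n_called if n_called else None
        metrics["per_direction"][direction] = {
            "n_true": n_true, "n_called": n_called, "tp": tp, "fp": fp,
            "sensitivity": sensitivity, "precision": precision,
            "false_discovery_proportion": fdp,
        }
    return metrics


def run_synthetic(
    sim_config: synthetic_data.SimulationConfig,
    run_config: Optional[RunConfig] = None,
    outdir: Optional[str | Path] = None,
    orf_strict: bool = False,
    skip_orf_screen: bool = False,
    with_enrichment: bool = True,
) -> dict:
    """Run the full pipeline on one synthetic dataset; returns the report.

    When *outdir* is given, all stage outputs (FASTAs, count table,
    truth, calls, summary, enrichment table, report) are written there.
    """
    run_config = run_config or RunConfig(rng_seed=sim_config.seed)
    report: dict = {
        "config": {
            "simulation": dataclasses.asdict(sim_config),
            "run": dataclasses.asdict(run_config),
        },
        "stages": {},
    }

    host, parasite, refs, truth = synthetic_data.simulate_transcriptomes(sim_config)
    design = synthetic_data.default_design()
    counts = synthetic_data.simulate_counts(truth, design, sim_config)
    report["stages"]["simulate"] = {
        "n_host": len(host), "n_parasite": len(parasite),
        "n_libraries": len(design),
    }

    all_records = host + parasite
    lengths = {r.id: r.length for r in all_records}
    fpkm = expression.compute_fpkm(counts, lengths)
    presence = expression.presence_calls(fpkm, run_config)
    report["stages"]["presence"] = {g: len(p) for g, p in sorted(presence.items())}

    # assembly-consensus filter: species-level reference sets are the two
    # species' own assemblies (surrogates of per-species re-assemblies)
    species_refs = {
        "species_host": homology.KmerIndex.build(host, run_config.kmer_k),
        "species_parasite": homology.KmerIndex.build(parasite, run_config.kmer_k),
    }
    union_present = sorted(set().union(*(p.present_ids for p in presence.values())))
    by_id = {r.id: r for r in all_records}
    evidence = homology.scan_kmer([by_id[i] for i in union_present],
                                  species_refs, run_config)
    retained = homology.consensus_filter(set(union_present), evidence, run_config)
    presence = {
        g: expression.PresenceSet(g, frozenset(p.present_ids & retained), p.rule)
        for g, p in presence.items()
    }
    report["stages"]["consensus_filter"] = {
        "n_in": len(union_present), "n_retained": len(retained),
    }

    if not skip_orf_screen:
        coding_ids, frac = orf_screen.screen_unigenes(
            all_records, run_config.min_orf_nt)
        report["stages"]["orf_screen"] = {
            "n_coding": len(coding_ids), "fraction_coding": frac,
        }
    else:
        coding_ids = None

    partition = mobility.venn_partition(presence)
    report["stages"]["venn"] = partition.counts()

    candidates = partition.candidates
    if orf_strict and coding_ids is not None:
        candidates = frozenset(candidates & coding_ids)
    family_refs = {
        label: homology.KmerIndex.build(recs, run_config.kmer_k)
        for label, recs in refs.items()
    }
    cand_records = [by_id[i] for i in sorted(candidates)]
    fam_evidence = homology.scan_kmer(cand_records, family_refs, run_config)
    assignments = homology.assign_families(
        sorted(candidates), fam_evidence, run_config,
        family_a=synthetic_data.PARASITE_FAMILY,
        family_b=synthetic_data.HOST_FAMILY,
    )
    if orf_strict and coding_ids is not None:
        # restrict the partition's candidate regions to coding candidates
        regions = {k: frozenset(v & candidates) if k in ("CD_HC", "CD_HC_HA")
                   else v for k, v in partition.regions.items()}
        partition = mobility.VennPartition(regions)

    calls = mobility.classify_mobility(partition, assignments,
                                       all_ids=sorted(by_id))
    frac_cd, frac_ha = mobility.haustorium_mediation(calls, presence["HI"])
    summary = mobility.summarize_transfer(calls, partition, presence, presence["HI"])
    report["transfer_summary"] = summary.as_dict()
    report["haustorium_mediation"] = {
        "fraction_CD_origin": frac_cd, "fraction_HA_origin": frac_ha,
    }

    contrast = stats.abundance_contrast(fpkm, calls, "CD", run_config)
    report["stats"] = {
        "abundance_contrast_CD": dataclasses.asdict(contrast),
    }
    n_mobile_cd = sum(1 for c in calls if c.direction == "CD_to_HC")
    if n_mobile_cd >= 3:
        rho, r_log, n = stats.source_dest_correlation(
            fpkm, calls, "CD_to_HC", run_config)
        report["stats"]["source_dest_correlation_CD_to_HC"] = {
            "spearman_rho": rho, "pearson_r_on_logs": r_log, "n": n,
        }

    enrichment_results = []
    if with_enrichment:
        background = set(presence["CD"].present_ids)
        annotation = synthetic_data.simulate_annotation(
            sorted(background), seed=sim_config.seed)
        mobile_set = {c.unigene_id for c in calls
                      if c.direction == "CD_to_HC"} & background
        enrichment_results = stats.hypergeometric_enrichment(
            mobile_set, background, annotation, run_config)
        report["stats"]["enrichment_CD_to_HC"] = {
            "n_terms": len(enrichment_results),
            "n_enriched": sum(r.enriched for r in enrichment_results),
        }

    report["recovery"] = evaluate_against_truth(calls, truth)
    report["stages"]["classify"] = {
        d: sum(1 for c in calls if c.direction == d)
        for d in mobility.DIRECTIONS
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        synthetic_data.write_simulation(outdir, host, parasite, refs, truth, counts)
        expression.write_presence(presence, outdir / "presence.tsv")
        calls_df = pd.DataFrame([c.__dict__ for c in calls])
        calls_df.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        if enrichment_results:
            stats.enrichment_frame(enrichment_results).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False)
            report["enrichment_table"] = "enrichment.tsv"
        write_report(report, outdir / "report.json")
    return report


def write_report(report: Mapping, path: str | Path) -> None:
    """Byte-stable JSON report (sorted keys, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")


def report_bytes(report: Mapping) -> bytes:
    return (json.dumps(report, sort_keys=True, indent=2) + "\n").encode()


def run_pipeline(config_path: str | Path) -> dict:
    """Run from a YAML configuration file.

    Keys: ``mode`` ("synthetic" or "tallies"); ``simulation`` (a
    SimulationConfig mapping, synthetic mode); ``run`` (a RunConfig
    mapping); ``tallies`` (path, tallies mode); ``outdir``.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    mode = cfg.get("mode", "synthetic")
    run_config = RunConfig(**cfg.get("run", {}))
    outdir = cfg.get("outdir")
    if mode == "synthetic":
        sim = synthetic_data.SimulationConfig(**cfg.get("simulation", {}))
        return run_synthetic(sim, run_config, outdir=outdir,
                             orf_strict=bool(cfg.get("orf_strict", False)))
    if mode == "tallies":
        tallies_path = cfg.get("tallies")
        tallies = (read_tally_table(config_path.parent / tallies_path)
                   if tallies_path else worked_example_tallies())
        summary = mobility.summarize_from_tallies(tallies)
        report = {"config": {"mode": "tallies"},
                  "transfer_summary": summary.as_dict()}
        if {"orthogroup_missing_total", "orthogroup_shared_missing"} <= set(tallies):
            report["orthogroup_shared_missing_pct"] = stats.shared_missing_pct(
                int(tallies["orthogroup_shared_missing"]),
                int(tallies["orthogroup_missing_total"]))
        if outdir:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            write_report(report, Path(outdir) / "report.json")
        return report
    raise ValueError(f"unknown pipeline mode {mode!r}")
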