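"""Pipeline orchestration: one config, one output directory, one summary.

Stages run in order map -> profile -> pirna -> eve (if an EVE reference is
supplied) -> phylo (if alignments are supplied) -> clock/prevalence (if
their inputs are supplied). When a ``simulate`` block is present, every
input is generated first by :mod:`herivome.simulate` and written under
``<out>/inputs`` so the run is fully self-contained and reproducible.

Every stage writes plain TSV/newick/JSON so each summary number can be
grepped in a stage output. A MANIFEST records which stages completed; a
failed stage aborts the run with the stage name and offending input.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io as hio
from . import eve as eve_mod
from . import pirna as pirna_mod
from . import profiler as prof_mod
from .mapper import map_reads, stranded_coverage
from .phylo import clock_date, congruence, nj_tree, p_distance_matrix, prevalence
from .simulate import (SimulationConfig, simulate_codiverging_loci, simulate_eve,
                       simulate_small_rna_library, simulate_virus_genome)

KNOWN_KEYS = {"seed", "simulate", "inputs", "mapper", "profiler", "pirna",
              "eve", "phylo", "clock"}
KNOWN_INPUT_KEYS = {"reads", "references", "eve", "eve_reference", "eve_exclude",
                    "host_alignment", "virus_alignment", "screening_table"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    unknown_inputs = set(config.get("inputs") or {}) - KNOWN_INPUT_KEYS
    if unknown_inputs:
        raise ValueError(f"unknown input keys: {sorted(unknown_inputs)}")


def _require_file(stage: str, path: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"input file not found: {path}")
    return p


def run_pipeline(config: dict, out_dir: str | Path, force: bool = False) -> dict:
    """Execute the configured stages; returns the summary dict."""
    validate_config(config)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(
                f"output directory {out} exists and is not empty (use force)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    config_text = yaml.safe_dump(config, sort_keys=True)
    (out / "config.yaml").write_text(config_text)
    log_lines = [f"herivome {__version__}",
                 f"seed {seed}",
                 f"config sha256 {hashlib.sha256(config_text.encode()).hexdigest()}"]
    manifest: dict[str, bool] = {}
    summary: dict = {"seed": seed}

    inputs = dict(config.get("inputs") or {})
    if "simulate" in config and config["simulate"] is not None:
        inputs.update(_simulate_inputs(config, seed, out))
        manifest["simulate"] = True

    # --- map
    contigs = reads = None
    if inputs.get("reads") and inputs.get("references"):
        mcfg = config.get("mapper") or {}
        contigs = hio.read_fasta(_require_file("map", inputs["references"]))
        reads = hio.read_reads(_require_file("map", inputs["reads"]))
        try:
            alignments = map_reads(reads, contigs,
                                   min_match_fraction=float(
                                       mcfg.get("min_match_fraction", 0.95)),
                                   policy=mcfg.get("policy", "best"))
        except Exception as err:  # invalid reads, thresholds
            raise PipelineError("map", str(err)) from err
        hio.write_alignments(alignments, out / "alignments.tsv")
        coverage = stranded_coverage(alignments, contigs)
        hio.write_bedgraph(coverage, out / "coverage.bedgraph")
        summary["n_reads"] = len(reads)
        summary["n_mapped"] = len({a.read_id for a in alignments})
        manifest["map"] = True

        # --- profile
        pcfg = config.get("profiler") or {}
        profiles = prof_mod.size_profile(alignments)
        calls = {cid: prof_mod.call_sirna_enrichment(
                    p, min_reads=int(pcfg.get("min_reads", 50)),
                    min_norm21=float(pcfg.get("min_norm21", 20.0)),
                    peak_ratio=float(pcfg.get("peak_ratio", 2.0)))
                 for cid, p in profiles.items()}
        prof_mod.profiles_to_frame(profiles, calls).to_csv(
            out / "profiles.tsv", sep="\t", index=False)
        summary["sirna_calls"] = {cid: c.is_enriched for cid, c in calls.items()}
        manifest["profile"] = True

        # --- pirna
        rcfg = config.get("pirna") or {}
        read_seqs = dict(reads)
        candidates = pirna_mod.filter_pirna_candidates(
            alignments, min_len=int(rcfg.get("min_len", 24)),
            max_len=int(rcfg.get("max_len", 31)))
        bias_rows = []
        contig_ids = sorted({a.contig_id for a in candidates})
        for cid in contig_ids:
            groups = pirna_mod.candidate_reads_by_strand(
                [a for a in candidates if a.contig_id == cid], read_seqs)
            anti = pirna_mod.positional_frequencies(groups["antisense"], "antisense")
            sense = pirna_mod.positional_frequencies(groups["sense"], "sense")
            call = pirna_mod.call_bias(
                anti, sense, background=float(rcfg.get("background", 0.25)),
                alpha=float(rcfg.get("alpha", 0.001)),
                n_tests=max(len(contig_ids), 1))
            bias_rows.append({"contig_id": cid, "n_antisense": anti.n_reads,
                              "n_sense": sense.n_reads, "u1_freq": call.u1_freq,
                              "a10_freq": call.a10_freq, "u1_p": call.u1_p,
                              "a10_p": call.a10_p, "verdict": call.verdict})
        pd.DataFrame(bias_rows).to_csv(out / "pirna_bias.tsv", sep="\t", index=False)
        summary["pirna_verdicts"] = {r["contig_id"]: r["verdict"] for r in bias_rows}
        manifest["pirna"] = True

    # --- eve
    if inputs.get("eve") and reads is not None:
        ecfg = config.get("eve") or {}
        eve_seqs = hio.read_fasta(_require_file("eve", inputs["eve"]))
        eve_id, eve_seq = next(iter(eve_seqs.items()))
        ref_id = inputs.get("eve_reference") or next(iter(contigs))
        if ref_id not in contigs:
            raise PipelineError("eve", f"eve_reference {ref_id!r} not in references")
        exclude = [tuple(iv) for iv in inputs.get("eve_exclude") or []]
        report = eve_mod.align_pair(contigs[ref_id], eve_seq, exclude=exclude)
        mask = eve_mod.build_ambiguity_mask(
            report, min_read_len=int(ecfg.get("min_read_len", 18)))
        labels, label_profiles = eve_mod.assign_reads(
            reads, contigs[ref_id], eve_seq, mask=mask,
            min_match_fraction=float(ecfg.get("min_match_fraction", 0.95)),
            virus_id=ref_id, eve_id=eve_id)
        pd.DataFrame({"read_id": list(labels), "label": list(labels.values())}
                     ).to_csv(out / "eve_labels.tsv", sep="\t", index=False)
        with open(out / "eve_mask.bed", "w") as fh:
            for name, ivs in (("virus", mask.virus_intervals),
                              ("eve", mask.eve_intervals)):
                for s, e in ivs:
                    fh.write(f"{name}\t{s}\t{e}\n")
        counts = pd.Series(list(labels.values())).value_counts().to_dict()
        summary["eve"] = {
            "identity_pct": report.identity_pct,
            "n_windows_ge_min": len(mask.virus_intervals),
            "labels": {k: int(counts.get(k, 0)) for k in eve_mod.LABELS}}
        manifest["eve"] = True

    # --- phylo
    if inputs.get("host_alignment") and inputs.get("virus_alignment"):
        fcfg = config.get("phylo") or {}
        host = hio.read_fasta(_require_file("phylo", inputs["host_alignment"]))
        virus = hio.read_fasta(_require_file("phylo", inputs["virus_alignment"]))
        host_dm = p_distance_matrix(host)
        virus_dm = p_distance_matrix(virus)
        host_dm.to_frame().to_csv(out / "host_distances.tsv", sep="\t")
        virus_dm.to_frame().to_csv(out / "virus_distances.tsv", sep="\t")
        host_nwk = nj_tree(host_dm)
        virus_nwk = nj_tree(virus_dm)
        (out / "host.nwk").write_text(host_nwk + "\n")
        (out / "virus.nwk").write_text(virus_nwk + "\n")
        result = congruence(host_nwk, virus_nwk, host_dm=host_dm,
                            virus_dm=virus_dm,
                            n_permutations=int(fcfg.get("n_permutations", 9999)),
                            seed=seed)
        summary["congruence"] = {
            "rf": result.rf, "normalized_rf": result.normalized_rf,
            "correlation": result.correlation, "p_value": result.p_value}
        manifest["phylo"] = True

    # --- clock
    if config.get("clock"):
        ccfg = config["clock"]
        est = clock_date(float(ccfg["divergence"]), float(ccfg["rate"]))
        summary["clock"] = {"divergence": est.divergence, "rate": est.rate,
                            "tmrca_years": est.tmrca_years,
                            "tmrca_rounded": est.tmrca_rounded}
        manifest["clock"] = True

    # --- prevalence
    if inputs.get("screening_table"):
        table = hio.read_screening_table(
            _require_file("prevalence", inputs["screening_table"]))
        res = prevalence(table)
        res.per_population.to_csv(out / "prevalence.tsv", sep="\t", index=False)
        summary["prevalence"] = {"overall_pct": res.overall_pct,
                                 "n_screened": res.n_screened,
                                 "n_positive": res.n_positive}
        manifest["prevalence"] = True

    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _simulate_inputs(config: dict, seed: int, out: Path) -> dict:
    """Generate every pipeline input from the simulate block."""
    overrides = dict(config["simulate"] or {})
    overrides.setdefault("seed", seed)
    if "eve_duplication" in overrides and overrides["eve_duplication"] is not None:
        overrides["eve_duplication"] = tuple(overrides["eve_duplication"])
    if "conserved_motifs" in overrides:
        overrides["conserved_motifs"] = [tuple(m) for m in overrides["conserved_motifs"]]
    if "split_times" in overrides:
        overrides["split_times"] = {tuple(k.split(":")): float(v)
                                    for k, v in overrides["split_times"].items()}
    if "pirna_length_weights" in overrides:
        overrides["pirna_length_weights"] = {
            int(k): float(v) for k, v in overrides["pirna_length_weights"].items()}
    sim = SimulationConfig(**overrides)

    indir = out / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    contigs = simulate_virus_genome(sim)
    hio.write_fasta(contigs, indir / "references.fasta")
    first_id = next(iter(contigs))
    eve_seq, truth = simulate_eve(contigs[first_id], sim)
    hio.write_fasta({f"{first_id}_EVE": eve_seq}, indir / "eve.fasta")
    reads, truth_table = simulate_small_rna_library(contigs, sim)
    hio.write_fastq(reads, indir / "reads.fastq")
    truth_table.to_csv(indir / "truth.tsv", sep="\t", index=False)
    codiv = simulate_codiverging_loci(sim)
    hio.write_fasta(codiv.host_alignment, indir / "host_coi.fasta")
    hio.write_fasta(codiv.virus_alignment, indir / "virus_locus.fasta")
    (indir / "true_tree.nwk").write_text(codiv.tree_newick + "\n")

    generated = {
        "reads": str(indir / "reads.fastq"),
        "references": str(indir / "references.fasta"),
        "eve": str(indir / "eve.fasta"),
        "eve_reference": first_id,
        "host_alignment": str(indir / "host_coi.fasta"),
        "virus_alignment": str(indir / "virus_locus.fasta"),
    }
    if truth.duplication_eve is not None:
        generated["eve_exclude"] = [list(truth.duplication_eve)]
    return generated
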