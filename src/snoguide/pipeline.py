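"""End-to-end synthetic demo wiring all stages together.

The demo simulates an rRNA with planted methylation fractions and a
genome with planted snoRNA genes, runs the scan → expression → RMS →
guide-assignment → conservation stages, writes every artifact as
FASTA/BED/TSV/JSON, and verifies the planted truth was recovered. The
configuration is a strict schema (unknown keys are rejected) and every
threshold is echoed into the run manifest, so a run is reproducible
from its output directory alone.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import boxscan, conservation, expression, guidemap, ribomethseq
from . import synthetic_data as synth
from .io import write_bed6, write_fasta
from .tracks import write_track
import pandas as pd

log = logging.getLogger("snoguide")


class ScanConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_cd_distance: int = 50
    max_cd_distance: int = 100
    min_box_score: float = 9.0
    classifier_threshold: float = 29.0
    consensus_weight: float = 0.91


class ExpressionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_reads: int = 100
    sharp5_window: int = 2
    sharp5_min_fraction: float = 0.5
    upstream_window: int = 20
    max_upstream_ratio: float = 0.1


class ScoreCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 6
    call_threshold: float = 0.75
    full_threshold: float = 0.9


class GuideConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_flank: int = 10
    min_duplex_len: int = 7
    max_mismatch: int = 1


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rrna_length: int = 2000
    at_fraction: float = 0.7
    n_sites: int = 5
    fractions: list[float] = [1.0, 0.85, 0.5, 0.25, 0.0]
    min_gap: int = 50
    n_fragments: int = 200_000
    n_replicates: int = 3
    duplex_len: int = 10
    spacer: int = 150
    n_decoys: int = 2
    depth: int = 500
    sharp5: float = 0.9


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    simulation: SimulationConfig = SimulationConfig()
    scan: ScanConfig = ScanConfig()
    expression: ExpressionConfig = ExpressionConfig()
    score_c: ScoreCConfig = ScoreCConfig()
    guide: GuideConfig = GuideConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _params(config: PipelineConfig):
    scan = boxscan.ScanParams(
        min_cd_distance=config.scan.min_cd_distance,
        max_cd_distance=config.scan.max_cd_distance,
        min_box_score=config.scan.min_box_score,
        classifier_threshold=config.scan.classifier_threshold)
    expr = expression.ExpressionParams(
        min_reads=config.expression.min_reads,
        sharp5_window=config.expression.sharp5_window,
        sharp5_min_fraction=config.expression.sharp5_min_fraction,
        upstream_window=config.expression.upstream_window,
        max_upstream_ratio=config.expression.max_upstream_ratio)
    scorec = ribomethseq.ScoreCParams(
        k=config.score_c.k, call_threshold=config.score_c.call_threshold,
        full_threshold=config.score_c.full_threshold)
    guide = guidemap.GuideParams(
        target_flank=config.guide.target_flank,
        min_duplex_len=config.guide.min_duplex_len,
        max_mismatch=config.guide.max_mismatch)
    return scan, expr, scorec, guide


def run_demo(config: PipelineConfig, outdir: str | Path) -> int:
    """Simulate → scan → express → rms → assign → conserve.

    Returns 0 when every planted feature was recovered (all expressed
    genes bona fide, all high-fraction sites called within tolerance,
    all planted guides reassigned), 1 otherwise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    sim = config.simulation
    seed = config.seed
    scan_params, expr_params, scorec_params, guide_params = _params(config)
    manifest = {"seed": seed, "config": config.model_dump()}
    (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    log.info("demo seed=%d thresholds=%s", seed, json.dumps(manifest["config"]))

    # --- simulate rRNA, methylation truth, end counts -------------------
    rrna = synth.generate_rrna(sim.rrna_length, sim.at_fraction, seed=seed)
    truth = synth.plant_methylation(rrna, sim.n_sites, tuple(sim.fractions),
                                    min_gap=sim.min_gap, seed=seed + 1)
    write_fasta([(rrna.name, rrna.sequence)], outdir / "rrna.fa")
    pd.DataFrame({"reference": rrna.name,
                  "position": [p for p, _ in truth.sites],
                  "fraction": [f for _, f in truth.sites]},
                 ).to_csv(outdir / "methylation_truth.tsv", sep="\t", index=False)

    profiles = []
    for rep in range(sim.n_replicates):
        end5, end3 = synth.simulate_rms_endcounts(
            rrna, truth, n_fragments=sim.n_fragments, seed=seed + 10 + rep)
        write_track(end5, outdir / f"rep{rep + 1}.end5.tsv", sparse=True)
        write_track(end3, outdir / f"rep{rep + 1}.end3.tsv", sparse=True)
        profiles.append(ribomethseq.profile_from_tracks(
            end5, end3, params=scorec_params, replicate=f"rep{rep + 1}"))

    # --- plant snoRNA genes guiding the methylated sites ----------------
    called_truth = [(p, f) for p, f in truth.sites
                    if f > scorec_params.call_threshold]
    genes: list[synth.SnoRnaGene] = []
    for i, (pos, _) in enumerate(called_truth):
        usage = ("D", "Dprime")[i % 2]
        genes.append(synth.generate_snorna_gene(
            (rrna, pos), box_usage=usage, duplex_len=sim.duplex_len,
            seed=seed + 100 + i, sno_id=f"sno{i + 1}",
            at_fraction=sim.at_fraction))
    if len(called_truth) >= 2:
        genes.append(synth.generate_snorna_gene(
            [(rrna, called_truth[0][0]), (rrna, called_truth[1][0])],
            box_usage="both", duplex_len=sim.duplex_len,
            seed=seed + 200, sno_id=f"sno{len(genes) + 1}",
            at_fraction=sim.at_fraction))
    # one silent gene: passes the scan but must fail the expression test
    silent = synth.generate_snorna_gene(
        (rrna, called_truth[0][0]) if called_truth else (rrna, rrna.length // 2),
        box_usage="D", duplex_len=sim.duplex_len, seed=seed + 300,
        sno_id="silent", at_fraction=sim.at_fraction)
    genes.append(silent)

    genome = synth.assemble_genome(genes, n_decoys=sim.n_decoys,
                                   spacer=sim.spacer,
                                   at_fraction=sim.at_fraction, seed=seed + 400)
    write_fasta([("genome", genome.sequence)], outdir / "genome.fa")
    write_bed6(pd.DataFrame([{
        "chrom": "genome", "start": l.start, "end": l.end,
        "name": l.snorna_id, "score": 0, "strand": l.strand,
    } for l in genome.truth_loci]), outdir / "truth_loci.bed")

    expressed = {g.id for g in genes if g.id != "silent"}
    end5_reads, coverage = synth.simulate_small_rna_reads(
        genome, expressed, depth=sim.depth, sharp5=sim.sharp5, seed=seed + 500)
    write_track(end5_reads, outdir / "smallrna.end5.tsv", sparse=True)
    write_track(coverage, outdir / "smallrna.coverage.tsv", sparse=True)

    # --- scan + expression + classifier ---------------------------------
    box_model = boxscan.build_box_model(consensus_weight=config.scan.consensus_weight)
    candidates = boxscan.scan_candidates(genome, box_model, scan_params)
    bona_fide = []
    rows = []
    for cand in candidates:
        diag = expression.expression_score(cand.start, cand.end, cand.strand,
                                           end5_reads, coverage, expr_params)
        cand.expression_score = diag.score
        total, ok = boxscan.total_classifier_score(cand, params=scan_params)
        rows.append({
            "id": cand.id, "strand": cand.strand, "start": cand.start,
            "end": cand.end, "box_c_score": round(cand.box_c_score, 2),
            "box_d_score": round(cand.box_d_score, 2), "ts_score": cand.ts_score,
            "distance_score": cand.distance_score,
            "expression_score": cand.expression_score,
            "classifier_score": round(total, 2), "bona_fide": ok,
            "kturn_ok": cand.kturn_ok,
        })
        if ok:
            bona_fide.append(cand)
    pd.DataFrame(rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    # --- RMS calls -------------------------------------------------------
    calls = ribomethseq.call_sites(profiles, rrna.sequence, scorec_params)
    ribomethseq.calls_to_frame(calls).to_csv(outdir / "rms_calls.tsv",
                                             sep="\t", index=False)

    # --- guide assignment ------------------------------------------------
    sno_seqs = [(c.id, c.sequence) for c in bona_fide]
    if sno_seqs and calls:
        assignments, labels, unguided = guidemap.assign_guides(
            sno_seqs, calls, {rrna.name: rrna.sequence}, guide_params)
        frame = guidemap.assignments_to_frame(assignments)
        frame["label"] = frame["snorna_id"].map(labels)
        frame.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        summary_duplex = guidemap.duplex_summary(assignments) if assignments else {}
    else:
        assignments, labels, unguided = [], {}, list(calls)
        summary_duplex = {}

    # --- conservation of the published table -----------------------------
    records = conservation.load_site_table()
    counts = conservation.conservation_counts(records)
    with open(outdir / "conservation_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)

    # --- truth recovery checks -------------------------------------------
    call_positions = {c.position for c in calls}
    mean_scores = ribomethseq.mean_profile(profiles)
    missed = [p for p, f in called_truth if p not in call_positions]
    spurious = [c.position for c in calls
                if truth.fraction_at(c.position) <= 0.5]
    score_errors = {p: float(abs(mean_scores[p - 1] - f)) for p, f in truth.sites}
    expressed_loci = [l for l in genome.truth_loci if l.snorna_id in expressed]
    bona_ids = set()
    for cand in bona_fide:
        for locus in expressed_loci:
            if cand.start < locus.end and locus.start < cand.end \
                    and cand.strand == locus.strand:
                bona_ids.add(locus.snorna_id)
    planted_guides = {(g.id, t.position, t.box)
                      for g in genes if g.id in expressed for t in g.targets
                      if t.position in call_positions}
    recovered_guides = {(a.snorna_id, a.position, a.box_used)
                        for a in assignments}
    # bona fide candidate ids map back to locus ids via overlap
    cand_to_locus = {}
    for cand in bona_fide:
        for locus in genome.truth_loci:
            if cand.start < locus.end and locus.start < cand.end \
                    and cand.strand == locus.strand:
                cand_to_locus[cand.id] = locus.snorna_id
    recovered_guides = {(cand_to_locus.get(sid, sid), pos, box)
                        for sid, pos, box in recovered_guides}

    checks = {
        "all_high_sites_called": not missed,
        "no_low_sites_called": not spurious,
        "scores_within_tolerance": all(e <= 0.05 for e in score_errors.values()),
        "all_expressed_genes_bona_fide":
            bona_ids == {l.snorna_id for l in expressed_loci},
        "silent_gene_rejected": "silent" not in bona_ids,
        "all_planted_guides_recovered": planted_guides <= recovered_guides,
        "table_counts": counts["conserved"] == 28 and counts["specific"] == 21,
    }
    summary = {
        "n_candidates": len(candidates), "n_bona_fide": len(bona_fide),
        "n_calls": len(calls), "n_assignments": len(assignments),
        "n_unguided": len(unguided),
        "score_abs_error_max": max(score_errors.values()) if score_errors else 0.0,
        "duplex_summary": summary_duplex,
        "conservation": counts, "checks": checks,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    status = 0 if all(checks.values()) else 1
    log.info("demo finished status=%d checks=%s", status, checks)
    return status
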