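"""End-to-end pipeline runner and run manifest.

In synthetic mode the runner generates a locus with a middle-exon hairpin,
simulates reads for an exon-4a-expressing and a skipping sample group,
designs and counts junction probes, classifies isoform subsets, matches
samples across subsets by total transcript expression, stratifies samples
into expression quartiles, runs permutation gene-set enrichment, folds the
locus under its simulated SHAPE reactivities with well-determined-region
calling, and fits simulated 1:1 sensorgrams — emitting every artifact plus
a JSON manifest with checksums, seeds and warnings.

In file-backed mode the same stages run from user-supplied inputs where
provided; referenced paths are validated before any stage runs.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .enrichment import (
    GeneSet,
    permutation_nes,
    row_zscore,
    stratify_quartiles,
)
from .junctions import (
    JunctionProbe,
    classify_isoform_subsets,
    count_junction_reads,
    design_junction_probes,
    match_samples_by_expression,
)
from .spr import fit_1to1_global, summarize_replicates
from .structure import (
    call_well_determined_regions,
    extract_fused_construct,
    normalize_reactivity,
    partition_pair_probabilities,
    predict_structure,
    raw_reactivity,
)
from .synthetic import (
    STAGE_SEED_OFFSETS,
    SimConfig,
    build_synthetic_locus,
    simulate_expression_matrix,
    simulate_map_counts,
    simulate_reads,
    simulate_sensorgram,
)

__all__ = ["PipelineConfig", "RunManifest", "PipelineConfigError", "run_pipeline"]


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (e.g. a referenced path is missing)."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``synthetic=True`` generates all inputs from ``sim``; otherwise the
    optional path fields supply them and stages without inputs are skipped.
    """

    outdir: Path
    sim: SimConfig = field(default_factory=SimConfig)
    synthetic: bool = True
    # thresholds
    min_count: int = 1
    pairing_threshold: float = 0.95
    min_helix: int = 3
    n_perm: int = 1000
    min_depth: int = 1000
    write_reads: bool = False
    # file-backed inputs (non-synthetic mode)
    fastq_paths: dict[str, str] | None = None
    probes_fasta: str | None = None
    expression_tsv: str | None = None
    cls_path: str | None = None
    gmt_path: str | None = None
    map_counts_tsv: str | None = None
    fold_sequence_fasta: str | None = None
    spr_csv: str | None = None

    def validate(self) -> None:
        if not self.synthetic:
            paths = dict(self.fastq_paths or {})
            named = {
                "probes_fasta": self.probes_fasta,
                "expression_tsv": self.expression_tsv,
                "cls_path": self.cls_path,
                "gmt_path": self.gmt_path,
                "map_counts_tsv": self.map_counts_tsv,
                "fold_sequence_fasta": self.fold_sequence_fasta,
                "spr_csv": self.spr_csv,
            }
            for sample, p in paths.items():
                if not Path(p).exists():
                    raise PipelineConfigError(
                        f"FASTQ for sample {sample!r} not found: {p}"
                    )
            for name, p in named.items():
                if p is not None and not Path(p).exists():
                    raise PipelineConfigError(f"{name} not found: {p}")
        if not 0 < self.pairing_threshold < 1:
            raise PipelineConfigError("pairing_threshold must be in (0, 1)")
        if self.n_perm < 1:
            raise PipelineConfigError("n_perm must be >= 1")


@dataclass
class RunManifest:
    """Record of one pipeline run: stages, files, seeds, warnings."""

    seed: int
    seed_offsets: dict[str, int]
    created: str = ""
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, str],
                  info: dict | None = None,
                  stage_warnings: list[str] | None = None,
                  status: str = "ok") -> None:
        self.stages.append(
            {
                "name": name,
                "status": status,
                "outputs": outputs,
                "info": info or {},
                "warnings": stage_warnings or [],
            }
        )

    def file_hashes(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for st in self.stages:
            out.update(st["outputs"])
        return out

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "seed_offsets": self.seed_offsets,
            "created": self.created,
            "stages": self.stages,
        }


def _hash_outputs(outdir: Path, paths: list[Path]) -> dict[str, str]:
    return {str(p.relative_to(outdir)): dio.file_sha256(p) for p in paths}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline and return its manifest.

    Reruns with the same configuration (including the master seed) produce
    byte-identical output files; the manifest records a sha256 for each.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    manifest = RunManifest(
        seed=sim.seed,
        seed_offsets=dict(STAGE_SEED_OFFSETS),
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    if config.synthetic:
        _run_synthetic(config, outdir, manifest)
    else:
        _run_file_backed(config, outdir, manifest)

    dio.write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Synthetic mode
# ---------------------------------------------------------------------------

def _run_synthetic(config: PipelineConfig, outdir: Path,
                   manifest: RunManifest) -> None:
    sim = config.sim

    # --- locus + ground truth -------------------------------------------
    locus = build_synthetic_locus(sim)
    locus_fa = outdir / "locus.fasta"
    dio.write_fasta(
        {
            "exon_upstream": locus.exon_upstream,
            "exon_middle": locus.exon_middle,
            "exon_downstream": locus.exon_downstream,
            "transcript_with_middle": locus.transcript_with_middle,
            "transcript_without_middle": locus.transcript_without_middle,
        },
        locus_fa,
    )
    truth_json = outdir / "ground_truth.json"
    dio.write_json(
        {
            "coordinates": {k: list(v) for k, v in locus.coordinates.items()},
            "true_structure": [list(p) for p in locus.true_structure],
            "true_reactivity": list(locus.true_reactivity),
            "helix_intervals": [list(v) for v in locus.helix_intervals],
            "spr_params": {
                "ka": sim.spr.ka,
                "kd": sim.spr.kd,
                "rmax": sim.spr.rmax,
                "KD": sim.spr.kd / sim.spr.ka,
                "concentrations": list(sim.spr.concentrations),
            },
            "delta": sim.delta,
            "read_model": "single-end, uniform start, uniform strand",
        },
        truth_json,
    )
    manifest.add_stage(
        "simulate_locus", _hash_outputs(outdir, [locus_fa, truth_json]),
        info={"transcript_length": len(locus.transcript_with_middle)},
    )

    # --- expression + phenotype -----------------------------------------
    matrix, labels, target_genes = simulate_expression_matrix(sim)
    expr_tsv = outdir / "expression.tsv"
    matrix.to_csv(expr_tsv, sep="\t")
    cls_path = outdir / "phenotype.cls"
    dio.write_cls(list(labels), cls_path)
    gmt_path = outdir / "target_sets.gmt"
    target_set = GeneSet.from_iterable("SYNTHETIC_TARGET_SET", target_genes)
    dio.write_gene_sets_gmt([target_set], gmt_path,
                            {"SYNTHETIC_TARGET_SET": "delta-shifted genes"})
    manifest.add_stage(
        "simulate_expression",
        _hash_outputs(outdir, [expr_tsv, cls_path, gmt_path]),
        info={"n_genes": sim.n_genes, "delta": sim.delta},
    )

    # --- probes ----------------------------------------------------------
    incl_probe, skip_probe = design_junction_probes(
        locus.exon_upstream, locus.exon_middle, locus.exon_downstream,
        strict=(len(locus.exon_middle) == 30),
    )
    probes_fa = outdir / "probes.fasta"
    dio.write_fasta(
        {incl_probe.name: incl_probe.sequence,
         skip_probe.name: skip_probe.sequence},
        probes_fa,
    )
    manifest.add_stage("design_probes", _hash_outputs(outdir, [probes_fa]))

    # --- reads + quantification -----------------------------------------
    mixtures = {
        s: (1.0 if lab == "exon4a" else 0.0) for s, lab in labels.items()
    }
    sim_reads_cfg = dataclasses.replace(sim, mixture=mixtures)
    quant_rows = []
    results = []
    read_files: list[Path] = []
    for sample_id in labels.index:
        reads = simulate_reads(locus, sim_reads_cfg, sample_id)
        if config.write_reads:
            fq = outdir / f"reads_{sample_id}.fastq"
            dio.write_fastq(reads, fq)
            read_files.append(fq)
        res = count_junction_reads(
            reads, [incl_probe, skip_probe], sample_id=sample_id
        )
        results.append(res)
        for probe in (incl_probe.name, skip_probe.name):
            quant_rows.append(
                {
                    "sample_id": sample_id,
                    "probe": probe,
                    "count": res.counts[probe],
                    "total_reads": res.total_mapped_reads,
                    "cpm": round(res.cpm[probe], 2),
                }
            )
    quant_tsv = outdir / "junction_quant.tsv"
    pd.DataFrame(quant_rows).to_csv(quant_tsv, sep="\t", index=False)
    manifest.add_stage(
        "quantify_junctions",
        _hash_outputs(outdir, [quant_tsv, *read_files]),
        info={"n_samples": len(results), "depth": sim.depth},
    )

    # --- subset classification + matching --------------------------------
    subset_labels, summary = classify_isoform_subsets(
        results, min_count=config.min_count
    )
    subsets_tsv = outdir / "subsets.tsv"
    pd.DataFrame(
        [{"sample_id": s.sample_id, "label": s.label} for s in subset_labels]
    ).to_csv(subsets_tsv, sep="\t", index=False)
    summary_tsv = outdir / "subset_summary.tsv"
    summary.to_csv(summary_tsv, sep="\t", index=False)

    total_cpm = {
        r.sample_id: sum(r.cpm.values()) for r in results
    }
    by_label = {s.sample_id: s.label for s in subset_labels}
    cases = {s: total_cpm[s] for s, lab in by_label.items() if lab == "B"}
    pool = {s: total_cpm[s] for s, lab in by_label.items() if lab == "A"}
    pairs_tsv = outdir / "matched_pairs.tsv"
    matched_info: dict = {"n_cases": len(cases), "n_pool": len(pool)}
    if cases and len(pool) >= len(cases):
        matched = match_samples_by_expression(cases, pool)
        pd.DataFrame(
            matched.pairs,
            columns=["case_id", "control_id", "case_cpm", "control_cpm",
                     "abs_diff"],
        ).to_csv(pairs_tsv, sep="\t", index=False)
        matched_info["objective_value"] = matched.objective_value
        match_outputs = [subsets_tsv, summary_tsv, pairs_tsv]
    else:
        match_outputs = [subsets_tsv, summary_tsv]
        matched_info["note"] = "matching skipped: no cases or pool too small"
    manifest.add_stage(
        "classify_and_match", _hash_outputs(outdir, match_outputs),
        info=matched_info,
    )

    # --- stratification + enrichment -------------------------------------
    incl_cpm = pd.Series({r.sample_id: r.cpm[incl_probe.name] for r in results})
    q1, q4 = stratify_quartiles(incl_cpm)
    strat_tsv = outdir / "quartiles.tsv"
    pd.DataFrame(
        [{"sample_id": s, "quartile": "Q1"} for s in q1]
        + [{"sample_id": s, "quartile": "Q4"} for s in q4]
    ).to_csv(strat_tsv, sep="\t", index=False)

    sub = matrix[q1 + q4]
    strat_labels = pd.Series(
        ["Q1"] * len(q1) + ["Q4"] * len(q4), index=q1 + q4
    )
    enr = permutation_nes(
        sub, strat_labels, target_set, n_perm=config.n_perm,
        seed=sim.seed, positive_class="Q4",
    )
    enr_tsv = outdir / "enrichment.tsv"
    pd.DataFrame(
        [{
            "set": enr.set_name, "size": enr.set_size, "ES": enr.es,
            "NES": enr.nes, "p_nominal": enr.p_nominal, "n_perm": enr.n_perm,
        }]
    ).to_csv(enr_tsv, sep="\t", index=False)

    z_tsv = outdir / "target_row_zscores.tsv"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        row_zscore(matrix.loc[sorted(target_set.members)]).to_csv(
            z_tsv, sep="\t"
        )
    manifest.add_stage(
        "stratify_and_enrich",
        _hash_outputs(outdir, [strat_tsv, enr_tsv, z_tsv]),
        info={"ES": enr.es, "NES": enr.nes, "p_nominal": enr.p_nominal},
    )

    # --- SHAPE + folding --------------------------------------------------
    counts = simulate_map_counts(locus, sim)
    counts_tsv = outdir / "map_counts.tsv"
    counts.to_csv(counts_tsv, sep="\t", index=False)
    profile = normalize_reactivity(
        raw_reactivity(counts, min_depth=config.min_depth)
    )
    shape_path = outdir / "reactivity.shape"
    dio.write_shape_profile(profile, shape_path)

    rna = locus.transcript_with_middle.replace("T", "U")
    pp = partition_pair_probabilities(
        rna, reactivity=np.asarray(profile.normalized)
    )
    pp_tsv = outdir / "pair_probabilities.tsv"
    dio.write_pair_probabilities(pp, pp_tsv)
    regions = call_well_determined_regions(
        pp, threshold=config.pairing_threshold, min_helix=config.min_helix
    )
    regions_tsv = outdir / "well_determined_regions.tsv"
    pd.DataFrame(
        [
            {
                "span_start": r.span[0], "span_end": r.span[1],
                "n_pairs": len(r.pairs), "min_probability": r.min_probability,
            }
            for r in regions
        ],
        columns=["span_start", "span_end", "n_pairs", "min_probability"],
    ).to_csv(regions_tsv, sep="\t", index=False)

    db = predict_structure(pp)
    ct_path = outdir / "structure.ct"
    dio.write_structure_ct(rna, db, ct_path, name="synthetic_locus")

    fused = extract_fused_construct(rna, locus.helix_intervals)
    fused_fa = outdir / "fused_construct.fasta"
    dio.write_fasta({"fused_hairpin": fused.sequence}, fused_fa)
    manifest.add_stage(
        "shape_fold",
        _hash_outputs(
            outdir,
            [counts_tsv, shape_path, pp_tsv, regions_tsv, ct_path, fused_fa],
        ),
        info={
            "n_regions": len(regions),
            "fused_length": len(fused.sequence),
        },
    )

    # --- SPR --------------------------------------------------------------
    sensor = simulate_sensorgram(sim)
    spr_csv = outdir / "sensorgrams.csv"
    sensor.to_csv(spr_csv, index=False)
    fits = [
        fit_1to1_global(grp, replicate=int(rep))
        for rep, grp in sensor.groupby("replicate")
    ]
    fit_tsv = outdir / "spr_fits.tsv"
    pd.DataFrame(
        [
            {
                "replicate": f.replicate, "ka": f.ka, "kd": f.kd,
                "Rmax": f.rmax, "KD": f.kD, "residual_rms": f.residual_rms,
                "converged": f.converged,
            }
            for f in fits
        ]
    ).to_csv(fit_tsv, sep="\t", index=False)
    summ = summarize_replicates(fits)
    summ_tsv = outdir / "spr_summary.tsv"
    pd.DataFrame(
        [{
            "n": summ.n,
            "ka_mean": summ.ka_mean, "ka_sd": summ.ka_sd,
            "kd_mean": summ.kd_mean, "kd_sd": summ.kd_sd,
            "KD_mean": summ.kD_mean, "KD_sd": summ.kD_sd,
        }]
    ).to_csv(summ_tsv, sep="\t", index=False)
    manifest.add_stage(
        "spr_kinetics", _hash_outputs(outdir, [spr_csv, fit_tsv, summ_tsv]),
        info={"KD_mean": summ.kD_mean},
    )


# ---------------------------------------------------------------------------
# File-backed mode
# ---------------------------------------------------------------------------

def _run_file_backed(config: PipelineConfig, outdir: Path,
                     manifest: RunManifest) -> None:
    # quantification from FASTQ
    if config.fastq_paths:
        if not config.probes_fasta:
            raise PipelineConfigError(
                "file-backed quantification needs probes_fasta"
            )
        probes = [
            JunctionProbe(
                name=name,
                sequence=seq,
                junction_offsets=(5, 35) if "4a" in name else (20,),
            )
            for name, seq in dio.read_fasta(config.probes_fasta).items()
        ]
        rows = []
        results = []
        for sample_id, fq in sorted(config.fastq_paths.items()):
            res = count_junction_reads(
                dio.read_fastq(fq), probes, sample_id=sample_id
            )
            results.append(res)
            for probe in probes:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "probe": probe.name,
                        "count": res.counts[probe.name],
                        "total_reads": res.total_mapped_reads,
                        "cpm": round(res.cpm[probe.name], 2),
                    }
                )
        quant_tsv = outdir / "junction_quant.tsv"
        pd.DataFrame(rows).to_csv(quant_tsv, sep="\t", index=False)
        subset_labels, summary = classify_isoform_subsets(
            results,
            inclusion_probe=probes[0].name,
            skipping_probe=probes[1].name,
            min_count=config.min_count,
        )
        subsets_tsv = outdir / "subsets.tsv"
        pd.DataFrame(
            [{"sample_id": s.sample_id, "label": s.label}
             for s in subset_labels]
        ).to_csv(subsets_tsv, sep="\t", index=False)
        manifest.add_stage(
            "quantify_junctions", _hash_outputs(outdir, [quant_tsv, subsets_tsv])
        )
    if config.expression_tsv and config.cls_path and config.gmt_path:
        matrix = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        labels = pd.Series(dio.read_cls(config.cls_path),
                           index=matrix.columns)
        sets = dio.load_gene_sets_gmt(config.gmt_path)
        rows = []
        for gs in sets:
            enr = permutation_nes(
                matrix, labels, gs, n_perm=config.n_perm, seed=config.sim.seed
            )
            rows.append(
                {
                    "set": enr.set_name, "size": enr.set_size, "ES": enr.es,
                    "NES": enr.nes, "p_nominal": enr.p_nominal,
                }
            )
        enr_tsv = outdir / "enrichment.tsv"
        pd.DataFrame(rows).to_csv(enr_tsv, sep="\t", index=False)
        manifest.add_stage("enrichment", _hash_outputs(outdir, [enr_tsv]))
    if config.map_counts_tsv and config.fold_sequence_fasta:
        counts = pd.read_csv(config.map_counts_tsv, sep="\t")
        profile = normalize_reactivity(
            raw_reactivity(counts, min_depth=config.min_depth)
        )
        shape_path = outdir / "reactivity.shape"
        dio.write_shape_profile(profile, shape_path)
        seq = next(iter(dio.read_fasta(config.fold_sequence_fasta).values()))
        pp = partition_pair_probabilities(
            seq.replace("T", "U"), reactivity=np.asarray(profile.normalized)
        )
        pp_tsv = outdir / "pair_probabilities.tsv"
        dio.write_pair_probabilities(pp, pp_tsv)
        manifest.add_stage(
            "shape_fold", _hash_outputs(outdir, [shape_path, pp_tsv])
        )
    if config.spr_csv:
        sensor = pd.read_csv(config.spr_csv)
        group_col = "replicate" if "replicate" in sensor.columns else None
        fits = (
            [fit_1to1_global(g, replicate=int(r))
             for r, g in sensor.groupby(group_col)]
            if group_col
            else [fit_1to1_global(sensor)]
        )
        fit_tsv = outdir / "spr_fits.tsv"
        pd.DataFrame(
            [{"replicate": f.replicate, "ka": f.ka, "kd": f.kd,
              "Rmax": f.rmax, "KD": f.kD} for f in fits]
        ).to_csv(fit_tsv, sep="\t", index=False)
        manifest.add_stage("spr_kinetics", _hash_outputs(outdir, [fit_tsv]))
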