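"""Top-level pipeline driver: simulate -> include -> difftest -> permute ->
characterize, with one configuration object and a run report.

Every stage writes its outputs under the configured directory; all tables
carry the configuration hash in a header comment, and all randomness flows
from the single configured seed (sub-seeds are spawned deterministically
per stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import difftest, features, io, permute
from .inclusion import apply_detection_filters, compute_inclusion
from .simulate import (
    SimulationParams,
    SyntheticAnnotationParams,
    generate_annotation,
    generate_dataset,
    generate_ese_set,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger("exoninclusion")


@dataclass
class PipelineConfig:
    """Paths, selections and thresholds for one pipeline run."""

    outdir: str = "results/pipeline"
    data_dir: str | None = None       # read inputs here instead of simulating
    stages: tuple[str, ...] = (
        "simulate", "include", "difftest", "permute", "characterize")
    probeset_set: str | None = None   # 'core' / 'full' / None (all)
    region: str | None = None         # 'exonic' / 'intronic' / None
    detection_threshold: float = 0.5
    enrichment_thresholds: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5)
    characterization_alpha: float = 0.01
    bin_width: float = 0.05
    lambda_grid: tuple[float, ...] = difftest.DEFAULT_LAMBDA_GRID
    correction: str = "bh"            # 'bh' or 'qvalue'
    permutation_modes: tuple[str, ...] = ("within-pair", "splits")
    seed: int = 0
    simulation: SimulationParams = field(default_factory=SimulationParams)
    annotation_params: SyntheticAnnotationParams = field(
        default_factory=SyntheticAnnotationParams)

    def __post_init__(self) -> None:
        if not 0 < self.detection_threshold <= 1:
            raise ValueError("detection_threshold must be in (0, 1]")
        if not 0 < self.characterization_alpha < 1:
            raise ValueError("characterization_alpha must be in (0, 1)")
        for tau in self.enrichment_thresholds:
            if not 0 < tau <= 1:
                raise ValueError("enrichment thresholds must be in (0, 1]")

    def config_hash(self) -> str:
        # paths do not affect results, so they do not enter the hash
        payload = asdict(self)
        payload.pop("outdir", None)
        payload.pop("data_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Record counts, attrition, seed and warnings for one run."""

    seed: int = 0
    config_hash: str = ""
    stage_counts: dict = field(default_factory=dict)
    filter_report: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    wall_clock_s: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the requested stages in order; abort on any stage failure.

    Identical config + seed gives identical outputs.  Stages not requested
    are skipped; later stages read the on-disk outputs of earlier ones, so
    a partial run can resume from precomputed files in ``outdir``.
    """
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    comments = [f"config_hash={chash}", f"seed={config.seed}"]
    report = RunReport(seed=config.seed, config_hash=chash)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = {
        "simulate": int(seeds[0].generate_state(1)[0] % (2**31)),
        "annotation": int(seeds[1].generate_state(1)[0] % (2**31)),
        "mapping": int(seeds[2].generate_state(1)[0] % (2**31)),
        "ese": int(seeds[3].generate_state(1)[0] % (2**31)),
    }

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------
    if "simulate" in config.stages:
        try:
            params = SimulationParams(
                **{**asdict(config.simulation),
                   "seed": stage_seed["simulate"]})
            bundle, truth = generate_dataset(params)
            io.write_bundle(bundle, outdir, comments=comments)
            io.write_table(truth, outdir / "truth.tsv", comments=comments)
            ann, seqs = generate_annotation(
                config.annotation_params, truth, seed=stage_seed["annotation"]
            )
            io.write_exon_annotation(ann, outdir / "exon_annotation.tsv",
                                     comments=comments)
            io.write_gff3(ann, outdir / "exons.gff3")
            io.write_fasta(seqs, outdir / "exon_sequences.fasta")
            with open(outdir / "ese_hexamers.txt", "w") as fh:
                fh.write("\n".join(
                    generate_ese_set(seed=stage_seed["ese"])) + "\n")
            report.stage_counts["simulate"] = {
                "probesets": int(bundle.probesets.shape[0]),
                "metaprobesets": int(bundle.metaprobesets.shape[0]),
                "exons": int(len(ann)),
            }
            logger.info("simulate: %d probesets", bundle.probesets.shape[0])
        except Exception as exc:  # noqa: BLE001
            _fail("simulate", exc)

    data_dir = Path(config.data_dir) if config.data_dir else outdir

    # --- include ------------------------------------------------------
    if "include" in config.stages:
        try:
            bundle = io.read_bundle(data_dir)
            if config.probeset_set or config.region:
                bundle = bundle.select(config.probeset_set, config.region)
            filtered, frep = apply_detection_filters(bundle)
            incl = compute_inclusion(filtered, provenance=frep.steps)
            io.write_inclusion(incl, outdir / "inclusion.tsv",
                               comments=comments)
            io.write_json(frep.as_dict(), outdir / "filter_report.json")
            report.filter_report = frep.as_dict()
            report.stage_counts["include"] = {
                "probesets_retained": int(incl.values.shape[0])}
            logger.info("include: %d probesets retained",
                        incl.values.shape[0])
        except Exception as exc:  # noqa: BLE001
            _fail("include", exc)

    # --- difftest -----------------------------------------------------
    if "difftest" in config.stages:
        try:
            incl = io.read_inclusion(outdir / "inclusion.tsv")
            design = io.read_design(data_dir / "design.tsv")
            table, mod = difftest.run_tests(incl, design)
            usable = ~table["zero_variance"]
            pi0 = difftest.estimate_pi0(
                table.loc[usable, "p_plain"], config.lambda_grid)
            table["q"] = difftest.compute_qvalues(
                table["p_mod"].to_numpy(), pi0.pi0)
            io.write_table(table, outdir / "test_results.tsv",
                           comments=comments)
            io.write_json(
                {
                    "pi0": pi0.pi0,
                    "lambda_grid": list(pi0.lambda_grid),
                    "raw_pi0": list(pi0.raw_pi0),
                    "n_tests": pi0.n_tests,
                    "method": pi0.method,
                    "moderation": {"d0": mod.d0, "s02": mod.s02, "d": mod.d},
                },
                outdir / "pi0.json",
            )
            enrich = pd.DataFrame([
                difftest.direction_enrichment(table, tau)
                for tau in config.enrichment_thresholds
            ])
            io.write_table(enrich, outdir / "direction_enrichment.tsv",
                           index=False, comments=comments)
            bins = difftest.bin_direction(table, width=config.bin_width)
            io.write_table(bins, outdir / "direction_bins.tsv", index=False,
                           comments=comments)
            bundle = io.read_bundle(data_dir)
            contrast = difftest.expression_level_contrast(
                bundle, table.loc[table.index.intersection(
                    bundle.probesets.index)],
                alpha=config.characterization_alpha)
            io.write_table(contrast, outdir / "expression_contrast.tsv",
                           index=False, comments=comments)
            report.stage_counts["difftest"] = {
                "tested": int(usable.sum()), "pi0": pi0.pi0}
            logger.info("difftest: pi0=%.3f over %d probesets", pi0.pi0,
                        int(usable.sum()))
        except Exception as exc:  # noqa: BLE001
            _fail("difftest", exc)

    # --- permute ------------------------------------------------------
    if "permute" in config.stages:
        try:
            incl = io.read_inclusion(outdir / "inclusion.tsv")
            design = io.read_design(data_dir / "design.tsv")
            for mode in config.permutation_modes:
                summary = permute.run_permutation_analysis(
                    incl, design, mode=mode,
                    lambda_grid=config.lambda_grid)
                tag = mode.replace("-", "_")
                io.write_table(summary.table(),
                               outdir / f"permutation_{tag}.tsv",
                               index=False, comments=comments)
                io.write_json(summary.as_dict(),
                              outdir / f"permutation_{tag}.json")
                report.stage_counts[f"permute_{tag}"] = {
                    "n_configurations": len(summary.configs),
                    "empirical_p": summary.empirical_p,
                }
                logger.info("permute[%s]: p=%.4f", mode, summary.empirical_p)
        except Exception as exc:  # noqa: BLE001
            _fail("permute", exc)

    # --- characterize -------------------------------------------------
    if "characterize" in config.stages:
        try:
            table = io.read_table(outdir / "test_results.tsv")
            ann = io.read_exon_annotation(data_dir / "exon_annotation.tsv")
            seqs = io.read_fasta(data_dir / "exon_sequences.fasta")
            scores = ann[["ss5_score", "ss3_score"]]
            feats = features.derive_features(
                ann.drop(columns=["ss5_score", "ss3_score"]),
                sequences=seqs, splice_scores=scores)
            links = list(zip(ann["probeset"], ann.index))
            mapping = features.map_one_to_one(links,
                                              seed=stage_seed["mapping"])
            groups = features.assign_groups(
                mapping, table, alpha=config.characterization_alpha)
            feats = feats.loc[groups.index]
            feats["group"] = groups
            total = feats[[f"count_{b}" for b in "ACGT"]].sum(axis=1)
            feats["at_fraction"] = (
                feats["count_A"] + feats["count_T"]) / total
            comp = features.compare_feature_table(
                feats,
                ["exon_length", "intron_up", "intron_dn", "ss5_score",
                 "ss3_score", "gene_length", "dist3", "at_fraction"],
                correction=config.correction,
            )
            io.write_table(comp, outdir / "feature_comparisons.tsv",
                           index=False, comments=comments)
            io.write_table(features.length_class_summaries(feats),
                           outdir / "length_classes.tsv", comments=comments)
            eses = features.ESESet.from_file(data_dir / "ese_hexamers.txt")
            prev = features.ese_prevalence(groups, seqs, eses)
            io.write_table(prev, outdir / "ese_prevalence.tsv",
                           comments=comments)
            io.write_table(feats, outdir / "exon_features.tsv",
                           comments=comments)
            report.stage_counts["characterize"] = {
                "exons": int(len(feats)),
                "up": int((feats["group"] == "Up").sum()),
                "down": int((feats["group"] == "Down").sum()),
            }
            logger.info("characterize: %d exons", len(feats))
        except Exception as exc:  # noqa: BLE001
            _fail("characterize", exc)

    report.wall_clock_s = time.monotonic() - t0
    io.write_json(report.as_dict(), outdir / "run_report.json")
    return report
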