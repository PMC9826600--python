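"""End-to-end orchestration: simulate/load -> QC -> differential -> DMR ->
longitudinal, with a machine-readable run summary.

Every stage consumes the previous stage's outputs; samples flagged by QC are
excluded downstream but retained (with flags) in the QC report. All
randomness derives from a single seed recorded in the summary, so a rerun
with the same inputs, config and seed reproduces every output byte for byte
(timestamps are opt-in for exactly that reason).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .differential import CohortDifferential, random_probe_purities
from .dmr import classify_singletons, dmr_group_means, merge_sites, rank_dmrs, sites_from_results, write_dmr_bed
from .imprint import ImprintQC
from .io import (
    BetaMatrix,
    ProbeAnnotation,
    RegionSet,
    SampleManifest,
    read_annotation,
    read_beta_matrix,
    read_manifest,
    read_regions,
    write_beta_matrix,
    write_manifest,
    write_annotation,
    write_regions,
)
from .longitudinal import LongitudinalModel
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("spermethylome")


@dataclass
class RunSummary:
    config: dict
    seed: int
    version: str = __version__
    stage_counts: dict = field(default_factory=dict)
    timestamps: dict | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _log_stage(stage: str, message: str) -> None:
    log.info("%s | %s", stage, message)


def run_all(
    out_dir: str | Path,
    sim_config: SimulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    inputs: dict | None = None,
    seed: int | None = None,
    write_matrices: bool = False,
    random_control_draws: int = 0,
    include_timestamps: bool = False,
) -> RunSummary:
    """Run the full pipeline into ``out_dir``.

    Either ``sim_config`` (synthetic cohort) or ``inputs`` (paths with keys
    beta, manifest, annotation, regions, optionally coverage) must be given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = analysis_config or AnalysisConfig()
    if seed is not None:
        cfg.rng_seed = seed
    timestamps: dict = {}

    def stamp(name: str) -> None:
        timestamps[name] = datetime.now(timezone.utc).isoformat()

    stamp("start")
    counts: dict = {}

    try:
        # ---- stage: inputs -------------------------------------------------
        if sim_config is not None:
            if seed is not None:
                sim_config.rng_seed = seed
            cohort = simulate_cohort(sim_config)
            betas, manifest, annotation, regions = (
                cohort.betas, cohort.manifest, cohort.annotation, cohort.regions,
            )
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {
                        "signature_sites": cohort.truth.signature_sites.to_dict("records"),
                        "contamination": cohort.truth.contamination,
                        "n_dynamic": int(cohort.truth.dynamic.sum()),
                        "pulse_sites": {k: list(map(str, v)) for k, v in cohort.truth.pulse_sites.items()},
                    },
                    fh, indent=2, sort_keys=True,
                )
            if write_matrices:
                write_beta_matrix(betas, out / "beta.tsv", out / "coverage.tsv")
                write_manifest(manifest, out / "manifest.csv")
                write_annotation(annotation, out / "annotation.tsv")
                write_regions(regions, out / "regions.bed")
            sim_snapshot = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(sim_config).items()
                if isinstance(v, (int, float, str, tuple, list, dict))
            }
        elif inputs is not None:
            betas = read_beta_matrix(inputs["beta"], inputs.get("coverage"))
            manifest = read_manifest(inputs["manifest"])
            annotation = read_annotation(inputs["annotation"])
            regions = read_regions(inputs["regions"])
            sim_snapshot = None
        else:
            raise ValueError("provide either sim_config or inputs")
        counts["samples_in"] = len(betas.samples)
        counts["probes_in"] = len(betas.probes)
        _log_stage("inputs", f"{counts['probes_in']} probes x {counts['samples_in']} samples")
        stamp("inputs")

        # ---- stage: imprint QC --------------------------------------------
        qc = ImprintQC(betas, annotation, regions, cfg).fit()
        qc.icr_means.to_csv(out / "icr_means.tsv", sep="\t", index_label="sample_id")
        pd.concat([qc.estimates_frame(), qc.flags], axis=1).to_csv(
            out / "qc_report.tsv", sep="\t", index_label="sample_id"
        )
        excluded = qc.excluded_samples
        keep = [s for s in betas.samples if s not in set(excluded)]
        betas_clean = betas.select_samples(keep)
        manifest_clean = manifest.select(keep)
        counts["samples_flagged"] = len(excluded)
        counts["samples_retained"] = len(keep)
        _log_stage("imprint_qc", f"flagged {excluded}")
        stamp("imprint_qc")

        # ---- stage: baseline differential ---------------------------------
        model = CohortDifferential(betas_clean, manifest_clean, annotation, cfg)
        res = model.fit(tukey="significant")
        res.table.to_csv(out / "differential.tsv", sep="\t", index_label="probe_id")
        counts["probes_filtered"] = len(res.table)
        counts["probes_significant"] = res.n_significant
        top = res.top_probes()
        (out / "top_probes.txt").write_text("\n".join(top) + "\n")
        purity_report = {"top_k": len(top)}
        if len(model.betas.samples) >= 3 and len(set(model.manifest["cohort"])) >= 2:
            cl = res.cluster_top_probes()
            purity_report["top_k_purity"] = cl.purity
            if random_control_draws > 0:
                rng = np.random.default_rng(cfg.rng_seed)
                rand = random_probe_purities(
                    model.betas.beta, model.manifest.set_index("sample_id")["cohort"],
                    k=len(top), n_draws=random_control_draws, rng=rng,
                )
                purity_report["random_purity_mean"] = float(rand.mean())
        with open(out / "purity.json", "w") as fh:
            json.dump(purity_report, fh, indent=2, sort_keys=True)
        counts.update({k: v for k, v in purity_report.items() if k != "top_k"})
        _log_stage("baseline_diff", f"{res.n_significant} significant probes")
        stamp("baseline_diff")

        # ---- stage: DMR discovery -----------------------------------------
        sites = sites_from_results(res.table, annotation.frame)
        dmrs = merge_sites(sites, cfg.merge_distance_bp)
        ranked = rank_dmrs(dmrs)
        ranked = dmr_group_means(ranked, res.table)
        singles = classify_singletons(dmrs)
        write_dmr_bed(ranked, out / "dmrs.bed")
        ranked.drop(columns="site_ids").to_csv(out / "dmrs_ranked.tsv", sep="\t", index=False)
        counts["dmr_singletons"] = singles.n_single
        counts["dmr_regions"] = singles.n_regions
        counts["dmr_pct_single"] = singles.pct_single
        _log_stage("dmr", f"{singles.n_regions} multi-site DMRs, {singles.n_single} singletons")
        stamp("dmr")

        # ---- stage: longitudinal ------------------------------------------
        mode = "capture" if betas_clean.coverage is not None else "array"
        lon = LongitudinalModel(betas_clean, manifest_clean, cfg, mode=mode).fit()
        if not lon.table.empty:
            lon.table.to_csv(out / "longitudinal.tsv", sep="\t", index=False)
            venns = {}
            for subj in lon.table["subject_id"].unique():
                sets = lon.subject_sets(subj)
                if len(sets) >= 2:
                    cells, persistent = lon.venn(subj)
                    venns[subj] = {
                        "cells": {"+".join(f"m{int(t)}" for t in k): v for k, v in cells.items()},
                        "persistent": len(persistent),
                    }
            with open(out / "venn.json", "w") as fh:
                json.dump(venns, fh, indent=2, sort_keys=True)
            counts["reference_drift"] = lon.reference_mean
        _log_stage("longitudinal", f"reference drift {lon.reference_mean}")
        stamp("longitudinal")
    except Exception as exc:
        # retain partial outputs under a .partial marker and re-raise with
        # the stage name embedded
        stage = list(timestamps)[-1]
        (out / f"{stage}.partial").write_text(str(exc) + "\n")
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    stamp("end")
    summary = RunSummary(
        config={"analysis": cfg.to_dict(), "simulation": sim_snapshot},
        seed=cfg.rng_seed,
        stage_counts=counts,
        timestamps=timestamps if include_timestamps else None,
    )
    summary.to_json(out / "run_summary.json")
    return summary
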