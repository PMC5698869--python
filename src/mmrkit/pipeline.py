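"""End-to-end orchestration: simulate -> erp -> qc -> assoc -> predict ->
power -> report, with a reproducibility manifest.

Stages communicate exclusively through files in the output directory (TSV
for tables, EDF for recordings, PNG for figures), so any stage can be rerun
from disk.  The manifest records the config hash, seeds and SHA-256 digests
of every artifact; deterministic stages reproduce identical digests under
identical config and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import report as mreport
from .association import association_scan, compare_covariate_adjustment
from .config import PipelineConfig
from .erp.workflow import measures_to_frame, process_subject, roi_mean_wave
from .panel import candidate_snps, load_panel
from .power import PowerQuery, required_effect_size
from .prediction import compare_models, compute_prs
from .qc import QCThresholds, apply_qc
from .simulate.eeg import generate_eeg_dataset
from .simulate.genotypes import generate_genotypes
from .simulate.phenotypes import SpellingModel, generate_phenotypes
from .simulate.seeds import STREAM_GENOTYPES, STREAM_PHENOTYPES, child_seed


class StageError(RuntimeError):
    """Failure wrapped with the name of the pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages_completed: list[str] = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)  # relpath -> sha256
    log: list[str] = field(default_factory=list)
    complete: bool = False
    started: float = field(default_factory=time.time)

    def record(self, out_dir: Path, *paths: Path) -> None:
        for p in paths:
            self.artifacts[str(p.relative_to(out_dir))] = hashlib.sha256(
                p.read_bytes()).hexdigest()

    def save(self, out_dir: Path) -> None:
        payload = {"config_hash": self.config_hash, "seed": self.seed,
                   "stages_completed": self.stages_completed,
                   "artifacts": self.artifacts, "log": self.log,
                   "complete": self.complete,
                   "elapsed_s": round(time.time() - self.started, 2)}
        (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2))


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(config.model_dump(), sort_keys=True)
                          .encode()).hexdigest()[:16]


def stage_simulate(config: PipelineConfig, out_dir: Path, manifest: RunManifest) -> None:
    sim = config.simulate
    panel = load_panel()
    genotypes = generate_genotypes(
        sim.n_subjects, panel, missing_rate=sim.missing_rate,
        seed=child_seed(config.seed, STREAM_GENOTYPES))
    phenotypes = generate_phenotypes(
        genotypes, panel, SpellingModel(genetic_r2=sim.genetic_r2),
        seed=child_seed(config.seed, STREAM_PHENOTYPES))
    mio.write_dosage_tsv(out_dir / "genotypes.tsv", genotypes)
    mio.write_vcf(out_dir / "genotypes.vcf", genotypes, panel)
    mio.write_table_tsv(out_dir / "phenotypes.tsv", phenotypes)

    dataset = generate_eeg_dataset(
        genotypes, phenotypes, config.template_model(),
        blocks=tuple(sim.blocks), fs_hz=sim.fs_hz,
        n_total=sim.stimulus.n_total, n_deviant=sim.stimulus.n_deviant,
        min_spacing=sim.stimulus.min_spacing,
        isi_range_ms=(sim.stimulus.isi_min_ms, sim.stimulus.isi_max_ms),
        seed=config.seed)
    eeg_dir = out_dir / "eeg"
    eeg_dir.mkdir(exist_ok=True)
    for subject, recs in dataset.items():
        for rec in recs:
            stem = f"{subject}_block{rec.block_id}"
            mio.write_edf(eeg_dir / f"{stem}.edf", rec.eeg)
            mio.write_events_tsv(eeg_dir / f"{stem}_events.tsv", rec.events)
    manifest.record(out_dir, out_dir / "genotypes.tsv", out_dir / "genotypes.vcf",
                    out_dir / "phenotypes.tsv")
    manifest.log.append(f"simulate: {len(dataset)} subjects x {len(sim.blocks)} blocks, "
                        f"{sim.stimulus.n_total} stimuli/block")


def stage_erp(config: PipelineConfig, out_dir: Path, manifest: RunManifest) -> None:
    eeg_dir = out_dir / "eeg"
    pconfig = config.preprocess_config()
    subjects = sorted({p.name.split("_block")[0] for p in eeg_dir.glob("*.edf")})
    if not subjects:
        raise FileNotFoundError(f"no EDF recordings in {eeg_dir}")
    measures, waves = [], {}
    times = None
    for subject in subjects:
        recs = []
        for edf in sorted(eeg_dir.glob(f"{subject}_block*.edf")):
            events = mio.read_events_tsv(edf.with_name(edf.stem + "_events.tsv"))
            recs.append((mio.read_edf(edf), events))
        measure, diff = process_subject(recs, pconfig, subject_id=subject)
        measures.append(measure)
        waves[subject] = roi_mean_wave(diff, pconfig.roi)
        times = diff.times_ms
    table = measures_to_frame(measures)
    mio.write_table_tsv(out_dir / "mmr.tsv", table)
    wave_df = pd.DataFrame(waves, index=pd.Index(times, name="time_ms")).T
    wave_df.index.name = "subject_id"
    mio.write_table_tsv(out_dir / "difference_waves.tsv", wave_df)
    manifest.record(out_dir, out_dir / "mmr.tsv", out_dir / "difference_waves.tsv")
    kept = table[["n_valid_deviant", "n_valid_standard"]].sum()
    manifest.log.append(f"erp: {len(subjects)} subjects; valid trials "
                        f"deviant={int(kept.iloc[0])} standard={int(kept.iloc[1])}")


def stage_qc(config: PipelineConfig, out_dir: Path, manifest: RunManifest) -> None:
    genotypes = mio.read_dosage_tsv(out_dir / "genotypes.tsv")
    thresholds = QCThresholds(hwe_alpha=config.qc.hwe_alpha,
                              snp_call_rate_min=config.qc.snp_call_rate_min,
                              ind_call_rate_min=config.qc.ind_call_rate_min,
                              maf_min=config.qc.maf_min)
    filtered, qc_report = apply_qc(genotypes, thresholds, config.qc.hwe_method)
    mio.write_dosage_tsv(out_dir / "genotypes_qc.tsv", filtered)
    mio.write_table_tsv(out_dir / "qc_snps.tsv", qc_report.snp_stats)
    mio.write_table_tsv(out_dir / "qc_individuals.tsv", qc_report.individual_stats)
    manifest.record(out_dir, out_dir / "genotypes_qc.tsv", out_dir / "qc_snps.tsv",
                    out_dir / "qc_individuals.tsv")
    manifest.log.append(f"qc: kept {qc_report.n_snps_kept} SNPs x "
                        f"{qc_report.n_individuals_kept} individuals "
                        f"(HWE Bonferroni m={qc_report.hwe_bonferroni_m})")


def stage_assoc(config: PipelineConfig, out_dir: Path, manifest: RunManifest) -> None:
    panel = load_panel()
    mmr = mio.read_table_tsv(out_dir / "mmr.tsv")["mmr_uv"]
    genotypes = mio.read_dosage_tsv(out_dir / "genotypes_qc.tsv")
    phenotypes = mio.read_table_tsv(out_dir / "phenotypes.tsv")
    common = mmr.index.intersection(genotypes.index).intersection(phenotypes.index)
    cand = [s for s in genotypes.columns if s in candidate_snps(panel).index]
    results = association_scan(mmr.loc[common], genotypes.loc[common, cand],
                               phenotypes.loc[common], adjust_add=False,
                               fdr_m=config.assoc.fdr_m)
    results_add = association_scan(mmr.loc[common], genotypes.loc[common, cand],
                                   phenotypes.loc[common], adjust_add=True,
                                   fdr_m=config.assoc.fdr_m)
    deltas = compare_covariate_adjustment(results, results_add)
    mio.write_table_tsv(out_dir / "association.tsv", results)
    mio.write_table_tsv(out_dir / "association_add_adjusted.tsv", results_add)
    mio.write_table_tsv(out_dir / "add_adjustment_deltas.tsv", deltas)
    table = mreport.association_table(results, panel)
    mio.write_table_tsv(out_dir / "association_top.tsv", table, index=False)
    manifest.record(out_dir, out_dir / "association.tsv",
                    out_dir / "association_add_adjusted.tsv",
                    out_dir / "add_adjustment_deltas.tsv",
                    out_dir / "association_top.tsv")
    manifest.log.append(f"assoc: {len(results)} SNPs tested on n="
                        f"{int(results['n_used'].max())}; "
                        f"{int((results['p'] < .05).sum())} nominal")


def stage_predict(config: PipelineConfig, out_dir: Path, manifest: RunManifest) -> None:
    panel = load_panel()
    mmr = mio.read_table_tsv(out_dir / "mmr.tsv")["mmr_uv"]
    genotypes = mio.read_dosage_tsv(out_dir / "genotypes_qc.tsv")
    phenotypes = mio.read_table_tsv(out_dir / "phenotypes.tsv")
    score = compute_prs(genotypes, panel)
    common = mmr.index.intersection(score.prs.index).intersection(phenotypes.index)
    comparison = compare_models(mmr.loc[common], score.prs.loc[common],
                                phenotypes.loc[common, "poor_speller"].astype(int),
                                ci_method=config.predict.ci_method)
    payload = comparison.to_dict()
    payload["n_snps_scored"] = score.n_snps_scored
    (out_dir / "prediction.json").write_text(json.dumps(payload, indent=2))
    mio.write_table_tsv(out_dir / "prs.tsv",
                        score.prs.rename("prs").to_frame())
    manifest.record(out_dir, out_dir / "prediction.json", out_dir / "prs.tsv")
    manifest.log.append(
        f"predict: AUC mmr={comparison.auc_mmr:.2f} prs={comparison.auc_prs:.2f} "
        f"combined={comparison.auc_combined:.2f}; NRI={comparison.nri_cont:.2f} "
        f"IDI={comparison.idi:.3f}")


def stage_power(config: PipelineConfig, out_dir: Path, manifest: RunManifest) -> None:
    rows = []
    for alpha in config.power.alpha_levels:
        res = required_effect_size(PowerQuery(
            alpha=alpha, target_power=config.power.target_power,
            df_num=config.power.df_num, df_den=config.power.df_den,
            method=config.power.method))
        rows.append({"alpha": alpha, "target_power": config.power.target_power,
                     "r2_explained": res.r2_explained, "f2": res.f2,
                     "ncp_lambda": res.ncp_lambda})
    table = pd.DataFrame(rows)
    mio.write_table_tsv(out_dir / "power.tsv", table, index=False)
    manifest.record(out_dir, out_dir / "power.tsv")
    manifest.log.append("power: " + ", ".join(
        f"alpha={r['alpha']:g}: R2={100 * r['r2_explained']:.1f}%" for r in rows))


def stage_report(config: PipelineConfig, out_dir: Path, manifest: RunManifest) -> None:
    phenotypes = mio.read_table_tsv(out_dir / "phenotypes.tsv")
    waves = mio.read_table_tsv(out_dir / "difference_waves.tsv")
    times = waves.columns.astype(float).to_numpy()
    poor_ids = phenotypes.index[phenotypes["poor_speller"].astype(bool)]
    groups = {"poor spellers": waves.loc[waves.index.intersection(poor_ids)].to_numpy(),
              "controls": waves.loc[waves.index.difference(poor_ids)].to_numpy()}
    mreport.plot_difference_waves(groups, times, out_dir / "difference_waves.png")
    results = mio.read_table_tsv(out_dir / "association.tsv")
    mreport.plot_qq(results["p"].dropna().to_numpy(), out_dir / "qq.png")
    genotypes = mio.read_dosage_tsv(out_dir / "genotypes_qc.tsv")
    mmr = mio.read_table_tsv(out_dir / "mmr.tsv")["mmr_uv"]
    top = results.sort_values("p").index[:3]
    common = mmr.index.intersection(genotypes.index)
    mreport.plot_genotype_boxplots(mmr.loc[common], genotypes.loc[common],
                                   [s for s in top if s in genotypes.columns],
                                   out_dir / "genotype_boxplots.png")
    manifest.record(out_dir, out_dir / "difference_waves.png", out_dir / "qq.png",
                    out_dir / "genotype_boxplots.png")
    manifest.log.append("report: figures rendered")


STAGES = [("simulate", stage_simulate), ("erp", stage_erp), ("qc", stage_qc),
          ("assoc", stage_assoc), ("predict", stage_predict),
          ("power", stage_power), ("report", stage_report)]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 simulate: bool = True) -> RunManifest:
    """Run all stages; fails fast with stage-named errors.

    Partial outputs are kept on failure, with the manifest marking the run
    incomplete.  With ``simulate=False`` the input artifacts (EDF + events,
    genotypes, phenotypes) must already exist in ``out_dir``.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    try:
        for name, stage in STAGES:
            if name == "simulate" and not simulate:
                continue
            try:
                stage(config, out, manifest)
            except Exception as err:
                raise StageError(name, err) from err
            manifest.stages_completed.append(name)
        manifest.complete = True
    finally:
        manifest.save(out)
    return manifest
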