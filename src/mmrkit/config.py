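"""Pipeline configuration: nested, validated, YAML round-trippable.

Defaults are the study conditions: two 600-stimulus oddball blocks (90
deviants, >= 2 standards between deviants, ISI 1450-1750 ms), 500 Hz
acquisition, the preprocessing chain of the protocol, candidate-panel QC
thresholds, and 67 subjects.  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StimulusSection(_Strict):
    n_total: int = 600
    n_deviant: int = 90
    min_spacing: int = 2
    isi_min_ms: float = 1450.0
    isi_max_ms: float = 1750.0


class TemplateSection(_Strict):
    control_amp_uv: float = 1.5
    poor_amp_uv: float = 4.5
    subject_sigma_uv: float = 4.0
    noise_sigma_uv: float = 8.0
    noise_exponent: float = 1.0
    alpha_amp_uv: float = 1.0
    artifact_rate: float = 0.2
    artifact_amp_uv: float = 150.0
    per_allele_shift_uv: dict[str, float] | None = None  # None -> packaged defaults


class SimulateSection(_Strict):
    n_subjects: int = 67
    fs_hz: float = 500.0
    blocks: list[int] = [1, 2]
    missing_rate: float = 0.01
    genetic_r2: float = 0.07
    stimulus: StimulusSection = StimulusSection()
    template: TemplateSection = TemplateSection()


class ErpSection(_Strict):
    lowpass_hz: float | None = 30.0
    highpass_hz: float | None = 0.5
    resample_hz: float | None = 250.0
    reject_threshold_uv: float = 80.0
    reject_window_ms: float = 200.0
    reject_mode: str = "absolute"
    epoch_start_ms: float = -200.0
    epoch_end_ms: float = 1250.0
    baseline_start_ms: float = -200.0
    baseline_end_ms: float = 0.0
    mmr_start_ms: float = 300.0
    mmr_end_ms: float = 600.0
    roi: list[str] = ["F3", "Fz", "F4"]
    contrast: str = "pooled"


class QcSection(_Strict):
    hwe_alpha: float = 0.05
    snp_call_rate_min: float = 0.97
    ind_call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_method: str = "chisq"


class AssocSection(_Strict):
    adjust_add: bool = False
    fdr_m: int | None = 25


class PredictSection(_Strict):
    ci_method: str = "delong"


class PowerSection(_Strict):
    alpha_levels: list[float] = [0.05, 0.01, 0.001]
    target_power: float = 0.80
    df_num: int = 1
    df_den: int = 52  # published-figures preset
    method: str = "normal_approx"


class PipelineConfig(_Strict):
    seed: int = 0
    out_dir: str = "mmrkit_run"
    simulate: SimulateSection = SimulateSection()
    erp: ErpSection = ErpSection()
    qc: QcSection = QcSection()
    assoc: AssocSection = AssocSection()
    predict: PredictSection = PredictSection()
    power: PowerSection = PowerSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def preprocess_config(self):
        from .erp.containers import PreprocessConfig

        e = self.erp
        return PreprocessConfig(
            lowpass_hz=e.lowpass_hz, highpass_hz=e.highpass_hz,
            resample_hz=e.resample_hz, reject_threshold_uv=e.reject_threshold_uv,
            reject_window_ms=e.reject_window_ms, reject_mode=e.reject_mode,
            epoch_window_ms=(e.epoch_start_ms, e.epoch_end_ms),
            baseline_window_ms=(e.baseline_start_ms, e.baseline_end_ms),
            mmr_window_ms=(e.mmr_start_ms, e.mmr_end_ms),
            roi=tuple(e.roi), contrast=e.contrast)

    def template_model(self):
        from .simulate.eeg import DEFAULT_ALLELE_SHIFTS_UV, ERPTemplateModel

        t = self.simulate.template
        shifts = (dict(DEFAULT_ALLELE_SHIFTS_UV) if t.per_allele_shift_uv is None
                  else dict(t.per_allele_shift_uv))
        return ERPTemplateModel(
            control_amp_uv=t.control_amp_uv, poor_amp_uv=t.poor_amp_uv,
            subject_sigma_uv=t.subject_sigma_uv, noise_sigma_uv=t.noise_sigma_uv,
            noise_exponent=t.noise_exponent, alpha_amp_uv=t.alpha_amp_uv,
            artifact_rate=t.artifact_rate, artifact_amp_uv=t.artifact_amp_uv,
            per_allele_shift_uv=shifts)
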