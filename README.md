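# mmrkit

Analysis toolkit for the **late mismatch response (MMR)** as a genetic
endophenotype of dyslexia-related spelling impairment — from continuous
oddball-paradigm EEG to per-SNP association, polygenic risk scoring and
classifier comparison — together with a synthetic-study generator that
emulates the full measurement chain (stimuli, EEG, genotypes, phenotypes).

It is written for researchers working on ERP endophenotypes and candidate-
gene association in modest cohorts who want a tested, reproducible,
end-to-end reference implementation.

## What it computes

**Endophenotype.** In a passive oddball paradigm (frequent standard
syllable, rare deviant; two blocks with swapped syllable roles) the EEG is
re-referenced to the mastoid average, low-pass filtered at 30 Hz,
decimated to 250 Hz, high-pass filtered at 0.5 Hz, epoched to [−200, 1250) ms
with [−200, 0) ms baseline, and cleaned (±80 µV criterion; standards
directly after a deviant excluded). The scalar endophenotype is

```
MMR = mean over {F3, Fz, F4} of ( deviant − standard ) over [300, 600) ms   [µV]
```

**Genetics.** After genotype QC (HWE with Bonferroni correction, SNP call
rate > 97%, individual call rate > 90%, MAF > 0.05) and greedy LD clumping,
each SNP is tested with an additive linear model

```
MMR_i = β0 + β·dosage_i + γ·poor_speller_i + ε_i
```

(β in µV per risk allele, two-sided t-tests, Benjamini-Hochberg FDR over
the 25-SNP candidate panel, Cook's-distance sensitivity, QQ plot with a
95% order-statistic envelope). An unweighted polygenic risk score
`PRS_i = Σ_j dosage_ij` over the 20 scorable SNPs feeds logistic
classifiers of poor spelling — MMR alone, PRS alone, MMR + PRS — compared
by ROC AUC (DeLong CI), continuous net reclassification improvement (NRI)
and integrated discrimination improvement (IDI). A power module reports
the detectable explained variance `R² = λ/(λ+v)` of the linear-model
F-test.

## Worked example

Simulate a scaled-down study (40 subjects, 120-stimulus blocks) and run
every stage:

```python
from mmrkit.config import PipelineConfig
from mmrkit.pipeline import run_pipeline

cfg = PipelineConfig.model_validate({
    "seed": 7, "out_dir": "example_run",
    "simulate": {"n_subjects": 40, "stimulus": {"n_total": 120, "n_deviant": 18}},
})
manifest = run_pipeline(cfg)
print("\n".join(manifest.log))
```

prints (numbers from this exact run):

```
simulate: 40 subjects x 2 blocks, 120 stimuli/block
erp: 40 subjects; valid trials deviant=1144 standard=5390
qc: kept 27 SNPs x 40 individuals (HWE Bonferroni m=27)
assoc: 25 SNPs tested on n=40; 1 nominal
predict: AUC mmr=0.65 prs=0.67 combined=0.81; NRI=0.83 IDI=0.041
power: alpha=0.05: R2=13.1%, alpha=0.01: R2=18.3%, alpha=0.001: R2=24.7%
report: figures rendered
```

`example_run/association_top.tsv` then holds the strongest association —
the SNP simulated with a +3 µV/allele effect is recovered on top:

```
snp	p	fdr	beta	gene
rs17819126	0.0011	0.03	3.3	DYX1C1
```

Reading: at this reduced scale the late MMR separates poor from normal
spellers (AUC 0.65), the risk score alone is similarly informative (0.67),
and combining them improves discrimination (0.81) — the same qualitative
structure the method is designed to exhibit at full study scale. The
`power` line is scale-independent arithmetic: with 80% power at α = .05
the design detects SNP effects explaining ≥ 13.1% of MMR variance.

The same run is available from the shell:

```bash
mmrkit run --seed 7 --out example_run     # full pipeline (study-scale defaults)
mmrkit power --alpha 0.001 --power 0.8 --v 52
mmrkit simulate --out d && mmrkit erp --out d && mmrkit qc --out d   # stage-wise
```

Full-scale defaults (67 subjects, 600-stimulus blocks at 500 Hz) produce
roughly a gigabyte of EDF and take correspondingly longer; every parameter
is overridable via `--config` (YAML).

## Layout

```
src/mmrkit/
  simulate/      stimuli, EEG, genotypes, phenotypes (seeded, reproducible)
  erp/           preprocessing, epoching, rejection, MMR, group statistics
  qc.py          HWE, call-rate/MAF filters, LD clumping
  association.py additive models, Cook's distance, BH FDR, QQ envelope
  prediction.py  PRS, logistic models, AUC/DeLong, NRI, IDI
  power.py       detectable effect size / achieved power
  io.py          EDF writer + MNE reader, TSV tables, minimal VCF
  pipeline.py    staged orchestration with a digest manifest
  cli.py         `mmrkit` command
docs/methods.md  model assumptions, defaults, conventions, limitations
```
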