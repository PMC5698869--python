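"""Synthetic spelling phenotypes.

A latent spelling score is the sum of an optional genetic liability (a
standardized unweighted risk-allele count with a configurable, by default
negative, loading — more risk alleles, worse spelling) and Gaussian noise.
Empirical percentiles of the latent score give the spelling percentile rank;
the poor-speller flag marks the lowest decile (percentile <= 10), mirroring
the lower-10%-percentile cutoff of the German spelling test that defines the
case group.  ADD (attention deficit disorder) status is drawn independently
at the study's observed prevalence (12 of 67).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..panel import scored_snps


@dataclass(frozen=True)
class SpellingModel:
    """Latent spelling-score model.

    ``genetic_r2`` is the variance share of the PRS-based liability; its
    square root (signed by ``loading_sign``) is the loading on the
    standardized risk-allele count.
    """

    genetic_r2: float = 0.07
    loading_sign: float = -1.0
    poor_percentile: float = 10.0
    add_rate: float = 12.0 / 67.0

    def __post_init__(self):
        if not 0.0 <= self.genetic_r2 < 1.0:
            raise ValueError(f"genetic_r2 must be in [0, 1), got {self.genetic_r2}")
        if not 0.0 < self.poor_percentile < 100.0:
            raise ValueError("poor_percentile must be in (0, 100)")


def generate_phenotypes(genotypes: pd.DataFrame, panel: pd.DataFrame,
                        spelling_model: SpellingModel = SpellingModel(),
                        seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Phenotype table with spelling percentile, poor-speller and ADD flags.

    Percentiles are empirical (rank / n * 100, ordinal ranks), so with n a
    multiple of 10 exactly n/10 individuals are flagged poor spellers.
    """
    n = len(genotypes)
    if n < 10:
        raise ValueError(f"need >= 10 individuals for a decile split, got {n}")
    rng = np.random.default_rng(seed)

    raw_prs = genotypes[scored_snps(panel)].fillna(0.0).sum(axis=1).to_numpy()
    sd = raw_prs.std(ddof=0)
    z_prs = (raw_prs - raw_prs.mean()) / sd if sd > 0 else np.zeros(n)

    loading = spelling_model.loading_sign * np.sqrt(spelling_model.genetic_r2)
    latent = loading * z_prs + np.sqrt(1.0 - spelling_model.genetic_r2) * rng.standard_normal(n)

    order = np.argsort(np.argsort(latent, kind="stable"), kind="stable")  # ordinal ranks 0..n-1
    percentile = (order + 1) * 100.0 / n
    poor = percentile <= spelling_model.poor_percentile
    add_status = rng.random(n) < spelling_model.add_rate

    return pd.DataFrame(
        {"spelling_percentile": percentile, "poor_speller": poor, "add_status": add_status},
        index=genotypes.index.copy(),
    )
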