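"""Synthetic genotype dosages.

Per-SNP dosages (copies of the panel risk allele, 0/1/2) are drawn from
Hardy-Weinberg proportions at a configurable risk-allele frequency, i.e.
dosage ~ Binomial(2, p).  Risk alleles are oriented as the minor allele by
default (frequency = MAF, as the downstream MAF >= 0.05 filter assumes).
Missing calls are uniform at a configurable rate and stored as NaN.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd


def generate_genotypes(n_individuals: int, panel: pd.DataFrame,
                       maf_per_snp: Mapping[str, float] | Sequence[float] | float | None = None,
                       missing_rate: float = 0.0,
                       seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Draw an individuals x SNPs dosage matrix under HWE.

    Parameters
    ----------
    maf_per_snp
        Risk-allele frequency per SNP: a mapping rsid->freq, a sequence in
        panel order, a scalar for all SNPs, or ``None`` to draw each SNP's
        frequency uniformly from [0.10, 0.45].
    missing_rate
        Per-call missingness probability in [0, 0.1]; missing entries are NaN.

    Returns
    -------
    DataFrame indexed by individual id (``S001`` ...) with one float column
    per panel SNP in panel order.
    """
    if n_individuals <= 0:
        raise ValueError(f"n_individuals must be positive, got {n_individuals}")
    if not 0.0 <= missing_rate <= 0.1:
        raise ValueError(f"missing_rate must be in [0, 0.1], got {missing_rate}")
    rng = np.random.default_rng(seed)
    snps = list(panel.index)

    if maf_per_snp is None:
        freqs = rng.uniform(0.10, 0.45, size=len(snps))
    elif isinstance(maf_per_snp, Mapping):
        freqs = np.array([maf_per_snp[s] for s in snps], dtype=float)
    elif np.isscalar(maf_per_snp):
        freqs = np.full(len(snps), float(maf_per_snp))
    else:
        freqs = np.asarray(maf_per_snp, dtype=float)
        if freqs.shape != (len(snps),):
            raise ValueError("maf_per_snp length does not match panel size")
    if np.any((freqs <= 0) | (freqs > 0.5)):
        raise ValueError("allele frequencies must lie in (0, 0.5]")

    dosage = rng.binomial(2, freqs, size=(n_individuals, len(snps))).astype(float)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan

    ids = [f"S{i + 1:03d}" for i in range(n_individuals)]
    return pd.DataFrame(dosage, index=pd.Index(ids, name="individual_id"), columns=snps)
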