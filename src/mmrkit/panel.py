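"""Candidate SNP panel for the MMR endophenotype analysis.

The packaged panel lists 25 independent dyslexia candidate SNPs across 10
genes (*ATP2C2*, *CMIP*, *CNTNAP2*, *DCDC2*, *DYX1C1*, *FOXP2*, *KIAA0319*,
*MRPL19-C2ORF3*, *MYO5B*, *NEDD4L*) plus two SNPs previously associated with
the late mismatch response itself (rs11100040, rs4234898).

The risk-allele *letters* in the packaged CSV are synthetic placeholders:
dosages throughout the package are already coded in copies of the panel risk
allele, so the letter is bookkeeping metadata only.  Five of the 25 candidate
SNPs carry no literature risk allele and are therefore excluded from the
unweighted polygenic risk score (20 of 25 scored); which five are unscored is
configurable in :func:`load_panel`.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

#: SNPs shipped without a literature risk allele (hence unscored in the PRS).
DEFAULT_UNSCORED: tuple[str, ...] = (
    "rs10246256",
    "rs1419228",
    "rs3743205",
    "rs9461045",
    "rs1000585",
)

DYSLEXIA_CANDIDATE = "dyslexia_candidate"
MMR_CANDIDATE = "mmr_candidate"


def load_panel(unscored: Sequence[str] | None = None) -> pd.DataFrame:
    """Load the packaged SNP panel.

    Parameters
    ----------
    unscored
        rsIDs whose ``risk_allele`` is set to missing (no literature risk
        allele).  ``None`` keeps the packaged default of five candidate SNPs.

    Returns
    -------
    DataFrame indexed by ``rsid`` with columns ``gene``, ``risk_allele``
    (``NaN`` when absent) and ``source`` (``dyslexia_candidate`` or
    ``mmr_candidate``).
    """
    with resources.files("mmrkit.data").joinpath("snp_panel.csv").open() as fh:
        panel = pd.read_csv(fh, dtype=str)
    panel = panel.set_index("rsid", verify_integrity=True)
    if unscored is not None:
        unknown = set(unscored) - set(panel.index)
        if unknown:
            raise KeyError(f"unscored rsIDs not in panel: {sorted(unknown)}")
        # restore a letter for SNPs scored again, blank the requested ones
        panel.loc[panel["risk_allele"].isna(), "risk_allele"] = "A"
        panel.loc[list(unscored), "risk_allele"] = pd.NA
    return panel


def candidate_snps(panel: pd.DataFrame) -> pd.DataFrame:
    """The 25 dyslexia candidate SNPs (association + FDR universe)."""
    return panel[panel["source"] == DYSLEXIA_CANDIDATE]


def mmr_replication_snps(panel: pd.DataFrame) -> pd.DataFrame:
    """The two SNPs previously associated with the late MMR, analysed separately."""
    return panel[panel["source"] == MMR_CANDIDATE]


def scored_snps(panel: pd.DataFrame, sources: Iterable[str] = (DYSLEXIA_CANDIDATE,)) -> list[str]:
    """rsIDs contributing to the unweighted PRS: candidate SNPs with a risk allele."""
    sel = panel["source"].isin(set(sources)) & panel["risk_allele"].notna()
    return list(panel.index[sel])
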