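"""File I/O: EDF recordings, event/phenotype/genotype tables, minimal VCF.

EEG is written as 16-bit EDF (European Data Format) with physical units uV
and one-second data records; the last record is zero-padded when the signal
length is not a whole number of records.  Reading goes through MNE's EDF
reader.  Tabular data (events, MMR measures, dosages, phenotypes) travel as
TSV; genotypes can additionally be written as a minimal VCF with GT calls
(risk allele as ALT, dosage = ALT-allele count) and read back with either
this module or any VCF-aware tool.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .erp.containers import ContinuousEEG

# ---------------------------------------------------------------------------
# EDF


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, eeg: ContinuousEEG, patient_id: str = "X",
              recording_id: str = "mmrkit") -> None:
    """Write a recording as 16-bit EDF with per-channel physical scaling.

    The sampling rate must be a whole number of samples per one-second
    record.  Physical units are uV; the final partial record is zero-padded.
    """
    fs = eeg.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per record per signal (1 s records)
    n_sig = len(eeg.channel_labels)
    n_records = int(np.ceil(eeg.n_samples / spr))
    padded = np.zeros((n_sig, n_records * spr))
    padded[:, :eeg.n_samples] = eeg.samples

    phys_max = np.maximum(np.ceil(np.abs(padded).max(axis=1)), 1.0)
    dig_max = 32767
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(patient_id, 80),
        _edf_field(recording_id, 80),
        _edf_field("01.01.01", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_sig)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(n_sig), 4),
    ])
    sig_header = b"".join([
        b"".join(_edf_field(lab, 16) for lab in eeg.channel_labels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_sig)),
        b"".join(_edf_field("uV", 8) for _ in range(n_sig)),
        b"".join(_edf_field(f"{-m:g}", 8) for m in phys_max),
        b"".join(_edf_field(f"{m:g}", 8) for m in phys_max),
        b"".join(_edf_field(str(-dig_max), 8) for _ in range(n_sig)),
        b"".join(_edf_field(str(dig_max), 8) for _ in range(n_sig)),
        b"".join(_edf_field("", 80) for _ in range(n_sig)),
        b"".join(_edf_field(str(spr), 8) for _ in range(n_sig)),
        b"".join(_edf_field("", 32) for _ in range(n_sig)),
    ])
    digital = np.rint(padded / phys_max[:, None] * dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())  # signal-major within each record


def read_edf(path: str | Path) -> ContinuousEEG:
    """Read an EDF recording into microvolts via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return ContinuousEEG(samples=np.asarray(data, dtype=float),
                         fs_hz=float(raw.info["sfreq"]),
                         channel_labels=list(raw.ch_names))


# ---------------------------------------------------------------------------
# TSV tables


def write_events_tsv(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table_tsv(path: str | Path, table: pd.DataFrame, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_table_tsv(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_dosage_tsv(path: str | Path, genotypes: pd.DataFrame) -> None:
    """Individuals x SNPs dosage matrix; missing calls stay empty cells."""
    genotypes.to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Minimal VCF (GT only)

_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}
#: placeholder reference letter per risk allele so REF != ALT
_OTHER_ALLELE = {"A": "G", "C": "T", "G": "A", "T": "C"}


def write_vcf(path: str | Path, genotypes: pd.DataFrame, panel: pd.DataFrame) -> None:
    """Write dosages as a minimal single-chromosome VCF with GT fields.

    The panel risk allele is the ALT allele, so the ALT-allele count of each
    GT equals the risk-allele dosage.  Positions are synthetic (rank-based);
    SNPs absent from the panel get placeholder alleles.
    """
    samples = [str(i) for i in genotypes.index]
    lines = ["##fileformat=VCFv4.2",
             "##source=mmrkit",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)]
    for rank, snp in enumerate(genotypes.columns, start=1):
        alt = "A"
        if snp in panel.index and isinstance(panel.loc[snp, "risk_allele"], str):
            alt = panel.loc[snp, "risk_allele"]
        ref = _OTHER_ALLELE.get(alt, "G")
        calls = []
        for v in genotypes[snp]:
            calls.append("./." if pd.isna(v) else _GT_BY_DOSAGE[int(v)])
        lines.append(f"1\t{rank * 1000}\t{snp}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                     + "\t".join(calls))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a GT-only VCF into an individuals x SNPs ALT-dosage matrix."""
    samples: list[str] = []
    snps: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            snps.append(fields[2])
            calls = []
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    calls.append(np.nan)
                else:
                    calls.append(float(sum(int(a) > 0 for a in gt.split("/"))))
            rows.append(calls)
    matrix = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return pd.DataFrame(matrix, index=pd.Index(samples, name="individual_id"),
                        columns=snps)
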