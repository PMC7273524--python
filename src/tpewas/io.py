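"""Plain-text readers and writers for the pipeline's interchange formats.

* ECG: two-column delimited text (time_s, mV) with a sidecar phase
  annotation file (phase, start_s, end_s).
* Genotypes: minimal VCF (GT hard calls) or a dosage TSV; VCF reading
  goes through cyvcf2 when available.
* Traits, summary statistics, fiducials, QC logs: TSV with header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import SUMSTAT_COLUMNS
from .ecg import EcgRecording, PhaseAnnotation
from .simulate import GenotypeCohort

__all__ = [
    "write_ecg", "read_ecg",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf",
    "write_sumstats", "read_sumstats",
]


def write_ecg(rec: EcgRecording, path: str | Path, ann_path: str | Path) -> None:
    """Write signal as (time_s, mV) text plus a phase annotation sidecar."""
    t = rec.time_s
    arr = np.column_stack([t, rec.samples])
    header = f"time_s\tmv\n# fs={rec.fs}"
    np.savetxt(path, arr, fmt="%.6f\t%.6f", header=header, comments="# ")
    with open(ann_path, "w") as fh:
        fh.write("phase\tstart_s\tend_s\n")
        for ann in rec.phases:
            fh.write(f"{ann.label}\t{ann.start_s:.3f}\t{ann.end_s:.3f}\n")


def read_ecg(path: str | Path, ann_path: str | Path) -> EcgRecording:
    data = np.loadtxt(path, comments="#")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    fs = 1.0 / float(np.median(dt))
    ann = pd.read_csv(ann_path, sep="\t")
    phases = [
        PhaseAnnotation(str(r["phase"]), float(r["start_s"]), float(r["end_s"]))
        for _, r in ann.iterrows()
    ]
    return EcgRecording(samples=x, fs=fs, phases=phases)


def write_dosage_tsv(cohort: GenotypeCohort, path: str | Path) -> None:
    """Individuals x variants dosage TSV; first column is the sample id."""
    df = pd.DataFrame(cohort.dosages, columns=cohort.variants["snv_id"])
    df.insert(0, "id", cohort.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path, variants: pd.DataFrame | None = None) -> GenotypeCohort:
    df = pd.read_csv(path, sep="\t")
    sample_ids = df["id"].to_numpy()
    dosages = df.drop(columns=["id"]).to_numpy(dtype=np.int8)
    if variants is None:
        snvs = [c for c in df.columns if c != "id"]
        variants = pd.DataFrame(
            {
                "snv_id": snvs,
                "chrom": 1,
                "pos": np.arange(1, len(snvs) + 1),
                "ref": "A",
                "alt": "G",
                "eaf": dosages.mean(axis=0) / 2.0,
            }
        )
    return GenotypeCohort(dosages=dosages, variants=variants, sample_ids=sample_ids)


def write_vcf(cohort: GenotypeCohort, path: str | Path) -> None:
    """Minimal uncompressed VCF 4.2 with GT hard calls."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(cohort.variants["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(cohort.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        order = cohort.variants.sort_values(["chrom", "pos"]).index
        for j in order:
            v = cohort.variants.loc[j]
            calls = "\t".join(gt_map[int(d)] for d in cohort.dosages[:, j])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['snv_id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> GenotypeCohort:
    """Read a hard-call VCF into a cohort (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        rows.append(
            {
                "snv_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": int(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "eaf": float(var.aaf),
            }
        )
        gts = var.genotype.array()[:, :2]
        dosage_cols.append(gts.sum(axis=1))
    dosages = np.column_stack(dosage_cols).astype(np.int8)
    return GenotypeCohort(
        dosages=dosages, variants=pd.DataFrame(rows), sample_ids=sample_ids
    )


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    table[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
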