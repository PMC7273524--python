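"""Published reference values for the resting-Tpe exercise-ECG GWAS.

The individual-level UK Biobank data behind the study are
access-controlled, but the printed per-SNV summary statistics and the
headline estimates are public; they serve here as fixed inputs for
exercising the stage-decision arithmetic and as generating truths for
the synthetic recovery experiments.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_lead_snvs", "PUBLISHED"]

#: Headline published estimates (percent where marked).
PUBLISHED = {
    "h2_resting_pct": 15.6,
    "h2_exercise_pct": 2.2,
    "h2_recovery_pct": 2.4,
    "rg_exercise_recovery": 0.55,
    "rg_resting_exercise": 0.30,
    "rg_resting_recovery": 0.11,
    "median_resting_tpe_ms": 62.0,
    "pve_resting_pct": 3.20,
    "n_candidates_resting": 21,
    "n_candidates_exercise": 4,
    "n_candidates_recovery": 7,
    "event_prevalence": 0.006,
}


def load_lead_snvs() -> pd.DataFrame:
    """The 28 published resting-Tpe lead SNVs with discovery,
    replication, and combined (full-dataset) statistics."""
    ref = resources.files("tpewas.data").joinpath("resting_tpe_lead_snvs.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def stage_tables(lead_snvs: pd.DataFrame | None = None):
    """Split the published table into discovery / replication / combined
    summary-statistic tables in the standard schema."""
    df = lead_snvs if lead_snvs is not None else load_lead_snvs()
    out = []
    for stage in ("disc", "repl", "comb"):
        out.append(
            pd.DataFrame(
                {
                    "snv_id": df["snv_id"],
                    "chrom": df["chrom"],
                    "pos": df["pos"],
                    "effect_allele": df["ea"],
                    "other_allele": df["aa"],
                    "eaf": df[f"eaf_{stage}"],
                    "beta": df[f"beta_{stage}"],
                    "se": df[f"se_{stage}"],
                    "p": df[f"p_{stage}"],
                    "n": df[f"n_{stage}"],
                }
            )
        )
    return tuple(out)
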