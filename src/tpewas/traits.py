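"""Trait assembly: Tpe responses, cohort pooling, rank-based
inverse-normal transformation, and plausibility QC.

Three phenotypes are carried forward to genetic analysis:

* resting Tpe (ms);
* Tpe response to exercise  = (Tpe_rest - Tpe_peak) / dRRex;
* Tpe response to recovery  = (Tpe_peak - Tpe_recovery) / dRRrec;

where dRRex and dRRrec are the magnitudes of the rest -> peak-exercise
and peak-exercise -> recovery RR changes (ms), so the responses are
dimensionless ms/ms and may be negative.  Because the trait
distributions are skewed, a rank-based inverse-normal transformation is
applied before association testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import InvalidParameterError, QCError

__all__ = [
    "TraitRecord",
    "QCBounds",
    "tpe_response_exercise",
    "tpe_response_recovery",
    "pool_resting",
    "inverse_normal",
    "apply_qc",
    "build_trait_table",
]


@dataclass
class TraitRecord:
    """Per-individual Tpe traits, RR values, covariates, and QC flags."""

    id: str
    tpe_rest: float = np.nan
    tpe_peak: float = np.nan
    tpe_recovery: float = np.nan
    rr_rest: float = np.nan
    rr_peak: float = np.nan
    rr_recovery: float = np.nan
    cohort: str = "EST"
    covariates: dict = field(default_factory=dict)
    qc_flags: list = field(default_factory=list)

    @property
    def delta_rr_ex(self) -> float:
        return self.rr_rest - self.rr_peak

    @property
    def delta_rr_rec(self) -> float:
        return self.rr_recovery - self.rr_peak


def tpe_response_exercise(rec: TraitRecord) -> float:
    """Tpe change rest -> peak exercise per ms of RR change.

    Raises :class:`QCError` when the RR interval did not shorten during
    exercise (the normalization is then undefined).
    """
    d = rec.delta_rr_ex
    if not np.isfinite(d) or d <= 0:
        raise QCError("nonpositive_delta_rr_ex", f"delta_rr_ex={d}")
    return (rec.tpe_rest - rec.tpe_peak) / d


def tpe_response_recovery(rec: TraitRecord) -> float:
    """Tpe change peak exercise -> recovery per ms of RR change."""
    d = rec.delta_rr_rec
    if not np.isfinite(d) or d <= 0:
        raise QCError("nonpositive_delta_rr_rec", f"delta_rr_rec={d}")
    return (rec.tpe_peak - rec.tpe_recovery) / d


def pool_resting(est: pd.DataFrame, image: pd.DataFrame) -> pd.DataFrame:
    """Pool resting-Tpe tables from the exercise-test and imaging
    cohorts into one table, keeping the cohort tag.

    The id sets must be disjoint (individuals present in both cohorts
    are expected to have been removed upstream).
    """
    for df, tag in ((est, "EST"), (image, "IMAGE")):
        if "id" not in df.columns:
            raise InvalidParameterError(f"{tag} table lacks an 'id' column")
    shared = sorted(set(est["id"]) & set(image["id"]))
    if shared:
        raise InvalidParameterError(
            f"{len(shared)} ids present in both cohorts: {shared[:10]}"
        )
    est = est.copy()
    image = image.copy()
    if "cohort" not in est.columns:
        est["cohort"] = "EST"
    if "cohort" not in image.columns:
        image["cohort"] = "IMAGE"
    return pd.concat([est, image], ignore_index=True)


def inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transformation (Blom offset).

    Maps values to ``Phi^{-1}((rank - c) / (n - 2c + 1))`` with
    ``c = 3/8``; ties receive their average rank.  The output is a
    monotone function of the input ranks, with sample mean ~0 and
    sample SD ~1 for tie-free data.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise InvalidParameterError("need a 1-d sample of length >= 2")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("values must be finite")
    if np.all(x == x[0]):
        raise InvalidParameterError("all values equal: ranks are undefined up to ties")
    n = len(x)
    ranks = rankdata(x, method="average")
    return norm.ppf((ranks - offset) / (n - 2 * offset + 1))


@dataclass(frozen=True)
class QCBounds:
    """Plausibility bounds for measured intervals (ms)."""

    tpe_min: float = 20.0
    tpe_max: float = 200.0
    rr_min: float = 300.0
    rr_max: float = 2000.0

    @classmethod
    def from_dict(cls, d: dict) -> "QCBounds":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "QCBounds":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def apply_qc(df: pd.DataFrame, bounds: QCBounds | None = None) -> pd.DataFrame:
    """Flag records with implausible Tpe or RR values.

    Adds a boolean ``qc_pass`` column and a ``qc_reason`` string; the
    rule is monotone in the bounds (widening them never fails a
    previously passing record).
    """
    bounds = bounds or QCBounds()
    df = df.copy()
    reasons = []
    for _, row in df.iterrows():
        tags = []
        for col in ("tpe_rest", "tpe_peak", "tpe_recovery"):
            if col in row and np.isfinite(row[col]):
                if not (bounds.tpe_min <= row[col] <= bounds.tpe_max):
                    tags.append(f"{col}_out_of_range")
        for col in ("rr_rest", "rr_peak", "rr_recovery"):
            if col in row and np.isfinite(row[col]):
                if not (bounds.rr_min <= row[col] <= bounds.rr_max):
                    tags.append(f"{col}_out_of_range")
        reasons.append(";".join(tags))
    df["qc_reason"] = reasons
    df["qc_pass"] = df["qc_reason"] == ""
    return df


def build_trait_table(records: list[TraitRecord]) -> pd.DataFrame:
    """Assemble per-individual records into the analysis trait table.

    Responses that fail their RR-change precondition are set to NaN and
    the record's flag list notes the reason; the record is retained so
    resting Tpe can still be analyzed.
    """
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "cohort": rec.cohort,
            "tpe_rest": rec.tpe_rest,
            "tpe_peak": rec.tpe_peak,
            "tpe_recovery": rec.tpe_recovery,
            "rr_rest": rec.rr_rest,
            "rr_peak": rec.rr_peak,
            "rr_recovery": rec.rr_recovery,
            "delta_rr_ex": rec.delta_rr_ex,
            "delta_rr_rec": rec.delta_rr_rec,
        }
        try:
            row["tpe_resp_ex"] = tpe_response_exercise(rec)
        except QCError as err:
            row["tpe_resp_ex"] = np.nan
            rec.qc_flags.append(err.reason)
        try:
            row["tpe_resp_rec"] = tpe_response_recovery(rec)
        except QCError as err:
            row["tpe_resp_rec"] = np.nan
            rec.qc_flags.append(err.reason)
        row.update(rec.covariates)
        row["qc_flags"] = ";".join(rec.qc_flags)
        rows.append(row)
    return pd.DataFrame(rows)
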