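"""Two-stage GWAS inference scaffold.

Implements the decision logic of a discovery/replication GWAS design:

* distance-based locus definition (greedy, smallest p first, members
  within 500 kb of the lead);
* candidate selection at p < 1e-6 and Bonferroni-corrected replication
  (p <= 0.05 / m with concordant effect direction);
* full-dataset genome-wide significance (p <= 5e-8) for loci that did
  not formally replicate;
* the three-condition secondary-signal rule from conditional analysis;
* sex-stratified scans with sex-specificity flags;
* percent variance explained by the identified variants; and
* the summary tally (lead + secondary SNV counts, PVE as a fraction of
  heritability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import gwas
from .exceptions import InvalidParameterError
from .simulate import GenotypeCohort

__all__ = [
    "Locus",
    "bonferroni_threshold",
    "define_loci",
    "replication_decide",
    "fulldata_decide",
    "secondary_signal_rule",
    "sex_stratified",
    "percent_variance_explained",
    "tally",
    "TallySummary",
]

P_CANDIDATE = 1e-6
P_GENOME_WIDE = 5e-8
LOCUS_DISTANCE_KB = 500.0


def bonferroni_threshold(m: int, alpha: float = 0.05) -> tuple[float, float]:
    """Replication threshold alpha/m, exact and rounded to 2 significant
    figures (the rounded value is the conventional printed form, e.g.
    0.05/21 -> 2.4e-3; decisions use the exact value)."""
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    exact = alpha / m
    rounded = float(f"{exact:.1e}")
    return exact, rounded


@dataclass
class Locus:
    """A lead SNV plus the candidate SNVs it absorbs within 500 kb."""

    lead_snv: str
    chrom: int
    span: tuple[int, int]
    member_snvs: list[str] = field(default_factory=list)
    secondary_snvs: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_snvs)


def define_loci(
    rows: pd.DataFrame,
    p_select: float = P_CANDIDATE,
    distance_kb: float = LOCUS_DISTANCE_KB,
) -> list[Locus]:
    """Greedy distance-based locus definition.

    All SNVs with p below ``p_select`` are compiled; repeatedly, the
    smallest-p unassigned SNV becomes a lead and absorbs every
    unassigned candidate on the same chromosome within ``distance_kb``
    of it (strictly more than 500 kb away means a separate locus, so a
    member at exactly 500,000 bp is absorbed).  The output partitions
    the candidate set.
    """
    cand = rows.loc[rows["p"] < p_select, ["snv_id", "chrom", "pos", "p"]].copy()
    loci: list[Locus] = []
    dist_bp = distance_kb * 1000.0
    cand = cand.sort_values("p", kind="mergesort").reset_index(drop=True)
    assigned = np.zeros(len(cand), dtype=bool)
    for i in range(len(cand)):
        if assigned[i]:
            continue
        lead = cand.iloc[i]
        near = (
            (~assigned)
            & (cand["chrom"].values == lead["chrom"])
            & (np.abs(cand["pos"].values - lead["pos"]) <= dist_bp)
        )
        members = cand.loc[near, "snv_id"].tolist()
        positions = cand.loc[near, "pos"]
        assigned |= near
        loci.append(
            Locus(
                lead_snv=str(lead["snv_id"]),
                chrom=int(lead["chrom"]),
                span=(int(positions.min()), int(positions.max())),
                member_snvs=members,
            )
        )
    return loci


def replication_decide(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    m_candidates: int | None = None,
    p_select: float = P_CANDIDATE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stage-two decisions for discovery lead SNVs.

    A SNV is a candidate if its discovery p is below ``p_select``; it
    replicates if its replication p is at most ``alpha / m`` (Bonferroni
    over the ``m_candidates`` taken forward — by default the number of
    candidates in the table) *and* the effect direction is concordant
    with discovery.  Candidates absent from the replication table are
    marked not testable.
    """
    disc = discovery.set_index("snv_id")
    repl = replication.set_index("snv_id")
    candidates = disc.index[disc["p"] < p_select]
    m = m_candidates if m_candidates is not None else len(candidates)
    thr = alpha / m if m > 0 else np.nan

    out = []
    for snv in disc.index:
        is_cand = snv in set(candidates)
        replicated = False
        reason = "not a candidate"
        if is_cand:
            if snv not in repl.index:
                reason = "not testable: absent from replication"
            else:
                p_r = float(repl.loc[snv, "p"])
                concordant = np.sign(disc.loc[snv, "beta"]) == np.sign(repl.loc[snv, "beta"])
                if p_r <= thr and concordant:
                    replicated = True
                    reason = f"p={p_r:.2e} <= {thr:.2e}, concordant"
                elif p_r > thr:
                    reason = f"p={p_r:.2e} > {thr:.2e}"
                else:
                    reason = "discordant effect direction"
        out.append(
            {"snv_id": snv, "candidate": is_cand, "replicated": replicated, "reason": reason}
        )
    return pd.DataFrame(out)


def fulldata_decide(
    combined: pd.DataFrame,
    already_replicated: set[str],
    p_gw: float = P_GENOME_WIDE,
) -> pd.DataFrame:
    """Full-dataset decisions: additional loci are those reaching
    genome-wide significance in the combined GWAS that did not already
    formally replicate."""
    out = []
    for _, row in combined.iterrows():
        snv = row["snv_id"]
        sig = bool(row["p"] <= p_gw) and snv not in already_replicated
        if snv in already_replicated:
            reason = "already replicated"
        elif row["p"] <= p_gw:
            reason = f"combined p={row['p']:.2e} <= {p_gw:.0e}"
        else:
            reason = f"combined p={row['p']:.2e} > {p_gw:.0e}"
        out.append({"snv_id": snv, "fulldata_significant": sig, "reason": reason})
    return pd.DataFrame(out)


def secondary_signal_rule(
    p_lead: float,
    p_secondary: float,
    p_conditional: float,
    p_candidate_max: float = P_CANDIDATE,
    fold: float = 1.5,
) -> bool:
    """Three-condition declaration of an independent secondary signal.

    True iff (1) the secondary SNV's original p is below 1e-6;
    (2) -log10(p_lead) / -log10(p_sec) < 1.5; and
    (3) -log10(p_sec) / -log10(p_cond) < 1.5.
    """
    for name, p in (("p_lead", p_lead), ("p_secondary", p_secondary),
                    ("p_conditional", p_conditional)):
        if p <= 0:
            raise InvalidParameterError(f"{name} must be > 0 (log undefined at 0)")
    if p_lead >= 1 or p_secondary >= 1 or p_conditional >= 1:
        return False
    if not (p_secondary < p_candidate_max):
        return False
    l_lead = -np.log10(p_lead)
    l_sec = -np.log10(p_secondary)
    l_cond = -np.log10(p_conditional)
    if l_lead / l_sec >= fold:
        return False
    if l_sec / l_cond >= fold:
        return False
    return True


@dataclass
class SexStratifiedResult:
    male: pd.DataFrame
    female: pd.DataFrame
    combined: pd.DataFrame
    flags: pd.DataFrame  # snv_id, sex_specific, specific_in


def sex_stratified(
    cohort: GenotypeCohort,
    trait: np.ndarray,
    covariates: pd.DataFrame,
    sex: np.ndarray,
    maf_min: float = 0.01,
    p_gw: float = P_GENOME_WIDE,
) -> SexStratifiedResult:
    """Per-sex GWAS (sex dropped from the covariates) with
    sex-specificity flags.

    A variant is sex-specific when it reaches genome-wide significance
    in one sex but not in the sex-adjusted combined scan.
    """
    sex = np.asarray(sex)
    cov_nosex = covariates.drop(columns=["sex"], errors="ignore")
    results = {}
    for label, code in (("male", 1), ("female", 0)):
        mask = sex == code
        if mask.sum() < 100:
            raise InvalidParameterError(f"{label} stratum has n={int(mask.sum())} < 100")
        results[label] = gwas(
            cohort.subset(mask),
            np.asarray(trait)[mask],
            cov_nosex.loc[mask].reset_index(drop=True),
            maf_min=maf_min,
        )
    cov_with_sex = cov_nosex.copy()
    cov_with_sex["sex"] = sex
    combined = gwas(cohort, trait, cov_with_sex, maf_min=maf_min)

    merged = (
        results["male"][["snv_id", "p"]]
        .rename(columns={"p": "p_male"})
        .merge(results["female"][["snv_id", "p"]].rename(columns={"p": "p_female"}), on="snv_id")
        .merge(combined[["snv_id", "p"]].rename(columns={"p": "p_combined"}), on="snv_id")
    )
    specific_in = np.where(
        (merged["p_male"] <= p_gw) & (merged["p_combined"] > p_gw), "male",
        np.where((merged["p_female"] <= p_gw) & (merged["p_combined"] > p_gw), "female", ""),
    )
    flags = pd.DataFrame(
        {"snv_id": merged["snv_id"], "sex_specific": specific_in != "", "specific_in": specific_in}
    )
    return SexStratifiedResult(
        male=results["male"], female=results["female"], combined=combined, flags=flags
    )


def _adjusted_r2(y: np.ndarray, x: np.ndarray) -> float:
    n, k = x.shape  # x includes the intercept column
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k)


def percent_variance_explained(
    cohort: GenotypeCohort,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    identified_snvs: list[str],
    n_pcs: int = 10,
) -> tuple[float, list[str]]:
    """Percent of trait variance explained by the identified variants.

    The trait is first residualized on the covariates; the PVE is the
    difference in adjusted R-squared between a model of the residuals
    on the identified variants plus the top ``n_pcs`` genotype
    principal components, and a model with the components alone.
    Duplicated (collinear) variant columns are dropped and flagged.

    Returns (pve_percent, flags).
    """
    from scipy.sparse.linalg import svds

    from .assoc import _design, _residualize

    y = np.asarray(trait, dtype=float)
    n = len(y)
    if n_pcs >= n:
        raise InvalidParameterError("n_pcs must be smaller than the sample size")
    design = _design(covariates, n)
    resid = _residualize(y, design)

    z = cohort.standardized()
    if n_pcs > 0:
        u, s, _ = svds(z, k=n_pcs, random_state=0)
        order = np.argsort(s)[::-1]
        pcs = u[:, order]
    else:
        pcs = np.empty((n, 0))

    flags: list[str] = []
    cols = []
    kept: list[str] = []
    for snv in identified_snvs:
        g = cohort.column(snv)
        dup = any(np.allclose(g, c) or np.allclose(g, -c) for c in cols)
        corr_dup = False
        for c in cols:
            if g.std() > 0 and c.std() > 0 and abs(np.corrcoef(g, c)[0, 1]) > 1 - 1e-10:
                corr_dup = True
        if dup or corr_dup:
            flags.append(f"dropped_collinear:{snv}")
            continue
        cols.append(g)
        kept.append(snv)

    base = np.column_stack([np.ones(n), pcs])
    r2_base = _adjusted_r2(resid, base)
    if cols:
        full = np.column_stack([base] + cols)
    else:
        full = base
    r2_full = _adjusted_r2(resid, full)
    return 100.0 * (r2_full - r2_base), flags


@dataclass
class TallySummary:
    n_replicated: int
    n_additional: int
    n_secondary: int
    n_sex_specific: int
    n_lead: int
    n_total: int
    heritability_fraction_pct: int | None


def tally(
    replicated_ids: set[str],
    additional_ids: set[str],
    secondary_ids: set[str],
    sex_specific_ids: set[str] | None = None,
    pve_pct: float | None = None,
    h2_pct: float | None = None,
) -> TallySummary:
    """Summary counts across the inference stages.

    Lead SNVs are the union of replicated and additional loci (the two
    must be disjoint); secondary signals add on top.  When PVE and
    heritability are supplied (both in percent), the tally also reports
    the identified variants' share of heritability,
    round(100 * PVE / h2), as an integer percent.
    """
    overlap = replicated_ids & additional_ids
    if overlap:
        raise InvalidParameterError(f"ids in both replicated and additional: {sorted(overlap)}")
    overlap2 = (replicated_ids | additional_ids) & secondary_ids
    if overlap2:
        raise InvalidParameterError(f"secondary ids overlap lead ids: {sorted(overlap2)}")
    sex_specific_ids = sex_specific_ids or set()
    n_lead = len(replicated_ids) + len(additional_ids)
    frac = None
    if pve_pct is not None and h2_pct is not None:
        if h2_pct <= 0:
            raise InvalidParameterError("h2_pct must be > 0")
        frac = int(round(100.0 * pve_pct / h2_pct))
    return TallySummary(
        n_replicated=len(replicated_ids),
        n_additional=len(additional_ids),
        n_secondary=len(secondary_ids),
        n_sex_specific=len(sex_specific_ids),
        n_lead=n_lead,
        n_total=n_lead + len(secondary_ids),
        heritability_fraction_pct=frac,
    )
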