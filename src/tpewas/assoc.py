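"""Per-variant association testing and desk-scale variance components.

GWAS is ordinary least squares per variant under the additive model
with trait-specific covariates.  On unrelated, unstructured simulated
individuals OLS coincides asymptotically with the mixed-model machinery
used at biobank scale, so it is the correct desk-scale analogue; the
mixed model's purpose there is relatedness and scalability, neither of
which applies here.

Heritability and genetic correlation are estimated with Haseman-Elston
regression: the products of (standardized) trait values over individual
pairs are regressed on the corresponding genetic relationship matrix
(GRM) entries.  Under the generating model E[y_i y_j] = h2 * A_ij for
i != j, so the slope estimates h2; the bivariate form with cross-trait
products estimates the genetic covariance, and rg is the genetic
covariance over the geometric mean of the genetic variances.  Standard
errors come from a delete-block jackknife over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CollinearityError, InvalidParameterError, QCError
from .simulate import GenotypeCohort

__all__ = [
    "CovariateSpec",
    "COVARIATES",
    "gwas",
    "conditional_regression",
    "ConditionalResult",
    "heritability_he",
    "genetic_correlation_he",
    "HeEstimate",
    "RgEstimate",
    "genomic_inflation",
]

SUMSTAT_COLUMNS = [
    "snv_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Named covariate list for one trait's association model."""

    trait: str
    covariates: tuple[str, ...]


#: Per-trait covariate sets used in the association models.
COVARIATES = {
    "resting": CovariateSpec(
        "resting", ("sex", "age", "bmi", "smoking", "rr_rest", "array")
    ),
    "exercise": CovariateSpec(
        "exercise", ("sex", "age", "bmi", "diabetes", "rr_rest", "delta_rr_ex", "array")
    ),
    "recovery": CovariateSpec(
        "recovery", ("sex", "age", "bmi", "diabetes", "rr_recovery", "delta_rr_rec", "array")
    ),
}


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    """Covariate design matrix with intercept; checks full rank."""
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if len(c) != n:
        raise InvalidParameterError("covariate rows do not match trait length")
    x = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    return x


def _residualize(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Project out the covariate space (including the intercept)."""
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def gwas(
    cohort: GenotypeCohort,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Additive-model OLS association scan over all cohort variants.

    Each variant is tested with a two-sided Wald test from the t
    statistic of its dosage coefficient after adjusting for the
    covariates (Frisch-Waugh residualization gives the exact joint-OLS
    estimate).  Variants below ``maf_min`` or monomorphic in the
    analyzed samples are skipped.

    Returns a summary-statistics table in the conventional column
    order: snv_id, chrom, pos, effect_allele, other_allele, eaf, beta,
    se, p, n.  The effect allele is ALT as loaded.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if n != cohort.n_individuals:
        raise InvalidParameterError("trait length does not match cohort")
    design = _design(covariates, n)
    k = design.shape[1]
    df = n - k - 1
    if df < 1:
        raise InvalidParameterError("not enough residual degrees of freedom")

    g = cohort.dosages.astype(float)
    eaf = g.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    variance = g.var(axis=0)
    usable = (variance > 0) & (maf >= maf_min)

    y_r = _residualize(y, design)
    g_r = _residualize(g[:, usable], design)

    gg = np.einsum("ij,ij->j", g_r, g_r)
    gy = g_r.T @ y_r
    beta = gy / gg
    rss = (y_r @ y_r) - beta * gy  # residual SS of the full model per variant
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    meta = cohort.variants.loc[usable].reset_index(drop=True)
    return pd.DataFrame(
        {
            "snv_id": meta["snv_id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "effect_allele": meta["alt"],
            "other_allele": meta["ref"],
            "eaf": eaf[usable],
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )


@dataclass
class ConditionalResult:
    """Candidate variant's statistics after conditioning on the lead."""

    snv_id: str
    beta: float
    se: float
    p: float
    dropped: bool = False
    flags: list = field(default_factory=list)


def conditional_regression(
    cohort: GenotypeCohort,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    lead_snv: str,
    candidate_snv: str,
) -> ConditionalResult:
    """Joint regression adding the lead variant's dosage as a covariate.

    With individual-level data available, conditioning is exact: the
    candidate is tested in a model that also contains the lead dosage.
    A candidate in (near-)perfect LD with the lead is unidentifiable;
    it is dropped with a flag and reported at p = 1.
    """
    if lead_snv == candidate_snv:
        raise InvalidParameterError("lead and candidate must differ")
    y = np.asarray(trait, dtype=float)
    n = len(y)
    g_lead = cohort.column(lead_snv)
    g_cand = cohort.column(candidate_snv)

    r = np.corrcoef(g_lead, g_cand)[0, 1] if g_lead.std() > 0 and g_cand.std() > 0 else 0.0
    if abs(r) > 1 - 1e-10:
        return ConditionalResult(
            snv_id=candidate_snv, beta=np.nan, se=np.nan, p=1.0,
            dropped=True, flags=["perfect_ld_with_lead"],
        )

    base = _design(covariates, n)
    design = np.column_stack([base, g_lead])
    k = design.shape[1]
    df = n - k - 1
    y_r = _residualize(y, design)
    g_r = _residualize(g_cand, design)
    gg = float(g_r @ g_r)
    if gg <= 1e-12:
        return ConditionalResult(
            snv_id=candidate_snv, beta=np.nan, se=np.nan, p=1.0,
            dropped=True, flags=["candidate_in_covariate_span"],
        )
    beta = float(g_r @ y_r) / gg
    rss = float(y_r @ y_r) - beta * float(g_r @ y_r)
    se = float(np.sqrt(rss / df / gg))
    p = float(2.0 * stats.t.sf(abs(beta / se), df))
    return ConditionalResult(snv_id=candidate_snv, beta=beta, se=se, p=max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# Haseman-Elston variance components
# ---------------------------------------------------------------------------


@dataclass
class HeEstimate:
    h2: float
    se: float
    n_blocks: int


@dataclass
class RgEstimate:
    rg: float
    se: float
    va: float
    vb: float
    cov_g: float
    n_blocks: int


class _HeSystem:
    """Pair-sum machinery for Haseman-Elston regression with a
    delete-block jackknife.

    All statistics are sums over unordered pairs i < j.  Deleting a
    block B of individuals removes every pair touching B; those sums
    are recovered from per-individual row sums plus small within-block
    matrices, so the jackknife costs O(n + |B|^2) per block.
    """

    def __init__(self, z: np.ndarray, n_blocks: int = 20):
        n, m = z.shape
        if n < 2 * n_blocks:
            raise InvalidParameterError("too few individuals for the jackknife")
        self.n = n
        self.a = z @ z.T / m  # GRM
        self.diag = np.diag(self.a).copy()
        self.row_a = self.a.sum(axis=1) - self.diag
        self.row_a2 = (self.a**2).sum(axis=1) - self.diag**2
        self.s_a = self.row_a.sum() / 2.0
        self.s_a2 = self.row_a2.sum() / 2.0
        if self.s_a2 <= 0:
            raise InvalidParameterError("degenerate GRM: no off-diagonal variance")
        self.blocks = np.array_split(np.arange(n), n_blocks)
        self.n_blocks = n_blocks

    @staticmethod
    def _standardize(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        sd = y.std()
        if sd == 0:
            raise InvalidParameterError("trait has zero variance")
        return (y - y.mean()) / sd

    def _pair_stats(self, u: np.ndarray, v: np.ndarray):
        """Row-wise and total pair sums for products and GRM-weighted
        products of two (standardized) trait vectors."""
        au = self.a @ u
        row_ap = 0.5 * (v * au + u * (self.a @ v)) - self.diag * u * v
        s_ap = row_ap.sum() / 2.0
        row_p = 0.5 * (u * v.sum() + v * u.sum()) - u * v
        s_p = row_p.sum() / 2.0
        return row_ap, s_ap, row_p, s_p

    def slope(self, u: np.ndarray, v: np.ndarray, exclude: np.ndarray | None = None) -> float:
        """HE regression slope of pair products on GRM entries
        (with intercept), optionally excluding a block of individuals."""
        row_ap, s_ap, row_p, s_p = self._cache(u, v)
        n_pairs = self.n * (self.n - 1) / 2.0
        s_a, s_a2 = self.s_a, self.s_a2
        if exclude is not None:
            b = exclude
            sub_a = self.a[np.ix_(b, b)]
            tri = np.triu_indices(len(b), k=1)
            within_a = sub_a[tri].sum()
            within_a2 = (sub_a[tri] ** 2).sum()
            ub, vb = u[b], v[b]
            within_p = 0.5 * (np.outer(ub, vb) + np.outer(vb, ub))[tri].sum()
            within_ap = (sub_a * 0.5 * (np.outer(ub, vb) + np.outer(vb, ub)))[tri].sum()
            s_a = s_a - self.row_a[b].sum() + within_a
            s_a2 = s_a2 - self.row_a2[b].sum() + within_a2
            s_p = s_p - row_p[b].sum() + within_p
            s_ap = s_ap - row_ap[b].sum() + within_ap
            n_rem = self.n - len(b)
            n_pairs = n_rem * (n_rem - 1) / 2.0
        denom = s_a2 - s_a**2 / n_pairs
        if denom <= 0:
            raise InvalidParameterError("degenerate GRM in jackknife block")
        return float((s_ap - s_a * s_p / n_pairs) / denom)

    def _cache(self, u: np.ndarray, v: np.ndarray):
        key = (id(u), id(v))
        if getattr(self, "_cache_key", None) != key:
            self._cache_key = key
            self._cache_val = self._pair_stats(u, v)
        return self._cache_val


def heritability_he(
    cohort: GenotypeCohort,
    trait: np.ndarray,
    n_blocks: int = 20,
    _system: _HeSystem | None = None,
) -> HeEstimate:
    """Narrow-sense heritability by Haseman-Elston regression.

    The trait is standardized internally, so the estimate is invariant
    to affine transformation.  The standard error is a delete-block
    jackknife over ``n_blocks`` blocks of individuals.
    """
    sys_ = _system or _HeSystem(cohort.standardized(), n_blocks)
    y = sys_._standardize(trait)
    h2 = sys_.slope(y, y)
    reps = np.array([sys_.slope(y, y, exclude=b) for b in sys_.blocks])
    bcount = len(sys_.blocks)
    se = float(np.sqrt((bcount - 1) / bcount * ((reps - reps.mean()) ** 2).sum()))
    return HeEstimate(h2=h2, se=se, n_blocks=bcount)


def genetic_correlation_he(
    cohort: GenotypeCohort,
    trait_a: np.ndarray,
    trait_b: np.ndarray,
    n_blocks: int = 20,
) -> RgEstimate:
    """Genetic correlation by bivariate Haseman-Elston regression.

    rg = cov_g / sqrt(va * vb) where va, vb are the univariate HE
    slopes and cov_g the slope of symmetrized cross-trait pair products
    on GRM entries.  The jackknife re-estimates the full ratio per
    deleted block.  Raises :class:`QCError` when either genetic
    variance estimate is non-positive (rg undefined).
    """
    sys_ = _HeSystem(cohort.standardized(), n_blocks)
    ya = sys_._standardize(trait_a)
    yb = sys_._standardize(trait_b)

    def rg_of(exclude=None) -> float:
        va = sys_.slope(ya, ya, exclude=exclude)
        vb = sys_.slope(yb, yb, exclude=exclude)
        if va <= 0 or vb <= 0:
            raise QCError("nonpositive_genetic_variance", f"va={va:.4g}, vb={vb:.4g}")
        c = sys_.slope(ya, yb, exclude=exclude)
        return c / np.sqrt(va * vb)

    va = sys_.slope(ya, ya)
    vb = sys_.slope(yb, yb)
    if va <= 0 or vb <= 0:
        raise QCError("nonpositive_genetic_variance", f"va={va:.4g}, vb={vb:.4g}")
    cov_g = sys_.slope(ya, yb)
    rg = cov_g / np.sqrt(va * vb)
    reps = np.array([rg_of(exclude=b) for b in sys_.blocks])
    bcount = len(sys_.blocks)
    se = float(np.sqrt((bcount - 1) / bcount * ((reps - reps.mean()) ** 2).sum()))
    return RgEstimate(rg=float(rg), se=se, va=float(va), vb=float(vb),
                      cov_g=float(cov_g), n_blocks=bcount)


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor lambda: the median observed chi-square
    statistic over its null expectation (median of chi2_1)."""
    p = np.asarray(p_values, dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
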