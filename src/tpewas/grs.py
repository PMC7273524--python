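"""Genetic risk score: threshold scan in training, logistic validation.

The GRS for an individual is the weighted sum of effect-allele dosages,
with weights taken verbatim from a source GWAS.  The variant set is
chosen by scanning a grid of p-value cutoffs in a training split (the
cutoff whose score shows the strongest training association wins) and
the chosen score is then tested once, in a held-out validation split,
by logistic regression of the binary outcome on the standardized score.
Optimizing in training and testing once in validation keeps the
validation p-value honest — that separation is the point of the
two-step design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InvalidParameterError
from .simulate import GenotypeCohort

__all__ = [
    "GrsModel",
    "GrsValidation",
    "score",
    "scan_cutoffs",
    "validate",
    "split_train_validation",
    "default_cutoff_grid",
]


@dataclass
class GrsModel:
    """A fitted risk-score definition.

    ``weights`` maps snv_id -> per-allele weight (the source GWAS
    beta); ``p_cutoff`` is the winning threshold and ``training_p`` the
    training-association p-value that selected it.
    """

    snv_ids: list[str]
    weights: pd.Series
    p_cutoff: float
    training_p: float | None = None
    flags: list = field(default_factory=list)


@dataclass
class GrsValidation:
    """Validation-split association of the standardized score."""

    beta: float
    se: float
    p: float
    or_per_sd: float
    n: int
    n_cases: int


def default_cutoff_grid(n: int = 20) -> np.ndarray:
    """Log-spaced p-value cutoffs from genome-wide significance to 1."""
    return np.geomspace(5e-8, 1.0, n)


def score(cohort: GenotypeCohort, model: GrsModel) -> np.ndarray:
    """Per-individual weighted allele count.

    Missing genotype calls (NaN dosages) are mean-imputed per variant;
    variants absent from the cohort are an error if none overlap.
    """
    present = [s for s in model.snv_ids if (cohort.variants["snv_id"] == s).any()]
    if not present:
        raise InvalidParameterError("no model SNVs present in the cohort")
    g = np.column_stack([cohort.column(s) for s in present])
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = col_mean[idx[1]]
    w = model.weights.loc[present].to_numpy(dtype=float)
    return g @ w


def split_train_validation(
    outcome: np.ndarray, train_frac: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split preserving case prevalence.

    Returns boolean masks (train, validation) forming a partition.
    """
    y = np.asarray(outcome)
    rng = np.random.default_rng(seed)
    train = np.zeros(len(y), dtype=bool)
    for value in np.unique(y):
        idx = np.flatnonzero(y == value)
        rng.shuffle(idx)
        k = int(round(train_frac * len(idx)))
        train[idx[:k]] = True
    return train, ~train


def _logistic_score_test(
    score_values: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Logistic fit of outcome on the standardized score; returns
    (beta_per_sd, se, two-sided Wald p)."""
    s = np.asarray(score_values, dtype=float)
    sd = s.std()
    if sd == 0:
        raise InvalidParameterError("score has zero variance")
    s_std = (s - s.mean()) / sd
    x = [np.ones(len(s)), s_std]
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        x.extend(c.T)
    design = np.column_stack(x)
    fit = sm.Logit(np.asarray(outcome), design).fit(disp=0, maxiter=200)
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def scan_cutoffs(
    cohort: GenotypeCohort,
    outcome: np.ndarray,
    summary_stats: pd.DataFrame,
    cutoffs: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
) -> GrsModel:
    """Pick the p-value cutoff with the strongest training association.

    For each cutoff, the score is built from all summary-statistics
    variants with p at or below the cutoff (weights = their betas) and
    a logistic model of the training outcome on the standardized score
    is fitted; the cutoff with the smallest association p wins.
    """
    y = np.asarray(outcome)
    if y.sum() == 0:
        raise InvalidParameterError("no cases in the training split")
    cutoffs = default_cutoff_grid() if cutoffs is None else np.asarray(cutoffs, dtype=float)
    ss = summary_stats.set_index("snv_id")

    best: GrsModel | None = None
    for cutoff in cutoffs:
        chosen = ss.index[ss["p"] <= cutoff].tolist()
        if not chosen:
            continue
        model = GrsModel(
            snv_ids=chosen,
            weights=ss.loc[chosen, "beta"].astype(float),
            p_cutoff=float(cutoff),
        )
        s = score(cohort, model)
        if s.std() == 0:
            continue
        _, _, p = _logistic_score_test(s, y, covariates)
        model.training_p = p
        if best is None or p < best.training_p:
            best = model
    if best is None:
        raise InvalidParameterError("no cutoff yielded a scorable variant set")
    return best


def validate(
    cohort: GenotypeCohort,
    outcome: np.ndarray,
    model: GrsModel,
    covariates: pd.DataFrame | None = None,
    training_ids: set | None = None,
) -> GrsValidation:
    """Held-out logistic test of the chosen score.

    ``training_ids`` (if given) are checked against the validation
    cohort's sample ids; any overlap is an error — the two-step design
    requires disjoint splits.
    """
    if training_ids is not None:
        overlap = set(cohort.sample_ids) & set(training_ids)
        if overlap:
            raise InvalidParameterError(
                f"{len(overlap)} individuals appear in both training and validation"
            )
    y = np.asarray(outcome)
    s = score(cohort, model)
    beta, se, p = _logistic_score_test(s, y, covariates)
    return GrsValidation(
        beta=beta, se=se, p=p, or_per_sd=float(np.exp(beta)),
        n=len(y), n_cases=int(y.sum()),
    )
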