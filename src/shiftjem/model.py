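"""Baseline-category (polytomous) logistic regression.

The outcome is a nominal variable with a designated reference level (here
normal/underweight); each remaining level gets its own log-odds-versus-
reference linear predictor. With outcome levels 0..K (0 = reference),
covariate row x_i and coefficient vectors b_1..b_K,

    P(y_i = j) = exp(x_i' b_j) / (1 + sum_k exp(x_i' b_k)),   j >= 1,

and the log-likelihood is maximised by full Newton iterations with
step-halving (the likelihood never decreases across iterations). The
covariance of the stacked coefficients is the inverse observed information
at the optimum; Wald 95% intervals use exp(b +/- 1.96 se) and two-tailed
p-values 2*(1 - Phi(|b/se|)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import logsumexp

from .errors import DataError, NotConvergedError, SingularDesignError
from .linkage import ALL_CATEGORIES

logger = logging.getLogger(__name__)

#: Default outcome coding: reference first.
OUTCOME_LEVELS = ("normal_under", "overweight", "obese")
#: z multiplier for the reported 95% intervals.
Z_95 = 1.96


@dataclass(frozen=True)
class Covariate:
    """One model covariate.

    For ``kind="categorical"`` the first entry of ``levels`` is the
    reference; dummies are emitted for the rest. For ``kind="continuous"``
    the column enters as-is.
    """

    name: str
    kind: str = "categorical"
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of outcome, exposure and adjustment covariates."""

    exposure: str = "category"
    exposure_levels: tuple[str, ...] = ALL_CATEGORIES
    outcome: str = "weight_class"
    outcome_levels: tuple[str, ...] = OUTCOME_LEVELS
    covariates: tuple[Covariate, ...] = ()

    def __post_init__(self):
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicated covariates: {sorted(names)}")
        if len(self.outcome_levels) < 2:
            raise ValueError("outcome needs at least two levels")

    def with_covariates(self, covariates: Sequence[Covariate]) -> "ModelSpec":
        return ModelSpec(
            exposure=self.exposure,
            exposure_levels=self.exposure_levels,
            outcome=self.outcome,
            outcome_levels=self.outcome_levels,
            covariates=tuple(covariates),
        )


def term_name(variable: str, level: str) -> str:
    return f"{variable}[{level}]"


def build_design(
    spec: ModelSpec, data: pd.DataFrame, drop_empty_cells: bool = True
) -> tuple[np.ndarray, list[str], np.ndarray, pd.Index, list[str]]:
    """Assemble (X, column names, outcome codes, row index, dropped groups).

    Rows with any missing model variable are dropped (complete case). When
    ``drop_empty_cells`` is set, non-reference exposure groups with an empty
    outcome cell are excluded from estimation with a logged note, since
    their group-specific odds ratio is not estimable.
    """
    cols = [spec.outcome, spec.exposure] + [c.name for c in spec.covariates]
    d = data[cols].dropna()

    present = set(d[spec.outcome].unique())
    for lvl in spec.outcome_levels:
        if lvl not in present:
            raise DataError(f"outcome level {lvl!r} has no observations")
    unknown = present - set(spec.outcome_levels)
    if unknown:
        raise DataError(f"unknown outcome levels {sorted(unknown)}")

    dropped_groups: list[str] = []
    if drop_empty_cells:
        ct = pd.crosstab(d[spec.exposure], d[spec.outcome])
        for lvl in spec.exposure_levels[1:]:
            if lvl in ct.index:
                counts = ct.loc[lvl].reindex(spec.outcome_levels, fill_value=0)
                if (counts == 0).any():
                    dropped_groups.append(lvl)
        if dropped_groups:
            logger.info(
                "exposure groups removed from estimation (empty outcome cell): %s",
                dropped_groups,
            )
            d = d[~d[spec.exposure].isin(dropped_groups)]
        for lvl in spec.outcome_levels:
            if lvl not in set(d[spec.outcome].unique()):
                raise DataError(
                    f"outcome level {lvl!r} empty after removing groups {dropped_groups}"
                )

    n = len(d)
    columns: list[str] = ["intercept"]
    blocks: list[np.ndarray] = [np.ones(n)]

    exp_present = set(d[spec.exposure].unique())
    unknown = exp_present - set(spec.exposure_levels)
    if unknown:
        raise DataError(f"unknown exposure levels {sorted(unknown)}")
    for lvl in spec.exposure_levels[1:]:
        if lvl in exp_present:
            blocks.append((d[spec.exposure] == lvl).to_numpy(dtype=float))
            columns.append(term_name(spec.exposure, lvl))

    for cov in spec.covariates:
        col = d[cov.name]
        if cov.kind == "continuous":
            vals = col.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise DataError(f"covariate {cov.name!r} has non-finite values")
            blocks.append(vals)
            columns.append(cov.name)
        else:
            levels = cov.levels or tuple(sorted(col.unique()))
            bad = set(col.unique()) - set(levels)
            if bad:
                raise DataError(f"covariate {cov.name!r} has unknown levels {sorted(bad)}")
            for lvl in levels[1:]:
                if (col == lvl).any():
                    blocks.append((col == lvl).to_numpy(dtype=float))
                    columns.append(term_name(cov.name, lvl))

    X = np.column_stack(blocks)
    _check_rank(X, columns)

    code = {lvl: i for i, lvl in enumerate(spec.outcome_levels)}
    y = d[spec.outcome].map(code).to_numpy(dtype=int)
    return X, columns, y, d.index, dropped_groups


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        collinear = [columns[piv[i]] for i in range(len(columns)) if diag[i] <= tol]
        raise SingularDesignError(collinear or [columns[piv[rank]]])


@dataclass
class FitResult:
    """Fitted baseline-category model with Wald inference."""

    spec: ModelSpec
    params: pd.DataFrame  # terms x contrasts, log-odds scale
    bse: pd.DataFrame
    cov: pd.DataFrame  # stacked (contrast:term) x (contrast:term)
    llf: float
    converged: bool
    n_used: int
    n_iter: int
    ll_path: list[float] = dc_field(default_factory=list)
    dropped_groups: list[str] = dc_field(default_factory=list)
    max_grad: float = float("nan")

    @property
    def contrasts(self) -> tuple[str, ...]:
        return tuple(self.params.columns)

    def coef(self, contrast: str, term: str) -> float:
        return float(self.params.loc[term, contrast])

    def se(self, contrast: str, term: str) -> float:
        return float(self.bse.loc[term, contrast])

    def odds_ratio(self, contrast: str, term: str) -> float:
        return float(np.exp(self.coef(contrast, term)))

    def or_table(self, z: float = Z_95) -> pd.DataFrame:
        """Tidy per-term odds ratios, 95% CIs and two-tailed Wald p-values."""
        rows = []
        for contrast in self.contrasts:
            for term in self.params.index:
                b = self.coef(contrast, term)
                se = self.se(contrast, term)
                zstat = b / se if se > 0 else np.nan
                rows.append(
                    {
                        "contrast": contrast,
                        "term": term,
                        "coef": b,
                        "se": se,
                        "odds_ratio": np.exp(b),
                        "ci_low": np.exp(b - z * se),
                        "ci_high": np.exp(b + z * se),
                        "p_value": 2.0 * (1.0 - stats.norm.cdf(abs(zstat))),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "params": {c: self.params[c].to_dict() for c in self.params.columns},
            "bse": {c: self.bse[c].to_dict() for c in self.bse.columns},
            "llf": self.llf,
            "converged": self.converged,
            "n_used": self.n_used,
            "n_iter": self.n_iter,
            "dropped_groups": list(self.dropped_groups),
            "or_table": self.or_table().to_dict("records"),
        }


def _loglik_and_probs(X, B, Y):
    eta = X @ B  # n x K
    padded = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    lse = logsumexp(padded, axis=1)
    ll = float((Y * eta).sum() - lse.sum())
    P = np.exp(eta - lse[:, None])
    return ll, P


def _information(X, P):
    n, p = X.shape
    K = P.shape[1]
    info = np.empty((p * K, p * K))
    for j in range(K):
        for k in range(j, K):
            w = P[:, j] * ((1.0 if j == k else 0.0) - P[:, k])
            blk = X.T @ (w[:, None] * X)
            info[j * p : (j + 1) * p, k * p : (k + 1) * p] = blk
            if k != j:
                info[k * p : (k + 1) * p, j * p : (j + 1) * p] = blk
    return info


def fit_multinomial(
    spec: ModelSpec,
    data: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
    drop_empty_cells: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of the baseline-category model.

    Newton iterations with step-halving run until the gradient max-norm is
    at or below ``tol`` (default 1e-8) or ``max_iter`` iterations; a fit
    that stops on the iteration cap is returned flagged ``converged=False``.
    """
    X, columns, y, index, dropped = build_design(spec, data, drop_empty_cells)
    n, p = X.shape
    K = len(spec.outcome_levels) - 1
    Y = np.zeros((n, K))
    for j in range(1, K + 1):
        Y[:, j - 1] = y == j

    B = np.zeros((p, K))
    ll, P = _loglik_and_probs(X, B, Y)
    ll_path = [ll]
    converged = False
    gmax = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        G = X.T @ (Y - P)  # p x K
        gmax = float(np.abs(G).max())
        if gmax <= tol:
            converged = True
            break
        info = _information(X, P)
        try:
            step = linalg.cho_solve(linalg.cho_factor(info), G.ravel(order="F"))
        except linalg.LinAlgError:
            # near-singular curvature away from the optimum: damp and retry
            ridge = 1e-8 * np.trace(info) / info.shape[0]
            try:
                step = linalg.solve(
                    info + ridge * np.eye(info.shape[0]),
                    G.ravel(order="F"),
                    assume_a="sym",
                )
            except linalg.LinAlgError:
                logger.warning("singular information matrix; stopping early")
                break
        step = step.reshape(p, K, order="F")
        t = 1.0
        for _ in range(50):
            B_new = B + t * step
            ll_new, P_new = _loglik_and_probs(X, B_new, Y)
            if ll_new >= ll - 1e-10:
                break
            t /= 2.0
        B, ll, P = B_new, ll_new, P_new
        ll_path.append(ll)
    else:
        it = max_iter

    if not converged:
        G = X.T @ (Y - P)
        gmax = float(np.abs(G).max())
        converged = gmax <= tol
        if not converged:
            logger.warning("multinomial fit did not converge (max|grad|=%.3g)", gmax)

    info = _information(X, P)
    try:
        cov = linalg.inv(info)
    except linalg.LinAlgError:
        cov = np.full_like(info, np.nan)

    contrasts = list(spec.outcome_levels[1:])
    params = pd.DataFrame(B, index=columns, columns=contrasts)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(K, p).T
    bse = pd.DataFrame(se, index=columns, columns=contrasts)
    stacked = [f"{c}:{t}" for c in contrasts for t in columns]
    cov_df = pd.DataFrame(cov, index=stacked, columns=stacked)

    return FitResult(
        spec=spec,
        params=params,
        bse=bse,
        cov=cov_df,
        llf=ll,
        converged=converged,
        n_used=n,
        n_iter=it,
        ll_path=ll_path,
        dropped_groups=dropped,
        max_grad=gmax,
    )


def wald_summary(fit: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Significance-annotated OR table at level ``alpha`` (two-tailed).

    Refuses non-converged fits. For the conventional alpha = 0.05 the CI
    multiplier is the customary 1.96; other levels use the exact normal
    quantile.
    """
    if not fit.converged:
        raise NotConvergedError(
            f"fit did not converge (max|grad|={fit.max_grad:.3g} "
            f"after {fit.n_iter} iterations); refusing to summarise"
        )
    z = Z_95 if alpha == 0.05 else float(stats.norm.ppf(1.0 - alpha / 2.0))
    table = fit.or_table(z=z)
    table["significant"] = table["p_value"] < alpha
    return table


def lr_test(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested fits (secondary to Wald)."""
    df = full.params.size - reduced.params.size
    if df <= 0:
        raise DataError("models are not nested (full has no extra parameters)")
    stat = 2.0 * (full.llf - reduced.llf)
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return float(stat), int(df), p
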