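"""Case-control replication: Firth logistic regression and rare-allele burden.

Carrier status of each candidate variant is tested against case status under
a dominant model with sex and the first 10 genetic principal components as
covariates.  Estimation uses Firth's penalized likelihood
l*(b) = l(b) + 1/2 log det I(b), which keeps estimates finite under
separation and low carrier counts; p-values come from the penalized
likelihood-ratio test and confidence intervals from the profile penalized
likelihood.  Ancestry outliers are removed beforehand by a 5-SD rule on
principal components 1-4 relative to the reference controls.  The
multiple-testing threshold is 0.05 divided by the number of genes with at
least one observed mutated allele.

The cohort table is a pandas DataFrame with columns ``id``, ``status``
(1 = case, 0 = control), ``familial`` (bool), ``sex`` (0/1), ``PC1``..``PC10``,
one ``carrier_<variant>`` column per genotyped variant (1/0/NaN) and
optionally one ``count_<gene>`` column per gene for the burden analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

DEFAULT_COVARIATES = ("sex",) + tuple(f"PC{i}" for i in range(1, 11))
CHI2_95 = stats.chi2.ppf(0.95, df=1)


class FirthConvergenceError(RuntimeError):
    pass


@dataclass
class FirthFit:
    """Result of one Firth-penalized logistic regression.

    ``odds_ratio``, ``ci`` and ``p_value`` refer to the coefficient of
    interest (by default the first column after the intercept).
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    interest: int
    odds_ratio: float
    ci: tuple[float, float] | None
    p_value: float | None
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.beta)):
            raise FirthConvergenceError("non-finite coefficient estimates")
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo <= self.odds_ratio <= hi):
                raise FirthConvergenceError("CI does not contain the OR")


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = special.expit(eta)
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(
    X: np.ndarray,
    y: np.ndarray,
    fixed: Mapping[int, float] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Maximize the penalized log-likelihood, optionally with coordinates
    fixed (used for LRT p-values and profile CIs).  Returns
    (beta, covariance, loglik, converged, iterations)."""
    n, k = X.shape
    fixed = dict(fixed or {})
    free = [j for j in range(k) if j not in fixed]
    beta = np.zeros(k)
    for j, v in fixed.items():
        beta[j] = v
    ll = _penalized_loglik(X, y, beta)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        p = special.expit(X @ beta)
        w = p * (1.0 - p)
        Xw = X * w[:, None]
        info = X.T @ Xw
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:
            raise FirthConvergenceError(f"singular information matrix: {e}")
        h = np.einsum("ij,ij->i", X @ cov, Xw)  # hat-matrix diagonal
        score = X.T @ (y - p + h * (0.5 - p))
        u = score[free]
        if np.max(np.abs(u)) < 1e-9:
            converged = True
            break
        info_free = info[np.ix_(free, free)]
        try:
            delta = np.linalg.solve(info_free, u)
        except np.linalg.LinAlgError as e:
            raise FirthConvergenceError(f"singular free-block information: {e}")
        # step-halving keeps the penalized likelihood non-decreasing
        step = 1.0
        for _ in range(25):
            cand = beta.copy()
            cand[free] += step * delta
            new_ll = _penalized_loglik(X, y, cand)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        else:
            converged = True  # no uphill step left: at the optimum
            break
        if abs(new_ll - ll) < tol and np.max(np.abs(step * delta)) < 1e-10:
            beta = cand
            ll = new_ll
            converged = True
            break
        beta = cand
        ll = new_ll
    p = special.expit(X @ beta)
    w = p * (1.0 - p)
    Xw = X * w[:, None]
    info = X.T @ Xw
    cov = np.linalg.inv(info)
    if not converged:
        # accept a near-stationary point when line search is noise-limited
        h = np.einsum("ij,ij->i", X @ cov, Xw)
        score = X.T @ (y - p + h * (0.5 - p))
        converged = bool(np.max(np.abs(score[free])) < 1e-6)
    return beta, cov, _penalized_loglik(X, y, beta), converged, it


def _profile_ci(
    X: np.ndarray, y: np.ndarray, j: int, beta_hat: np.ndarray,
    ll_max: float, se_j: float,
) -> tuple[float, float]:
    """95% CI from the profile penalized likelihood for coefficient j."""
    target = ll_max - 0.5 * CHI2_95

    def profile(b: float) -> float:
        _, _, ll, _, _ = _firth_newton(X, y, fixed={j: b})
        return ll - target

    bounds = []
    for direction in (-1.0, 1.0):
        step = max(se_j, 0.25)
        b0 = beta_hat[j]
        b1 = b0 + direction * step
        val = profile(b1)
        n_expand = 0
        while val > 0 and n_expand < 40:
            b0 = b1
            step *= 1.6
            b1 = b0 + direction * step
            val = profile(b1)
            n_expand += 1
        if val > 0:
            bounds.append(direction * np.inf)
        else:
            lo, hi = sorted((b0, b1))
            bounds.append(float(optimize.brentq(profile, lo, hi, xtol=1e-6)))
    return (min(bounds), max(bounds))


def firth_fit(
    outcome: np.ndarray | pd.Series,
    design: np.ndarray | pd.DataFrame,
    names: Sequence[str] | None = None,
    interest: int = 1,
    compute_ci: bool = True,
    compute_p: bool = True,
) -> FirthFit:
    """Fit a Firth-penalized logistic regression.

    ``design`` must include the intercept column; ``interest`` indexes the
    coefficient reported as odds ratio (default: first column after the
    intercept).  The design must be full rank after standardization.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = list(names) if names is not None else [
            f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, cov, ll, converged, it = _firth_newton(X, y)
    if not converged:
        raise FirthConvergenceError(f"no convergence after {it} iterations")
    se = np.sqrt(np.diag(cov))
    p_value = None
    if compute_p:
        _, _, ll0, conv0, _ = _firth_newton(X, y, fixed={interest: 0.0})
        if not conv0:
            raise FirthConvergenceError("constrained fit did not converge")
        dev = max(0.0, 2.0 * (ll - ll0))
        p_value = float(stats.chi2.sf(dev, df=1))
    ci = None
    if compute_ci:
        lo, hi = _profile_ci(X, y, interest, beta, ll, se[interest])
        ci = (math.exp(lo) if np.isfinite(lo) else 0.0,
              math.exp(hi) if np.isfinite(hi) else np.inf)
    return FirthFit(
        names=names,
        beta=beta,
        se=se,
        loglik=ll,
        interest=interest,
        odds_ratio=float(np.exp(beta[interest])),
        ci=ci,
        p_value=p_value,
        converged=converged,
        n_iter=it,
    )


def firth_2x2(n11: int, n10: int, n01: int, n00: int) -> float:
    """Haldane-Anscombe closed form for the saturated binary case.

    For a single binary predictor with intercept, the Firth-penalized OR
    equals the add-1/2 cross ratio (n11+1/2)(n00+1/2)/((n10+1/2)(n01+1/2)),
    with cells (exposed case, exposed control, unexposed case, unexposed
    control).  Used as the independent oracle for :func:`firth_fit`.
    """
    return ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))


# ---------------------------------------------------------------------------
# Ancestry filter


def ancestry_filter(
    cohort: pd.DataFrame,
    reference_means: Sequence[float],
    reference_sds: Sequence[float],
    n_sd: float = 5.0,
    pcs: Sequence[str] = ("PC1", "PC2", "PC3", "PC4"),
    method: str = "componentwise",
) -> pd.DataFrame:
    """Retain persons within ``n_sd`` of the reference-control PC centre.

    Component-wise by default (|PCk - mean_k| <= n_sd * sd_k for each of
    PCs 1-4); ``method='mahalanobis'`` instead thresholds the Mahalanobis
    distance (under a diagonal covariance) at ``n_sd``.
    """
    missing = [c for c in pcs if c not in cohort.columns
               or cohort[c].isna().any()]
    if missing:
        raise ValueError(f"missing principal components: {missing}")
    z = (cohort[list(pcs)].to_numpy() - np.asarray(reference_means)) \
        / np.asarray(reference_sds)
    if method == "componentwise":
        keep = (np.abs(z) <= n_sd).all(axis=1)
    elif method == "mahalanobis":
        keep = np.sqrt((z ** 2).sum(axis=1)) <= n_sd
    else:
        raise ValueError(f"unknown method {method!r}")
    return cohort.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Per-variant association, Bonferroni, burden


@dataclass(frozen=True)
class SkippedTest:
    name: str
    reason: str


def variant_association(
    cohort: pd.DataFrame,
    carrier_column: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    compute_ci: bool = True,
) -> FirthFit | SkippedTest:
    """Dominant-model Firth association of one variant with case status.

    Rows with missing carrier state are dropped; variants with zero carriers
    overall are skipped with the reason recorded.
    """
    cols = [carrier_column, "status", *covariates]
    data = cohort.dropna(subset=[carrier_column])[cols]
    carriers = data[carrier_column].astype(float)
    if carriers.sum() == 0:
        return SkippedTest(carrier_column, "no carriers observed")
    X = pd.DataFrame({"intercept": 1.0, "carrier": carriers})
    for c in covariates:
        X[c] = data[c].astype(float)
    return firth_fit(data["status"].to_numpy(), X, interest=1,
                     compute_ci=compute_ci)


def bonferroni_threshold(
    carrier_counts: Mapping[str, tuple[int, int]]
) -> tuple[int, float]:
    """(number of genes with >= 1 mutated allele in cases or controls,
    0.05 / that number).  Input maps gene -> (case carriers, control carriers)."""
    n_genes = sum(1 for a, b in carrier_counts.values() if a + b >= 1)
    if n_genes == 0:
        raise ValueError("no gene has an observed mutated allele")
    return n_genes, 0.05 / n_genes


def burden_test(
    cohort: pd.DataFrame,
    count_columns: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    compute_ci: bool = False,
) -> dict[str, FirthFit | SkippedTest]:
    """Per-gene Firth regression of case status on the count of rare,
    damaging minor alleles carried (qualifying variants: MAF < 1%, effect
    class in the frozen damaging vocabulary; counting happens upstream)."""
    out: dict[str, FirthFit | SkippedTest] = {}
    for col in count_columns:
        data = cohort.dropna(subset=[col])
        counts = data[col].astype(float)
        if (counts == 0).all():
            out[col] = SkippedTest(col, "no qualifying alleles observed")
            continue
        X = pd.DataFrame({"intercept": 1.0, "count": counts})
        for c in covariates:
            X[c] = data[c].astype(float)
        out[col] = firth_fit(data["status"].to_numpy(), X, interest=1,
                             compute_ci=compute_ci)
    return out


# ---------------------------------------------------------------------------
# Table-4-style report


def association_table(
    cohort: pd.DataFrame,
    carrier_columns: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Carrier counts and Firth results for all cases and familial-only cases."""
    familial = cohort[(cohort["status"] == 0) | cohort["familial"]]
    rows = []
    for col in carrier_columns:
        name = col.removeprefix("carrier_")
        carr = cohort[col].astype(float)
        ctrl = int(carr[cohort["status"] == 0].sum())
        case = int(carr[cohort["status"] == 1].sum())
        fam = int(carr[(cohort["status"] == 1) & cohort["familial"]].sum())
        row = {"variant": name, "carriers_controls": ctrl,
               "carriers_cases": case, "carriers_familial_cases": fam}
        for label, table in (("all", cohort), ("familial", familial)):
            fit = variant_association(table, col, covariates,
                                      compute_ci=compute_ci)
            if isinstance(fit, SkippedTest):
                row[f"OR_{label}"] = row[f"CI_{label}"] = row[f"P_{label}"] = "-"
            else:
                row[f"OR_{label}"] = round(fit.odds_ratio, 3)
                if fit.ci is not None:
                    row[f"CI_{label}"] = f"{fit.ci[0]:.3g}-{fit.ci[1]:.3g}"
                else:
                    row[f"CI_{label}"] = ""
                row[f"P_{label}"] = round(fit.p_value, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["familial"] = df["familial"].astype(bool)
    return df


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    out = cohort.copy()
    out["familial"] = out["familial"].astype(int)
    out.to_csv(path, sep="\t", index=False)
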