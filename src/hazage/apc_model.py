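"""Anchored multiplicative age-period-cohort (APC) model, fit by Poisson ML.

Cell counts are modelled as O[i, j] ~ Poisson(PY[i, j] * exp(mu + a_i + b_j
+ c_k)) with the cohort index k = j - i + n.  The APC design is structurally
rank-deficient: the three effect families each carry a free level, and the
exact linear dependence cohort = period - age leaves a free linear drift.
Identification here is by *anchoring* — a_{i*} = b_{j*} = c_{k*} = 0 at
user-chosen reference indices — plus a zero-drift convention on the cohort
effects, sum_k (k - kbar) c_k = 0, which allocates the common linear trend
to the age effects.  Under this convention the fitted age curve exp(mu +
a_i) is the population hazard corrected to the anchored period and cohort
chain.

The likelihood is concave on the constrained parameter space; fitting uses
a damped Newton (IRLS) iteration on a null-space parameterization of the
constraints, and the covariance is the inverse observed information
projected back to the full effect vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import null_space

from .registry_io import AgeGrid, PeriodGrid, RegistryTable, RunConfig
from .rates import apply_min_case_mask
from .susceptibility import HazardCurve

__all__ = [
    "APCDecomposition",
    "EffectCI",
    "APCFitError",
    "fit_apc",
    "population_hazard",
    "effect_cis",
    "export_effects_tsv",
]

_Z95 = 1.959963984540054

MAX_ITER = 200
GRAD_TOL = 1e-8


class APCFitError(RuntimeError):
    """Fit could not be completed (non-convergence or unidentifiable layout)."""


@dataclass
class APCDecomposition:
    """Fitted anchored APC effects on the log-hazard scale.

    Parameter order in ``covariance`` is [mu, a_1..a_n, b_1..b_J,
    c_1..c_{n+J-1}]; anchored entries are exactly zero with zero rows and
    columns in the covariance.
    """

    intercept: float
    age_effects: np.ndarray
    period_effects: np.ndarray
    cohort_effects: np.ndarray
    covariance: np.ndarray
    anchors: tuple[int, int, int]  # (i*, j*, k*), 1-based
    age_grid: AgeGrid
    period_grid: PeriodGrid
    drift_convention: str = "zero linear trend over multi-cell cohort effects"
    n_iter: int = 0
    loglik: float = float("nan")

    @property
    def n(self) -> int:
        return self.age_grid.n

    @property
    def J(self) -> int:
        return self.period_grid.J

    @property
    def K(self) -> int:
        return self.n + self.J - 1

    def theta(self) -> np.ndarray:
        return np.concatenate(
            [[self.intercept], self.age_effects, self.period_effects, self.cohort_effects]
        )

    def fitted_log_means(self, person_years: np.ndarray) -> np.ndarray:
        n, J = self.n, self.J
        ii, jj = np.meshgrid(np.arange(n), np.arange(J), indexing="ij")
        kk = jj - ii + n - 1
        return (
            np.log(person_years)
            + self.intercept
            + self.age_effects[ii]
            + self.period_effects[jj]
            + self.cohort_effects[kk]
        )

    def fitted_means(self, person_years: np.ndarray) -> np.ndarray:
        return np.exp(self.fitted_log_means(person_years))


@dataclass
class EffectCI:
    """Point estimates with 95% Wald intervals for one effect family."""

    estimate: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    se: np.ndarray
    family: str


def _design(n: int, J: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-major cell order; returns (X, age_idx, cohort_idx) for an n x J grid."""
    K = n + J - 1
    p = 1 + n + J + K
    cells = n * J
    X = np.zeros((cells, p))
    ii, jj = np.meshgrid(np.arange(n), np.arange(J), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    kk = jj - ii + n - 1
    rows = np.arange(cells)
    X[rows, 0] = 1.0
    X[rows, 1 + ii] = 1.0
    X[rows, 1 + n + jj] = 1.0
    X[rows, 1 + n + J + kk] = 1.0
    return X, ii, kk


def cohort_cell_counts(n: int, J: int) -> np.ndarray:
    """Number of grid cells supporting each cohort k = 1 .. n+J-1."""
    K = n + J - 1
    ks = np.arange(1, K + 1)
    return np.minimum.reduce([ks, K + 1 - ks, np.full(K, min(n, J))])


def drift_coefficients(n: int, J: int) -> np.ndarray:
    """Coefficient vector d of the zero-drift convention d @ c = 0.

    The linear trend is constrained to zero over the cohorts supported by at
    least two grid cells.  The extreme anti-diagonal cohorts rest on a
    single (often sparsely populated) cell each; including them in the
    trend constraint lets a diverging corner effect (a zero-count cell
    drives its cohort effect to -inf) redistribute through every parameter.
    Excluding them keeps such divergences local while still pinning the
    drift.  Falls back to all cohorts when fewer than two are multi-cell
    (e.g. single-period tables).
    """
    K = n + J - 1
    m = cohort_cell_counts(n, J)
    sel = m >= 2
    if sel.sum() < 2:
        sel = np.ones(K, dtype=bool)
    ks = np.arange(1, K + 1, dtype=float)
    d = np.zeros(K)
    d[sel] = ks[sel] - ks[sel].mean()
    return d


def _constraints(n: int, J: int, i_star: int, j_star: int) -> tuple[np.ndarray, int]:
    """Constraint matrix C theta = 0: three anchors plus zero cohort drift."""
    K = n + J - 1
    p = 1 + n + J + K
    k_star = j_star - i_star + n
    if not 1 <= k_star <= K:
        raise APCFitError(f"anchored cohort index k*={k_star} outside 1..{K}")
    C = np.zeros((4, p))
    C[0, 1 + (i_star - 1)] = 1.0
    C[1, 1 + n + (j_star - 1)] = 1.0
    C[2, 1 + n + J + (k_star - 1)] = 1.0
    C[3, 1 + n + J :] = drift_coefficients(n, J)
    return C, k_star


def _poisson_loglik(O: np.ndarray, eta: np.ndarray, w: np.ndarray) -> float:
    # constant terms (log O!) dropped
    return float(np.sum(w * (O * eta - np.exp(eta))))


def fit_apc(table: RegistryTable, config: RunConfig) -> APCDecomposition:
    """Constrained Poisson maximum likelihood fit of the anchored APC model.

    Cells failing the min-case threshold get likelihood weight zero when
    ``config.exclude_masked`` is set; by default all cells enter the
    likelihood.  Raises :class:`APCFitError` when an age row (or any period
    or cohort) has no weighted cell, or when the damped Newton iteration
    fails to reach the gradient tolerance within the iteration cap.
    """
    n, J = table.age_grid.n, table.period_grid.J
    config.validate(table.age_grid, table.period_grid)
    K = n + J - 1

    O = table.cases.ravel()
    PY = table.person_years.ravel()
    if config.exclude_masked:
        w = apply_min_case_mask(table, config.min_cases).ravel().astype(float)
    else:
        w = np.ones_like(O)

    X, ii, kk = _design(n, J)
    jj = np.tile(np.arange(J), n)

    for name, idx, count in (("age row", ii, n), ("period", jj, J), ("cohort", kk, K)):
        covered = np.bincount(idx, weights=w, minlength=count)
        empty = np.flatnonzero(covered == 0)
        if empty.size:
            raise APCFitError(
                f"{name}(s) {', '.join(str(e + 1) for e in empty)} have no retained "
                "cells; the corresponding effects are unidentifiable"
            )

    C, k_star = _constraints(n, J, config.age_index, config.period_index)
    Z = null_space(C)  # p x (p - 4) orthonormal basis of the constraint space
    A = X @ Z
    offset = np.log(PY)

    # start from a flat model at the observed overall rate
    theta0 = np.zeros(X.shape[1])
    theta0[0] = np.log(max(np.sum(w * O), 0.5) / np.sum(w * PY))
    gamma, *_ = np.linalg.lstsq(Z, theta0, rcond=None)

    eta = offset + A @ gamma
    ll = _poisson_loglik(O, eta, w)
    # the score is in count units; scale the tolerance with the count
    # magnitude so the stopping rule sits above floating-point noise
    gtol = GRAD_TOL * max(1.0, float(np.sqrt(np.sum(w * O))))
    grad_norm = np.inf
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = np.exp(eta)
        g = A.T @ (w * (O - mu))
        grad_norm = float(np.max(np.abs(g)))
        if grad_norm < gtol:
            break
        Awm = A * (w * mu)[:, None]
        Hn = A.T @ Awm
        # lstsq with a singular-value cutoff keeps the step in the identified
        # subspace when the design is aliased (e.g. single-period tables)
        step, *_ = np.linalg.lstsq(Hn, g, rcond=1e-12)
        # damping: halve until the likelihood does not decrease
        t = 1.0
        for _ in range(50):
            eta_new = offset + A @ (gamma + t * step)
            ll_new = _poisson_loglik(O, eta_new, w)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            t *= 0.5
        else:
            raise APCFitError(
                f"line search failed at iteration {it}, |grad|={grad_norm:.3g}"
            )
        gamma = gamma + t * step
        eta, ll = eta_new, ll_new
    else:
        raise APCFitError(
            f"no convergence after {MAX_ITER} iterations, |grad|={grad_norm:.3g}"
        )

    theta = Z @ gamma
    mu_hat = np.exp(eta)
    Hn = A.T @ (A * (w * mu_hat)[:, None])
    cov_gamma = np.linalg.pinv(Hn)
    cov_theta = Z @ cov_gamma @ Z.T

    age = theta[1 : 1 + n].copy()
    period = theta[1 + n : 1 + n + J].copy()
    cohort = theta[1 + n + J :].copy()
    # anchors are exact zeros by construction; clean rounding residue
    age[config.age_index - 1] = 0.0
    period[config.period_index - 1] = 0.0
    cohort[k_star - 1] = 0.0

    return APCDecomposition(
        intercept=float(theta[0]),
        age_effects=age,
        period_effects=period,
        cohort_effects=cohort,
        covariance=cov_theta,
        anchors=(config.age_index, config.period_index, k_star),
        age_grid=table.age_grid,
        period_grid=table.period_grid,
        n_iter=it,
        loglik=ll,
    )


def population_hazard(apc: APCDecomposition, age_grid: AgeGrid | None = None) -> HazardCurve:
    """Population hazard rate h_U(t_i) = exp(mu + a_i), per person-year.

    This is the incidence corrected to the anchored period and cohort chain.
    SEs follow by the delta method, SE[h_U] = h_U * SE[mu + a_i]; the full
    covariance of the curve (needed for correlated error propagation
    downstream) is attached to the returned curve.
    """
    grid = age_grid or apc.age_grid
    n = apc.n
    values = np.exp(apc.intercept + apc.age_effects)
    # gradient rows: d(mu + a_i)/dtheta
    G = np.zeros((n, apc.covariance.shape[0]))
    G[:, 0] = 1.0
    G[np.arange(n), 1 + np.arange(n)] = 1.0
    cov_log = G @ apc.covariance @ G.T
    cov = values[:, None] * cov_log * values[None, :]
    se = values * np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    return HazardCurve(
        values=values, se=se, age_grid=grid, kind="unconditional", covariance=cov
    )


def _family_ci(
    apc: APCDecomposition, family: str, zero_before_anchor_period: bool = False
) -> EffectCI:
    n, J = apc.n, apc.J
    if family == "age":
        est = apc.age_effects.copy()
        sl = slice(1, 1 + n)
        anchor = apc.anchors[0] - 1
    elif family == "period":
        est = apc.period_effects.copy()
        sl = slice(1 + n, 1 + n + J)
        anchor = apc.anchors[1] - 1
    elif family == "cohort":
        est = apc.cohort_effects.copy()
        sl = slice(1 + n + J, None)
        anchor = apc.anchors[2] - 1
    else:
        raise ValueError(f"unknown effect family {family!r}")
    se = np.sqrt(np.clip(np.diag(apc.covariance)[sl], 0.0, None))
    se[anchor] = 0.0
    if family == "period" and zero_before_anchor_period:
        # display convention: periods preceding the anchor shown as zero
        est[:anchor] = 0.0
        se[:anchor] = 0.0
    return EffectCI(
        estimate=est,
        lower95=est - _Z95 * se,
        upper95=est + _Z95 * se,
        se=se,
        family=family,
    )


def effect_cis(
    apc: APCDecomposition, zero_before_anchor_period: bool = False
) -> dict[str, EffectCI]:
    """95% Wald intervals per effect family; anchored entries have zero width."""
    return {
        fam: _family_ci(apc, fam, zero_before_anchor_period)
        for fam in ("age", "period", "cohort")
    }


def export_effects_tsv(
    path: str | Path, apc: APCDecomposition, zero_before_anchor_period: bool = False
) -> None:
    """Tidy table: family, 1-based index, label, estimate, se, lower95, upper95."""
    cis = effect_cis(apc, zero_before_anchor_period)
    labels = {
        "age": apc.age_grid.labels(),
        "period": apc.period_grid.labels(),
        "cohort": [f"k={k}" for k in range(1, apc.K + 1)],
    }
    lines = ["family\tindex\tlabel\testimate\tse\tlower95\tupper95"]
    for fam in ("age", "period", "cohort"):
        ci = cis[fam]
        for idx in range(len(ci.estimate)):
            lines.append(
                f"{fam}\t{idx + 1}\t{labels[fam][idx]}"
                f"\t{ci.estimate[idx]:.10g}\t{ci.se[idx]:.10g}"
                f"\t{ci.lower95[idx]:.10g}\t{ci.upper95[idx]:.10g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
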