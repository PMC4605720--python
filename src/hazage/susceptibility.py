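"""Dichotomous-susceptibility hazard algebra.

The model assumes the population splits into a susceptible fraction ``p``
(who can ever present the cancer) and an immune remainder ``1 - p``.  With
S(t), h(t), f(t) the survival, hazard and density *conditional on
susceptibility* and H(t) the conditional cumulative hazard, the population
(unconditional) quantities follow from the mixture:

    S_U(t) = 1 - p + p * S(t)
    h_U(t) = p * h(t) / (p + (1 - p) * exp(H(t)))          (exact forward map)
    h(t)   = h_U(t) / (1 + (p - 1) * exp(H_U(t)))          (exact inverse)

The overall cumulative unconditional hazard H_UO = \\int_0^inf h_U dt equals
-ln(1 - p), which to first order in small p is p itself.  The small-p
working estimate of the individual cancer presentation rate is

    h^(t) = h^_U(t) / (H^_UO - H^_U(t))

with a matching first-order error-propagation formula for its SE.

Discretization convention: hazards live on a uniform age grid of width
``Delta`` and are evaluated at interval midpoints; cumulative hazards use the
left-cumulative rectangle rule, H(t_1) = 0 and H(t_i) = Delta * sum_{m<i}
h[m], so H_UO - H_U(t_i) always retains interval i's own mass and the
working estimate stays positive through the last interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registry_io import AgeGrid

__all__ = [
    "HazardCurve",
    "CumulativeHazard",
    "SusceptibilityEstimate",
    "IndividualRates",
    "cumulative_hazard",
    "cumulative_hazard_se",
    "susceptible_fraction",
    "individual_hazard_approx",
    "individual_hazard_exact",
    "unconditional_hazard_exact",
    "individual_hazard_se",
    "individual_hazard_se_delta",
    "unconditional_cumulative_from_conditional",
    "conditional_cumulative_from_unconditional",
    "survival_curves",
    "individual_rates",
    "export_curve_tsv",
]


@dataclass
class HazardCurve:
    """Per-age-interval hazard values (events per person-year) with SEs.

    ``kind`` distinguishes the population ("unconditional") hazard from the
    individual presentation rate ("conditional").  ``covariance`` optionally
    carries the full n x n covariance of the values (from the registry fit)
    for correlated error propagation.
    """

    values: np.ndarray
    se: np.ndarray = None
    age_grid: AgeGrid = field(default_factory=AgeGrid)
    kind: str = "unconditional"
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.se is None:
            self.se = np.zeros_like(self.values)
        self.se = np.asarray(self.se, dtype=float)
        if self.values.shape != (self.age_grid.n,):
            raise ValueError(
                f"curve has {self.values.shape[0]} values but grid has "
                f"{self.age_grid.n} intervals"
            )
        if np.any(self.values < 0):
            raise ValueError("hazard values must be nonnegative")


@dataclass
class CumulativeHazard:
    """Left-cumulative hazard H(t_i) (dimensionless) and the overall total.

    ``at_interval[i]`` is the cumulative hazard at the *left edge* of
    interval i (so at_interval[0] == 0); ``overall`` is the total over the
    whole grid.  ``se_at_interval``/``se_overall`` propagate the hazard SEs
    under the independent-interval assumption.
    """

    at_interval: np.ndarray
    overall: float
    convention: str = "left-cumulative rectangle"
    se_at_interval: np.ndarray | None = None
    se_overall: float | None = None


@dataclass
class SusceptibilityEstimate:
    """Overall cumulative unconditional hazard and the susceptible fraction.

    ``p_first_order`` is the small-p working value (= H_UO, used by the
    working presentation-rate formula); ``p_exact`` = 1 - exp(-H_UO).
    """

    H_UO: float
    p_first_order: float
    p_exact: float
    se_H_UO: float = 0.0

    @property
    def se_p_exact(self) -> float:
        # delta method through p = 1 - exp(-H)
        return float(np.exp(-self.H_UO) * self.se_H_UO)


@dataclass
class IndividualRates:
    """Conditional presentation rate, cumulative hazard, resistance and density."""

    presentation: HazardCurve
    cumulative: CumulativeHazard
    resistance: np.ndarray
    resistance_se: np.ndarray
    density: np.ndarray
    population_resistance: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Cumulative hazards and the susceptible fraction
# ---------------------------------------------------------------------------

def cumulative_hazard(curve: HazardCurve) -> CumulativeHazard:
    """Left-cumulative rectangle rule on a uniform grid.

    H(t_i) = Delta * sum_{m < i} h[m] (zero at the first interval) and
    overall = Delta * sum over all intervals.  With midpoint-evaluated
    hazards the overall total is a midpoint-rule quadrature of the integral.

    SEs of the partial sums use the curve covariance when the curve carries
    one (per-interval hazards estimated from one registry fit share the
    intercept and are strongly positively correlated, so the independent
    sum would understate them), else the independent-interval sum.
    """
    width = float(curve.age_grid.width)
    csum = np.concatenate([[0.0], np.cumsum(curve.values)]) * width
    if curve.covariance is not None:
        block = np.cumsum(np.cumsum(curve.covariance, axis=0), axis=1)
        partial = np.concatenate([[0.0], np.clip(np.diag(block), 0.0, None)])
        se_cum = np.sqrt(partial) * width
    else:
        se_cum = np.sqrt(np.concatenate([[0.0], np.cumsum(curve.se**2)])) * width
    return CumulativeHazard(
        at_interval=csum[:-1],
        overall=float(csum[-1]),
        se_at_interval=se_cum[:-1],
        se_overall=float(se_cum[-1]),
    )


def cumulative_hazard_se(curve: HazardCurve) -> np.ndarray:
    """SE of H(t_i) assuming independent intervals: Delta * sqrt(sum_{m<i} se^2)."""
    width = float(curve.age_grid.width)
    return width * np.sqrt(np.concatenate([[0.0], np.cumsum(curve.se**2)]))[:-1]


def susceptible_fraction(H_UO: float, se_H_UO: float = 0.0) -> SusceptibilityEstimate:
    """Susceptible fraction from the overall cumulative unconditional hazard.

    H_UO = -ln(1 - p), hence p_exact = 1 - exp(-H_UO); for small p the
    first-order value is H_UO itself.
    """
    if H_UO < 0:
        raise ValueError(f"overall cumulative hazard must be >= 0, got {H_UO}")
    return SusceptibilityEstimate(
        H_UO=float(H_UO),
        p_first_order=float(H_UO),
        p_exact=float(-np.expm1(-H_UO)),
        se_H_UO=float(se_H_UO),
    )


# ---------------------------------------------------------------------------
# Conversions between unconditional and conditional hazards
# ---------------------------------------------------------------------------

def individual_hazard_approx(
    h_U: HazardCurve, H: CumulativeHazard | None = None
) -> HazardCurve:
    """Small-p working estimate h(t_i) = h_U(t_i) / (H_UO - H_U(t_i)).

    ``H`` must follow the left-cumulative convention (computed internally
    when omitted), which keeps the denominator positive wherever h_U > 0.
    """
    if H is None:
        H = cumulative_hazard(h_U)
    denom = H.overall - H.at_interval
    bad = np.flatnonzero((denom <= 0) & (h_U.values > 0))
    if bad.size:
        labels = ", ".join(h_U.age_grid.labels()[i] for i in bad)
        raise ValueError(
            f"nonpositive denominator H_UO - H_U at interval(s) {labels}; "
            "cumulative hazard must be left-cumulative and consistent with h_U"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(h_U.values > 0, h_U.values / denom, 0.0)
    return HazardCurve(
        values=values,
        se=individual_hazard_se(h_U, H),
        age_grid=h_U.age_grid,
        kind="conditional",
    )


def individual_hazard_exact(
    h_U: HazardCurve, H_U: CumulativeHazard, p: float
) -> HazardCurve:
    """Exact inverse map h(t_i) = h_U(t_i) / (1 + (p - 1) exp(H_U(t_i))).

    ``p`` may be 1 (everyone susceptible, h = h_U).  The denominator turns
    nonpositive when H_U(t_i) >= -ln(1 - p), i.e. when the accumulated
    unconditional mass exceeds what a susceptible fraction p can supply —
    that signals inconsistent inputs and raises.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    # algebraically 1 + (p - 1) exp(H_U) = p S / S_U; the expm1 form avoids
    # catastrophic cancellation when the susceptible pool is nearly exhausted
    em = np.expm1(-np.asarray(H_U.at_interval, dtype=float))
    denom = (em + p) / (1.0 + em)
    bad = np.flatnonzero((denom <= 0) & (h_U.values > 0))
    if bad.size:
        labels = ", ".join(h_U.age_grid.labels()[i] for i in bad)
        raise ValueError(
            f"H_U exceeds -ln(1-p) at interval(s) {labels}: inputs inconsistent"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(h_U.values > 0, h_U.values / denom, 0.0)
    return HazardCurve(values=values, age_grid=h_U.age_grid, kind="conditional")


def unconditional_hazard_exact(
    h: HazardCurve, H: CumulativeHazard, p: float
) -> HazardCurve:
    """Exact forward map h_U(t_i) = p h(t_i) / (p + (1 - p) exp(H(t_i))).

    ``H`` is the *conditional* cumulative hazard of ``h``.  The denominator
    is bounded below by p, so the map is defined for any 0 < p <= 1.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    denom = p + (1.0 - p) * np.exp(H.at_interval)
    return HazardCurve(
        values=p * h.values / denom, age_grid=h.age_grid, kind="unconditional"
    )


def unconditional_cumulative_from_conditional(
    H: CumulativeHazard, p: float
) -> CumulativeHazard:
    """H_U(t) = -ln(1 - p + p exp(-H(t))) — the mixture identity on the log scale.

    This is the cumulative hazard algebraically consistent with the exact
    forward map; using it (rather than re-integrating h_U on the coarse
    grid) makes forward map followed by exact inverse an identity to
    rounding error.
    """
    at = -np.log1p(p * np.expm1(-np.asarray(H.at_interval, dtype=float)))
    overall = float(-np.log1p(p * np.expm1(-H.overall)))
    return CumulativeHazard(at_interval=at, overall=overall, convention=H.convention)


def conditional_cumulative_from_unconditional(
    H_U: CumulativeHazard, p: float
) -> CumulativeHazard:
    """Inverse of :func:`unconditional_cumulative_from_conditional`."""
    at = -np.log1p(np.expm1(-np.asarray(H_U.at_interval, dtype=float)) / p)
    overall = float(-np.log1p(np.expm1(-H_U.overall) / p))
    return CumulativeHazard(at_interval=at, overall=overall, convention=H_U.convention)


# ---------------------------------------------------------------------------
# Error propagation
# ---------------------------------------------------------------------------

def individual_hazard_se(
    h_U: HazardCurve,
    H: CumulativeHazard | None = None,
    use_covariance: bool = False,
) -> np.ndarray:
    """First-order SE of the working presentation-rate estimate.

    SE^2[h(t_i)] = (h_U^2 / D^2) * (SE^2[h_U]/h_U^2 + SE^2[D]/D^2) with
    D = H_UO - H_U(t_i).  SE^2[D] is the independent-interval tail sum
    Delta^2 * sum_{m >= i} SE^2[h_U(t_m)], or, with ``use_covariance`` and
    a curve covariance present, the full tail-block quadratic form (still
    without the numerator-denominator cross term — see
    :func:`individual_hazard_se_delta` for the complete propagation).
    Intervals with zero hazard get SE 0.
    """
    if H is None:
        H = cumulative_hazard(h_U)
    width = float(h_U.age_grid.width)
    denom = H.overall - H.at_interval
    if use_covariance and h_U.covariance is not None:
        n = h_U.values.size
        tail_var = np.array(
            [h_U.covariance[i:, i:].sum() for i in range(n)]
        ) * width**2
        tail_var = np.clip(tail_var, 0.0, None)
    else:
        # tail sum of variances: Delta^2 * sum_{m >= i} se_m^2
        tail_var = width**2 * np.cumsum((h_U.se**2)[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = h_U.se**2 / h_U.values**2 + tail_var / denom**2
        se2 = (h_U.values**2 / denom**2) * rel
    return np.where(h_U.values > 0, np.sqrt(se2), 0.0)


def individual_hazard_se_delta(h_U: HazardCurve) -> np.ndarray:
    """Full delta-method SE of h_U(t_i) / (H_UO - H_U(t_i)) using the curve covariance.

    Unlike :func:`individual_hazard_se`, this keeps the covariances among the
    fitted per-interval hazards (which share the fit intercept) and the
    numerator-denominator covariance.  Requires ``h_U.covariance``.
    """
    if h_U.covariance is None:
        raise ValueError("h_U.covariance is required for the correlated-error mode")
    n = h_U.age_grid.n
    width = float(h_U.age_grid.width)
    H = cumulative_hazard(h_U)
    denom = H.overall - H.at_interval
    se = np.zeros(n)
    for i in range(n):
        if h_U.values[i] <= 0:
            continue
        g = np.zeros(n)
        # d/dh_m of h_i / (Delta * sum_{m>=i} h_m)
        g[i] = 1.0 / denom[i]
        g[i:] -= h_U.values[i] * width / denom[i] ** 2
        se[i] = np.sqrt(g @ h_U.covariance @ g)
    return se


# ---------------------------------------------------------------------------
# Survival / resistance curves
# ---------------------------------------------------------------------------

def survival_curves(
    h: HazardCurve, p: float, H: CumulativeHazard | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resistance and density from a conditional hazard curve.

    Returns ``(S, S_U, f, se_S)`` with S(t_i) = exp(-H(t_i)) the individual
    cancer resistance rate, S_U = 1 - p + p S its population analogue
    (floored at the immune fraction 1 - p), f = h * S the presentation
    density, and SE[S] = S * SE[H] by the delta method with the
    independent-interval SE of H.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if H is None:
        H = cumulative_hazard(h)
    S = np.exp(-H.at_interval)
    S_U = 1.0 - p + p * S
    f = h.values * S
    se_H = (
        H.se_at_interval if H.se_at_interval is not None else cumulative_hazard_se(h)
    )
    return S, S_U, f, S * se_H


def population_resistance_inverse(S_U: np.ndarray, p: float) -> np.ndarray:
    """Conditional resistance recovered from the population curve: (S_U + p - 1)/p."""
    return (np.asarray(S_U, dtype=float) + p - 1.0) / p


def individual_rates(
    h_U: HazardCurve,
    se_mode: str = "delta",
) -> tuple[IndividualRates, SusceptibilityEstimate]:
    """Full conditional-rate stack from a fitted population hazard curve.

    Computes the left-cumulative H_U, the susceptible fraction, the working
    presentation-rate estimate with SEs (``se_mode``: "delta" uses the
    fitted covariance when available, "independent" uses the
    independent-interval first-order formula), the conditional cumulative
    hazard and the resistance/density curves.
    """
    H_U = cumulative_hazard(h_U)
    estimate = susceptible_fraction(H_U.overall, H_U.se_overall or 0.0)
    presentation = individual_hazard_approx(h_U, H_U)
    if se_mode == "delta" and h_U.covariance is not None:
        presentation.se = individual_hazard_se_delta(h_U)
    elif se_mode not in ("delta", "independent"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    H_cond = cumulative_hazard(presentation)
    if estimate.p_exact > 0:
        # the mixture identities need a proper probability: use the exact p
        S, S_U, f, se_S = survival_curves(presentation, estimate.p_exact, H_cond)
    else:  # degenerate all-zero hazard
        S = np.exp(-H_cond.at_interval)
        S_U = np.ones_like(S)
        f = presentation.values * S
        se_S = np.zeros_like(S)
    rates = IndividualRates(
        presentation=presentation,
        cumulative=H_cond,
        resistance=S,
        resistance_se=se_S,
        density=f,
        population_resistance=S_U,
    )
    return rates, estimate


def export_curve_tsv(
    path: str | Path,
    curve: HazardCurve,
    scale: float = 1e5,
    header: str = "hazard_per_100k",
) -> None:
    """Age-interval label, scaled value, SE and 95% CI columns."""
    z = 1.959963984540054
    lines = [f"age_interval\t{header}\tse\tlower95\tupper95"]
    for lab, v, s in zip(curve.age_grid.labels(), curve.values, curve.se):
        lines.append(
            f"{lab}\t{v * scale:.6g}\t{s * scale:.6g}"
            f"\t{(v - z * s) * scale:.6g}\t{(v + z * s) * scale:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
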