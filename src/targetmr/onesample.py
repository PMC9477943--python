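"""One-sample MR (allele score + 2SLS), 2x2 factorial MR, triangulation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate, WeakInstrumentError, _estimate
from .sumstats import ValidationError, Z_95, two_sided_p


@dataclass(frozen=True)
class AlleleScore:
    """Fixed per-variant weights; score = sum_j w_j * dosage_j."""

    weights: tuple
    dosage_columns: tuple

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if len(w) != len(self.dosage_columns):
            raise ValidationError("weights and dosage columns must match")
        if not all(np.isfinite(w)):
            raise ValidationError("weights must be finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "dosage_columns", tuple(self.dosage_columns))

    def values(self, cohort: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.dosage_columns if c not in cohort.columns]
        if missing:
            raise ValidationError(f"cohort missing dosage columns {missing}")
        return cohort[list(self.dosage_columns)].to_numpy(dtype=float) @ np.array(self.weights)


def _ols(x: np.ndarray, y: np.ndarray):
    """Simple regression y ~ 1 + x; returns (intercept, slope, se_slope, rss)."""
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx == 0:
        raise WeakInstrumentError("regressor has zero variance")
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    rss = float(np.sum(resid**2))
    se_slope = np.sqrt(rss / (n - 2) / sxx)
    return float(intercept), float(slope), float(se_slope), rss


def first_stage_f(score: np.ndarray, exposure: np.ndarray) -> float:
    _, slope, se_slope, _ = _ols(score, exposure)
    return float((slope / se_slope) ** 2)


def two_stage_least_squares(cohort: pd.DataFrame, score: AlleleScore) -> MREstimate:
    """2SLS of outcome on exposure instrumented by the allele score.

    Stage 1 regresses exposure on the score; stage 2 regresses outcome on
    the fitted exposure, with the SE using residuals from the *observed*
    exposure (the standard 2SLS correction). A first-stage F below 10
    attaches a weak-instrument warning rather than failing.
    """
    if len(cohort) < 30:
        raise ValidationError("2SLS requires n >= 30")
    g = score.values(cohort)
    x = cohort["EXPOSURE"].to_numpy(dtype=float)
    y = cohort["OUTCOME"].to_numpy(dtype=float)
    if np.var(g) == 0:
        raise WeakInstrumentError("allele score has zero variance")

    a1, b1, se_b1, _ = _ols(g, x)
    f1 = (b1 / se_b1) ** 2 if se_b1 > 0 else float("inf")
    xhat = a1 + b1 * g

    _, beta, _, _ = _ols(xhat, y)
    # 2SLS SE: residuals from observed exposure, variance of fitted exposure
    alpha = y.mean() - beta * x.mean()
    u = y - alpha - beta * x
    n = len(y)
    sxx_hat = np.sum((xhat - xhat.mean()) ** 2)
    se = float(np.sqrt(np.sum(u**2) / (n - 2) / sxx_hat))

    warnings = ()
    if f1 < 10:
        warnings = (f"weak instrument: first-stage F = {f1:.2f} < 10",)
    est = _estimate("2sls", beta, se, len(score.weights), warnings=warnings)
    return est


# ---------------------------------------------------------------------------
# Factorial MR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Effect:
    beta: float
    se: float
    pval: float


@dataclass(frozen=True)
class FactorialResult:
    """2x2 median-split factorial contrast (low/low reference cell)."""

    cell_counts: dict          # (a, b) -> n, keys "low_low", ...
    cell_means: dict
    main_a: Effect             # A effect at B = low
    main_b: Effect             # B effect at A = low
    interaction: Effect
    a_given_high_b: Effect     # A effect conditional on B = high

    def to_dict(self) -> dict:
        def eff(e: Effect):
            return {"beta": e.beta, "se": e.se, "pval": e.pval}
        return {
            "cell_counts": self.cell_counts,
            "cell_means": self.cell_means,
            "main_a": eff(self.main_a), "main_b": eff(self.main_b),
            "interaction": eff(self.interaction),
            "a_given_high_b": eff(self.a_given_high_b),
        }


def _median_split(values: np.ndarray, label: str) -> np.ndarray:
    med = np.median(values)
    ties = np.sum(values == med)
    if ties > 0.5 * len(values):
        raise ValidationError(
            f"score {label}: more than half of values tie at the median; "
            "jitter the score or use a quantile split")
    return (values > med).astype(float)  # ties go to the low group


def factorial_2x2(cohort: pd.DataFrame, score_a: AlleleScore,
                  score_b: AlleleScore) -> FactorialResult:
    """Dichotomise two allele scores at their medians and regress the
    outcome on indicator_A + indicator_B + interaction (OLS)."""
    a = _median_split(score_a.values(cohort), "A")
    b = _median_split(score_b.values(cohort), "B")
    y = cohort["OUTCOME"].to_numpy(dtype=float)
    n = len(y)

    design = np.column_stack([np.ones(n), a, b, a * b])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 4:
        raise ValidationError("degenerate factorial design (empty cell?)")
    resid = y - design @ coef
    sigma2 = float(np.sum(resid**2) / (n - 4))
    cov = sigma2 * np.linalg.inv(design.T @ design)
    ses = np.sqrt(np.diag(cov))

    def eff(i: int) -> Effect:
        return Effect(float(coef[i]), float(ses[i]),
                      two_sided_p(coef[i] / ses[i]))

    # A effect at B=high: beta_A + beta_AB
    c = np.array([0.0, 1.0, 0.0, 1.0])
    b_ahb = float(c @ coef)
    se_ahb = float(np.sqrt(c @ cov @ c))
    a_given_high_b = Effect(b_ahb, se_ahb, two_sided_p(b_ahb / se_ahb))

    counts, means = {}, {}
    for ai, aname in ((0.0, "low"), (1.0, "high")):
        for bi, bname in ((0.0, "low"), (1.0, "high")):
            mask = (a == ai) & (b == bi)
            counts[f"{aname}_{bname}"] = int(mask.sum())
            means[f"{aname}_{bname}"] = float(y[mask].mean()) if mask.any() else float("nan")
    assert sum(counts.values()) == n

    return FactorialResult(cell_counts=counts, cell_means=means,
                           main_a=eff(1), main_b=eff(2), interaction=eff(3),
                           a_given_high_b=a_given_high_b)


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------

_KNOWN_SCALES = ("sd", "log_or", "or")


def triangulate(estimates: Sequence[dict]) -> tuple:
    """Express estimates from different sources on a common scale and
    z-test their pairwise differences.

    Each entry is ``{"source", "beta", "se", "scale"}`` with scale one of
    ``sd`` (already per 1 SD exposure lowering), ``log_or`` (log-odds per
    SD lowering) or ``or`` (odds ratio; converted by log).

    Returns ``(table, pairwise)`` DataFrames.
    """
    rows = []
    for e in estimates:
        scale = e["scale"]
        if scale not in _KNOWN_SCALES:
            raise ValidationError(f"unknown scale tag {scale!r}")
        beta = float(np.log(e["beta"])) if scale == "or" else float(e["beta"])
        se = float(e["se"])
        rows.append({
            "source": e["source"], "scale_in": scale,
            "beta_common": beta, "se": se,
            "ci_low": beta - Z_95 * se, "ci_high": beta + Z_95 * se,
        })
    table = pd.DataFrame(rows)

    pw = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            d = rows[i]["beta_common"] - rows[j]["beta_common"]
            sd = np.sqrt(rows[i]["se"] ** 2 + rows[j]["se"] ** 2)
            z = d / sd if sd > 0 else 0.0
            pw.append({
                "source_a": rows[i]["source"], "source_b": rows[j]["source"],
                "difference": d, "se_diff": float(sd), "z": float(z),
                "pval": two_sided_p(z),
            })
    return table, pd.DataFrame(pw)
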