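"""Two-sample MR estimators over harmonised instruments.

Wald ratio, inverse-variance-weighted (fixed / random), Cochran's Q,
Egger regression, weighted median, weighted mode, and a single-variant /
leave-one-out influence scan. All confidence intervals use the normal
multiplier 1.959964; p-values are two-sided normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonisedInstrument, ValidationError, Z_95, two_sided_p


class WeakInstrumentError(ValidationError):
    """The instrument carries no usable exposure signal."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_stat: Optional[float] = None
    q_pval: Optional[float] = None
    tau2: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    warnings: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pval": self.pval,
            "n_snps": self.n_snps, "q_stat": self.q_stat, "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }


def _estimate(method: str, beta: float, se: float, n_snps: int, **kw) -> MREstimate:
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z_95 * se), ci_high=float(beta + Z_95 * se),
        pval=two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0),
        n_snps=n_snps, **kw,
    )


def _arrays(insts: Sequence[HarmonisedInstrument]):
    be = np.array([i.beta_exposure for i in insts], dtype=float)
    se_e = np.array([i.se_exposure for i in insts], dtype=float)
    bo = np.array([i.beta_outcome for i in insts], dtype=float)
    se_o = np.array([i.se_outcome for i in insts], dtype=float)
    return be, se_e, bo, se_o


def ratio_estimates(insts: Sequence[HarmonisedInstrument]):
    """Per-variant Wald ratios and first-order delta-method SEs."""
    be, _, bo, se_o = _arrays(insts)
    if np.any(be == 0):
        raise WeakInstrumentError("zero exposure beta: Wald ratio undefined")
    return bo / be, np.abs(se_o / be)


# ---------------------------------------------------------------------------
# Wald ratio and IVW
# ---------------------------------------------------------------------------

def wald_ratio(inst: HarmonisedInstrument, second_order: bool = False) -> MREstimate:
    """Single-instrument ratio estimate.

    First-order SE is |se_out / beta_exp|; the second-order option adds the
    exposure-uncertainty delta-method term.
    """
    if inst.beta_exposure == 0:
        raise WeakInstrumentError(f"{inst.variant_id}: exposure beta is zero")
    beta = inst.beta_outcome / inst.beta_exposure
    var = inst.se_outcome**2 / inst.beta_exposure**2
    if second_order:
        var += inst.beta_outcome**2 * inst.se_exposure**2 / inst.beta_exposure**4
    return _estimate("wald_ratio", beta, np.sqrt(var), 1)


def cochran_q(insts: Sequence[HarmonisedInstrument], beta_hat: float):
    """Heterogeneity of per-variant ratios about ``beta_hat``.

    Q = sum_j w_j (theta_j - beta_hat)^2 with w_j = (beta_exp_j / se_out_j)^2;
    df = n - 1; p from the chi-square upper tail.
    """
    if len(insts) < 2:
        raise ValidationError("Cochran's Q requires >= 2 instruments")
    theta, se_theta = ratio_estimates(insts)
    w = 1.0 / se_theta**2
    q = float(np.sum(w * (theta - beta_hat) ** 2))
    df = len(insts) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(insts: Sequence[HarmonisedInstrument], model: str = "fixed",
        random_method: str = "multiplicative") -> MREstimate:
    """Inverse-variance-weighted estimate (weighted regression through the
    origin of outcome on exposure betas, weights 1/se_out^2).

    ``model='random'`` inflates the fixed SE multiplicatively by
    max(1, sqrt(Q/df)); ``random_method='dl'`` instead adds a
    DerSimonian-Laird tau^2 to the per-ratio variances.
    A single instrument delegates to :func:`wald_ratio`.
    """
    if len(insts) < 1:
        raise ValidationError("IVW requires at least one instrument")
    if model not in ("fixed", "random"):
        raise ValidationError(f"unknown IVW model {model!r}")
    if len(insts) == 1:
        est = wald_ratio(insts[0])
        return MREstimate(**{**est.__dict__, "method": f"ivw_{model}"})

    be, _, bo, se_o = _arrays(insts)
    w = 1.0 / se_o**2
    denom = np.sum(w * be**2)
    beta = float(np.sum(w * be * bo) / denom)
    se_fixed = float(1.0 / np.sqrt(denom))
    q, df, q_p = cochran_q(insts, beta)

    if model == "fixed":
        return _estimate("ivw_fixed", beta, se_fixed, len(insts),
                         q_stat=q, q_pval=q_p)

    if random_method == "multiplicative":
        se = se_fixed * max(1.0, np.sqrt(q / df))
        return _estimate("ivw_random", beta, se, len(insts),
                         q_stat=q, q_pval=q_p)
    if random_method == "dl":
        theta, se_theta = ratio_estimates(insts)
        wj = 1.0 / se_theta**2
        c = np.sum(wj) - np.sum(wj**2) / np.sum(wj)
        tau2 = max(0.0, (q - df) / c)
        w_star = 1.0 / (se_theta**2 + tau2)
        beta_r = float(np.sum(w_star * theta) / np.sum(w_star))
        se_r = float(1.0 / np.sqrt(np.sum(w_star)))
        return _estimate("ivw_random_dl", beta_r, se_r, len(insts),
                         q_stat=q, q_pval=q_p, tau2=tau2)
    raise ValidationError(f"unknown random model {random_method!r}")


# ---------------------------------------------------------------------------
# Egger
# ---------------------------------------------------------------------------

def egger(insts: Sequence[HarmonisedInstrument]) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure betas with an
    intercept (the directional-pleiotropy test).

    Instruments are oriented so every exposure beta is non-negative before
    fitting. SEs use multiplicative overdispersion floored at 1.
    """
    if len(insts) < 3:
        raise ValidationError("Egger regression requires >= 3 instruments")
    be, _, bo, se_o = _arrays(insts)
    flip = np.sign(be)
    flip[flip == 0] = 1.0
    x = be * flip
    y = bo * flip
    w = 1.0 / se_o**2

    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0:
        raise WeakInstrumentError("no spread in exposure betas")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)

    resid = y - intercept - slope * x
    df = len(insts) - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    infl = max(1.0, np.sqrt(sigma2))
    se_slope = infl / np.sqrt(sxx)
    se_int = infl * np.sqrt(1.0 / sw + xbar**2 / sxx)

    return _estimate(
        "egger", slope, se_slope, len(insts),
        egger_intercept=intercept,
        egger_intercept_se=float(se_int),
        egger_intercept_p=two_sided_p(intercept / se_int),
    )


# ---------------------------------------------------------------------------
# Weighted median / mode
# ---------------------------------------------------------------------------

def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    t = theta[order]
    ww = w[order] / np.sum(w)
    p = np.cumsum(ww) - 0.5 * ww
    if p[0] >= 0.5:
        return float(t[0])
    k = int(np.searchsorted(p, 0.5))
    if k >= len(t):
        return float(t[-1])
    return float(t[k - 1] + (t[k] - t[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1]))


def weighted_median(insts: Sequence[HarmonisedInstrument],
                    n_boot: int = 1000, seed: Optional[int] = None) -> MREstimate:
    """Weighted median of per-variant ratios (inverse-variance weights);
    SE from a parametric bootstrap over the summary betas."""
    if len(insts) < 3:
        raise ValidationError("weighted median requires >= 3 instruments")
    theta, se_theta = ratio_estimates(insts)
    w = 1.0 / se_theta**2
    point = _weighted_median_point(theta, w)

    be, se_e, bo, se_o = _arrays(insts)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, se_o)
        ok = be_b != 0
        t_b = bo_b[ok] / be_b[ok]
        w_b = (be_b[ok] / se_o[ok]) ** 2
        boots[b] = _weighted_median_point(t_b, w_b)
    return _estimate("weighted_median", point, float(np.std(boots, ddof=1)), len(insts))


def _silverman_bandwidth(theta: np.ndarray) -> float:
    n = len(theta)
    s = np.std(theta, ddof=1)
    mad = stats.median_abs_deviation(theta, scale="normal")
    scale = min(s, mad) if mad > 0 else s
    return 0.9 * scale * n ** (-0.2)


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray,
                         bandwidth_factor: float, n_grid: int = 512) -> float:
    lo, hi = float(np.min(theta)), float(np.max(theta))
    if lo == hi:
        return lo
    h = bandwidth_factor * _silverman_bandwidth(theta)
    if h <= 0:
        return float(theta[np.argmax(w)])
    grid = np.linspace(lo, hi, n_grid)
    dens = np.sum((w / np.sum(w))[None, :]
                  * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(insts: Sequence[HarmonisedInstrument],
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: Optional[int] = None) -> MREstimate:
    """Mode of the weighted kernel density of per-variant ratios
    (normal kernel, modified-Silverman bandwidth); bootstrap SE."""
    if len(insts) < 3:
        raise ValidationError("weighted mode requires >= 3 instruments")
    if bandwidth_factor <= 0:
        raise ValidationError("bandwidth_factor must be positive")
    theta, se_theta = ratio_estimates(insts)
    w = 1.0 / se_theta**2
    point = _weighted_mode_point(theta, w, bandwidth_factor)

    be, se_e, bo, se_o = _arrays(insts)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, se_o)
        ok = be_b != 0
        t_b = bo_b[ok] / be_b[ok]
        w_b = (be_b[ok] / se_o[ok]) ** 2
        boots[b] = _weighted_mode_point(t_b, w_b, bandwidth_factor, n_grid=128)
    return _estimate("weighted_mode", point, float(np.std(boots, ddof=1)), len(insts))


# ---------------------------------------------------------------------------
# Influence diagnostics
# ---------------------------------------------------------------------------

def single_variant_scan(insts: Sequence[HarmonisedInstrument]) -> pd.DataFrame:
    """Per-variant Wald ratios plus leave-one-out IVW.

    A variant is flagged when removing it moves the full IVW estimate by
    more than one pooled SE. With a single instrument the leave-one-out
    columns are absent (NaN).
    """
    if len(insts) < 1:
        raise ValidationError("scan requires at least one instrument")
    rows = []
    if len(insts) >= 2:
        full = ivw(insts, model="fixed")
    else:
        full = None
    for j, inst in enumerate(insts):
        wr = wald_ratio(inst)
        row = {
            "variant_id": inst.variant_id,
            "beta": wr.beta, "se": wr.se, "pval": wr.pval,
            "loo_beta": np.nan, "loo_se": np.nan, "influential": False,
        }
        if full is not None:
            rest = [x for k, x in enumerate(insts) if k != j]
            loo = ivw(rest, model="fixed")
            row["loo_beta"] = loo.beta
            row["loo_se"] = loo.se
            row["influential"] = bool(abs(loo.beta - full.beta) > full.se)
        rows.append(row)
    return pd.DataFrame(rows)
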