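"""Per-target effects, the pooled general drug effect, and reporting arithmetic.

Per-target MR estimates are meta-analysed (inverse-variance fixed effect,
plus a multiplicative random-effect model) into the drug's general effect;
helpers rescale log-odds estimates to odds ratios per 1 SD exposure
lowering and handle multiplicity and CI arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import estimators
from .estimators import MREstimate
from .instruments import InstrumentSet
from .sumstats import (LDMatrix, ValidationError, VariantAssociation, Z_95,
                       find_proxy, harmonise, HarmonisedInstrument, two_sided_p)

#: 1 SD of the glycaemic biomarker in native units (configurable, not baked
#: into any operation).
DEFAULT_SD_MMOL_PER_MOL = 6.75
DEFAULT_SD_PERCENT = 1.09


# ---------------------------------------------------------------------------
# Generic inverse-variance meta-analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaResult:
    fixed_beta: float
    fixed_se: float
    fixed_p: float
    random_beta: float
    random_se: float
    random_p: float
    q_stat: float
    q_df: int
    q_pval: float

    @property
    def fixed_ci(self):
        return (self.fixed_beta - Z_95 * self.fixed_se,
                self.fixed_beta + Z_95 * self.fixed_se)


def meta_analyse(betas: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Fixed-effect inverse-variance pooling plus multiplicative
    random-effect inflation (se_random = se_fixed * max(1, sqrt(Q/df)))."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 1 or b.shape != s.shape:
        raise ValidationError("need matching non-empty beta/se vectors")
    if np.any(s <= 0):
        raise ValidationError("all SEs must be positive")
    w = 1.0 / s**2
    beta_f = float(np.sum(w * b) / np.sum(w))
    se_f = float(1.0 / np.sqrt(np.sum(w)))
    if b.size >= 2:
        q = float(np.sum(w * (b - beta_f) ** 2))
        df = b.size - 1
        q_p = float(stats.chi2.sf(q, df))
        se_r = se_f * max(1.0, np.sqrt(q / df))
    else:
        q, df, q_p, se_r = 0.0, 0, 1.0, se_f
    return MetaResult(
        fixed_beta=beta_f, fixed_se=se_f, fixed_p=two_sided_p(beta_f / se_f),
        random_beta=beta_f, random_se=se_r, random_p=two_sided_p(beta_f / se_r),
        q_stat=q, q_df=df, q_pval=q_p,
    )


# ---------------------------------------------------------------------------
# Target-level and pooled effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetEffect:
    target_name: str
    outcome_name: str
    estimate: Optional[MREstimate]
    instrument_count: int
    min_f: float
    usable: bool
    sensitivity: dict = field(default_factory=dict)  # method -> MREstimate
    warnings: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class GeneralEffect:
    outcome_name: str
    meta: MetaResult
    included_targets: tuple
    warnings: tuple = field(default_factory=tuple)

    @property
    def cross_target_q(self) -> float:
        return self.meta.q_stat

    @property
    def cross_target_q_pval(self) -> float:
        return self.meta.q_pval


def estimate_target_effect(instrument_set: InstrumentSet,
                           outcome_gwas: Sequence[VariantAssociation],
                           ld: Optional[LDMatrix] = None,
                           proxy_r2: float = 0.8,
                           sensitivity: bool = True,
                           outcome_name: str = "",
                           seed: Optional[int] = None) -> TargetEffect:
    """Harmonise a target's instruments against an outcome GWAS (with LD
    proxy fallback for missing variants) and estimate the causal effect.

    IVW for two or more instruments (Wald ratio for one); sensitivity
    estimators are attached when instrument counts permit. An unusable
    instrument set (empty, or nothing passing the coloc filter) yields
    ``usable=False`` with no estimate.
    """
    passing = instrument_set.passing
    if not passing:
        return TargetEffect(
            target_name=instrument_set.target_name, outcome_name=outcome_name,
            estimate=None, instrument_count=0, min_f=float("nan"),
            usable=False, warnings=instrument_set.warnings + ("no usable instruments",))

    out_by_id = {r.variant_id: r for r in outcome_gwas}
    harmonised: list[HarmonisedInstrument] = []
    warnings = list(instrument_set.warnings)
    for inst in passing:
        exp = inst.exposure_assoc
        out = out_by_id.get(exp.variant_id)
        proxy_used, p_r2 = False, None
        if out is None and ld is not None and exp.variant_id in ld:
            proxy = find_proxy(exp.variant_id, list(out_by_id), ld, r2_min=proxy_r2)
            if proxy is not None:
                out = out_by_id[proxy]
                proxy_used, p_r2 = True, ld.r2(exp.variant_id, proxy)
        if out is None:
            warnings.append(f"{exp.variant_id}: missing from outcome, no proxy")
            continue
        res = harmonise(exp, out, proxy_used=proxy_used, proxy_r2=p_r2)
        if isinstance(res, HarmonisedInstrument):
            harmonised.append(res)
        else:
            warnings.append(f"{exp.variant_id}: {res.reason}")

    if not harmonised:
        return TargetEffect(
            target_name=instrument_set.target_name, outcome_name=outcome_name,
            estimate=None, instrument_count=0, min_f=instrument_set.min_f,
            usable=False, warnings=tuple(warnings) + ("no harmonisable instruments",))

    if len(harmonised) == 1:
        est = estimators.wald_ratio(harmonised[0])
    else:
        est = estimators.ivw(harmonised, model="fixed")

    sens: dict = {}
    if sensitivity and len(harmonised) >= 2:
        sens["ivw_random"] = estimators.ivw(harmonised, model="random")
    if sensitivity and len(harmonised) >= 3:
        sens["egger"] = estimators.egger(harmonised)
        sens["weighted_median"] = estimators.weighted_median(harmonised, seed=seed)
        sens["weighted_mode"] = estimators.weighted_mode(harmonised, seed=seed)

    min_f = min(i.f_stat for i in passing)
    if min_f < 10:
        warnings.append("weak instruments: min F below 10")
    return TargetEffect(
        target_name=instrument_set.target_name, outcome_name=outcome_name,
        estimate=est, instrument_count=len(harmonised), min_f=min_f,
        usable=True, sensitivity=sens, warnings=tuple(dict.fromkeys(warnings)))


def pool_general_effect(target_effects: Sequence[TargetEffect],
                        outcome_name: str = "") -> GeneralEffect:
    """Inverse-variance pooling of per-target estimates into the general
    drug effect; fixed and random models share the same target set, and
    cross-target heterogeneity is reported as Cochran's Q."""
    usable = [t for t in target_effects if t.usable and t.estimate is not None]
    warnings: tuple = ()
    if not usable:
        raise ValidationError("no usable target effects to pool")
    if len(usable) < 2:
        warnings = ("fewer than 2 usable targets: pooled estimate is a pass-through",)
    meta = meta_analyse([t.estimate.beta for t in usable],
                        [t.estimate.se for t in usable])
    name = outcome_name or usable[0].outcome_name
    return GeneralEffect(outcome_name=name, meta=meta,
                         included_targets=tuple(t.target_name for t in usable),
                         warnings=warnings)


# ---------------------------------------------------------------------------
# Scaling and reporting arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaledEffect:
    """A log-odds effect per 1 SD exposure change, on the odds scale."""

    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    percent_change: float      # 100*(1-OR): percent lower odds when OR < 1
    direction: str
    sd_native: float = DEFAULT_SD_MMOL_PER_MOL
    sd_percent: float = DEFAULT_SD_PERCENT


def scale_to_or(beta: float, se: float, direction: str = "lowering",
                sd_native: float = DEFAULT_SD_MMOL_PER_MOL,
                sd_percent: float = DEFAULT_SD_PERCENT) -> ScaledEffect:
    """Express a log-odds estimate per 1 SD exposure *lowering* (or raising)
    as an OR with 95% CI and percent change in odds."""
    if direction not in ("lowering", "raising"):
        raise ValidationError(f"unknown direction {direction!r}")
    if not (np.isfinite(beta) and np.isfinite(se) and se >= 0):
        raise ValidationError("beta/se must be finite, se >= 0")
    b = -beta if direction == "lowering" else beta
    or_ = float(np.exp(b))
    return ScaledEffect(
        log_or=float(b), se=float(se), or_=or_,
        ci_low=float(np.exp(b - Z_95 * se)), ci_high=float(np.exp(b + Z_95 * se)),
        percent_change=float(100.0 * (1.0 - or_)),
        direction=direction, sd_native=sd_native, sd_percent=sd_percent,
    )


def percent_change_from_or(or_: float) -> float:
    """Percent change in odds implied by an odds ratio: 100*(1-OR)."""
    if not (np.isfinite(or_) and or_ > 0):
        raise ValidationError("OR must be positive and finite")
    return float(100.0 * (1.0 - or_))


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0,1)")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha / n_tests


def wald_p_from_ci(point: float, ci_low: float, ci_high: float) -> float:
    """Reconstruct the two-sided Wald p from a point estimate and its
    normal-theory 95% CI."""
    if not ci_low < ci_high:
        raise ValidationError("degenerate confidence interval")
    if not (ci_low <= point <= ci_high):
        raise ValidationError("point estimate outside its CI")
    se = (ci_high - ci_low) / (2.0 * Z_95)
    return two_sided_p(point / se)
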