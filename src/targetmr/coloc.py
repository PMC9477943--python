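"""Approximate-Bayes-factor colocalisation under a single causal variant.

Two regional association sets are compared across five hypotheses:
H0 no association, H1/H2 association with one trait only, H3 two distinct
causal variants, H4 one shared causal variant. Per-variant evidence is the
Wakefield asymptotic Bayes factor; hypothesis posteriors are accumulated
in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .sumstats import ValidationError, VariantAssociation

#: default effect-size prior SDs for the Wakefield ABF
QUANT_PRIOR_SD = 0.15   # quantitative trait, per-SD scale
CC_PRIOR_SD = 0.2       # case-control trait, log-odds scale

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
DEFAULT_THRESHOLD = 0.70


def wakefield_labf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for a single association.

    With V = se^2, W = prior_sd^2 and r = W/(V+W):
    log ABF = 0.5*log(1-r) + 0.5*z^2*r.
    """
    if not (np.isfinite(se) and se > 0):
        raise ValidationError("se must be positive and finite")
    if not (np.isfinite(prior_sd) and prior_sd > 0):
        raise ValidationError("prior_sd must be positive and finite")
    v = se * se
    w = prior_sd * prior_sd
    r = w / (v + w)
    z = beta / se
    return float(0.5 * np.log1p(-r) + 0.5 * z * z * r)


@dataclass(frozen=True)
class RegionalAssoc:
    """Ordered per-variant associations for one trait over a region."""

    variant_ids: tuple
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quantitative"  # or "case_control"
    case_fraction: Optional[float] = None

    def __post_init__(self):
        ids = tuple(self.variant_ids)
        beta = np.asarray(self.beta, dtype=float)
        se = np.asarray(self.se, dtype=float)
        if len(ids) < 2:
            raise ValidationError("a region needs at least 2 variants")
        if beta.shape != (len(ids),) or se.shape != (len(ids),):
            raise ValidationError("beta/se length must match variant ids")
        if np.any(se <= 0) or not np.all(np.isfinite(beta / se)):
            raise ValidationError("non-finite z-scores in region")
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValidationError(f"unknown trait type {self.trait_type!r}")
        object.__setattr__(self, "variant_ids", ids)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "se", se)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def default_prior_sd(self) -> float:
        return CC_PRIOR_SD if self.trait_type == "case_control" else QUANT_PRIOR_SD

    @classmethod
    def from_associations(cls, records: Sequence[VariantAssociation],
                          trait_type: str = "quantitative",
                          case_fraction: Optional[float] = None) -> "RegionalAssoc":
        return cls(
            variant_ids=tuple(r.variant_id for r in records),
            beta=np.array([r.beta for r in records]),
            se=np.array([r.se for r in records]),
            trait_type=trait_type,
            case_fraction=case_fraction,
        )


@dataclass(frozen=True)
class ColocResult:
    pp: np.ndarray                 # PP0..PP4
    p1: float
    p2: float
    p12: float
    labf1: np.ndarray
    labf2: np.ndarray
    threshold: float
    rule: str = "pp4"
    verdict: str = field(default="")

    @property
    def pp0(self): return float(self.pp[0])
    @property
    def pp1(self): return float(self.pp[1])
    @property
    def pp2(self): return float(self.pp[2])
    @property
    def pp3(self): return float(self.pp[3])
    @property
    def pp4(self): return float(self.pp[4])

    @property
    def coloc_probability(self) -> float:
        if self.rule == "conditional":
            denom = self.pp3 + self.pp4
            return self.pp4 / denom if denom > 0 else 0.0
        return self.pp4

    @property
    def colocalised(self) -> bool:
        return self.verdict == "colocalised"

    def to_dict(self) -> dict:
        return {
            "pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
            "pp3": self.pp3, "pp4": self.pp4,
            "p1": self.p1, "p2": self.p2, "p12": self.p12,
            "threshold": self.threshold, "rule": self.rule,
            "verdict": self.verdict,
        }


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def colocalise(trait1: RegionalAssoc, trait2: RegionalAssoc,
               p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
               p12: float = DEFAULT_P12, threshold: float = DEFAULT_THRESHOLD,
               prior_sd1: Optional[float] = None,
               prior_sd2: Optional[float] = None,
               rule: str = "pp4") -> ColocResult:
    """Posterior probabilities of the five sharing hypotheses for a region.

    Variant panels are intersected and aligned (order of ``trait1``); at
    least two shared variants are required. The verdict is "colocalised"
    iff the colocalisation probability (PP4 by default; PP4/(PP3+PP4)
    under ``rule='conditional'``) is >= ``threshold``.
    """
    if rule not in ("pp4", "conditional"):
        raise ValidationError(f"unknown verdict rule {rule!r}")
    idx2 = {v: i for i, v in enumerate(trait2.variant_ids)}
    shared = [v for v in trait1.variant_ids if v in idx2]
    if len(shared) < 2:
        raise ValidationError("fewer than 2 shared variants between traits")
    i1 = [trait1.variant_ids.index(v) for v in shared]
    i2 = [idx2[v] for v in shared]

    sd1 = trait1.default_prior_sd if prior_sd1 is None else prior_sd1
    sd2 = trait2.default_prior_sd if prior_sd2 is None else prior_sd2
    l1 = np.array([wakefield_labf(trait1.beta[i], trait1.se[i], sd1) for i in i1])
    l2 = np.array([wakefield_labf(trait2.beta[i], trait2.se[i], sd2) for i in i2])
    if not (np.all(np.isfinite(l1)) and np.all(np.isfinite(l2))):
        raise ValidationError("non-finite log Bayes factors")

    ls1 = float(logsumexp(l1))
    ls2 = float(logsumexp(l2))
    l12 = float(logsumexp(l1 + l2))

    lh = np.array([
        0.0,
        np.log(p1) + ls1,
        np.log(p2) + ls2,
        np.log(p1) + np.log(p2) + _log_diff_exp(ls1 + ls2, l12),
        np.log(p12) + l12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()

    res = ColocResult(pp=pp, p1=p1, p2=p2, p12=p12, labf1=l1, labf2=l2,
                      threshold=threshold, rule=rule)
    verdict = "colocalised" if res.coloc_probability >= threshold else "not colocalised"
    object.__setattr__(res, "verdict", verdict)
    return res
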