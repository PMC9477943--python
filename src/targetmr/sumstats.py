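"""GWAS summary-statistics backbone: records, I/O, harmonisation, LD utilities.

The on-disk dialect is a headered, tab-delimited table with columns
``SNP CHR POS EA OA EAF BETA SE P N PHENO`` (``#`` lines are comments).
LD panels are plink ``--r square``-style: a whitespace-delimited square
matrix plus a one-column variant-id file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window within which a palindromic (A/T or C/G) variant's strand
#: cannot be inferred from allele frequency and the variant is rejected.
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)

TSV_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "PHENO"]

Z_95 = 1.959964


class SchemaError(ValueError):
    """A summary-statistics file is missing mandatory columns or is empty."""


class LDPanelError(KeyError):
    """A variant required for an LD operation is absent from the panel."""


class ValidationError(ValueError):
    """Invalid user-supplied value or configuration."""


def two_sided_p(z: float) -> float:
    """Two-sided normal p-value for a z-score, floored at the smallest
    positive float (extreme z would otherwise underflow to 0)."""
    return float(max(2.0 * stats.norm.sf(abs(z)), 5e-324))


@dataclass(frozen=True)
class VariantAssociation:
    """One variant x phenotype GWAS summary record (per-allele effect)."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: Optional[int] = None
    eaf: Optional[float] = None
    phenotype: str = ""
    unit: str = ""

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def validate(self) -> Optional[str]:
        """Return a reason string if the record breaks an invariant, else None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid allele code"
        if self.effect_allele == self.other_allele:
            return "effect and other allele identical"
        if not np.isfinite(self.beta):
            return "non-finite beta"
        if not (np.isfinite(self.se) and self.se > 0):
            return "se not positive"
        if self.pos < 1:
            return "position must be 1-based"
        if self.n is not None and self.n <= 0:
            return "non-positive sample size"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "eaf outside (0,1)"
        if not (0.0 < self.pval <= 1.0):
            return "p outside (0,1]"
        # |beta/se| must agree with p within rounding; tolerate a factor of 10
        p_calc = two_sided_p(self.z)
        if p_calc > 1e-300 and self.pval > 1e-300:
            if abs(np.log10(self.pval) - np.log10(p_calc)) > 1.0:
                return "p inconsistent with beta/se"
        return None


@dataclass(frozen=True)
class HarmonisedInstrument:
    """Exposure and outcome effects aligned to one shared effect allele."""

    variant_id: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: Optional[float] = None
    proxy_used: bool = False
    proxy_r2: Optional[float] = None


@dataclass(frozen=True)
class Rejection:
    """A variant that could not be harmonised, with the reason."""

    variant_id: str
    reason: str


@dataclass
class ParseReport:
    n_read: int = 0
    n_kept: int = 0
    dropped: list = field(default_factory=list)  # (variant_id, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise LD correlations (r, not r^2) for an ordered variant panel."""

    variant_ids: tuple
    r: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValidationError("LD matrix must be square")
        if r.shape[0] != len(self.variant_ids):
            raise ValidationError("LD matrix dimension does not match id list")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        if np.any(np.abs(r) > 1.0 + 1e-8):
            raise ValidationError("LD correlations must lie in [-1, 1]")
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.variant_ids)})

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise LDPanelError(f"variant {variant_id!r} absent from LD panel") from None

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)] ** 2)

    @classmethod
    def from_files(cls, matrix_path, ids_path) -> "LDMatrix":
        ids = [line.strip() for line in Path(ids_path).read_text().splitlines() if line.strip()]
        r = np.loadtxt(matrix_path, ndmin=2)
        return cls(tuple(ids), r)

    def to_files(self, matrix_path, ids_path) -> None:
        Path(ids_path).write_text("\n".join(self.variant_ids) + "\n")
        np.savetxt(matrix_path, self.r, fmt="%.10g")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANDATORY = ["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE"]


def read_sumstats(path, column_map: Optional[dict] = None):
    """Read a summary-statistics TSV into validated records.

    Rows breaking record invariants are dropped (never repaired) and counted.

    Returns
    -------
    (records, report) : (list[VariantAssociation], ParseReport)
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str})
    if column_map:
        df = df.rename(columns=column_map)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    records, report = frame_to_records(df)
    log.info("read %s: kept %d / %d rows (%d dropped)",
             path, report.n_kept, report.n_read, report.n_dropped)
    for vid, reason in report.dropped:
        log.debug("dropped %s: %s", vid, reason)
    return records, report


def frame_to_records(df: pd.DataFrame):
    """Validate a dialect-shaped DataFrame row by row."""
    records, report = [], ParseReport(n_read=len(df))
    for row in df.itertuples(index=False):
        d = row._asdict()
        beta = float(d["BETA"])
        se = float(d["SE"])
        pval = d.get("P")
        if pval is None or (isinstance(pval, float) and np.isnan(pval)):
            # recompute from beta/se so the consistency invariant is closed
            pval = two_sided_p(beta / se) if se > 0 else np.nan
        eaf = d.get("EAF")
        if eaf is not None and isinstance(eaf, float) and np.isnan(eaf):
            eaf = None
        n_val = d.get("N")
        rec = VariantAssociation(
            variant_id=str(d["SNP"]),
            chrom=str(d["CHR"]),
            pos=int(d["POS"]),
            effect_allele=str(d["EA"]).upper(),
            other_allele=str(d["OA"]).upper(),
            eaf=None if eaf is None else float(eaf),
            beta=beta,
            se=se,
            pval=float(pval),
            n=int(n_val) if n_val is not None and not pd.isna(n_val) else None,
            phenotype=str(d.get("PHENO", "") or ""),
        )
        reason = rec.validate()
        if reason is None:
            records.append(rec)
        else:
            report.dropped.append((rec.variant_id, reason))
    report.n_kept = len(records)
    return records, report


def records_to_frame(records: Sequence[VariantAssociation]) -> pd.DataFrame:
    rows = [
        {
            "SNP": r.variant_id, "CHR": r.chrom, "POS": r.pos,
            "EA": r.effect_allele, "OA": r.other_allele,
            "EAF": np.nan if r.eaf is None else r.eaf,
            "BETA": r.beta, "SE": r.se, "P": r.pval, "N": r.n,
            "PHENO": r.phenotype,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_sumstats(records: Sequence[VariantAssociation], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Harmonisation
# ---------------------------------------------------------------------------

def _in_window(eaf: float) -> bool:
    lo, hi = PALINDROMIC_EAF_WINDOW
    return lo <= eaf <= hi


def harmonise(exposure: VariantAssociation, outcome: VariantAssociation,
              *, proxy_used: bool = False, proxy_r2: Optional[float] = None):
    """Align an exposure/outcome pair onto the exposure's effect allele.

    Returns a :class:`HarmonisedInstrument`, or a :class:`Rejection` when the
    alleles are incompatible or the variant is an unresolvable palindrome.
    Applying ``harmonise`` to an already-aligned pair is a no-op.
    """
    ea, oa = exposure.effect_allele, exposure.other_allele
    o_ea, o_oa = outcome.effect_allele, outcome.other_allele

    if exposure.is_palindromic():
        if {o_ea, o_oa} != {ea, oa}:
            return Rejection(exposure.variant_id, "incompatible alleles")
        if exposure.eaf is None or outcome.eaf is None:
            return Rejection(exposure.variant_id, "palindromic variant without eaf")
        if _in_window(exposure.eaf) or _in_window(outcome.eaf):
            return Rejection(exposure.variant_id, "ambiguous palindromic variant")
        # nominal alignment from allele letters, then strand check via eaf
        eaf_out = outcome.eaf if o_ea == ea else 1.0 - outcome.eaf
        flip = o_ea != ea
        if (exposure.eaf < 0.5) != (eaf_out < 0.5):
            flip = not flip  # opposite strands: reverse the nominal alignment
    else:
        c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        if (o_ea, o_oa) == (ea, oa):
            flip = False
        elif (o_ea, o_oa) == (oa, ea):
            flip = True
        elif (c_ea, c_oa) == (ea, oa):
            flip = False
        elif (c_ea, c_oa) == (oa, ea):
            flip = True
        else:
            return Rejection(exposure.variant_id, "incompatible alleles")

    beta_out = -outcome.beta if flip else outcome.beta
    return HarmonisedInstrument(
        variant_id=exposure.variant_id,
        effect_allele=ea,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
        eaf=exposure.eaf,
        proxy_used=proxy_used,
        proxy_r2=proxy_r2,
    )


def harmonise_pairs(exposures: Sequence[VariantAssociation],
                    outcomes: Sequence[VariantAssociation]):
    """Harmonise by shared variant id; returns (instruments, rejections)."""
    out_by_id = {r.variant_id: r for r in outcomes}
    kept, rejected = [], []
    for exp in exposures:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            rejected.append(Rejection(exp.variant_id, "absent from outcome"))
            continue
        res = harmonise(exp, out)
        (kept if isinstance(res, HarmonisedInstrument) else rejected).append(res)
    return kept, rejected


# ---------------------------------------------------------------------------
# LD proxying and pruning
# ---------------------------------------------------------------------------

def find_proxy(target_id: str, available_ids, ld: LDMatrix,
               r2_min: float = 0.8) -> Optional[str]:
    """Best available proxy for a missing variant (max r^2, r^2 >= r2_min).

    Raises :class:`LDPanelError` if the target itself is not in the panel —
    distinct from returning ``None`` (no candidate passes the threshold).
    """
    ti = ld.index(target_id)
    best_id, best_r2 = None, -1.0
    for vid in available_ids:
        if vid not in ld:
            continue
        r2 = float(ld.r[ti, ld.index(vid)] ** 2)
        if r2 > best_r2:
            best_id, best_r2 = vid, r2
    if best_id is not None and best_r2 >= r2_min:
        return best_id
    return None


def ld_prune(records: Sequence[VariantAssociation], ld: LDMatrix,
             r2_max: float = 0.001):
    """Greedy p-value-ordered pruning: keep a record iff its r^2 with every
    already-kept record is below ``r2_max``.

    Ties in p are broken lexicographically by (chrom, pos, variant_id), so the
    result is independent of input order.
    """
    for rec in records:
        if rec.variant_id not in ld:
            raise LDPanelError(f"variant {rec.variant_id!r} absent from LD panel")
    ordered = sorted(records, key=lambda r: (r.pval, r.chrom, r.pos, r.variant_id))
    kept: list[VariantAssociation] = []
    for rec in ordered:
        if all(ld.r2(rec.variant_id, k.variant_id) < r2_max for k in kept):
            kept.append(rec)
    return kept
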