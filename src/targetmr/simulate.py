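"""Synthetic GWAS, coloc-region, and cohort generators with known truth.

Everything downstream of this module is tested against the ground truth
stored in the returned truth records. Generators take one integer seed and
are reproducible bit-for-bit; per-variant standard errors follow the
analytic GWAS formula se ~ 1/sqrt(2*n*eaf*(1-eaf)) for a standardised
trait, so instrument strength is controlled by sample size alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .sumstats import TSV_COLUMNS, ValidationError, two_sided_p

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T")]  # non-palindromic pairs only

DEFAULT_PREVALENCE = 0.15


def _gwas_se(n, eaf):
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


# ---------------------------------------------------------------------------
# Two-sample GWAS generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Generative settings for a two-sample summary-statistics pair."""

    n_exposure_gwas: int = 344_182
    n_outcome_gwas: int = 455_258
    true_causal_effect: float = 0.0
    n_instruments: int = 32
    eaf_range: tuple = (0.05, 0.95)
    exposure_effect_range: tuple = (0.02, 0.15)
    pleiotropy_mode: str = "none"       # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0        # directional offset
    seed: int = 0

    def __post_init__(self):
        for name in ("true_causal_effect", "pleiotropy_sd", "pleiotropy_mean"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        lo, hi = self.eaf_range
        if not (0.01 < lo < hi < 0.99):
            raise ValidationError("eaf_range must lie within (0.01, 0.99)")
        if self.n_instruments < 1:
            raise ValidationError("n_instruments must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if (self.pleiotropy_sd == 0) != (self.pleiotropy_mode == "none"):
            if self.pleiotropy_mode == "none" and self.pleiotropy_sd != 0:
                raise ValidationError("pleiotropy_sd must be 0 when mode is 'none'")
            if self.pleiotropy_mode != "none" and self.pleiotropy_sd == 0:
                raise ValidationError("pleiotropy_sd must be > 0 when mode is not 'none'")
        if self.n_exposure_gwas < 2 or self.n_outcome_gwas < 2:
            raise ValidationError("sample sizes must be >= 2")


def _variant_frame(ids, chrom, pos, ea, oa, eaf, beta, se, n, pheno):
    z = beta / se
    return pd.DataFrame({
        "SNP": ids, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
        "EAF": eaf, "BETA": beta, "SE": se,
        "P": [two_sided_p(v) for v in z], "N": n, "PHENO": pheno,
    }, columns=TSV_COLUMNS)


def generate_two_sample_gwas(config: SimConfig,
                             exposure_name: str = "exposure",
                             outcome_name: str = "outcome"):
    """Simulate exposure and outcome summary statistics for independent
    instruments under the standard instrumental-variable model.

    Per instrument j the exposure effect is gamma_j, and the outcome effect
    is theta*gamma_j + alpha_j; estimates add sampling noise with the
    analytic per-variant SE.

    Returns ``(exposure_df, outcome_df, truth)`` where ``truth`` records
    theta, gamma, alpha and eaf.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_instruments
    eaf = rng.uniform(*config.eaf_range, size=m)
    gamma = rng.uniform(*config.exposure_effect_range, size=m)
    gamma *= rng.choice([-1.0, 1.0], size=m)

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(m)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=m)
    else:
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=m)

    se_exp = _gwas_se(config.n_exposure_gwas, eaf)
    se_out = _gwas_se(config.n_outcome_gwas, eaf)
    gamma_hat = gamma + rng.normal(0.0, se_exp)
    # alpha is defined on the exposure-raising orientation, so a directional
    # offset stays directional after Egger's sign alignment
    beta_out = config.true_causal_effect * gamma + np.sign(gamma) * alpha
    beta_out_hat = beta_out + rng.normal(0.0, se_out)

    ids = [f"rs{config.seed % 1000:03d}{j:04d}" for j in range(m)]
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    ea = [p[0] for p in pairs]
    oa = [p[1] for p in pairs]
    chrom = [str(1 + j % 22) for j in range(m)]
    pos = [1_000_000 + 10_000 * j for j in range(m)]

    exposure = _variant_frame(ids, chrom, pos, ea, oa, eaf, gamma_hat, se_exp,
                              config.n_exposure_gwas, exposure_name)
    outcome = _variant_frame(ids, chrom, pos, ea, oa, eaf, beta_out_hat, se_out,
                             config.n_outcome_gwas, outcome_name)
    truth = {
        "theta": config.true_causal_effect,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "eaf": eaf.tolist(),
        "variant_ids": ids,
        "pleiotropy_mode": config.pleiotropy_mode,
        "seed": config.seed,
    }
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# Colocalisation region generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocSimConfig:
    """Generative settings for a two-trait region with AR(1)-style LD."""

    n_variants: int = 50
    shared_causal: bool = True
    z_strength: float = 8.0
    ld_decay: float = 0.7
    n_gwas: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 2:
            raise ValidationError("n_variants must be >= 2")
        if not self.z_strength > 0:
            raise ValidationError("z_strength must be > 0")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValidationError("ld_decay must lie in [0,1)")


def ar1_ld(n_variants: int, decay: float) -> np.ndarray:
    """AR(1) correlation matrix r_ij = decay^|i-j| (positive definite)."""
    idx = np.arange(n_variants)
    return decay ** np.abs(idx[:, None] - idx[None, :])


def generate_coloc_region(config: ColocSimConfig,
                          trait1_name: str = "trait1",
                          trait2_name: str = "trait2",
                          chrom: str = "5", start_pos: int = 500_000,
                          id_prefix: str = "rg"):
    """Simulate two regional summary tables over a shared variant panel.

    One causal variant per trait; mean z-scores are the causal z propagated
    through LD, observed z-scores add correlated noise (same LD). Under
    ``shared_causal`` both traits share one causal variant (H4 world),
    otherwise the causal variants sit at opposite ends of the region (H3).

    Returns ``(trait1_df, trait2_df, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    sigma = ar1_ld(m, config.ld_decay)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(m))

    c1 = m // 3
    c2 = c1 if config.shared_causal else (2 * m) // 3
    mean1 = sigma[:, c1] * config.z_strength
    mean2 = sigma[:, c2] * config.z_strength
    z1 = mean1 + chol @ rng.standard_normal(m)
    z2 = mean2 + chol @ rng.standard_normal(m)

    eaf = np.full(m, 0.5)
    se = _gwas_se(config.n_gwas, eaf)
    ids = [f"{id_prefix}{config.seed % 1000:03d}_{j:04d}" for j in range(m)]
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    ea = [p[0] for p in pairs]
    oa = [p[1] for p in pairs]
    pos = [start_pos + 500 * j for j in range(m)]

    df1 = _variant_frame(ids, chrom, pos, ea, oa, eaf, z1 * se, se,
                         config.n_gwas, trait1_name)
    df2 = _variant_frame(ids, chrom, pos, ea, oa, eaf, z2 * se, se,
                         config.n_gwas, trait2_name)
    truth = {
        "shared_causal": config.shared_causal,
        "causal_index_1": int(c1),
        "causal_index_2": int(c2),
        "causal_id_1": ids[c1],
        "causal_id_2": ids[c2],
        "variant_ids": ids,
        "seed": config.seed,
    }
    return df1, df2, truth


def generate_region_traits(n_variants: int, ld_decay: float,
                           traits: Sequence[tuple], n_gwas: dict,
                           seed: int = 0, chrom: str = "5",
                           start_pos: int = 500_000,
                           variant_ids: Optional[Sequence[str]] = None):
    """Simulate several traits over one LD region.

    ``traits`` is a sequence of ``(name, causal_index, causal_beta)``; each
    trait's mean per-variant effect is its causal effect propagated through
    the AR(1) LD, and observed effects add LD-correlated noise scaled by
    the analytic SE for that trait's sample size (``n_gwas[name]``).

    Returns ``(frames, truth)`` with ``frames`` a name -> DataFrame dict.
    """
    rng = np.random.default_rng(seed)
    m = n_variants
    sigma = ar1_ld(m, ld_decay)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(m))
    eaf = np.full(m, 0.5)
    if variant_ids is None:
        variant_ids = [f"rg{seed % 10000:04d}_{j:02d}" for j in range(m)]
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    ea = [p[0] for p in pairs]
    oa = [p[1] for p in pairs]
    pos = [start_pos + 500 * j for j in range(m)]

    frames, truth_traits = {}, {}
    for name, causal_idx, causal_beta in traits:
        n = n_gwas[name]
        se = _gwas_se(n, eaf)
        mean_z = sigma[:, causal_idx] * (causal_beta / se[causal_idx])
        z = mean_z + chol @ rng.standard_normal(m)
        frames[name] = _variant_frame(list(variant_ids), chrom, pos, ea, oa,
                                      eaf, z * se, se, n, name)
        truth_traits[name] = {"causal_index": int(causal_idx),
                              "causal_id": variant_ids[causal_idx],
                              "causal_beta": float(causal_beta)}
    truth = {"variant_ids": list(variant_ids), "traits": truth_traits,
             "ld_decay": ld_decay, "seed": seed}
    return frames, truth


def generate_outcome_from_truth(truth: dict, theta: float, n_outcome: int,
                                seed: int, outcome_name: str,
                                exposure_df: pd.DataFrame) -> pd.DataFrame:
    """Outcome summary statistics for an existing exposure truth record:
    per-variant outcome effect theta*gamma_j (+ sampling noise)."""
    rng = np.random.default_rng(seed)
    gamma = np.asarray(truth["gamma"], dtype=float)
    eaf = np.asarray(truth["eaf"], dtype=float)
    se_out = _gwas_se(n_outcome, eaf)
    beta = theta * gamma + rng.normal(0.0, se_out)
    base = exposure_df.copy()
    return _variant_frame(list(base["SNP"]), list(base["CHR"]), list(base["POS"]),
                         list(base["EA"]), list(base["OA"]), eaf, beta, se_out,
                         n_outcome, outcome_name)


# ---------------------------------------------------------------------------
# Individual-level cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(n: int, weights: Sequence[float], theta: float,
                    binary_outcome: bool = False, seed: int = 0,
                    eaf: Optional[Sequence[float]] = None,
                    prevalence: float = DEFAULT_PREVALENCE,
                    noise_sd: float = 1.0) -> pd.DataFrame:
    """Simulate an individual-level cohort for one-sample / factorial MR.

    exposure = sum_j w_j * dosage_j + noise; continuous outcomes are
    theta*exposure + noise, binary outcomes follow a logistic model with
    the configured baseline prevalence (theta on the log-odds scale).

    Columns: ``IID, G1..Gm, EXPOSURE, OUTCOME``.
    """
    weights = np.asarray(weights, dtype=float)
    if n < 10:
        raise ValidationError("n must be >= 10 (degenerate regression)")
    if not np.all(np.isfinite(weights)):
        raise ValidationError("weights must be finite")
    if not (0.0 < prevalence < 1.0):
        raise ValidationError("prevalence must lie in (0,1)")
    rng = np.random.default_rng(seed)
    m = len(weights)
    if eaf is None:
        eaf = rng.uniform(0.2, 0.8, size=m)
    eaf = np.asarray(eaf, dtype=float)
    dosages = rng.binomial(2, eaf, size=(n, m)).astype(float)
    exposure = dosages @ weights + rng.normal(0.0, noise_sd, size=n)
    if binary_outcome:
        p = expit(logit(prevalence) + theta * exposure)
        outcome = rng.binomial(1, p).astype(float)
    else:
        outcome = theta * exposure + rng.normal(0.0, noise_sd, size=n)
    df = pd.DataFrame(dosages, columns=[f"G{j+1}" for j in range(m)])
    df.insert(0, "IID", [f"id{i:07d}" for i in range(n)])
    df["EXPOSURE"] = exposure
    df["OUTCOME"] = outcome
    return df


# ---------------------------------------------------------------------------
# Whole-study fixture
# ---------------------------------------------------------------------------

TARGET_NAMES = ("AMPK", "MCI", "MG3", "GDF15", "GLP1_GCG")
#: genes per target: 22 genes across the 5 targets, 32 variants overall
GENES_PER_TARGET = (6, 6, 4, 3, 3)
VARIANTS_PER_TARGET = (9, 9, 6, 4, 4)


def default_target_map(seed: int = 0) -> dict:
    """A 5-target / 22-gene / 32-variant labelled mapping fixture."""
    targets = []
    vcount = 0
    for t_idx, (name, n_genes, n_vars) in enumerate(
            zip(TARGET_NAMES, GENES_PER_TARGET, VARIANTS_PER_TARGET)):
        base = [1] * n_genes
        for k in range(n_vars - n_genes):
            base[k % n_genes] += 1
        genes = []
        for g_idx in range(n_genes):
            gene = f"{name}_G{g_idx+1}"
            variants = [f"rsv{vcount + k:04d}" for k in range(base[g_idx])]
            vcount += base[g_idx]
            genes.append({"gene": gene, "variants": variants})
        targets.append({"target_name": name, "genes": genes})
    return {"drug": "drugX", "targets": targets}


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def generate_study(out_dir, seed: int = 0,
                   theta_ad: float = 0.16252, theta_cf: float = -0.09,
                   region_size: int = 40, ld_decay: float = 0.7,
                   n_hba1c: int = 344_182, n_ad: int = 455_258,
                   n_cf: int = 300_486, n_eqtl: int = 31_684,
                   eqtl_z: float = 10.0,
                   confounded_variants: Sequence[str] = (),
                   cohort_n: int = 20_000,
                   n_sens_instruments: int = 99, n_excluded: int = 54,
                   n_t2d_instruments: int = 118) -> dict:
    """Write a complete synthetic study to ``out_dir`` and return a manifest.

    theta values are per 1 SD exposure *increase* (so the default
    ``theta_ad=0.16252`` corresponds to OR 0.85 per SD lowering). One LD
    region per instrument variant: the labelled variant is the shared
    causal variant of gene expression, biomarker and outcomes, except for
    labels in ``confounded_variants`` whose expression signal is moved to a
    distinct variant (an H3 world).

    Files written: target map, regions manifest, regional biomarker /
    eQTL / outcome tables, per-region LD panels, sensitivity instrument
    sets, a cohort with score weights, triangulation inputs, and a
    ``truth.json`` sidecar.
    """
    from .sumstats import LDMatrix  # local import to avoid cycle at module load

    out = Path(out_dir)
    (out / "ld").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    map_dict = default_target_map(seed)
    triples = [(t["target_name"], g["gene"], v)
               for t in map_dict["targets"] for g in t["genes"]
               for v in g["variants"]]

    n_gwas = {"expression": n_eqtl, "hba1c": n_hba1c, "AD": n_ad, "CF": n_cf}
    se_eqtl_causal = _gwas_se(n_eqtl, 0.5)
    c = region_size // 2
    c_alt = max(0, c - 15)  # distant enough that r^2 is negligible

    hba1c_frames, eqtl_frames, ad_frames, cf_frames = [], [], [], []
    manifest_rows, truth_regions = [], {}
    for j, (target, gene, label) in enumerate(triples):
        gamma = float(rng.uniform(0.02, 0.15) * rng.choice([-1.0, 1.0]))
        beta_expr = float(eqtl_z * se_eqtl_causal)
        confounded = label in confounded_variants
        ids = [label if k == c else f"{label}_{k:02d}" for k in range(region_size)]
        traits = [
            ("expression", c_alt if confounded else c, beta_expr),
            ("hba1c", c, gamma),
            ("AD", c, theta_ad * gamma),
            ("CF", c, theta_cf * gamma),
        ]
        frames, rtruth = generate_region_traits(
            region_size, ld_decay, traits, n_gwas, seed=seed * 1000 + j,
            chrom=str(1 + j % 22), start_pos=1_000_000 + 100_000 * j,
            variant_ids=ids)
        frames["expression"]["PHENO"] = gene
        hba1c_frames.append(frames["hba1c"])
        eqtl_frames.append(frames["expression"])
        ad_frames.append(frames["AD"])
        cf_frames.append(frames["CF"])
        LDMatrix(tuple(ids), ar1_ld(region_size, ld_decay)).to_files(
            out / "ld" / f"{label}.ld", out / "ld" / f"{label}.ids")
        manifest_rows.extend(
            {"REGION": label, "TARGET": target, "GENE": gene, "SNP": vid}
            for vid in ids)
        truth_regions[label] = {
            "target": target, "gene": gene, "gamma": gamma,
            "beta_expression": beta_expr, "confounded": confounded,
            "theta_expression_AD": theta_ad * gamma / beta_expr,
            "theta_expression_CF": theta_cf * gamma / beta_expr,
        }

    paths = {
        "target_map": out / "target_map.yaml",
        "regions_manifest": out / "regions.tsv",
        "hba1c_gwas": out / "hba1c_gwas.tsv",
        "eqtl_gwas": out / "eqtl_gwas.tsv",
        "outcome_AD": out / "outcome_AD.tsv",
        "outcome_CF": out / "outcome_CF.tsv",
        "ld_dir": out / "ld",
        "truth": out / "truth.json",
    }
    import yaml as _yaml
    paths["target_map"].write_text(_yaml.safe_dump(map_dict, sort_keys=False))
    pd.DataFrame(manifest_rows).to_csv(paths["regions_manifest"], sep="\t", index=False)
    for key, frames in (("hba1c_gwas", hba1c_frames), ("eqtl_gwas", eqtl_frames),
                        ("outcome_AD", ad_frames), ("outcome_CF", cf_frames)):
        pd.concat(frames, ignore_index=True).to_csv(paths[key], sep="\t",
                                                    index=False, na_rep="NA")

    # --- sensitivity instrument sets: null circulating-biomarker and
    # disease-liability effects on both outcomes
    sens = {}
    for tag, m, n_exp in (("hba1c_wide", n_sens_instruments, n_hba1c),
                          ("t2d_liability", n_t2d_instruments, 200_000)):
        cfg = SimConfig(n_exposure_gwas=n_exp, n_outcome_gwas=n_ad,
                        true_causal_effect=0.0, n_instruments=m,
                        seed=seed * 17 + (3 if tag == "hba1c_wide" else 5))
        exp_df, out_ad, truth_s = generate_two_sample_gwas(cfg, tag, "AD")
        out_cf = generate_outcome_from_truth(truth_s, 0.0, n_cf,
                                             cfg.seed + 1, "CF", exp_df)
        p_exp = out / f"sens_{tag}.tsv"
        p_ad = out / f"sens_{tag}_AD.tsv"
        p_cf = out / f"sens_{tag}_CF.tsv"
        exp_df.to_csv(p_exp, sep="\t", index=False, na_rep="NA")
        out_ad.to_csv(p_ad, sep="\t", index=False, na_rep="NA")
        out_cf.to_csv(p_cf, sep="\t", index=False, na_rep="NA")
        sens[tag] = {"exposure": p_exp, "AD": p_ad, "CF": p_cf,
                     "variant_ids": truth_s["variant_ids"]}
    exclusion = sens["hba1c_wide"]["variant_ids"][:n_excluded]
    paths["exclusion_list"] = out / "exclusion_erythrocyte.txt"
    paths["exclusion_list"].write_text("\n".join(exclusion) + "\n")
    paths["sensitivity"] = sens

    # --- individual-level cohort + score weights (weights = per-allele
    # biomarker effects of the 32 instruments, in map order)
    gammas = np.array([truth_regions[label]["gamma"] for _, _, label in triples])
    cohort = generate_cohort(cohort_n, gammas * 5.0, theta_cf, seed=seed * 31 + 7)
    paths["cohort"] = out / "cohort.tsv"
    cohort.to_csv(paths["cohort"], sep="\t", index=False, float_format="%.6g")
    weight_rows = []
    for k, (target, gene, label) in enumerate(triples):
        col = f"G{k+1}"
        for score, keep in (("ALL", True), ("MCI", target == "MCI"),
                            ("AMPK", target == "AMPK")):
            if keep:
                weight_rows.append({"SCORE": score, "COLUMN": col,
                                    "SNP": label, "WEIGHT": gammas[k] * 5.0})
    paths["score_weights"] = out / "score_weights.tsv"
    pd.DataFrame(weight_rows).to_csv(paths["score_weights"], sep="\t", index=False)

    # --- triangulation inputs (synthetic observational + MR-style entries
    # on a common per-SD-lowering scale)
    tri_rng = np.random.default_rng(seed * 13 + 11)
    tri = pd.DataFrame([
        {"source": "observational_meta", "beta": -theta_cf + tri_rng.normal(0, 0.03),
         "se": 0.04, "scale": "sd"},
        {"source": "one_sample_mr", "beta": -theta_cf + tri_rng.normal(0, 0.03),
         "se": 0.035, "scale": "sd"},
        {"source": "two_sample_mr", "beta": -theta_cf + tri_rng.normal(0, 0.03),
         "se": 0.036, "scale": "sd"},
    ])
    paths["triangulation"] = out / "triangulation_inputs.tsv"
    tri.to_csv(paths["triangulation"], sep="\t", index=False)

    truth = {
        "seed": seed,
        "theta": {"AD": theta_ad, "CF": theta_cf},
        "cohort_theta": theta_cf,
        "confounded_variants": list(confounded_variants),
        "regions": truth_regions,
        "n_gwas": n_gwas,
    }
    write_truth(truth, paths["truth"])
    paths["truth_record"] = truth
    return paths
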