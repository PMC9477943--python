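"""Configuration-driven orchestration: instruments -> coloc -> per-target MR
-> pooled general effect -> candidate-gene MR -> sensitivity suite.

A run is fully described by a YAML config (paths + thresholds + seed); every
report carries a manifest with the seed and SHA-256 of each input so that
results are reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import coloc as coloc_mod
from . import drug_effect, estimators, instruments as instr_mod
from .instruments import TargetGeneMap, merge_instrument_sets, select_instruments
from .sumstats import (LDMatrix, SchemaError, ValidationError, harmonise_pairs,
                       read_sumstats)

log = logging.getLogger(__name__)


class ConfigError(ValidationError):
    """The run configuration is invalid or references missing files."""


_DEFAULT_THRESHOLDS = {
    "coloc": 0.70,
    "proxy_r2": 0.8,
    "prune_r2": 0.001,
    "instrument_p": 5e-8,
    "f_warn": 10.0,
    "alpha": 0.05,
}

_DEFAULT_SCALING = {
    "sd_native": drug_effect.DEFAULT_SD_MMOL_PER_MOL,
    "sd_percent": drug_effect.DEFAULT_SD_PERCENT,
}


@dataclass
class RunConfig:
    seed: int
    base_dir: Path
    target_map: Path
    regions_manifest: Path
    hba1c_gwas: Path
    eqtl_gwas: Path
    ld_dir: Path
    outcomes: list                       # [{name, path, binary}]
    sensitivity: list = field(default_factory=list)
    cohort: Optional[Path] = None
    score_weights: Optional[Path] = None
    triangulation: Optional[Path] = None
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    scaling: dict = field(default_factory=lambda: dict(_DEFAULT_SCALING))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        base = path.parent

        def p(key, required=True):
            v = raw.get(key)
            if v is None:
                if required:
                    raise ConfigError(f"config key {key!r} is required")
                return None
            q = (base / v).resolve() if not Path(v).is_absolute() else Path(v)
            if not q.exists():
                raise ConfigError(f"{key}: path does not exist: {q}")
            return q

        outcomes = raw.get("outcomes") or []
        if not outcomes:
            raise ConfigError("config must declare at least one outcome")
        resolved_outcomes = []
        for o in outcomes:
            op = (base / o["path"]).resolve()
            if not op.exists():
                raise ConfigError(f"outcome {o.get('name')}: missing file {op}")
            resolved_outcomes.append({"name": o["name"], "path": op,
                                      "binary": bool(o.get("binary", False))})

        sens = []
        for s in raw.get("sensitivity") or []:
            entry = {"name": s["name"],
                     "exposure": (base / s["exposure"]).resolve(),
                     "outcomes": [], "exclusion_list": None}
            if not entry["exposure"].exists():
                raise ConfigError(f"sensitivity {s['name']}: missing exposure file")
            for o in s.get("outcomes", []):
                op = (base / o["path"]).resolve()
                if not op.exists():
                    raise ConfigError(f"sensitivity outcome file missing: {op}")
                entry["outcomes"].append({"name": o["name"], "path": op,
                                          "binary": bool(o.get("binary", False))})
            if s.get("exclusion_list"):
                ep = (base / s["exclusion_list"]).resolve()
                if not ep.exists():
                    raise ConfigError(f"exclusion list missing: {ep}")
                entry["exclusion_list"] = ep
            sens.append(entry)

        thresholds = dict(_DEFAULT_THRESHOLDS)
        thresholds.update(raw.get("thresholds") or {})
        _validate_thresholds(thresholds)
        scaling = dict(_DEFAULT_SCALING)
        scaling.update(raw.get("scaling") or {})

        return cls(
            seed=int(raw.get("seed", 0)),
            base_dir=base,
            target_map=p("target_map"),
            regions_manifest=p("regions_manifest"),
            hba1c_gwas=p("hba1c_gwas"),
            eqtl_gwas=p("eqtl_gwas"),
            ld_dir=p("ld_dir"),
            outcomes=resolved_outcomes,
            sensitivity=sens,
            cohort=p("cohort", required=False),
            score_weights=p("score_weights", required=False),
            triangulation=p("triangulation", required=False),
            thresholds=thresholds,
            scaling=scaling,
        )


def _validate_thresholds(t: dict) -> None:
    if not (0.0 < t["coloc"] <= 1.0):
        raise ConfigError("coloc threshold must lie in (0,1]")
    if not (0.0 < t["proxy_r2"] <= 1.0):
        raise ConfigError("proxy_r2 must lie in (0,1]")
    if not (0.0 < t["prune_r2"] <= 1.0):
        raise ConfigError("prune_r2 must lie in (0,1]")
    if not (0.0 < t["alpha"] < 1.0):
        raise ConfigError("alpha must lie in (0,1)")


def write_config_yaml(paths: dict, out_path) -> Path:
    """Write a RunConfig YAML pointing at a generate_study manifest."""
    out_path = Path(out_path)
    base = out_path.parent

    def rel(p):
        return str(Path(p).resolve().relative_to(base.resolve()))

    cfg = {
        "seed": paths["truth_record"]["seed"],
        "target_map": rel(paths["target_map"]),
        "regions_manifest": rel(paths["regions_manifest"]),
        "hba1c_gwas": rel(paths["hba1c_gwas"]),
        "eqtl_gwas": rel(paths["eqtl_gwas"]),
        "ld_dir": rel(paths["ld_dir"]),
        "outcomes": [
            {"name": "AD", "path": rel(paths["outcome_AD"]), "binary": True},
            {"name": "CF", "path": rel(paths["outcome_CF"]), "binary": False},
        ],
        "sensitivity": [
            {
                "name": tag,
                "exposure": rel(info["exposure"]),
                "outcomes": [
                    {"name": "AD", "path": rel(info["AD"]), "binary": True},
                    {"name": "CF", "path": rel(info["CF"]), "binary": False},
                ],
                **({"exclusion_list": rel(paths["exclusion_list"])}
                   if tag == "hba1c_wide" else {}),
            }
            for tag, info in paths["sensitivity"].items()
        ],
        "cohort": rel(paths["cohort"]),
        "score_weights": rel(paths["score_weights"]),
        "triangulation": rel(paths["triangulation"]),
    }
    out_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return out_path


# ---------------------------------------------------------------------------
# Shared loading helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _manifest(config: RunConfig, extra_paths=()) -> dict:
    files = [config.target_map, config.regions_manifest, config.hba1c_gwas,
             config.eqtl_gwas, *[o["path"] for o in config.outcomes],
             *extra_paths]
    return {
        "package": "targetmr",
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds,
        "inputs": {str(Path(f).name): _sha256(f) for f in files},
    }


@dataclass
class _StudyData:
    target_map: TargetGeneMap
    regions: pd.DataFrame                 # REGION, TARGET, GENE, SNP
    hba1c_by_region: dict
    eqtl_by_region: dict
    ld_by_region: dict
    outcome_records: dict                 # outcome name -> records
    combined_ld: Optional[LDMatrix]


def _group_by_region(records, region_of: dict) -> dict:
    grouped: dict = {}
    for r in records:
        reg = region_of.get(r.variant_id)
        if reg is not None:
            grouped.setdefault(reg, []).append(r)
    return grouped


def load_study(config: RunConfig) -> _StudyData:
    tmap = TargetGeneMap.from_file(config.target_map)
    regions = pd.read_csv(config.regions_manifest, sep="\t")
    region_of = dict(zip(regions["SNP"], regions["REGION"]))

    hba1c, _ = read_sumstats(config.hba1c_gwas)
    eqtl, _ = read_sumstats(config.eqtl_gwas)
    outcome_records = {}
    for o in config.outcomes:
        recs, _ = read_sumstats(o["path"])
        outcome_records[o["name"]] = recs

    ld_by_region = {}
    blocks, ids = [], []
    for region in regions["REGION"].unique():
        mat = config.ld_dir / f"{region}.ld"
        idf = config.ld_dir / f"{region}.ids"
        if mat.exists() and idf.exists():
            ld = LDMatrix.from_files(mat, idf)
            ld_by_region[region] = ld
            blocks.append(ld.r)
            ids.extend(ld.variant_ids)
    combined = None
    if blocks:
        n = sum(b.shape[0] for b in blocks)
        big = np.zeros((n, n))
        ofs = 0
        for b in blocks:
            k = b.shape[0]
            big[ofs:ofs + k, ofs:ofs + k] = b
            ofs += k
        np.fill_diagonal(big, 1.0)
        combined = LDMatrix(tuple(ids), big)

    return _StudyData(
        target_map=tmap, regions=regions,
        hba1c_by_region=_group_by_region(hba1c, region_of),
        eqtl_by_region=_group_by_region(eqtl, region_of),
        ld_by_region=ld_by_region,
        outcome_records=outcome_records,
        combined_ld=combined,
    )


# ---------------------------------------------------------------------------
# Main analysis
# ---------------------------------------------------------------------------

def build_target_instruments(data: _StudyData, config: RunConfig) -> dict:
    """Per-target instrument sets via per-region selection + union."""
    t = config.thresholds
    sets = {}
    for target in data.target_map.targets:
        per_region = []
        for region in data.regions[data.regions["TARGET"] == target.target_name][
                "REGION"].unique():
            eqtls = data.eqtl_by_region.get(region, [])
            bio = data.hba1c_by_region.get(region, [])
            if not eqtls or not bio:
                continue
            gene = data.regions.loc[data.regions["REGION"] == region, "GENE"].iloc[0]
            try:
                per_region.append(select_instruments(
                    eqtls, bio, ld=data.ld_by_region.get(region),
                    coloc_threshold=t["coloc"], prune_r2=t["prune_r2"],
                    target_name=target.target_name, gene=gene,
                    pval_max=t["instrument_p"],
                    biomarker_trait_type="quantitative"))
            except ValidationError as exc:
                log.warning("target %s region %s: %s",
                            target.target_name, region, exc)
        sets[target.target_name] = merge_instrument_sets(
            target.target_name, per_region)
    return sets


def run_main_analysis(config: RunConfig, out_dir) -> dict:
    """Full main analysis: instrument selection with coloc validation,
    per-target MR against each outcome, pooled general effect, Bonferroni
    over the declared outcome count. Writes ``report.json`` and
    ``forest.tsv``; per-target failures are recorded, not fatal."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = load_study(config)
    t = config.thresholds
    target_sets = build_target_instruments(data, config)

    n_tests = len(config.outcomes)
    alpha_corrected = drug_effect.bonferroni(t["alpha"], n_tests)

    target_rows, pooled_rows = [], []
    for o in config.outcomes:
        effects = []
        for target in data.target_map.targets:
            iset = target_sets[target.target_name]
            try:
                eff = drug_effect.estimate_target_effect(
                    iset, data.outcome_records[o["name"]],
                    ld=data.combined_ld, proxy_r2=t["proxy_r2"],
                    outcome_name=o["name"], seed=config.seed)
            except ValidationError as exc:
                log.warning("target %s / outcome %s failed: %s",
                            target.target_name, o["name"], exc)
                eff = drug_effect.TargetEffect(
                    target_name=target.target_name, outcome_name=o["name"],
                    estimate=None, instrument_count=0, min_f=float("nan"),
                    usable=False, warnings=(str(exc),))
            effects.append(eff)
            row = {
                "target": eff.target_name, "outcome": o["name"],
                "usable": eff.usable, "n_snps": eff.instrument_count,
                "min_F": None if np.isnan(eff.min_f) else eff.min_f,
                "warnings": list(eff.warnings),
            }
            if eff.estimate is not None:
                e = eff.estimate
                row.update(beta=e.beta, se=e.se, ci_low=e.ci_low,
                           ci_high=e.ci_high, pval=e.pval,
                           q_stat=e.q_stat, q_pval=e.q_pval,
                           significant=bool(e.pval < alpha_corrected))
                if o["binary"]:
                    sc = drug_effect.scale_to_or(
                        e.beta, e.se, direction="lowering",
                        sd_native=config.scaling["sd_native"],
                        sd_percent=config.scaling["sd_percent"])
                    row.update(or_per_sd_lowering=sc.or_, or_ci_low=sc.ci_low,
                               or_ci_high=sc.ci_high,
                               percent_change=sc.percent_change)
                row["sensitivity"] = {k: v.to_dict()
                                      for k, v in eff.sensitivity.items()}
            target_rows.append(row)

        try:
            pooled = drug_effect.pool_general_effect(effects, outcome_name=o["name"])
            m = pooled.meta
            prow = {
                "outcome": o["name"], "included_targets": list(pooled.included_targets),
                "fixed_beta": m.fixed_beta, "fixed_se": m.fixed_se,
                "fixed_p": m.fixed_p, "random_beta": m.random_beta,
                "random_se": m.random_se, "random_p": m.random_p,
                "cross_target_q": m.q_stat, "cross_target_q_df": m.q_df,
                "cross_target_q_p": m.q_pval,
                "significant": bool(m.fixed_p < alpha_corrected),
                "warnings": list(pooled.warnings),
            }
            if o["binary"]:
                sc = drug_effect.scale_to_or(
                    m.fixed_beta, m.fixed_se, direction="lowering",
                    sd_native=config.scaling["sd_native"],
                    sd_percent=config.scaling["sd_percent"])
                prow.update(or_per_sd_lowering=sc.or_, or_ci_low=sc.ci_low,
                            or_ci_high=sc.ci_high,
                            percent_change=sc.percent_change)
            pooled_rows.append(prow)
        except ValidationError as exc:
            pooled_rows.append({"outcome": o["name"], "error": str(exc)})

    report = {
        "analysis": "main",
        "n_tests": n_tests,
        "alpha": t["alpha"],
        "alpha_corrected": alpha_corrected,
        "targets": target_rows,
        "pooled": pooled_rows,
        "instrument_sets": {
            name: json.loads(s.to_frame().to_json(orient="records"))
            for name, s in target_sets.items()
        },
        "manifest": _manifest(config),
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n")

    forest = pd.DataFrame([
        {"label": r["target"], "outcome": r["outcome"],
         "beta": r.get("beta"), "se": r.get("se"),
         "ci_low": r.get("ci_low"), "ci_high": r.get("ci_high"),
         "pval": r.get("pval"), "n_snps": r["n_snps"],
         "or": r.get("or_per_sd_lowering")}
        for r in target_rows
    ] + [
        {"label": "general_effect", "outcome": r["outcome"],
         "beta": r.get("fixed_beta"), "se": r.get("fixed_se"),
         "pval": r.get("fixed_p"), "or": r.get("or_per_sd_lowering")}
        for r in pooled_rows
    ])
    forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False)
    return report


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# Candidate-gene analysis
# ---------------------------------------------------------------------------

def run_candidate_gene_analysis(config: RunConfig, out_dir) -> pd.DataFrame:
    """Per-gene MR of expression on each outcome: lowest-p pruned eQTL
    instruments, Wald/IVW estimate, coloc verdict versus the outcome, and
    Bonferroni over the tests actually run. Genes without usable eQTLs are
    listed as untested."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = load_study(config)
    t = config.thresholds

    rows = []
    n_tests = 0
    for gene in data.target_map.all_genes:
        gene_regions = data.regions[data.regions["GENE"] == gene]["REGION"].unique()
        for o in config.outcomes:
            out_by_id = {r.variant_id: r for r in data.outcome_records[o["name"]]}
            insts, pp4s = [], []
            for region in gene_regions:
                eqtls = data.eqtl_by_region.get(region, [])
                eqtls = [r for r in eqtls if r.pval <= t["instrument_p"]]
                if not eqtls:
                    continue
                ld = data.ld_by_region.get(region)
                pruned = (instr_mod.ld_prune(eqtls, ld, t["prune_r2"])
                          if ld is not None else
                          sorted(eqtls, key=lambda r: (r.pval, r.chrom, r.pos)))
                top = pruned[0]
                out_rec = out_by_id.get(top.variant_id)
                if out_rec is None:
                    continue
                h = harmonise_pairs([top], [out_rec])[0]
                if h:
                    insts.extend(h)
                # regional coloc: expression vs outcome
                region_eqtls = data.eqtl_by_region.get(region, [])
                region_out = [out_by_id[r.variant_id] for r in region_eqtls
                              if r.variant_id in out_by_id]
                if len(region_out) >= 2:
                    t1 = coloc_mod.RegionalAssoc.from_associations(region_eqtls)
                    t2 = coloc_mod.RegionalAssoc.from_associations(
                        region_out,
                        "case_control" if o["binary"] else "quantitative")
                    res = coloc_mod.colocalise(t1, t2, threshold=t["coloc"])
                    pp4s.append(res.pp4)
            if not insts:
                rows.append({"gene": gene, "outcome": o["name"],
                             "tested": False, "reason": "no usable eQTL instrument"})
                continue
            est = (estimators.wald_ratio(insts[0]) if len(insts) == 1
                   else estimators.ivw(insts, model="fixed"))
            best_pp4 = max(pp4s) if pp4s else None
            verdict = ("colocalised" if best_pp4 is not None
                       and best_pp4 >= t["coloc"] else "not colocalised")
            n_tests += 1
            rows.append({
                "gene": gene, "outcome": o["name"], "tested": True,
                "method": est.method, "beta": est.beta, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
                "n_snps": est.n_snps, "pp4": best_pp4, "coloc_verdict": verdict,
            })

    alpha_corrected = (drug_effect.bonferroni(t["alpha"], n_tests)
                       if n_tests else None)
    for r in rows:
        if r.get("tested"):
            r["significant"] = bool(r["pval"] < alpha_corrected)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    report = {"analysis": "candidate_genes", "n_tests": n_tests,
              "alpha_corrected": alpha_corrected, "genes": rows,
              "manifest": _manifest(config)}
    (out_dir / "genes.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n")
    if n_tests == 0:
        log.warning("candidate-gene analysis: no genes were testable")
    return df


# ---------------------------------------------------------------------------
# Sensitivity suite
# ---------------------------------------------------------------------------

def _estimator_suite(insts, seed):
    out = {}
    if len(insts) == 1:
        out["wald_ratio"] = estimators.wald_ratio(insts[0])
        return out
    out["ivw_fixed"] = estimators.ivw(insts, model="fixed")
    out["ivw_random"] = estimators.ivw(insts, model="random")
    if len(insts) >= 3:
        out["egger"] = estimators.egger(insts)
        out["weighted_median"] = estimators.weighted_median(insts, seed=seed)
        out["weighted_mode"] = estimators.weighted_mode(insts, seed=seed)
    return out


def run_sensitivity_suite(config: RunConfig, out_dir) -> pd.DataFrame:
    """Run the estimator suite over each configured sensitivity instrument
    set (full set, plus the set after applying the exclusion list) against
    each outcome; instrument counts surviving each filter are reported."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not config.sensitivity:
        raise ConfigError("no sensitivity datasets configured")

    rows = []
    for entry in config.sensitivity:
        exposure, _ = read_sumstats(entry["exposure"])
        variants = {r.variant_id for r in exposure}
        sets = {"all": exposure}
        if entry["exclusion_list"] is not None:
            excluded = {line.strip()
                        for line in Path(entry["exclusion_list"]).read_text().splitlines()
                        if line.strip()}
            absent = excluded - variants
            if absent:
                log.warning("%s: %d excluded ids absent from exposure",
                            entry["name"], len(absent))
            sets["filtered"] = [r for r in exposure
                                if r.variant_id not in excluded]
        for o in entry["outcomes"]:
            out_recs, _ = read_sumstats(o["path"])
            for set_name, exp_records in sets.items():
                insts, _rej = harmonise_pairs(exp_records, out_recs)
                if not insts:
                    continue
                for method, est in _estimator_suite(insts, config.seed).items():
                    rows.append({
                        "analysis": entry["name"], "set": set_name,
                        "outcome": o["name"], "n_exposure": len(exp_records),
                        "n_instruments": len(insts), "method": method,
                        "beta": est.beta, "se": est.se,
                        "ci_low": est.ci_low, "ci_high": est.ci_high,
                        "pval": est.pval,
                        "egger_intercept": est.egger_intercept,
                        "egger_intercept_p": est.egger_intercept_p,
                    })
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "sensitivity.tsv", sep="\t", index=False)
    return df
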