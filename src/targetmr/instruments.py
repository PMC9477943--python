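"""Instrument construction for drug targets: selection, strength, coloc filter.

An instrument proxies a target through a gene: its eQTL signal must share a
causal variant with the glycaemic biomarker (colocalisation filter), and its
strength is summarised by the variance explained (R^2) and F statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from .sumstats import (HarmonisedInstrument, LDMatrix, ValidationError,
                       VariantAssociation, harmonise, ld_prune)

F_WEAK_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# Strength statistics
# ---------------------------------------------------------------------------

def variance_explained(beta: float, eaf: float, se: Optional[float] = None,
                       n: Optional[int] = None) -> float:
    """Variance in a unit-variance exposure explained by one variant:
    R^2 = 2*eaf*(1-eaf)*beta^2, clipped to [0, 1)."""
    if not (0.0 < eaf < 1.0):
        raise ValidationError("eaf must lie in (0,1)")
    if not np.isfinite(beta):
        raise ValidationError("beta must be finite")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    return float(min(r2, np.nextafter(1.0, 0.0)))


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """F = (r2/k) * (n-k-1)/(1-r2). Values above 10 indicate adequate
    instrument strength."""
    if not (0.0 <= r2 < 1.0):
        raise ValidationError("r2 must lie in [0,1)")
    if n <= k + 1:
        raise ValidationError("need n > k+1")
    return float((r2 / k) * (n - k - 1) / (1.0 - r2))


def f_from_beta_se(beta: float, se: float) -> float:
    """Single-variant approximation F ~ (beta/se)^2."""
    if se <= 0:
        raise ValidationError("se must be positive")
    return float((beta / se) ** 2)


# ---------------------------------------------------------------------------
# Target / gene / variant mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneEntry:
    gene: str
    variants: tuple


@dataclass(frozen=True)
class TargetEntry:
    target_name: str
    genes: tuple  # of GeneEntry


@dataclass(frozen=True)
class TargetGeneMap:
    """drug -> targets -> genes -> instrument variants."""

    drug: str
    targets: tuple  # of TargetEntry

    def __post_init__(self):
        names = [t.target_name for t in self.targets]
        if len(names) != len(set(names)):
            raise ValidationError("target names must be unique")
        gene_owner: dict = {}
        variant_owner: dict = {}
        for t in self.targets:
            for g in t.genes:
                if g.gene in gene_owner:
                    raise ValidationError(f"gene {g.gene} maps to multiple targets")
                gene_owner[g.gene] = t.target_name
                for v in g.variants:
                    if v in variant_owner:
                        raise ValidationError(f"variant {v} maps to multiple genes")
                    variant_owner[v] = g.gene

    @property
    def all_variants(self) -> list:
        return [v for t in self.targets for g in t.genes for v in g.variants]

    @property
    def all_genes(self) -> list:
        return [g.gene for t in self.targets for g in t.genes]

    def genes_of(self, target_name: str):
        for t in self.targets:
            if t.target_name == target_name:
                return list(t.genes)
        raise KeyError(target_name)

    @classmethod
    def from_dict(cls, d: dict) -> "TargetGeneMap":
        targets = tuple(
            TargetEntry(
                target_name=t["target_name"],
                genes=tuple(GeneEntry(gene=g["gene"], variants=tuple(g["variants"]))
                            for g in t["genes"]),
            )
            for t in d["targets"]
        )
        return cls(drug=d.get("drug", ""), targets=targets)

    @classmethod
    def from_file(cls, path) -> "TargetGeneMap":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "targets": [
                {"target_name": t.target_name,
                 "genes": [{"gene": g.gene, "variants": list(g.variants)}
                           for g in t.genes]}
                for t in self.targets
            ],
        }


# ---------------------------------------------------------------------------
# Instrument sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Instrument:
    """One validated instrument: aligned expression/biomarker pair plus the
    biomarker-side association used as the MR exposure downstream."""

    harmonised: HarmonisedInstrument          # gene expression -> biomarker
    exposure_assoc: VariantAssociation        # biomarker association
    gene: str
    r2_explained: float
    f_stat: float
    coloc_pass: bool
    coloc_pp4: Optional[float] = None

    @property
    def variant_id(self) -> str:
        return self.harmonised.variant_id


@dataclass(frozen=True)
class InstrumentSet:
    target_name: str
    instruments: tuple  # of Instrument
    warnings: tuple = field(default_factory=tuple)

    @property
    def usable(self) -> bool:
        return any(i.coloc_pass for i in self.instruments)

    @property
    def passing(self) -> tuple:
        return tuple(i for i in self.instruments if i.coloc_pass)

    @property
    def min_f(self) -> float:
        if not self.instruments:
            return float("nan")
        return min(i.f_stat for i in self.instruments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "target": self.target_name, "gene": i.gene,
                "variant_id": i.variant_id,
                "beta_exposure": i.exposure_assoc.beta,
                "se_exposure": i.exposure_assoc.se,
                "r2": i.r2_explained, "F": i.f_stat,
                "coloc_pass": i.coloc_pass, "pp4": i.coloc_pp4,
            }
            for i in self.instruments
        ])


def select_instruments(gene_eqtls: Sequence[VariantAssociation],
                       biomarker_gwas: Sequence[VariantAssociation],
                       ld: Optional[LDMatrix] = None,
                       coloc_threshold: float = 0.70,
                       prune_r2: float = 0.001,
                       target_name: str = "",
                       gene: str = "",
                       pval_max: float = 5e-8,
                       eqtl_trait_type: str = "quantitative",
                       biomarker_trait_type: str = "quantitative") -> InstrumentSet:
    """Build a target's instrument set from one gene region.

    Pipeline: restrict to eQTLs below ``pval_max``, LD-prune them (lowest p
    wins), harmonise each retained eQTL against the biomarker, run regional
    colocalisation between the two traits (full panel), and attach strength
    statistics from the biomarker side. Instruments in a non-colocalised
    region are kept with ``coloc_pass=False`` and excluded from default
    estimation.
    """
    bio_by_id = {r.variant_id: r for r in biomarker_gwas}
    overlap = [r for r in gene_eqtls if r.variant_id in bio_by_id]
    if not overlap:
        raise ValidationError(
            f"no variant overlap between eQTLs and biomarker GWAS for "
            f"{gene or target_name or 'region'}")

    candidates = [r for r in overlap if r.pval <= pval_max] or overlap
    pruned = (ld_prune(candidates, ld, r2_max=prune_r2)
              if ld is not None else list(candidates))

    # Regional coloc over the full shared panel (single verdict per region).
    pp4 = None
    coloc_ok = True
    if len(overlap) >= 2:
        t1 = coloc_mod.RegionalAssoc.from_associations(gene_eqtls, eqtl_trait_type)
        t2 = coloc_mod.RegionalAssoc.from_associations(
            [bio_by_id[r.variant_id] for r in gene_eqtls if r.variant_id in bio_by_id],
            biomarker_trait_type)
        res = coloc_mod.colocalise(t1, t2, threshold=coloc_threshold)
        pp4 = res.pp4
        coloc_ok = res.colocalised

    warnings = []
    instruments = []
    for rec in pruned:
        bio = bio_by_id[rec.variant_id]
        h = harmonise(rec, bio)
        if not isinstance(h, HarmonisedInstrument):
            warnings.append(f"{rec.variant_id}: {h.reason}")
            continue
        if bio.eaf is not None:
            r2 = variance_explained(bio.beta, bio.eaf)
            f = (f_statistic(r2, bio.n) if bio.n is not None and bio.n > 2
                 else f_from_beta_se(bio.beta, bio.se))
        else:
            f = f_from_beta_se(bio.beta, bio.se)
            r2 = float("nan")
        instruments.append(Instrument(
            harmonised=h, exposure_assoc=bio, gene=gene or rec.phenotype,
            r2_explained=r2, f_stat=f, coloc_pass=coloc_ok, coloc_pp4=pp4,
        ))

    iset = InstrumentSet(target_name=target_name, instruments=tuple(instruments),
                         warnings=tuple(warnings))
    if instruments and iset.min_f < F_WEAK_THRESHOLD:
        iset = InstrumentSet(
            target_name=target_name, instruments=tuple(instruments),
            warnings=tuple(warnings) + ("weak instruments: min F below 10",))
    return iset


def merge_instrument_sets(target_name: str,
                          sets: Sequence[InstrumentSet]) -> InstrumentSet:
    """Union per-gene instrument sets into one per-target set; a variant
    passing coloc in any gene/tissue set passes overall."""
    by_id: dict = {}
    warnings: list = []
    for s in sets:
        warnings.extend(s.warnings)
        for inst in s.instruments:
            prev = by_id.get(inst.variant_id)
            if prev is None or (inst.coloc_pass and not prev.coloc_pass):
                by_id[inst.variant_id] = inst
    return InstrumentSet(target_name=target_name,
                         instruments=tuple(by_id.values()),
                         warnings=tuple(dict.fromkeys(warnings)))
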