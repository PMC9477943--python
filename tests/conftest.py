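import numpy as np
import pytest

from targetmr.sumstats import HarmonisedInstrument, VariantAssociation, two_sided_p


def make_inst(variant_id="rs1", be=0.1, se_e=0.01, bo=0.02, se_o=0.01,
              eaf=0.3) -> HarmonisedInstrument:
    return HarmonisedInstrument(
        variant_id=variant_id, effect_allele="A",
        beta_exposure=be, se_exposure=se_e,
        beta_outcome=bo, se_outcome=se_o, eaf=eaf)


def make_insts(be, bo, se_o, se_e=None):
    be = np.asarray(be, dtype=float)
    bo = np.asarray(bo, dtype=float)
    se_o = np.asarray(se_o, dtype=float)
    se_e = np.full_like(be, 1e-4) if se_e is None else np.asarray(se_e, dtype=float)
    return [make_inst(f"rs{j}", be[j], se_e[j], bo[j], se_o[j])
            for j in range(len(be))]


def make_assoc(variant_id="rs1", chrom="1", pos=100, ea="A", oa="G",
               eaf=0.3, beta=0.1, se=0.01, pval=None, n=10_000,
               phenotype="x") -> VariantAssociation:
    if pval is None:
        pval = two_sided_p(beta / se)
    return VariantAssociation(variant_id=variant_id, chrom=chrom, pos=pos,
                              effect_allele=ea, other_allele=oa, eaf=eaf,
                              beta=beta, se=se, pval=pval, n=n,
                              phenotype=phenotype)


def insts_from_frames(exposure_df, outcome_df):
    """Fast path from simulate frames to harmonised instruments (panels are
    generated pre-aligned)."""
    return [
        HarmonisedInstrument(
            variant_id=s, effect_allele=ea,
            beta_exposure=be, se_exposure=se_e,
            beta_outcome=bo, se_outcome=se_o, eaf=eaf)
        for s, ea, be, se_e, bo, se_o, eaf in zip(
            exposure_df["SNP"], exposure_df["EA"],
            exposure_df["BETA"], exposure_df["SE"],
            outcome_df["BETA"], outcome_df["SE"], exposure_df["EAF"])
    ]


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """One small synthetic study shared by pipeline/CLI tests."""
    from targetmr.simulate import generate_study
    from targetmr.pipeline import write_config_yaml

    d = tmp_path_factory.mktemp("study")
    # rsv0006 is the sole variant of a single-region gene (AMPK_G4), so the
    # whole gene is an H3 world in the candidate-gene analysis
    paths = generate_study(d, seed=3, cohort_n=4000,
                           confounded_variants=["rsv0006"])
    write_config_yaml(paths, d / "config.yaml")
    return d
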