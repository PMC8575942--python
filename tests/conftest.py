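"""Shared fixtures: small deterministic instrument sets and synthetic studies."""

import numpy as np
import pandas as pd
import pytest

import tsmr
from tsmr import (
    ExposureSpec,
    HarmonisedSet,
    OutcomeSpec,
    SyntheticTruth,
    generate_study,
    harmonise,
)


@pytest.fixture
def five_snp_hset() -> HarmonisedSet:
    """Fixed 5-SNP single-exposure set for closed-form oracle checks."""
    return HarmonisedSet(
        variant_ids=[f"rs{i}" for i in range(1, 6)],
        exposure_names=["X"],
        exposure_betas=np.array([[0.05], [0.08], [0.03], [0.10], [0.06]]),
        exposure_ses=np.array([[0.004], [0.005], [0.003], [0.006], [0.004]]),
        outcome_betas=np.array([0.021, 0.044, 0.012, 0.055, 0.028]),
        outcome_ses=np.array([0.006, 0.007, 0.005, 0.008, 0.006]),
        eafs=np.array([0.3, 0.5, 0.2, 0.7, 0.4]),
        outcome_name="Y",
    )


@pytest.fixture
def five_snp_mv_hset() -> HarmonisedSet:
    """Fixed 5-SNP two-exposure set for multivariable oracle checks."""
    return HarmonisedSet(
        variant_ids=[f"rs{i}" for i in range(1, 6)],
        exposure_names=["X1", "X2"],
        exposure_betas=np.array(
            [[0.05, 0.02], [0.08, 0.05], [0.03, 0.06], [0.10, 0.01], [0.06, 0.04]]
        ),
        exposure_ses=np.full((5, 2), 0.004),
        outcome_betas=np.array([0.030, 0.055, 0.031, 0.052, 0.040]),
        outcome_ses=np.array([0.006, 0.007, 0.005, 0.008, 0.006]),
        eafs=np.array([0.3, 0.5, 0.2, 0.7, 0.4]),
        outcome_name="Y",
    )


def plain_truth(**overrides) -> SyntheticTruth:
    """Study conditions without harmonisation obstacles: no LD satellites,
    palindromes, missing variants or null background, so every causal SNP
    is usable directly as an instrument."""
    base = dict(
        n_null_snps=0,
        ld_block_size=1,
        palindrome_fraction=0.0,
        missing_outcome_fraction=0.0,
        annotation_fraction=0.0,
    )
    base.update(overrides)
    return SyntheticTruth(**base)


def uni_truth(theta: float = 0.0, **overrides) -> SyntheticTruth:
    """Single-exposure, single continuous-outcome conditions, so the
    univariable Wald ratios are homogeneous apart from sampling noise."""
    base = dict(
        exposures=(ExposureSpec("X", r2_target=0.03, trait_sd=20.1, n=500_000),),
        outcomes=(
            OutcomeSpec("Y", causal_effects=(theta,), trait_type="continuous",
                        n=400_000, case_fraction=None),
        ),
    )
    base.update(overrides)
    return plain_truth(**base)


def quick_hset(truth: SyntheticTruth, outcome: str = "CVD"):
    """Generate a study and harmonise all causal SNPs against one outcome."""
    study = generate_study(truth)
    ids = list(study.per_snp["variant_id"])
    return harmonise(study.exposures, study.outcomes[outcome], ids, study.ld), study


@pytest.fixture(scope="session")
def default_study():
    """One full default-condition study (LD blocks, palindromes, proxies)."""
    return generate_study(SyntheticTruth(seed=11))
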