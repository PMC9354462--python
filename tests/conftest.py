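import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from cardiopls import (
    GenePanel,
    SyntheticSpec,
    clr_transform,
    filter_by_reference,
    generate_cohort,
    remove_score_outliers,
)


@pytest.fixture(scope="session")
def panel():
    return GenePanel()


def preprocess_cohort(spec, panel):
    """Standard pipeline: reference filter -> CLR -> score-outlier removal."""
    expr, meta, truth = generate_cohort(spec, panel)
    kept, _ = filter_by_reference(expr, panel.reference_gene)
    clr = clr_transform(kept, basis=list(panel.all_genes))
    clr, _ = remove_score_outliers(clr, panel)
    return clr, meta.loc[clr.sample_ids], truth


@pytest.fixture(scope="session")
def default_cohort(panel):
    """One cohort at generator defaults (planted sex effect + confounder)."""
    return preprocess_cohort(SyntheticSpec(seed=3), panel)


@pytest.fixture(scope="session")
def null_cohort(panel):
    """Cohort with no sex effect and no confounder effect."""
    spec = SyntheticSpec(seed=11, sex_delta={}, confounder_effect={})
    return preprocess_cohort(spec, panel)


@pytest.fixture(scope="session")
def null_blocks(null_cohort, panel):
    clr, meta, _ = null_cohort
    return clr.block(panel.modifier_genes), clr.block(panel.ic_genes), meta


@pytest.fixture
def rng():
    return np.random.default_rng(0)
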