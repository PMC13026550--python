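from types import SimpleNamespace

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from intronscape.io import load_cohort
from intronscape.simulate import SimConfig, demo_families, emit_cohort, simulate_cohort


@pytest.fixture(scope="session")
def clean_cohort(tmp_path_factory):
    """Zero-mutation, no-degeneration cohort: 12 families x 20 species."""
    cfg = SimConfig(n_species=20, seed=42, families=demo_families())
    cohort = simulate_cohort(cfg)
    out = tmp_path_factory.mktemp("clean_cohort")
    paths = emit_cohort(cohort, str(out))
    data = load_cohort(str(out))
    return SimpleNamespace(cfg=cfg, cohort=cohort, paths=paths, data=data, dir=str(out))


@pytest.fixture(scope="session")
def rich_cohort(tmp_path_factory):
    """Degeneration-rich cohort exercising every lineage-specific feature."""
    cfg = SimConfig(
        n_species=10,
        seed=7,
        subst_rate_rna=0.0,
        subst_rate_orf=0.0,
        families=demo_families(rich=True),
    )
    cohort = simulate_cohort(cfg)
    out = tmp_path_factory.mktemp("rich_cohort")
    paths = emit_cohort(cohort, str(out))
    data = load_cohort(str(out))
    return SimpleNamespace(cfg=cfg, cohort=cohort, paths=paths, data=data, dir=str(out))
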