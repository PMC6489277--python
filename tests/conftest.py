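"""Shared fixtures: synthetic families and libraries built once per session."""

import pytest

from cupp.clustering import ClusteringParams, run_incremental
from cupp.evaluation import build_family_library
from cupp.library import compile_library, finalize_family
from cupp.synthetic import SyntheticFamilySpec, generate_family


@pytest.fixture(scope="session")
def default_params():
    return ClusteringParams()


@pytest.fixture(scope="session")
def family():
    """The reference synthetic family: 5 groups x 12 members, 3% mutation."""
    spec = SyntheticFamilySpec(seed=1)
    records, truth, clusters = generate_family(spec)
    return spec, records, truth, clusters


@pytest.fixture(scope="session")
def family_result(family, default_params):
    _, records, _, _ = family
    sequences = {r.protein_id: r.sequence for r in records}
    return run_incremental(sequences, default_params)


@pytest.fixture(scope="session")
def family_library(family, family_result, default_params):
    spec, records, _, _ = family
    metas = {r.protein_id: r.metas for r in records}
    groups = finalize_family(
        family_result, metas, spec.family,
        retain=default_params.retain_conservation,
    )
    return compile_library(groups, default_params.peptide_params)


@pytest.fixture(scope="session")
def small_family():
    """A fast-to-cluster family for pipeline-level tests."""
    spec = SyntheticFamilySpec(
        n_groups=3, members_per_group=6, ancestor_length=150, seed=11
    )
    records, truth, clusters = generate_family(spec)
    return spec, records, truth, clusters


@pytest.fixture(scope="session")
def small_library(small_family, default_params):
    _, records, _, _ = small_family
    lib, _ = build_family_library(records, default_params)
    return lib
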