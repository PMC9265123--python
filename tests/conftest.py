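"""Shared fixtures: a small synthetic cohort run through the early pipeline."""

import pytest

from chromgat.breakpoints import group_by_sample
from chromgat.connectivity import connectivity_profile
from chromgat.filtering import FilterConfig, filter_graphs, split_dataset
from chromgat.graphs import build_cohort
from chromgat.synthetic import make_separable_cohort


@pytest.fixture(scope="session")
def small_cohort_records():
    """40 samples/class, three classes with disjoint interchromosomal signatures."""
    return make_separable_cohort(n_per_class=40, seed=0)


@pytest.fixture(scope="session")
def small_cohort_graphs(small_cohort_records):
    return build_cohort(group_by_sample(small_cohort_records), mode="integrated")


@pytest.fixture(scope="session")
def small_cohort_profiles(small_cohort_graphs):
    return [connectivity_profile(g) for g in small_cohort_graphs]


@pytest.fixture(scope="session")
def small_kept(small_cohort_graphs, small_cohort_profiles):
    kept, _ = filter_graphs(small_cohort_graphs, small_cohort_profiles, FilterConfig())
    return kept


@pytest.fixture(scope="session")
def small_split(small_kept):
    return split_dataset(small_kept, test_fraction=0.2, seed=0)
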