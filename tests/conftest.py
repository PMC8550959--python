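import warnings

import numpy as np
import pytest

import persnet as pn


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no biclusters extracted")
        warnings.filterwarnings("ignore", message="networks .* dropped")
        yield


@pytest.fixture(scope="session")
def small_config():
    return pn.CohortConfig(n_subjects=400, n_snps=120, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One modest cohort shared by read-only tests."""
    return pn.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_phen_result(small_cohort):
    """Phenotype-only pipeline result on the small cohort."""
    phen, _, _, _ = small_cohort
    return pn.run_pipeline(phen, None, None, pn.PipelineConfig(seed=7))


@pytest.fixture(scope="session")
def small_full_result(small_cohort):
    """Full pipeline (genotype + environment) on the small cohort."""
    phen, gen, env, _ = small_cohort
    return pn.run_pipeline(phen, gen, env, pn.PipelineConfig(seed=7))


def best_jaccard(planted, collection, subject_ids):
    """Best subject-axis Jaccard of a planted set over a collection."""
    pl = set(subject_ids[i] for i in planted.subject_idx)
    return max(
        len(pl & set(b.subject_ids)) / len(pl | set(b.subject_ids))
        for b in collection.biclusters
    )


def subject_ari(truth, partition, subject_ids):
    """ARI between truth network labels and assigned networks, over
    subjects labeled and assigned."""
    from sklearn.metrics import adjusted_rand_score

    t, p = [], []
    for i, s in enumerate(subject_ids):
        tl = truth.subject_network_labels[i]
        pl = partition.subject_networks.get(s)
        if tl is not None and pl is not None:
            t.append(tl)
            p.append(pl)
    return adjusted_rand_score(t, p)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
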