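import pytest
from hypothesis import settings

from simdta import chem, seqsim
from simdta.cv import build_folds
from simdta.data import observed_pairs
from simdta.features import pair_grid_array
from simdta.model import SimCNNRegressor
from simdta.synthetic import SyntheticSpec, generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def synth_spec():
    return SyntheticSpec()  # 20 drugs x 15 targets, 4x3 clusters, seed 0


@pytest.fixture(scope="session")
def synth_ds(synth_spec):
    return generate_dataset(synth_spec)


@pytest.fixture(scope="session")
def k1(synth_ds):
    return chem.drug_similarity_matrix(list(synth_ds.drugs))


@pytest.fixture(scope="session")
def k2(synth_ds):
    return seqsim.target_similarity_matrix(list(synth_ds.targets))


@pytest.fixture(scope="session")
def synth_pairs(synth_ds):
    return observed_pairs(synth_ds)


@pytest.fixture(scope="session")
def synth_Xy(synth_ds, synth_pairs, k1, k2):
    return pair_grid_array(synth_ds, synth_pairs, k1, k2)


@pytest.fixture(scope="session")
def fold5(synth_pairs):
    return build_folds(synth_pairs, 5, seed=0)


@pytest.fixture(scope="session")
def fitted_fold0(synth_Xy, fold5):
    """Model trained on the out-of-fold pairs of fold 0 with the published
    hyperparameters; shared across recovery tests."""
    X, y = synth_Xy
    tr = fold5.train_indices(0)
    est = SimCNNRegressor(seed=0).fit(X[tr], y[tr])
    return est
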