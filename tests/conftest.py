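import warnings

import numpy as np
import pytest

from pistack import featurization as fz
from pistack import synthetic_fixtures as sf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic molecule + pair fixture shared across test modules."""
    spec = sf.FixtureSpec(
        n_molecules=150,
        n_descriptors=20,
        n_complementary=6,
        n_labelled_pairs=250,
        correlation=0.9,
        low_bias=3.5,
        outlier_fraction=0.15,
        seed=42,
    )
    molf = sf.generate_molecules(spec)
    pairf = sf.generate_labelled_pairs(spec, molf)
    return spec, molf, pairf


def build_pair_matrix(spec, molf, pairf, columns=None, full=False):
    """Scaled pair-vector matrix + outlier mask from a fixture (pipeline order)."""
    desc = molf.descriptors
    gt = pairf.ground_truth
    is_out = gt["is_outlier"].to_numpy()
    if columns is None:
        if full:
            columns = list(desc.columns)
        else:
            A, B = sf.pair_value_arrays(molf, pairf)
            kept = fz.prune_descriptors(desc.to_numpy())
            sel = fz.select_complementary_features(A[~is_out][:, kept], B[~is_out][:, kept])
            columns = [desc.columns[kept[j]] for j in sel.kept_indices]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaler = fz.fit_scaler(desc[columns].to_numpy())
        scaled = scaler.transform(desc[columns].to_numpy())
    lut = dict(zip(desc.index, scaled))
    A = np.stack([lut[m] for m in gt["first_member"]])
    B = np.stack([lut[m] for m in gt["second_member"]])
    return np.hstack([A, B]), is_out
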