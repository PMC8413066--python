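import numpy as np
import pytest

from hvpnet.synthetic import SyntheticSpec, generate, protocol_spec

# Narrow network widths used throughout the unit tests; the architecture is
# identical to the benchmark-scale one, only thinner.
TINY_MODEL = dict(conv_filters=8, fc_units=32, agg_units=16, dropout_rate=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small 2-subject, 3-gesture synthetic dataset plus its protocol."""
    spec = SyntheticSpec(n_subjects=2, n_gestures=3, n_trials=3, channels=4,
                         trial_duration=1.2, rest_duration=0.4, seed=7)
    return spec, generate(spec), protocol_spec(spec)


@pytest.fixture(scope="session")
def tiny_views(tiny_dataset):
    """Per-subject featurized train/test sets for the tiny dataset."""
    from hvpnet.signals import segment_windows, split_by_trial
    from hvpnet.train import featurize
    spec, recs, pspec = tiny_dataset
    classes = np.arange(1, spec.n_gestures + 1)
    out = {}
    for rec in recs:
        ws = segment_windows(rec, 200, 100)
        tr, te = split_by_trial(ws, pspec)
        out[rec.subject_id] = (featurize(tr, classes), featurize(te, classes))
    return out
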