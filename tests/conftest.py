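import numpy as np
import pytest

from sonobag import EncoderSpec, encode_subject, gen_grouped_subjects, make_encoder


@pytest.fixture(scope="session")
def small_dataset():
    """64 two-class subjects with strong separation, for training tests."""
    return gen_grouped_subjects(
        64, K=2, size_range=(2, 8), class_effect=6.0, distractor_rate=0.3,
        image_shape=(32, 32), seed=5,
    )


@pytest.fixture(scope="session")
def tiny_encoder():
    return make_encoder(EncoderSpec(name="tinycnn", input_size=(32, 32), d=16), seed=1)


@pytest.fixture(scope="session")
def small_features(small_dataset, tiny_encoder):
    feats = [encode_subject(s, tiny_encoder).features for s in small_dataset]
    labels = np.array([s.label for s in small_dataset])
    return feats, labels
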