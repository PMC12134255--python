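"""Shared helpers for the test suite."""
import numpy as np

from nucleovit.enhancement import normalize_for_classifier
from nucleovit.synthetic import benign_spec, generate_sample, malignant_spec

SPEC_FNS = (benign_spec, malignant_spec)


def make_samples(n, seed0):
    """Alternating benign/malignant synthetic samples."""
    return [generate_sample(SPEC_FNS[i % 2](seed=seed0 + i)) for i in range(n)]


def to_cls_samples(labeled):
    return [(s.id, s.label, normalize_for_classifier(s.image).astype(np.float32))
            for s in labeled]
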