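import numpy as np
import pytest

from afdetect import AFRecordingDetector, ClassifierParams, LabeledBeat


@pytest.fixture(scope="session")
def params() -> ClassifierParams:
    return ClassifierParams()


@pytest.fixture(scope="session")
def detector() -> AFRecordingDetector:
    return AFRecordingDetector().fit()


def make_labeled(labels, rr_ms=1000.0):
    """Build a LabeledBeat sequence from label strings with uniform RR."""
    rrs = np.full(len(labels), rr_ms) if np.isscalar(rr_ms) else np.asarray(rr_ms)
    t = np.cumsum(rrs)
    return [
        LabeledBeat(i, float(t[i]), float(rrs[i]), lab,
                    None if lab == "warmup" else 0.5)
        for i, lab in enumerate(labels)
    ]
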