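import numpy as np
import pytest

from sibload import CrossRecord

# Published per-strain logistic estimates with the printed load values and
# slope p-values they must reproduce: (strain, beta0, se0, beta1, se1,
# A_R, B_R, printed_p).  printed_p is a float for exact entries or a string
# "<x" upper bound.
PUBLISHED_LOADS = [
    ("fog-2", 1.517, 0.156, -0.219, 0.313, 0.198, 0.043, 0.484),
    ("EM464", 3.330, 0.272, -1.816, 0.376, 0.035, 0.164, "<1e-5"),
    ("PB219", 2.730, 0.220, -1.974, 0.356, 0.063, 0.322, "<1e-7"),
    ("QG548", 3.935, 0.334, -2.123, 0.427, 0.019, 0.132, "<1e-6"),
    ("QG549", 4.038, 0.372, -1.320, 0.464, 0.017, 0.046, 0.004),
    ("QG122", 3.633, 0.299, -2.048, 0.398, 0.026, 0.160, "<1e-6"),
    ("QG123", 3.134, 0.252, -1.931, 0.368, 0.043, 0.220, "<1e-6"),
    ("QG702", 4.403, 0.380, -2.798, 0.478, 0.012, 0.171, "<1e-8"),
    ("QG703", 4.391, 0.383, -2.675, 0.478, 0.012, 0.153, "<1e-7"),
    ("QG704", 3.513, 0.307, -0.899, 0.402, 0.029, 0.041, 0.025),
    ("QG711", 3.671, 0.325, -0.985, 0.419, 0.025, 0.041, 0.019),
]


def bernoulli_records(rng, F, p):
    """Quick plain cross records: success ~ Bernoulli(p_i) at covariate F_i."""
    y = rng.random(len(F)) < p
    return [
        CrossRecord(line_id=f"L{i}", generation=1, F_parents=float(f), success=bool(s))
        for i, (f, s) in enumerate(zip(F, y))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
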