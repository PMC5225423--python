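import numpy as np
import pandas as pd
import pytest

from mirsynet.containers import ExpressionMatrix

# 6 probes x 8 samples (4 case, 4 control), heterogeneous variances and
# effects; also the fixture behind the frozen external moderated-t oracle.
TOY_VALUES = [
    [10.134, 10.001, 10.091, 9.84, 9.36, 9.329, 9.116, 9.434],
    [8.036, 7.24, 7.977, 7.18, 8.283, 7.726, 7.645, 7.347],
    [9.401, 7.749, 7.42, 7.512, 10.073, 9.873, 9.93, 9.951],
    [9.946, 8.927, 8.885, 8.764, 9.036, 9.241, 8.744, 8.453],
    [5.635, 6.962, 7.046, 6.866, 5.778, 6.586, 6.482, 6.574],
    [12.338, 12.014, 12.242, 11.936, 10.047, 10.218, 9.174, 9.743],
]


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    samples = [f"s{i}" for i in range(8)]
    values = pd.DataFrame(TOY_VALUES, index=[f"m{i}" for i in range(6)], columns=samples)
    groups = pd.Series(["case"] * 4 + ["control"] * 4, index=samples)
    return ExpressionMatrix(values, groups)


def make_matrix(values: np.ndarray, n_case: int, prefix: str = "m") -> ExpressionMatrix:
    """Wrap a numpy array as an ExpressionMatrix with the first n_case columns as cases."""
    n_rows, n_samples = values.shape
    samples = [f"s{i}" for i in range(n_samples)]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (n_samples - n_case), index=samples
    )
    frame = pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(n_rows)], columns=samples)
    return ExpressionMatrix(frame, groups)
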