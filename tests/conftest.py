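import numpy as np
import pandas as pd
import pytest

from circscreen.iolib import ExpressionDataset


@pytest.fixture
def make_dataset():
    """Build an ExpressionDataset from a log2 matrix (values = 2**log2x)."""

    def _make(log2x, groups=None, probe_ids=None, sample_ids=None):
        log2x = np.asarray(log2x, dtype=float)
        n_probes, n_samples = log2x.shape
        probe_ids = probe_ids or [f"p{i + 1:03d}" for i in range(n_probes)]
        sample_ids = sample_ids or [f"s{j + 1:03d}" for j in range(n_samples)]
        if groups is None:
            groups = {s: "all" for s in sample_ids}
        values = pd.DataFrame(2.0**log2x, index=probe_ids, columns=sample_ids)
        return ExpressionDataset(values=values, groups=groups)

    return _make
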