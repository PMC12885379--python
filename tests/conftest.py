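import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_runs(values, threshold, min_consecutive=4):
    """Independent run-length oracle: plain scan, strictly-above comparison."""
    runs = []
    start = None
    for i, v in enumerate(values):
        if v > threshold:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_consecutive:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(values) - start >= min_consecutive:
        runs.append((start, len(values) - 1))
    return runs


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher by direct hypergeometric enumeration."""
    from scipy.stats import hypergeom

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    pobs = hypergeom.pmf(a, n, r1, c1)
    return min(float(pmf[pmf <= pobs * (1 + 1e-7)].sum()), 1.0)
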