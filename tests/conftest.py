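import math

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_probs(rng, n):
    """Random normalized dosage matrix, no missing rows."""
    p = rng.uniform(0.0, 1.0, size=(n, 3)) + 1e-6
    return p / p.sum(axis=1, keepdims=True)


def naive_marker(probs):
    """Pure-python re-implementation of all per-marker quantities.

    Deliberately loop-based and independent of the package's vectorized
    path; used as the oracle in equivalence tests.
    """
    rows = [list(map(float, row)) for row in probs]
    usable = [r for r in rows if sum(r) > 0.0]
    n = len(usable)
    d = [r[1] + 2.0 * r[2] for r in usable]
    f = sum(d) / (2.0 * n)
    q = sum(sum(p * (1.0 - p) for p in r) for r in usable) / n
    iam_c = 1.0 - q / (2.0 / 3.0)
    qh = (-2.0 * f) * (f - 1.0) * (3.0 * f * f - 3.0 * f + 2.0)
    iam_h = 1.0 - q / qh if qh > 0.0 else math.nan
    f_ad = [sum(r[g] for r in usable) / n for g in range(3)]
    f_bg = [0.0, 0.0, 0.0]
    for r in usable:
        mx = max(r)
        ties = [g for g in range(3) if r[g] == mx]
        for g in ties:
            f_bg[g] += 1.0 / (len(ties) * n)
    bc = sum(math.sqrt(f_ad[g] * f_bg[g]) for g in range(3))
    hiq = 1.0 - math.sqrt(max(1.0 - bc, 0.0))
    return {
        "maf_hat": f,
        "q_bar": q,
        "iam_chance": iam_c,
        "iam_hwe": iam_h,
        "hiq": hiq,
        "n_used": n,
    }
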