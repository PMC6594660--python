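import itertools
import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dielshift.core_io import ExpressionMatrix, SampleKey


# -- independent oracles --------------------------------------------------


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for hypergeometric(N, K, n) by direct exact summation."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(max(k, 0), min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(acc)


def kendall_s(x, template) -> int:
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dt = template[j] - template[i]
            dx = x[j] - x[i]
            if dt != 0 and dx != 0:
                s += 1 if dt * dx > 0 else -1
    return s


def kendall_null_enumeration(template) -> Counter:
    """Null distribution of S over all orderings of a tie-free observation."""
    n = len(template)
    counts: Counter = Counter()
    for perm in itertools.permutations(range(n)):
        counts[kendall_s(perm, template)] += 1
    return counts


def permutation_pvalue(x, template) -> float:
    """Two-sided permutation p-value of S(x, template), enumerating x orderings."""
    s_obs = abs(kendall_s(x, template))
    counts = kendall_null_enumeration(template)
    total = sum(counts.values())
    extreme = sum(c for s, c in counts.items() if abs(s) >= s_obs)
    return min(1.0, extreme / total)


# -- fixtures -------------------------------------------------------------


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    keys = [
        SampleKey("WW", zt, rep)
        for zt in range(0, 24, 2)
        for rep in (1, 2)
    ] + [
        SampleKey("DR", zt, rep)
        for zt in range(0, 24, 2)
        for rep in (1, 2)
    ]
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.uniform(1, 10, size=(5, len(keys))),
        index=[f"gene{i}" for i in range(5)],
        columns=[k.label for k in keys],
    )
    return ExpressionMatrix(data, keys)
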