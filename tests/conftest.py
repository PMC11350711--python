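import numpy as np
import pandas as pd
import pytest

from cernet import ExpressionMatrix, RunConfig, SampleSheet


@pytest.fixture
def sheet44() -> SampleSheet:
    return SampleSheet(
        ("H1", "H2", "H3", "H4", "L1", "L2", "L3", "L4"),
        ("high",) * 4 + ("low",) * 4,
    )


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture
def toy_matrix(sheet44) -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.poisson(50, size=(5, 8)),
        index=[f"g{i}" for i in range(5)],
        columns=list(sheet44.sample_ids),
    )
    return ExpressionMatrix("mRNA", data, sheet44)


def brute_force_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Independent oracle: enumerate every size-n draw from N items of
    which the first K are marked, and count overlaps >= k."""
    from itertools import combinations

    marked = set(range(K))
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def average_ranks(values) -> np.ndarray:
    """Independent oracle for mean-rank assignment under ties."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def naive_spearman(x, y) -> float:
    """Pearson correlation of average ranks, via the covariance formula."""
    rx, ry = average_ranks(x), average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
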