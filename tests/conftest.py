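import numpy as np
import pytest

from txrev.io import CONDITIONS_8, DesignTable, ExpressionMatrix, ProbeAnnotation


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 probes x 4 samples (2 conditions x 2 replicates), log2 scale."""
    values = np.array(
        [
            [5.0, 5.2, 7.0, 7.4],
            [8.0, 8.0, 8.0, 8.0],
            [3.0, 3.5, 3.8, 4.2],
        ]
    )
    return ExpressionMatrix(
        ["p1", "p2", "p3"], ["c0_r1", "c0_r2", "cC_r1", "cC_r2"], values, scale="log2"
    )


@pytest.fixture
def tiny_design() -> DesignTable:
    return DesignTable(
        {"c0_r1": ("0", 1), "c0_r2": ("0", 2), "cC_r1": ("C", 1), "cC_r2": ("C", 2)}
    )


@pytest.fixture
def tiny_annotation() -> ProbeAnnotation:
    return ProbeAnnotation({"p1": "GENE1", "p2": "GENE2"})  # p3 unannotated


def bh_oracle(p):
    """Naive O(n^2) Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def hypergeom_enumeration_oracle(k, n, K, N):
    """P[overlap >= k] by enumerating every size-n draw from an N-universe."""
    from itertools import combinations

    special = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def make_null_matrix(
    rng: np.random.Generator,
    n_probes: int = 10_000,
    sd: float = 0.2,
    baseline_low: float = 5.0,
    baseline_high: float = 11.0,
    conditions=("0", "C"),
    n_replicates: int = 2,
):
    """Homoscedastic null data: no condition effects, just replicate noise."""
    baseline = rng.uniform(baseline_low, baseline_high, size=n_probes)
    sample_ids, assignments, cols = [], {}, []
    for cond in conditions:
        for r in range(1, n_replicates + 1):
            sid = f"{cond}_r{r}"
            sample_ids.append(sid)
            assignments[sid] = (cond, r)
            cols.append(baseline + rng.normal(0.0, sd, size=n_probes))
    matrix = ExpressionMatrix(
        [f"p{i}" for i in range(n_probes)], sample_ids, np.column_stack(cols), scale="log2"
    )
    return matrix, DesignTable(assignments), baseline
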