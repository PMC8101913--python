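"""Shared fixtures and independent oracles.

The oracle functions deliberately use the slowest, most literal formulation
of each quantity (double loops, full enumeration) so they stay independent
of the vectorized implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chewtex import SpecimenSpec

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def classic_grid() -> np.ndarray:
    """The textbook 4-level 4x4 grid whose horizontal GLCM is known by hand."""
    return np.array(
        [
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [0, 2, 2, 2],
            [2, 2, 3, 3],
        ]
    )


@pytest.fixture()
def lowres_spec() -> SpecimenSpec:
    """Specimen at 2 px/mm: fast enough for study-scale simulations."""
    return SpecimenSpec(px_per_mm=2)


# ---------------------------------------------------------------- oracles


def naive_glcm(q: np.ndarray, levels: int, distance: int, angle: int, symmetric: bool) -> np.ndarray:
    """Literal pair-loop co-occurrence counting; -1 marks excluded pixels."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = offsets[angle]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and q[r, c] >= 0 and q[r2, c2] >= 0:
                counts[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    counts[q[r2, c2], q[r, c]] += 1
    return counts


@pytest.fixture()
def glcm_oracle():
    return naive_glcm


def wilcoxon_enumeration_p(differences) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Mirrors the test definition (zeros dropped, mid-ranks of |d|, doubled
    minimum tail) but computes the null distribution by brute force.
    """
    from scipy.stats import rankdata

    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


@pytest.fixture()
def wilcoxon_oracle():
    return wilcoxon_enumeration_p


def mannwhitney_enumeration_p(a, b) -> float:
    """Two-sided U-test p by enumerating all group assignments (tie-free data)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size

    def u_of(first: np.ndarray, second: np.ndarray) -> float:
        return float(sum((x > y) + 0.5 * (x == y) for x in first for y in second))

    u_obs = u_of(a, b)
    center = n * m / 2.0
    dev_obs = abs(u_obs - center)
    hits = total = 0
    for idx in itertools.combinations(range(n + m), n):
        first = pooled[list(idx)]
        second = np.delete(pooled, list(idx))
        total += 1
        if abs(u_of(first, second) - center) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


@pytest.fixture()
def mannwhitney_oracle():
    return mannwhitney_enumeration_p


def friedman_enumeration_p(blocks) -> float:
    """Friedman permutation p by enumerating within-block orderings."""
    from scipy.stats import rankdata

    x = np.asarray(blocks, dtype=float)
    n, k = x.shape
    ranks = np.array([rankdata(row) for row in x])
    denom = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0

    def stat(rank_rows) -> float:
        sums = np.sum(rank_rows, axis=0)
        dev = sums - n * (k + 1) / 2.0
        return (k - 1) * (dev**2).sum() / denom

    obs = stat(ranks)
    hits = total = 0
    for combo in itertools.product(*(list(itertools.permutations(row)) for row in ranks)):
        total += 1
        if stat(np.array(combo)) >= obs - 1e-9:
            hits += 1
    return hits / total


@pytest.fixture()
def friedman_oracle():
    return friedman_enumeration_p
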