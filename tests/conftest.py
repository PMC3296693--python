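"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: Fisher
tests by direct hypergeometric enumeration with exact binomial
coefficients, PWM scanning by per-window Python enumeration, BH by the
literal step-up formula, and the WMW statistic by pairwise counting.
"""

from __future__ import annotations

from math import comb, inf

import numpy as np
import pandas as pd
import pytest

from txaging.simulate import SimulationConfig

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of the 2x2 support."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = {k: comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p by enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    hi = min(r1, c1)
    denom = comb(n, c1)
    return min(1.0, sum(comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(a, hi + 1)))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the textbook formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def scan_count_oracle(sequence: str, probs: np.ndarray, background: np.ndarray) -> int:
    """Brute-force both-strand scan with greedy left-to-right collapse.

    Scores every window by an explicit Python loop; windows containing N
    never match. Mirrors only the published scoring rule, not the package's
    vectorized implementation.
    """
    L = probs.shape[0]
    score_matrix = np.log2(probs / background)
    max_score = sum(max(score_matrix[i]) for i in range(L))
    threshold = 0.9 * max_score
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def window_score(window: str) -> float:
        total = 0.0
        for i, ch in enumerate(window):
            if ch not in base_idx:
                return -inf
            total += score_matrix[i, base_idx[ch]]
        return total

    seq = sequence.upper()
    rc = revcomp(seq)
    n = len(seq)
    hits = []
    for s in range(n - L + 1):
        if window_score(seq[s : s + L]) > threshold:
            hits.append(s)
    for s in range(n - L + 1):
        # reverse-strand window covering forward interval [n-L-s, n-s)
        if window_score(rc[s : s + L]) > threshold:
            hits.append(n - L - s)
    count = 0
    last_end = -1
    for s in sorted(set(hits)):
        if s >= last_end:
            count += 1
            last_end = s + L
    return count


def wmw_u_oracle(ranked: list, foreground: set) -> int:
    """U by direct pairwise counting: foreground above background pairs."""
    u = 0
    for i, x in enumerate(ranked):
        if x in foreground:
            u += sum(1 for y in ranked[i + 1 :] if y not in foreground)
    return u


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120307)


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=300, n_samples=40, signature_size=60, n_decoys=4, n_reference=10)


@pytest.fixture
def toy_profile() -> pd.DataFrame:
    """A hand-built aging profile for counting rules."""
    genes = [f"g{i}" for i in range(10)]
    fc = [1.5, 1.2, 0.8, 1.0, 2.0, 0.5, 1.1, 0.9, 1.3, 0.7]
    p = [0.01, 0.2, 0.03, 0.5, 0.001, 0.04, 0.6, 0.2, 0.01, 0.03]
    slope = [np.log2(f) for f in fc]
    return pd.DataFrame({"fc": fc, "p": p, "slope": slope}, index=genes)
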