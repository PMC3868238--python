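"""Shared fixtures and independent brute-force oracles.

The oracles below use exact rational arithmetic (``fractions.Fraction``)
and naive enumeration, sharing no code path with the package's
vectorized implementation.
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd
import pytest

from kinconn import ActivityMatrix


def brute_ab(query_ranks, n_ref):
    """Enumerate every j term of both KS maxima with exact rationals."""
    ranks = sorted(query_ranks)
    m = len(ranks)
    a = max(
        Fraction(j, m) - Fraction(ranks[j - 1], n_ref)
        for j in range(1, m + 1)
    )
    b = max(
        Fraction(ranks[j - 1], n_ref) - Fraction(j - 1, m)
        for j in range(1, m + 1)
    )
    return a, b


def brute_ks(query_ranks, n_ref):
    a, b = brute_ab(query_ranks, n_ref)
    return a if a >= b else -b


def brute_running_sum(query_ranks, n_ref):
    """Position-by-position hit fraction minus uniform drift."""
    hits = set(query_ranks)
    m = len(hits)
    out = []
    seen = 0
    for r in range(1, n_ref + 1):
        if r in hits:
            seen += 1
        out.append(Fraction(seen, m) - Fraction(r, n_ref))
    return out


@pytest.fixture
def tiny_kd_matrix() -> ActivityMatrix:
    """Three drugs, four kinases; drugX is engineered most potent on
    ABL1 and KIT, the others favor the opposite end."""
    df = pd.DataFrame(
        {
            "ABL1": [0.001, 50.0, 80.0],
            "KIT": [0.010, 90.0, 60.0],
            "MET": [5.0, 0.02, 0.5],
            "SRC": [9.0, 0.01, 0.1],
        },
        index=["drugX", "drugY", "drugZ"],
    )
    return ActivityMatrix(values=df, assay_type="kd")
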