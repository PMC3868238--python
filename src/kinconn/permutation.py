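"""Permutation p-values for observed KS connectivity scores.

The null model keeps the drug's profile fixed and redraws the query as a
uniform random M-subset of the ranks 1..N (without replacement — a query
cannot contain a kinase twice).  The p-value is the exceedance fraction
f/T over T trials; by default trials count as exceedances when
|KS_t| ≥ |KS_0| (a genuinely two-sided rule), with a ``literal-one-sided``
mode counting KS_t ≥ KS_0 instead.  No pseudocount is added, so p = 0 is
representable; ``add_pseudocount=True`` switches to (f+1)/(T+1).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "PermutationResult",
    "permutation_pvalue",
    "exhaustive_pvalue",
    "DEFAULT_N_TRIALS",
]

#: default trial count for the Monte-Carlo p-value
DEFAULT_N_TRIALS = 500

_MODES = ("two-sided-abs", "literal-one-sided")


@dataclass(frozen=True)
class PermutationResult:
    drug: str
    ks0: float
    n_trials: int
    n_exceed: int
    p_value: float
    seed: int
    mode: str


def _drug_rng(seed: int, drug: str) -> np.random.Generator:
    # per-drug substream from (seed, drug id): results do not depend on
    # the order drugs are iterated in, nor on parallel scheduling
    digest = hashlib.sha256(drug.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _ks_batch(rank_sets: np.ndarray, n_ref: int) -> np.ndarray:
    """Vectorized KS score for a (T, m) array of rank subsets.

    Works on integer numerators over the common denominator m·n_ref so
    the a vs b branch is decided exactly, matching the scalar path.
    """
    r = np.sort(rank_sets, axis=1).astype(np.int64)
    m = r.shape[1]
    j = np.arange(1, m + 1, dtype=np.int64)
    a_num = np.max(j * n_ref - r * m, axis=1)
    b_num = np.max(r * m - (j - 1) * n_ref, axis=1)
    return np.where(a_num >= b_num, a_num, -b_num) / (m * n_ref)


def _exceeds(ks_trials: np.ndarray, ks0: float, mode: str) -> int:
    if mode == "two-sided-abs":
        return int(np.count_nonzero(np.abs(ks_trials) >= abs(ks0) - 1e-12))
    if mode == "literal-one-sided":
        return int(np.count_nonzero(ks_trials >= ks0 - 1e-12))
    raise ValueError(f"pvalue mode must be one of {_MODES}, got {mode!r}")


def permutation_pvalue(
    n_ref: int,
    m: int,
    ks0: float,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    drug: str = "",
    mode: str = "two-sided-abs",
    add_pseudocount: bool = False,
) -> PermutationResult:
    """Monte-Carlo p-value for an observed KS score.

    Draws ``n_trials`` uniform m-subsets of {1..n_ref}, recomputes the
    KS score for each, and returns the exceedance fraction.  Given the
    same (seed, drug, inputs) the result is bit-identical across runs.
    """
    if not 1 <= m <= n_ref:
        raise ValueError(f"need 1 <= m <= n_ref, got m={m}, n_ref={n_ref}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1 (use n_trials=0 upstream to skip)")
    rng = _drug_rng(seed, drug)
    trials = np.empty((n_trials, m), dtype=np.int64)
    for t in range(n_trials):
        trials[t] = rng.choice(n_ref, size=m, replace=False) + 1
    ks_trials = _ks_batch(trials, n_ref)
    f = _exceeds(ks_trials, ks0, mode)
    if add_pseudocount:
        p = (f + 1) / (n_trials + 1)
    else:
        p = f / n_trials
    return PermutationResult(
        drug=drug, ks0=float(ks0), n_trials=n_trials,
        n_exceed=f, p_value=float(p), seed=int(seed), mode=mode,
    )


def exhaustive_pvalue(
    n_ref: int,
    m: int,
    ks0: float,
    mode: str = "two-sided-abs",
    max_subsets: int = 100_000,
) -> float:
    """Exact exceedance fraction over all C(n_ref, m) query subsets.

    Feasible only while C(n_ref, m) ≤ ``max_subsets``; raises
    ``ValueError`` otherwise (fall back to :func:`permutation_pvalue`).
    The Monte-Carlo estimate converges to this value as T grows.
    """
    if not 1 <= m <= n_ref:
        raise ValueError(f"need 1 <= m <= n_ref, got m={m}, n_ref={n_ref}")
    total = comb(n_ref, m)
    if total > max_subsets:
        raise ValueError(
            f"C({n_ref}, {m}) = {total} exceeds cap {max_subsets}; "
            "use permutation_pvalue instead"
        )
    subsets = np.fromiter(
        (r for c in combinations(range(1, n_ref + 1), m) for r in c),
        dtype=np.int64,
    ).reshape(total, m)
    ks_all = _ks_batch(subsets, n_ref)
    return _exceeds(ks_all, ks0, mode) / total
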