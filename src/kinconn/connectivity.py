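"""Rank-based KS connectivity scoring of inhibitors against a query kinase set.

For a drug whose profile ranks N kinases and a query matching M of them
at ranks R_1 ≤ … ≤ R_M, two one-sided enrichment deviations are taken
over j = 1..M::

    a = max_j ( j/M − R_j/N )        # query concentrated near the top
    b = max_j ( R_j/N − (j−1)/M )    # query concentrated near the bottom

and the KS score is ``a`` if a > b else ``−b``.  Across the drugs of one
reference database the scores are rescaled by P = max KS and Q = min KS
into the connectivity score S (S = KS/P for KS > 0, −KS/Q for KS < 0),
so the best enriched drug gets S = 1 and the most anti-enriched S = −1.
S is finally mapped onto [0, 1] by (S + 1)/2 for ranking.  The running
sum D(r) = hits(r)/M − r/N traces the enrichment down the ranked list;
its maximum equals ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import RankedReference
from .query import QuerySet

__all__ = [
    "KSResult",
    "ConnectivityTable",
    "ks_statistic",
    "running_sum",
    "connectivity_scores",
    "normalize_scores",
    "connect",
]


@dataclass(frozen=True)
class KSResult:
    """KS statistic bookkeeping for one drug."""

    drug: str
    a: float
    b: float
    ks: float
    matched_query_ranks: tuple[int, ...]
    n_matched: int
    n_ref: int


@dataclass
class ConnectivityTable:
    """Ranked connectivity result for one query against one database.

    ``table`` columns: rank, drug, n_matched, ks, score (S),
    normalized_score, p_value (NaN when permutations are disabled);
    rows sorted by normalized_score descending, ties by drug id.
    ``running_sums`` maps drug → the length-N_i running-sum curve.
    ``unscored`` lists drugs whose profile contains no query kinase.
    """

    table: pd.DataFrame
    running_sums: dict[str, np.ndarray] = field(default_factory=dict)
    unscored: list[str] = field(default_factory=list)
    dropped_per_drug: dict[str, int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _validate_ranks(query_ranks: Iterable[int], n_ref: int) -> np.ndarray:
    ranks = np.asarray(sorted(int(r) for r in query_ranks), dtype=np.int64)
    if ranks.size == 0:
        raise ValueError("empty query rank set")
    if len(set(ranks.tolist())) != ranks.size:
        raise ValueError(f"duplicate query ranks: {ranks.tolist()}")
    if ranks[0] < 1 or ranks[-1] > n_ref:
        raise ValueError(f"query ranks {ranks.tolist()} outside 1..{n_ref}")
    return ranks


def _ks_ab_numerators(ranks: np.ndarray, n_ref: int) -> tuple[int, int]:
    # j/M − R_j/N and R_j/N − (j−1)/M over the common denominator M·N:
    # integer arithmetic makes the a vs b comparison exact
    m = ranks.size
    j = np.arange(1, m + 1, dtype=np.int64)
    a_num = int(np.max(j * n_ref - ranks * m))
    b_num = int(np.max(ranks * m - (j - 1) * n_ref))
    return a_num, b_num


def ks_ab(query_ranks: Iterable[int], n_ref: int) -> tuple[float, float]:
    """The two KS deviations (a, b) for sorted query ranks within 1..n_ref."""
    ranks = _validate_ranks(query_ranks, n_ref)
    a_num, b_num = _ks_ab_numerators(ranks, n_ref)
    denom = ranks.size * n_ref
    return a_num / denom, b_num / denom


def ks_statistic(
    query_ranks: Iterable[int], n_ref: int, drug: str = ""
) -> KSResult:
    """KS score of one drug: ``a`` if a > b, ``−b`` if b > a.

    The a == b tie (decided exactly, in integer arithmetic) takes the
    positive branch (ks = a); the tie set has measure zero on
    continuous activity values.
    """
    ranks = _validate_ranks(query_ranks, n_ref)
    a_num, b_num = _ks_ab_numerators(ranks, n_ref)
    denom = ranks.size * n_ref
    a, b = a_num / denom, b_num / denom
    ks = a if a_num >= b_num else -b
    return KSResult(
        drug=drug,
        a=a,
        b=b,
        ks=ks,
        matched_query_ranks=tuple(int(r) for r in ranks),
        n_matched=int(ranks.size),
        n_ref=int(n_ref),
    )


def running_sum(query_ranks: Iterable[int], n_ref: int) -> np.ndarray:
    """Enrichment curve D(r) = hits(r)/M − r/N for r = 1..N.

    hits(r) counts query ranks ≤ r.  max_r D(r) equals the ``a``
    deviation of :func:`ks_statistic`, and D(N) = 0.
    """
    ranks = _validate_ranks(query_ranks, n_ref)
    m = ranks.size
    hit = np.zeros(n_ref, dtype=float)
    hit[ranks - 1] = 1.0
    r = np.arange(1, n_ref + 1, dtype=float)
    return np.cumsum(hit) / m - r / n_ref


def connectivity_scores(ks_values: Sequence[float]) -> list[float]:
    """Rescale KS scores by the database extremes P = max KS, Q = min KS.

    S = KS/P when KS > 0, −KS/Q when KS < 0, and 0 when KS = 0; NaN
    (no-score sentinels) pass through untouched.  Whenever any KS is
    positive exactly the drugs attaining P get S = 1, and symmetrically
    the drugs attaining Q get S = −1.
    """
    arr = np.asarray(ks_values, dtype=float)
    valid = arr[~np.isnan(arr)]
    out = np.full(arr.shape, np.nan)
    if valid.size == 0:
        return out.tolist()
    p = float(np.max(valid))
    q = float(np.min(valid))
    for i, ks in enumerate(arr):
        if math.isnan(ks):
            continue
        if ks > 0:
            out[i] = ks / p
        elif ks < 0:
            out[i] = -ks / q
        else:
            out[i] = 0.0
    return out.tolist()


def normalize_scores(s_values: Sequence[float]) -> list[float]:
    """Affine map S ↦ (S + 1)/2 from [−1, 1] onto [0, 1]; order-preserving."""
    return [(float(s) + 1.0) / 2.0 if not math.isnan(s) else float("nan")
            for s in np.asarray(s_values, dtype=float)]


def connect(
    reference: RankedReference,
    query: QuerySet | Iterable[str],
    n_permutations: int = 500,
    seed: int = 0,
    pvalue_mode: str = "two-sided-abs",
    exact_when_feasible: bool = False,
) -> ConnectivityTable:
    """Score every drug of a ranked reference against a query kinase set.

    Query kinases not assayed for a drug are dropped from that drug's
    query (M becomes the per-drug match count, reported as
    ``n_matched``); drugs matching no query kinase land in the
    ``unscored`` list.  With ``n_permutations > 0`` each scored drug
    gets a permutation p-value over random same-size rank sets drawn
    from its own profile.

    Raises ``ValueError`` when the query shares no kinase with any
    drug profile.
    """
    from .permutation import exhaustive_pvalue, permutation_pvalue

    kinases = (
        set(query.kinases) if isinstance(query, QuerySet)
        else {str(k).strip().upper() for k in query}
    )
    if not kinases:
        raise ValueError("empty query")

    results: list[KSResult] = []
    curves: dict[str, np.ndarray] = {}
    unscored: list[str] = []
    dropped: dict[str, int] = {}
    for drug in reference.drugs:
        profile = reference.profile(drug)
        matched = profile[profile.index.isin(kinases)]
        dropped[drug] = len(kinases) - len(matched)
        if matched.empty:
            unscored.append(drug)
            continue
        n = reference.n_ref[drug]
        res = ks_statistic(matched.tolist(), n, drug=drug)
        results.append(res)
        curves[drug] = running_sum(res.matched_query_ranks, n)

    if not results:
        raise ValueError(
            f"query {sorted(kinases)} shares no kinase with any drug profile"
        )

    s_vals = connectivity_scores([r.ks for r in results])
    norm = normalize_scores(s_vals)

    pvals: list[float] = []
    for res in results:
        if n_permutations <= 0:
            pvals.append(float("nan"))
            continue
        if exact_when_feasible:
            try:
                pvals.append(
                    exhaustive_pvalue(res.n_ref, res.n_matched, res.ks)
                )
                continue
            except ValueError:
                pass
        pr = permutation_pvalue(
            res.n_ref,
            res.n_matched,
            res.ks,
            n_trials=n_permutations,
            seed=seed,
            drug=res.drug,
            mode=pvalue_mode,
        )
        pvals.append(pr.p_value)

    df = pd.DataFrame(
        {
            "drug": [r.drug for r in results],
            "n_matched": [r.n_matched for r in results],
            "ks": [r.ks for r in results],
            "score": s_vals,
            "normalized_score": norm,
            "p_value": pvals,
        }
    )
    df = df.sort_values(
        ["normalized_score", "drug"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    meta = {
        "n_permutations": n_permutations,
        "seed": seed,
        "pvalue_mode": pvalue_mode,
        "assay_type": reference.assay_type,
        "query": sorted(kinases),
    }
    return ConnectivityTable(
        table=df,
        running_sums=curves,
        unscored=sorted(unscored),
        dropped_per_drug=dropped,
        meta=meta,
    )
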