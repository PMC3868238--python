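"""scikit-learn style estimator wrapping the connectivity scoring pipeline.

``ConnectivityMapper`` follows the fit/query pattern of retrieval
estimators (compare ``sklearn.neighbors.NearestNeighbors``): ``fit``
ingests and rank-orders a reference activity matrix, after which query
kinase sets can be scored with :meth:`connect` (full ranked table) or
:meth:`transform` (normalized-score matrix, one row per query set).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .connectivity import ConnectivityTable, connect
from .matrix import ActivityMatrix, AssayType, rank_profiles
from .query import QuerySet

__all__ = ["ConnectivityMapper"]


class ConnectivityMapper(BaseEstimator):
    """Rank-based KS connectivity scoring of inhibitors vs. query kinases.

    Parameters
    ----------
    assay_type : {"kd", "ic50"}, default="kd"
        How fit-time values are interpreted when ``X`` is a plain
        DataFrame: dissociation constants (lower = more potent) or
        percent inhibition (higher = more potent).
    n_permutations : int, default=500
        Permutation trials per drug for the p-value; 0 disables.
    pvalue_mode : {"two-sided-abs", "literal-one-sided"}
        Exceedance rule for the permutation test.
    exact_when_feasible : bool, default=False
        Use the exhaustive p-value whenever C(N, M) is small enough.
    random_state : int, default=0
        Seed for the permutation null draws.

    Attributes
    ----------
    reference_ : RankedReference
        Per-drug rank-ordered kinase lists built at fit time.
    drugs_ : list of str
    kinases_ : list of str
        The reference kinase universe (feature names).
    n_features_in_ : int
    """

    def __init__(
        self,
        assay_type: AssayType = "kd",
        n_permutations: int = 500,
        pvalue_mode: str = "two-sided-abs",
        exact_when_feasible: bool = False,
        random_state: int = 0,
    ):
        self.assay_type = assay_type
        self.n_permutations = n_permutations
        self.pvalue_mode = pvalue_mode
        self.exact_when_feasible = exact_when_feasible
        self.random_state = random_state

    def fit(self, X: ActivityMatrix | pd.DataFrame, y=None) -> "ConnectivityMapper":
        """Validate and rank-order the reference activity matrix ``X``."""
        if isinstance(X, ActivityMatrix):
            matrix = X
        else:
            matrix = ActivityMatrix(
                values=pd.DataFrame(X).astype(float),
                assay_type=self.assay_type,
            )
        self.reference_ = rank_profiles(matrix)
        self.drugs_ = self.reference_.drugs
        self.kinases_ = list(self.reference_.ranks.columns)
        self.n_features_in_ = len(self.kinases_)
        return self

    def connect(self, query: QuerySet | Iterable[str]) -> ConnectivityTable:
        """Full ranked connectivity table for one query kinase set."""
        check_is_fitted(self, "reference_")
        return connect(
            self.reference_,
            query,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            pvalue_mode=self.pvalue_mode,
            exact_when_feasible=self.exact_when_feasible,
        )

    def transform(
        self, X: Sequence[Iterable[str]]
    ) -> np.ndarray:
        """Normalized connectivity scores for several query kinase sets.

        Returns an array of shape ``(len(X), n_drugs)`` aligned with
        ``drugs_``; NaN marks drugs whose profile contains no kinase of
        that query.  Permutation p-values are not computed here.
        """
        check_is_fitted(self, "reference_")
        out = np.full((len(X), len(self.drugs_)), np.nan)
        index = {d: i for i, d in enumerate(self.drugs_)}
        for qi, query in enumerate(X):
            ct = connect(self.reference_, query, n_permutations=0)
            for row in ct.table.itertuples():
                out[qi, index[row.drug]] = row.normalized_score
        return out

    def fit_transform(self, X, y=None, queries: Sequence[Iterable[str]] = ()):
        return self.fit(X).transform(queries)
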