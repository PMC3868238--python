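"""Reference activity matrices and rank-ordered kinase profiles.

A reference database is a drug × kinase table of quantitative activity
measurements: either percent kinase inhibition at fixed compound
concentration (``assay_type="ic50"``, values in [0, 100], higher = more
potent) or equilibrium dissociation constants in μM
(``assay_type="kd"``, values > 0, lower = more potent).  Each drug's
profile is converted into a rank-ordered kinase list — rank 1 is the
kinase the drug hits hardest — and those ranked lists are what the
connectivity scoring consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AssayType = Literal["ic50", "kd"]

#: tokens treated as missing measurements on load (besides empty cells)
DEFAULT_NA_TOKEN = "NA"


class ActivityMatrixError(ValueError):
    """Raised when an activity table violates the assay-type value ranges
    or structural invariants (duplicate drugs/kinases/cells)."""


def _normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class ActivityMatrix:
    """Validated drug × kinase activity measurements.

    Parameters
    ----------
    values : pandas.DataFrame
        Drugs as the index, uppercased kinase symbols as columns,
        floats with NaN marking kinases not assayed for that drug.
    assay_type : {"ic50", "kd"}
        ``ic50``: percent inhibition in [0, 100]; ``kd``: dissociation
        constant in μM, strictly positive.
    """

    values: pd.DataFrame
    assay_type: AssayType

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ActivityMatrixError(f"duplicate drug identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ActivityMatrixError(f"duplicate kinase symbols: {dups}")
        if self.assay_type not in ("ic50", "kd"):
            raise ActivityMatrixError(f"unknown assay_type: {self.assay_type!r}")
        arr = df.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        if self.assay_type == "ic50":
            bad = finite & ((arr < 0.0) | (arr > 100.0))
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ActivityMatrixError(
                    f"ic50 percent inhibition out of [0, 100]: "
                    f"drug {df.index[r]!r}, kinase {df.columns[c]!r}, "
                    f"value {arr[r, c]}"
                )
        else:
            bad = finite & (arr <= 0.0)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ActivityMatrixError(
                    f"kd must be strictly positive (μM): drug {df.index[r]!r}, "
                    f"kinase {df.columns[c]!r}, value {arr[r, c]}"
                )

    @property
    def drugs(self) -> list[str]:
        return list(self.values.index)

    @property
    def kinases(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RankedReference:
    """Per-drug rank-ordered kinase lists.

    ``ranks`` holds, for every drug, an integer rank for each kinase it
    was assayed against (1 = most potently inhibited / bound) and NaN
    elsewhere.  ``n_ref`` maps each drug to the size N_i of its ranked
    profile; N is per-drug because different source panels cover
    different kinase sets.
    """

    ranks: pd.DataFrame
    assay_type: AssayType
    n_ref: dict[str, int] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.ranks.columns)

    def profile(self, drug: str) -> pd.Series:
        """Ranks 1..N_i for one drug, indexed by kinase symbol."""
        row = self.ranks.loc[drug].dropna()
        return row.astype(int).sort_values()


def load_activity_matrix(
    path: str | Path,
    assay_type: AssayType,
    layout: Literal["wide", "long"] = "wide",
    delimiter: str | None = None,
    na_token: str = DEFAULT_NA_TOKEN,
) -> ActivityMatrix:
    """Read an activity table from delimited text.

    Two layouts are accepted, selected explicitly (no sniffing):

    * ``wide`` — first column holds drug identifiers, header row holds
      kinase symbols, cells hold measurements;
    * ``long`` — three columns ``drug, kinase, value``, one measurement
      per row.

    The delimiter defaults from the file extension (``.csv`` → comma,
    otherwise tab).  Lines starting with ``#`` are skipped; empty cells
    or the ``na_token`` string mark missing measurements.  Kinase
    symbols are uppercased and whitespace-stripped.  Duplicate
    (drug, kinase) cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    read_kwargs = dict(
        sep=delimiter,
        comment="#",
        na_values=[na_token, ""],
        keep_default_na=False,
        skip_blank_lines=True,
        dtype_backend="numpy_nullable",
    )
    try:
        if layout == "wide":
            df = pd.read_csv(path, index_col=0, **read_kwargs)
            df.index = [str(d).strip() for d in df.index]
            df.columns = [_normalize_symbol(k) for k in df.columns]
            df = df.astype(float)
        elif layout == "long":
            df_long = pd.read_csv(path, header=None, **read_kwargs)
            if df_long.shape[1] != 3:
                raise ActivityMatrixError(
                    f"long layout needs 3 columns (drug, kinase, value); "
                    f"got {df_long.shape[1]} in {path}"
                )
            df_long.columns = ["drug", "kinase", "value"]
            # tolerate an optional header row
            first = str(df_long.iloc[0, 2])
            try:
                float(first)
            except ValueError:
                df_long = df_long.iloc[1:]
            df_long = df_long.assign(
                drug=df_long["drug"].astype(str).str.strip(),
                kinase=df_long["kinase"].map(_normalize_symbol),
                value=df_long["value"].astype(float),
            )
            dup = df_long.duplicated(subset=["drug", "kinase"], keep=False)
            if dup.any():
                row = df_long.index[dup][0]
                rec = df_long.loc[row]
                raise ActivityMatrixError(
                    f"duplicate (drug, kinase) cell {rec['drug']!r}/"
                    f"{rec['kinase']!r} at data row {int(row) + 1} of {path}"
                )
            df = df_long.pivot(index="drug", columns="kinase", values="value")
            df.index.name = None
            df.columns.name = None
        else:
            raise ValueError(f"unknown layout: {layout!r}")
    except (ValueError, pd.errors.ParserError) as exc:
        if isinstance(exc, ActivityMatrixError):
            raise
        raise ActivityMatrixError(f"cannot parse {path}: {exc}") from exc
    return ActivityMatrix(values=df, assay_type=assay_type)


def rank_profiles(matrix: ActivityMatrix) -> RankedReference:
    """Convert each drug's activity profile into a rank-ordered kinase list.

    Rank 1 is the most potent interaction: the lowest Kd for ``kd``
    matrices, the highest percent inhibition for ``ic50``.  Ties in the
    measured value are broken by ascending kinase symbol so ranks are
    always an integer permutation of 1..N_i.  Drugs with no assayed
    kinase are dropped with a warning.
    """
    df = matrix.values
    ascending = matrix.assay_type == "kd"
    rank_rows: dict[str, pd.Series] = {}
    n_ref: dict[str, int] = {}
    for drug, row in df.iterrows():
        assayed = row.dropna()
        if assayed.empty:
            logger.warning("drug %r has no assayed kinases; excluded", drug)
            continue
        key = assayed if ascending else -assayed
        order = key.sort_index().sort_values(kind="stable")
        ranks = pd.Series(
            np.arange(1, len(order) + 1), index=order.index, dtype=float
        )
        rank_rows[drug] = ranks
        n_ref[drug] = len(order)
    if not rank_rows:
        raise ActivityMatrixError("no drug has any assayed kinase")
    ranks = pd.DataFrame(rank_rows).T.reindex(
        index=[d for d in df.index if d in rank_rows], columns=df.columns
    )
    return RankedReference(ranks=ranks, assay_type=matrix.assay_type, n_ref=n_ref)
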