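"""Design-matrix construction from covariate name lists.

Categorical columns (object / pandas Categorical / boolean-like strings) are
expanded into treatment-coded indicator columns with the first sorted level as
reference; numeric columns pass through. Column order is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design_matrix"]


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)


def build_design_matrix(
    df: pd.DataFrame,
    terms: list[str],
    add_intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Expand ``terms`` of ``df`` into a dense float design matrix.

    Returns (X, column_names). Rows with missing values are NOT dropped here;
    callers decide the estimation sample. Missing categorical values yield NaN
    in every indicator of that term so complete-case masks propagate.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(df)))
        names.append("const")
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"covariate {term!r} not found in data")
        s = df[term]
        if _is_categorical(s):
            levels = sorted(x for x in s.dropna().unique())
            missing = s.isna().to_numpy()
            for lev in levels[1:]:
                v = (s == lev).to_numpy(dtype=float)
                v[missing] = np.nan
                cols.append(v)
                names.append(f"{term}[{lev}]")
        else:
            cols.append(pd.to_numeric(s).to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names
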