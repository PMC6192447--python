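"""Questionnaire scoring and covariate-adjusted trait correlations.

The resilience scale has six 1-5 Likert items with even-numbered items
reverse-keyed; the total score is the mean of the recoded items, so it
lives on [1, 5]. The 48-item coping inventory is summed over three
16-item subscales (task-, emotion- and avoidance-oriented coping), each
on [16, 80]. Missing items are prorated when at least half of a scale's
items are present, otherwise the score is missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_CISS_MAP = {
    "ToC": list(range(1, 17)),
    "EoC": list(range(17, 33)),
    "AoC": list(range(33, 49)),
}
"""Default item -> subscale assignment: three consecutive 16-item blocks.

The genuine instrument's assignment is proprietary; this placeholder
ordering matches the synthetic item generator and is fully configurable.
"""


def _item_matrix(items: pd.DataFrame, n_items: int) -> np.ndarray:
    cols = [c for c in items.columns if c.lower().startswith("item")]
    if len(cols) != n_items:
        raise ValueError(f"expected {n_items} item columns, found {len(cols)}")
    cols = sorted(cols, key=lambda c: int("".join(ch for ch in c if ch.isdigit())))
    x = items[cols].to_numpy(dtype=float)
    valid = np.isnan(x) | ((x >= 1) & (x <= 5))
    if not valid.all():
        raise ValueError("item responses must be in 1..5 or missing")
    return x


def _prorated(x: np.ndarray, reducer: str) -> np.ndarray:
    """Row means/sums over available items; rows with <50% items -> NaN."""
    import warnings

    n_items = x.shape[1]
    avail = (~np.isnan(x)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
        mean = np.nanmean(x, axis=1)
    out = mean if reducer == "mean" else mean * n_items
    out = np.where(avail * 2 >= n_items, out, np.nan)
    out = np.where(avail == 0, np.nan, out)
    return out


def score_brs(items: pd.DataFrame) -> pd.Series:
    """Resilience score: mean of 6 items after reverse-coding items 2, 4, 6."""
    x = _item_matrix(items, 6)
    x[:, 1::2] = 6.0 - x[:, 1::2]
    score = _prorated(x, "mean")
    index = items["id"] if "id" in items.columns else items.index
    return pd.Series(score, index=index, name="resilience")


def score_ciss(items: pd.DataFrame, subscale_map: dict | None = None) -> pd.DataFrame:
    """Coping subscale scores: prorated sums over the three 16-item subscales."""
    x = _item_matrix(items, 48)
    smap = subscale_map or DEFAULT_CISS_MAP
    assigned = sorted(i for sub in smap.values() for i in sub)
    if assigned != list(range(1, 49)):
        raise ValueError("subscale map must assign each of items 1..48 exactly once")
    index = items["id"] if "id" in items.columns else items.index
    out = {}
    for sub, item_nums in smap.items():
        cols = np.array(item_nums) - 1
        out[sub] = _prorated(x[:, cols], "sum")
    return pd.DataFrame(out, index=index)


def adjusted_pearson(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation of two traits after residualizing on covariates.

    Both vectors are regressed (with intercept) on the covariate columns;
    the correlation r of the residuals is returned with its large-sample
    standard error sqrt((1 - r^2) / (n - 2 - q)) for q covariates.
    Rows with any missing value are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
    x, y, C = x[keep], y[keep], C[keep]
    n, q = len(x), C.shape[1]
    if n < 4 + q:
        raise ValueError(f"need at least {4 + q} complete cases, have {n}")
    X = np.column_stack([np.ones(n), C])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance: correlation undefined")
    r = float(rx @ ry / (n * sx * sy))
    se = float(np.sqrt((1.0 - r**2) / (n - 2 - q)))
    return r, se
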