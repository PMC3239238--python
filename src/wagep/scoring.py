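"""Tissue-match (tm) and tissue-specificity (ts) scores for a query profile.

For a query sample with expression value x_g for gene g:

* ``tm(g, c) = f_{g,c}(x_g) / max_x f_{g,c}(x)`` — the class-c reference
  density at the query value, normalized by that class's modal density, so
  tm ∈ [0, 1]: 1 means the value sits exactly at the most typical level for
  class c, 0 means it is outside anything class c exhibits.
* ``ts(g, c) = tm(g, c) − max_{c' ≠ c} tm(g, c')`` — how much better the
  gene fits class c than its best competitor, so ts ∈ [−1, 1]: +1 is a
  perfect fit to c to the exclusion of every other class, −1 means the
  value fits some other class perfectly and c not at all, 0 is
  indeterminate.

Both matrices are genes × classes DataFrames; NaN marks a masked entry
(class unavailable for the gene, or query value missing).  tm of a value
outside the grid span is 0 (a valid, unmasked score).  Densities are
linearly interpolated between grid points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import NoOverlapError
from .reference import ReferenceModel

__all__ = ["tm_score", "ts_score"]


def tm_score(model: ReferenceModel, query) -> pd.DataFrame:
    """Tissue-match scores of one query profile against every model class.

    ``query`` is a gene → value mapping (a :class:`pandas.Series` or dict);
    genes absent from the query, or with NaN values, yield fully masked rows.
    """
    q = pd.Series(query, dtype=float)
    x = q.reindex(model.gene_index).to_numpy()
    usable = np.isfinite(x)
    if not usable.any():
        raise NoOverlapError("query shares no usable gene with the model")

    G, K, M = model.densities.shape
    grids = model.grids
    dx = (grids[:, -1] - grids[:, 0]) / (M - 1)
    pos = (np.where(usable, x, 0.0) - grids[:, 0]) / dx
    inside = usable & (pos >= 0.0) & (pos <= M - 1)
    posc = np.clip(pos, 0.0, M - 1.0)
    i0 = np.minimum(np.floor(posc).astype(np.int64), M - 2)
    frac = posc - i0

    d0 = np.take_along_axis(model.densities, i0[:, None, None], axis=2)[:, :, 0]
    d1 = np.take_along_axis(model.densities, (i0 + 1)[:, None, None], axis=2)[:, :, 0]
    f = d0 * (1.0 - frac)[:, None] + d1 * frac[:, None]
    f = np.where(inside[:, None], f, 0.0)

    with np.errstate(invalid="ignore"):
        tm = f / model.modal()
    tm[~usable] = np.nan                      # query value missing -> masked row
    tm[model.n_samples == 0] = np.nan         # class absent for the gene -> masked
    tm = np.clip(tm, 0.0, 1.0)
    return pd.DataFrame(tm, index=model.gene_index, columns=model.class_labels)


def ts_score(tm: pd.DataFrame) -> pd.DataFrame:
    """Tissue-specificity scores: tm minus the best competing class's tm.

    Rows with fewer than two unmasked classes are fully masked (a score
    against no competitor is meaningless).
    """
    a = tm.to_numpy(dtype=float)
    filled = np.where(np.isnan(a), -np.inf, a)
    order = np.sort(filled, axis=1)
    m1 = order[:, -1]
    m2 = order[:, -2] if a.shape[1] >= 2 else np.full(a.shape[0], -np.inf)
    # competitor max: for the (a/the) top class it is the runner-up, else the top
    comp = np.where(filled == m1[:, None], m2[:, None], m1[:, None])
    ts = a - comp
    ts[np.isfinite(a).sum(axis=1) < 2] = np.nan
    return pd.DataFrame(ts, index=tm.index, columns=tm.columns)
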