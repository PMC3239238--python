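"""Gene-uniqueness weights from the reference densities.

The weight of gene g for class c measures how uniquely the gene's expression
identifies that class: over the region where the class-c density is strictly
higher than every other class's density, it is the area between the class-c
curve and the pointwise maximum of the competing curves,

    w(g, c) = ∫_{f_c > g_c} (f_c(x) − g_c(x)) dx,   g_c = max_{c' ≠ c} f_{c'}.

All densities integrate to 1 on the shared grid, so w ∈ [0, 1]: identical
curves give exactly 0 (the strict region is empty), disjoint supports give
≈ 1 for each class.  Weights depend on the reference densities only — never
on any query.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InsufficientClassesError, WagepError
from .kde import DensityEstimate
from .reference import ReferenceModel

__all__ = ["gene_weight", "weight_matrix", "specific_genes"]

_CLAMP_TOL = 1e-6  # overshoot beyond [0, 1] larger than this is an internal error


def _weight_tensor(densities: np.ndarray, grids: np.ndarray) -> np.ndarray:
    """(G, K) weights from a (G, K, M) density tensor on (G, M) uniform grids.

    NaN density rows (absent classes) yield NaN weights and are excluded
    from the competitor maximum.
    """
    G, K, M = densities.shape
    dx = (grids[:, -1] - grids[:, 0]) / (M - 1)
    filled = np.where(np.isnan(densities), -np.inf, densities)
    order = np.sort(filled, axis=1)
    m1 = order[:, -1, :]                      # pointwise best density
    m2 = order[:, -2, :]                      # pointwise runner-up
    comp = np.where(filled == m1[:, None, :], m2[:, None, :], m1[:, None, :])
    excess = np.maximum(densities - comp, 0.0)      # NaN rows stay NaN
    area = dx[:, None] * (excess.sum(axis=2) - 0.5 * (excess[:, :, 0] + excess[:, :, -1]))
    finite = area[np.isfinite(area)]
    if finite.size and (finite.min() < -_CLAMP_TOL or finite.max() > 1.0 + _CLAMP_TOL):
        raise WagepError(
            f"gene weight outside [0,1] beyond numerical tolerance "
            f"(min={finite.min():.3e}, max={finite.max():.3e})"
        )
    return np.clip(area, 0.0, 1.0)


def gene_weight(densities: Mapping[str, DensityEstimate], target_class: str) -> float:
    """Uniqueness weight of one gene for ``target_class``.

    ``densities`` maps every available class label to that class's
    :class:`DensityEstimate` for the gene; all estimates must share the
    same grid.
    """
    if len(densities) < 2:
        raise InsufficientClassesError("gene weight needs at least two classes")
    if target_class not in densities:
        raise KeyError(f"target class {target_class!r} not among densities")
    labels = list(densities)
    grid = densities[labels[0]].grid
    for lab in labels[1:]:
        if not np.array_equal(densities[lab].grid, grid):
            raise WagepError("all class densities for a gene must share one grid")
    stack = np.stack([densities[lab].density for lab in labels])[None, :, :]
    w = _weight_tensor(stack, grid[None, :])
    return float(w[0, labels.index(target_class)])


def weight_matrix(model: ReferenceModel) -> pd.DataFrame:
    """Genes × classes uniqueness weights for every available pair in the model.

    Deterministic; NaN marks (gene, class) pairs absent from the model.
    """
    w = _weight_tensor(model.densities, model.grids)
    return pd.DataFrame(w, index=model.gene_index, columns=model.class_labels)


def specific_genes(weights: pd.DataFrame, class_label: str, *, threshold: float = 0.25) -> list:
    """Genes whose uniqueness weight for ``class_label`` exceeds ``threshold``.

    The default 0.25 selects the strongly class-specific tail of the weight
    distribution (the level used to pick out cancer-specific marker panels).
    """
    if class_label not in weights.columns:
        raise KeyError(f"unknown class {class_label!r}")
    col = weights[class_label]
    return list(col.index[col > threshold])
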