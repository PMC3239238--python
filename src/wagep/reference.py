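"""The reference model: per-gene, per-class density estimates on shared grids.

Building a model from a labeled cohort proceeds gene by gene:

1. pool every non-missing value of the gene across all samples and lay a
   shared uniform evaluation grid over ``[min - 3·SD, max + 3·SD]``;
2. for every class with at least ``min_class_n`` non-missing values, fit a
   Gaussian KDE on that grid (see :mod:`wagep.kde`);
3. drop the gene if fewer than two classes are eligible (a density with no
   competitor cannot score or weight anything).

The model stores the full density tensor (genes × classes × grid points)
with NaN rows for absent (gene, class) pairs, so absence is queryable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyModelError
from .kde import DensityEstimate, _batch_density
from .matrix import ExpressionMatrix, SampleAnnotation

__all__ = ["ReferenceModel", "build_reference"]

log = logging.getLogger(__name__)

_CHUNK = 256  # genes per KDE batch; bounds peak memory of the (B, M, n) temporaries


@dataclass
class ReferenceModel:
    """Per-gene, per-class density estimates on shared per-gene grids.

    densities[g, c, :] is NaN everywhere iff class c is unavailable for
    gene g (fewer than ``min_class_n`` usable values); ``n_samples[g, c]``
    is 0 in that case.
    """

    gene_ids: np.ndarray          # (G,) str
    class_labels: list            # (K,)
    grids: np.ndarray             # (G, M) uniform, strictly increasing
    densities: np.ndarray         # (G, K, M), NaN where absent
    n_samples: np.ndarray         # (G, K) int
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self._gene_index = pd.Index(self.gene_ids, name="gene_id")

    # -- lookups -----------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def grid_size(self) -> int:
        return self.grids.shape[1]

    @property
    def gene_index(self) -> pd.Index:
        return self._gene_index

    def class_pos(self, class_label: str) -> int:
        return self.class_labels.index(class_label)

    def has(self, gene_id: str, class_label: str) -> bool:
        """Whether a density exists for this (gene, class) pair."""
        try:
            g = self._gene_index.get_loc(gene_id)
        except KeyError:
            return False
        return self.n_samples[g, self.class_pos(class_label)] > 0

    def density(self, gene_id: str, class_label: str) -> DensityEstimate:
        g = self._gene_index.get_loc(gene_id)
        c = self.class_pos(class_label)
        if self.n_samples[g, c] == 0:
            raise KeyError(f"no density for gene {gene_id!r} in class {class_label!r}")
        return DensityEstimate(
            grid=self.grids[g], density=self.densities[g, c], n_samples=int(self.n_samples[g, c])
        )

    def modal(self) -> np.ndarray:
        """(G, K) peak density per curve (NaN where absent); cached."""
        if getattr(self, "_modal_cache", None) is None:
            with np.errstate(all="ignore"):
                self._modal_cache = np.nanmax(self.densities, axis=2)
        return self._modal_cache

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Losslessly serialize to a single ``.npz``-style archive."""
        with open(Path(path), "wb") as fh:
            np.savez_compressed(
                fh,
                gene_ids=self.gene_ids.astype(str),
                class_labels=np.asarray(self.class_labels, dtype=str),
                grids=self.grids,
                densities=self.densities,
                n_samples=self.n_samples,
                config=np.asarray(json.dumps(self.config)),
            )

    @classmethod
    def load(cls, path) -> "ReferenceModel":
        with np.load(Path(path), allow_pickle=False) as archive:
            return cls(
                gene_ids=archive["gene_ids"].astype(object),
                class_labels=[str(c) for c in archive["class_labels"]],
                grids=archive["grids"],
                densities=archive["densities"],
                n_samples=archive["n_samples"],
                config=json.loads(str(archive["config"])),
            )


def build_reference(
    em: ExpressionMatrix,
    annot: SampleAnnotation,
    *,
    min_class_n: int = 6,
    n_grid: int = 512,
    pad_sd: float = 3.0,
    grid_from: "ReferenceModel | None" = None,
) -> ReferenceModel:
    """Build the per-gene, per-class density reference model.

    Parameters
    ----------
    min_class_n:
        Minimum non-missing values a class must contribute for a gene to get
        a density in that class (default 6, the smallest class size the
        method is intended to support).
    n_grid, pad_sd:
        Shared-grid resolution and padding (in pooled-SD units).
    grid_from:
        Optional existing model whose per-gene grids are reused instead of
        being refit from the pooled values.  Only genes present in that
        model are kept.  This pins the evaluation grid across model rebuilds
        (e.g. leave-one-out folds), making densities of untouched classes
        bit-identical across rebuilds.
    """
    if n_grid < 8:
        raise ConfigError("n_grid must be at least 8")
    if min_class_n < 2:
        raise ConfigError("min_class_n must be at least 2")
    annot.require_complete(em)

    classes = sorted({annot.class_of(s) for s in em.sample_ids})
    members = {
        c: em.sample_ids.get_indexer([s for s in annot.samples_of(c) if s in em.sample_ids])
        for c in classes
    }
    V = em.values  # (G_all, S)
    finite = np.isfinite(V)

    # per-gene per-class usable-value counts
    counts_all = np.stack([finite[:, members[c]].sum(axis=1) for c in classes], axis=1)

    if grid_from is not None:
        keep_ids = [g for g in grid_from.gene_ids if g in em.gene_ids]
        keep = em.gene_ids.get_indexer(keep_ids)
        grids_fixed = grid_from.grids[grid_from.gene_index.get_indexer(keep_ids)]
    else:
        # a gene needs >= 2 distinct pooled values to carry a grid
        with np.errstate(all="ignore"):
            vmin = np.nanmin(np.where(finite, V, np.nan), axis=1)
            vmax = np.nanmax(np.where(finite, V, np.nan), axis=1)
        degenerate = ~np.isfinite(vmin) | (vmin == vmax)
        if degenerate.any():
            log.info("dropping %d degenerate gene(s) (no spread)", int(degenerate.sum()))
        keep = np.flatnonzero(~degenerate)
        grids_fixed = None

    eligible = counts_all[keep] >= min_class_n
    enough = eligible.sum(axis=1) >= 2
    if (~enough).any():
        log.info("dropping %d gene(s) with < 2 eligible classes", int((~enough).sum()))
    keep = keep[enough]
    eligible = eligible[enough]
    if keep.size == 0:
        raise EmptyModelError("no gene has at least two eligible classes")
    if grids_fixed is not None:
        grids_fixed = grids_fixed[enough]

    G, K, M = keep.size, len(classes), n_grid
    Vk = V[keep]
    finite_k = finite[keep]

    if grids_fixed is None:
        pooled = np.where(finite_k, Vk, np.nan)
        with np.errstate(all="ignore"):
            lo = np.nanmin(pooled, axis=1)
            hi = np.nanmax(pooled, axis=1)
            sd = np.nanstd(pooled, axis=1, ddof=1)
        grids = np.linspace(lo - pad_sd * sd, hi + pad_sd * sd, n_grid, axis=1)
    else:
        grids = grids_fixed
        M = grids.shape[1]

    densities = np.full((G, K, M), np.nan)
    n_samples = np.zeros((G, K), dtype=np.int64)
    for ci, c in enumerate(classes):
        rows = np.flatnonzero(eligible[:, ci])
        if rows.size == 0:
            continue
        vals = Vk[np.ix_(rows, members[c])]
        for start in range(0, rows.size, _CHUNK):
            sl = slice(start, start + _CHUNK)
            dens, counts = _batch_density(vals[sl], grids[rows[sl]])
            densities[rows[sl], ci, :] = dens
            n_samples[rows[sl], ci] = counts

    config = {
        "min_class_n": min_class_n,
        "n_grid": int(M),
        "pad_sd": pad_sd,
        "grid_fixed": grid_from is not None,
    }
    return ReferenceModel(
        gene_ids=em.gene_ids[keep].to_numpy(dtype=object),
        class_labels=classes,
        grids=grids,
        densities=densities,
        n_samples=n_samples,
        config=config,
    )
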