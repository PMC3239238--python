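"""Weighted similarity scores, class ranking, accuracy categories and
reliability tiers.

The similarity of a query to class c is the weight-weighted mean of the
query's ts-scores for that class:

    S(c) = Σ_g ts(g,c)·w(g,c) / Σ_g w(g,c)

over genes unmasked in both matrices (algebraically identical to
"multiply each ts by its weight, divide by the mean weight, then average" —
the form used when the weights were introduced).  With all weights equal the
weighted score reduces exactly to the plain mean of ts-scores (the
unweighted method).  The predicted class is the similarity argmax.

Against a known truth label, a prediction falls into one of four accuracy
categories: ``exact`` (predicted class == truth), ``similar`` (same organ
group, e.g. the two lung carcinoma types), ``same_site`` (the top class
represents the metastasis site and the runner-up is exact/similar), or
``incorrect``.  The best-hit similarity also buckets the prediction into a
reliability tier: high (score ≥ 0.10), medium (≥ 0.05), low otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TaxonomyError, WagepError
from .matrix import Taxonomy

__all__ = [
    "SimilarityVector",
    "ClassificationResult",
    "similarity",
    "unweighted_similarity",
    "classify",
    "reliability_tier",
]

CATEGORIES = ("exact", "similar", "same_site", "incorrect")

#: reliability tier thresholds on the best-hit similarity score
TIER_HIGH = 0.10
TIER_MEDIUM = 0.05


@dataclass
class SimilarityVector:
    """Per-class similarity of one query sample.

    scores : class → similarity (weighted mean of ts-scores).
    n_genes : class → number of unmasked genes used.
    fallback : class → True when the mean weight was ~0 and the score fell
        back to the unweighted mean.
    """

    scores: pd.Series
    n_genes: pd.Series
    fallback: pd.Series

    def ranked(self) -> list:
        """(class, score) pairs by descending score, ties broken by label."""
        items = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return items


@dataclass
class ClassificationResult:
    ranked: list                      # (class, score), best first
    best: str
    best_score: float
    tie: bool
    tier: str
    category: str | None = None       # only when a truth label was supplied
    truth: str | None = None
    n_genes: pd.Series | None = field(default=None, repr=False)

    def top(self, k: int = 5) -> list:
        return self.ranked[:k]


def similarity(ts: pd.DataFrame, w: pd.DataFrame, *, min_mean_weight: float = 1e-6) -> SimilarityVector:
    """Weighted similarity S(c) = Σ ts·w / Σ w over genes unmasked in both.

    Classes whose mean weight over usable genes is below ``min_mean_weight``
    fall back to the unweighted mean (flagged); classes with no usable gene
    are omitted from the result.
    """
    if not ts.index.equals(w.index) or list(ts.columns) != list(w.columns):
        raise WagepError("ts and weight matrices must share gene and class axes")
    t = ts.to_numpy(dtype=float)
    wa = w.to_numpy(dtype=float)
    valid = np.isfinite(t) & np.isfinite(wa)
    n = valid.sum(axis=0)
    tw = np.where(valid, t * wa, 0.0)
    wsum = np.where(valid, wa, 0.0).sum(axis=0)
    tsum = np.where(valid, t, 0.0).sum(axis=0)

    scores = np.full(t.shape[1], np.nan)
    fallback = np.zeros(t.shape[1], dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = n > 0
        mean_w = np.where(ok, wsum / np.maximum(n, 1), np.nan)
        use_w = ok & (mean_w > min_mean_weight)
        scores[use_w] = tw.sum(axis=0)[use_w] / wsum[use_w]
        fb = ok & ~use_w
        scores[fb] = tsum[fb] / n[fb]
        fallback[fb] = True

    cols = ts.columns
    keep = n > 0
    return SimilarityVector(
        scores=pd.Series(scores[keep], index=cols[keep], name="similarity"),
        n_genes=pd.Series(n[keep], index=cols[keep], name="n_genes"),
        fallback=pd.Series(fallback[keep], index=cols[keep], name="fallback"),
    )


def unweighted_similarity(ts: pd.DataFrame) -> SimilarityVector:
    """Plain mean of ts-scores per class (the unweighted method).

    Implemented as :func:`similarity` with a unit weight matrix, which it
    equals bit-for-bit by construction.
    """
    unit = pd.DataFrame(1.0, index=ts.index, columns=ts.columns)
    sv = similarity(ts, unit)
    sv.fallback[:] = False
    return sv


def reliability_tier(best_score: float, *, high: float = TIER_HIGH, medium: float = TIER_MEDIUM) -> str:
    """Confidence bucket from the best-hit similarity (both bounds inclusive)."""
    if not np.isfinite(best_score):
        raise WagepError("reliability tier needs a finite score")
    if best_score >= high:
        return "high"
    if best_score >= medium:
        return "medium"
    return "low"


def classify(
    sim: SimilarityVector,
    truth: str | None = None,
    *,
    taxonomy: Taxonomy | None = None,
    site: str | None = None,
) -> ClassificationResult:
    """Rank classes, name the best hit and (optionally) grade it against truth.

    Ties at the top score are broken lexicographically and flagged.  With a
    ``truth`` label, the accuracy category is evaluated; the ``same_site``
    category additionally needs the sample's metastasis ``site`` and a
    taxonomy with a representative class for that site.
    """
    if len(sim.scores) == 0:
        raise WagepError("empty similarity vector")
    ranked = sim.ranked()
    best, best_score = ranked[0]
    tie = len(ranked) > 1 and ranked[1][1] == best_score

    category = None
    if truth is not None:
        tax = taxonomy or Taxonomy()
        known = tax.known_classes()
        if known and truth not in known and truth not in sim.scores.index:
            raise TaxonomyError(f"truth label {truth!r} absent from the taxonomy")
        category = _category(ranked, truth, tax, site)

    return ClassificationResult(
        ranked=ranked,
        best=best,
        best_score=float(best_score),
        tie=tie,
        tier=reliability_tier(best_score),
        category=category,
        truth=truth,
        n_genes=sim.n_genes,
    )


def _category(ranked, truth, tax: Taxonomy, site) -> str:
    best = ranked[0][0]
    if best == truth:
        return "exact"
    if tax.similar(best, truth):
        return "similar"
    if site is not None and len(ranked) > 1:
        rep = tax.site_representatives.get(site)
        second = ranked[1][0]
        if rep is not None and best == rep and (second == truth or tax.similar(second, truth)):
            return "same_site"
    return "incorrect"
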