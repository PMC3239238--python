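"""Cohort validation: leave-one-out cross-validation, per-class metrics,
the accuracy-vs-score curve, threshold summaries and the specific-gene
retention report.

LOOCV removes each sample in turn, reconstructs its own class's density
estimates (and, by default, the full gene-weight matrix) without it, scores
the held-out sample against the reduced reference, and grades the
prediction.  Evaluation grids are pinned from the full cohort, so densities
of the untouched classes are bit-identical across folds and only the
held-out sample's class needs refitting — the fold result is exactly what a
from-scratch rebuild on the same grids produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassificationResult, classify, similarity, unweighted_similarity
from .errors import ConfigError, EmptySelectionError, WagepError
from .kde import _batch_density
from .matrix import ExpressionMatrix, SampleAnnotation, Taxonomy
from .reference import ReferenceModel, build_reference
from .scoring import tm_score, ts_score
from .weighting import _weight_tensor, specific_genes

__all__ = [
    "CohortResult",
    "AccuracyCurve",
    "classify_cohort",
    "loocv",
    "per_class_metrics",
    "accuracy_curve",
    "threshold_accuracy",
    "gene_retention",
]

log = logging.getLogger(__name__)


@dataclass
class CohortResult:
    """Per-sample LOOCV (or test-cohort) outcomes.

    ``table`` has one row per classified sample: truth, best, best_score,
    second, second_score, category, tier, correct, n_class_holdout.
    ``accept`` records which categories counted as correct.
    """

    table: pd.DataFrame
    accept: tuple
    skipped: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        """Fraction of classified samples whose category is in ``accept``."""
        return float(self.table["correct"].mean())

    def exact_accuracy(self) -> float:
        return float((self.table["category"] == "exact").mean())


@dataclass
class AccuracyCurve:
    """Sliding-window accuracy along the best-score axis.

    Windows are ``[edge, edge + width)``; accuracy is NaN where a window
    holds no sample.
    """

    left_edges: np.ndarray
    accuracy: np.ndarray
    counts: np.ndarray
    width: float
    step: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_left": self.left_edges, "accuracy": self.accuracy, "n": self.counts}
        )


def _score_sample(fold_model, query, weights_df, taxonomy, truth, site):
    """Score one query against a (fold) model and classify it both ways."""
    tm = tm_score(fold_model, query)
    ts = ts_score(tm)
    sv_w = similarity(ts, weights_df)
    sv_u = unweighted_similarity(ts)
    res_w = classify(sv_w, truth, taxonomy=taxonomy, site=site)
    res_u = classify(sv_u, truth, taxonomy=taxonomy, site=site)
    return res_w, res_u


def _record(res: ClassificationResult, accept) -> dict:
    second = res.ranked[1] if len(res.ranked) > 1 else (None, np.nan)
    return {
        "truth": res.truth,
        "best": res.best,
        "best_score": res.best_score,
        "second": second[0],
        "second_score": float(second[1]),
        "category": res.category,
        "tier": res.tier,
        "correct": res.category in accept,
    }


def classify_cohort(
    model: ReferenceModel,
    weights: pd.DataFrame,
    queries: ExpressionMatrix,
    truth: dict,
    *,
    taxonomy: Taxonomy | None = None,
    sites: dict | None = None,
    accept: tuple = ("exact", "similar"),
) -> CohortResult:
    """Classify a query cohort against a fixed reference model.

    ``truth`` maps each query sample id to its true class; ``sites``
    optionally maps sample ids to metastasis-site labels for the
    ``same_site`` category.
    """
    sites = sites or {}
    rows, index = [], []
    for sid in queries.sample_ids:
        ts = ts_score(tm_score(model, queries.sample_values(sid)))
        sv = similarity(ts, weights)
        res = classify(sv, truth.get(sid), taxonomy=taxonomy, site=sites.get(sid))
        rows.append(_record(res, accept))
        index.append(sid)
    return CohortResult(
        pd.DataFrame(rows, index=pd.Index(index, name="sample_id")),
        accept,
        [],
        {"mode": "query-cohort"},
    )


def loocv(
    em: ExpressionMatrix,
    annot: SampleAnnotation,
    *,
    taxonomy: Taxonomy | None = None,
    min_class_n: int = 6,
    n_grid: int = 512,
    pad_sd: float = 3.0,
    accept: tuple = ("exact", "similar"),
    recompute_weights: bool = True,
    method: str = "both",
):
    """Leave-one-out cross-validation of a labeled cohort.

    For each sample: the density estimates of the sample's own class are
    rebuilt without it, the gene-weight matrix is recomputed from the fold's
    densities (``recompute_weights=False`` freezes the full-cohort weights
    instead), the sample is scored and classified, and the prediction is
    graded against its annotation.  Samples whose class would fall below
    ``min_class_n`` members after holdout are skipped (logged).

    ``method`` selects the returned result: ``"wagep"`` (weighted),
    ``"agep"`` (unweighted) or ``"both"`` (dict with both, sharing one pass
    over the folds).  Deterministic given inputs.
    """
    if method not in ("wagep", "agep", "both"):
        raise ConfigError(f"unknown method {method!r}")
    annot.require_complete(em)
    model = build_reference(em, annot, min_class_n=min_class_n, n_grid=n_grid, pad_sd=pad_sd)
    W_full = _weight_tensor(model.densities, model.grids)
    W_full_df = pd.DataFrame(W_full, index=model.gene_index, columns=model.class_labels)

    V = em.subset_genes(model.gene_ids).values  # (G, S) aligned to model genes
    sample_ids = list(em.sample_ids)
    class_pos = {c: i for i, c in enumerate(model.class_labels)}
    members = {c: [s for s in sample_ids if annot.class_of(s) == c] for c in model.class_labels}

    modal_full = model.modal()
    rows_w, rows_u, index, skipped = [], [], [], []
    for j, sid in enumerate(sample_ids):
        truth = annot.class_of(sid)
        ci = class_pos[truth]
        others = [s for s in members[truth] if s != sid]
        if len(others) < min_class_n:
            skipped.append((sid, f"class {truth!r} has only {len(others)} samples after holdout"))
            continue

        cols = [sample_ids.index(s) for s in others]
        vals = V[:, cols]
        counts = np.isfinite(vals).sum(axis=1)
        refit = np.flatnonzero(
            (model.n_samples[:, ci] > 0) & np.isfinite(V[:, j]) & (counts >= min_class_n)
        )
        lost = np.flatnonzero((model.n_samples[:, ci] > 0) & (counts < min_class_n))

        # swap the held-out class's slice in place (restored in `finally`):
        # all other classes are untouched, so the fold model is exactly what
        # a from-scratch rebuild on the same grids would produce.
        old_dens = model.densities[:, ci, :].copy()
        old_n = model.n_samples[:, ci].copy()
        modal_fold = modal_full.copy()
        try:
            if refit.size:
                dens, cnt = _batch_density(vals[refit], model.grids[refit])
                model.densities[refit, ci, :] = dens
                model.n_samples[refit, ci] = cnt
                modal_fold[refit, ci] = dens.max(axis=1)
            if lost.size:
                model.densities[lost, ci, :] = np.nan
                model.n_samples[lost, ci] = 0
                modal_fold[lost, ci] = np.nan
            model._modal_cache = modal_fold

            if recompute_weights:
                W_df = pd.DataFrame(
                    _weight_tensor(model.densities, model.grids),
                    index=model.gene_index,
                    columns=model.class_labels,
                )
            else:
                W_df = W_full_df

            res_w, res_u = _score_sample(
                model, em.sample_values(sid), W_df, taxonomy, truth, annot.site_of(sid)
            )
        finally:
            model.densities[:, ci, :] = old_dens
            model.n_samples[:, ci] = old_n
            model._modal_cache = modal_full
        rec_w, rec_u = _record(res_w, accept), _record(res_u, accept)
        rec_w["n_class_holdout"] = rec_u["n_class_holdout"] = len(others)
        rows_w.append(rec_w)
        rows_u.append(rec_u)
        index.append(sid)

    for sid, reason in skipped:
        log.info("LOOCV skipped %s: %s", sid, reason)
    config = {
        "min_class_n": min_class_n,
        "n_grid": n_grid,
        "pad_sd": pad_sd,
        "recompute_weights": recompute_weights,
    }
    out = {
        "wagep": CohortResult(
            pd.DataFrame(rows_w, index=pd.Index(index, name="sample_id")),
            accept,
            skipped,
            dict(config, method="wagep"),
        ),
        "agep": CohortResult(
            pd.DataFrame(rows_u, index=pd.Index(index, name="sample_id")),
            accept,
            skipped,
            dict(config, method="agep"),
        ),
    }
    return out if method == "both" else out[method]


def per_class_metrics(cohort: CohortResult) -> pd.DataFrame:
    """Per-class correct counts, sensitivity and specificity, plus a
    ``Total/average`` row (overall accuracy; unweighted mean sensitivity and
    specificity).

    sensitivity(c) = correctly classified samples of class c / samples of c;
    specificity(c) = 1 − (samples of other classes predicted as c) / (samples
    of other classes).
    """
    t = cohort.table
    classes = sorted(t["truth"].unique())
    rows = []
    for c in classes:
        in_c = t["truth"] == c
        n_c = int(in_c.sum())
        correct_c = int((in_c & t["correct"]).sum())
        fp = int((~in_c & (t["best"] == c)).sum())
        n_not = int((~in_c).sum())
        rows.append(
            {
                "class": c,
                "n_correct": correct_c,
                "n_samples": n_c,
                "percent_correct": 100.0 * correct_c / n_c,
                "sensitivity": correct_c / n_c,
                "specificity": 1.0 - fp / n_not if n_not else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("class")
    total = {
        "n_correct": int(df["n_correct"].sum()),
        "n_samples": int(df["n_samples"].sum()),
        "percent_correct": 100.0 * df["n_correct"].sum() / df["n_samples"].sum(),
        "sensitivity": float(df["sensitivity"].mean()),
        "specificity": float(df["specificity"].mean()),
    }
    df.loc["Total/average"] = total
    return df


def accuracy_curve(cohort: CohortResult, *, width: float = 0.1, step: float = 0.005) -> AccuracyCurve:
    """Accuracy within a window of width ``width`` slid along the best-score
    axis in increments of ``step``, starting at the observed minimum score."""
    if width <= 0 or step <= 0:
        raise ConfigError("window width and step must be positive")
    t = cohort.table
    if len(t) == 0:
        raise WagepError("empty cohort")
    scores = t["best_score"].to_numpy(dtype=float)
    correct = t["correct"].to_numpy(dtype=bool)
    lo, hi = scores.min(), scores.max()
    n_win = int(np.floor((hi - lo) / step)) + 1
    edges = lo + step * np.arange(n_win)
    acc = np.full(n_win, np.nan)
    counts = np.zeros(n_win, dtype=np.int64)
    for i, e in enumerate(edges):
        mask = (scores >= e) & (scores < e + width)
        counts[i] = mask.sum()
        if counts[i]:
            acc[i] = correct[mask].mean()
    return AccuracyCurve(left_edges=edges, accuracy=acc, counts=counts, width=width, step=step)


def threshold_accuracy(cohort: CohortResult, threshold: float):
    """(fraction of samples with best score ≥ threshold, accuracy among them).

    The accuracy is NaN when no sample reaches the threshold.
    """
    if not np.isfinite(threshold):
        raise ConfigError("threshold must be finite")
    t = cohort.table
    above = t["best_score"] >= threshold
    frac = float(above.mean()) if len(t) else np.nan
    acc = float(t.loc[above, "correct"].mean()) if above.any() else np.nan
    return frac, acc


def gene_retention(
    model: ReferenceModel,
    weights: pd.DataFrame,
    queries: ExpressionMatrix,
    class_label: str,
    *,
    weight_threshold: float = 0.25,
):
    """Unweighted ts-scores of one class's specific genes across query samples.

    Genes with weight > ``weight_threshold`` for ``class_label`` that are
    non-missing in *every* query are retained; queries are ordered by
    descending weighted similarity to the class, so loss of class-specific
    expression (drift) reads left-to-right as a fading score.

    Returns ``(ts_table, similarities)``: the genes × queries ts matrix
    (columns in similarity order) and the per-query similarity to the class.
    """
    if class_label not in model.class_labels:
        raise KeyError(f"unknown class {class_label!r}")
    sel = specific_genes(weights, class_label, threshold=weight_threshold)
    if not sel:
        raise EmptySelectionError(
            f"no gene with weight > {weight_threshold} for class {class_label!r}"
        )
    qframe = queries.to_frame().reindex(sel)
    present = list(qframe.index[qframe.notna().all(axis=1)])
    if not present:
        raise EmptySelectionError("no selected gene is present in all query samples")

    cols, sims = {}, {}
    for sid in queries.sample_ids:
        tm = tm_score(model, queries.sample_values(sid))
        ts = ts_score(tm)
        sims[sid] = float(similarity(ts, weights).scores[class_label])
        cols[sid] = ts.loc[present, class_label]
    order = sorted(sims, key=lambda s: (-sims[s], s))
    table = pd.DataFrame({s: cols[s] for s in order})
    table.index.name = "gene_id"
    return table, pd.Series(sims, name=f"similarity_to_{class_label}").loc[order]
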