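"""Expression matrices, sample annotations and the class taxonomy.

The universal input container is a genes × samples matrix of continuous
log2-scale expression intensities.  Missing entries are permitted and are
represented internally as NaN; on disk they are written with a configurable
token (``NA`` by default).  No normalization of any kind is performed here:
cross-platform harmonization is expected to have happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "Taxonomy",
    "read_expression",
    "write_expression",
    "read_annotation",
]


class ExpressionMatrix:
    """A genes × samples matrix of continuous expression values.

    Parameters
    ----------
    values:
        2-D float array, shape ``(n_genes, n_samples)``.  NaN marks a
        missing measurement; every non-missing value must be finite.
    gene_ids, sample_ids:
        Unique identifiers for the rows / columns.
    """

    def __init__(self, values, gene_ids: Iterable[str], sample_ids: Iterable[str]):
        values = np.asarray(values, dtype=float)
        gene_ids = np.asarray(list(gene_ids), dtype=object)
        sample_ids = np.asarray(list(sample_ids), dtype=object)
        if values.ndim != 2:
            raise ParseError(f"expression values must be 2-D, got ndim={values.ndim}")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ParseError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(gene_ids)} genes × {len(sample_ids)} samples"
            )
        for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
            if len(dupes):
                raise ParseError(f"duplicate {name} id(s): {', '.join(map(str, dupes[:5]))}")
        if np.isinf(values).any():
            g, s = np.argwhere(np.isinf(values))[0]
            raise ParseError(
                f"non-finite value at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
            )
        self._values = values
        self._gene_index = pd.Index(gene_ids, name="gene_id")
        self._sample_index = pd.Index(sample_ids, name="sample_id")

    # -- basic accessors ---------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def gene_ids(self) -> pd.Index:
        return self._gene_index

    @property
    def sample_ids(self) -> pd.Index:
        return self._sample_index

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._values, index=self._gene_index, columns=self._sample_index)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), df.index, df.columns)

    def sample_values(self, sample_id: str) -> pd.Series:
        """One sample's gene → value profile (NaN where missing)."""
        j = self._sample_index.get_loc(sample_id)
        return pd.Series(self._values[:, j], index=self._gene_index, name=sample_id)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = self._gene_index.get_indexer(list(gene_ids))
        if (idx < 0).any():
            raise KeyError("unknown gene id(s) in subset")
        return ExpressionMatrix(self._values[idx], self._gene_index[idx], self._sample_index)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = self._sample_index.get_indexer(list(sample_ids))
        if (idx < 0).any():
            raise KeyError("unknown sample id(s) in subset")
        return ExpressionMatrix(self._values[:, idx], self._gene_index, self._sample_index[idx])

    def drop_sample(self, sample_id: str) -> "ExpressionMatrix":
        keep = [s for s in self._sample_index if s != sample_id]
        if len(keep) == len(self._sample_index):
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.subset_samples(keep)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self._gene_index.equals(other._gene_index)
            and self._sample_index.equals(other._sample_index)
            and np.array_equal(self._values, other._values, equal_nan=True)
        )

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes × {s} samples)"


def read_expression(path, *, missing: str = "NA", sep: str = "\t") -> ExpressionMatrix:
    """Read a genes × samples TSV (first row sample ids, first column gene ids).

    Any cell that is neither numeric nor the ``missing`` token raises a
    :class:`ParseError` naming the gene and sample of the offending cell.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"{path}: cannot parse expression table: {exc}") from exc
    if df.index.hasnans or any(s == "" for s in df.index):
        raise ParseError(f"{path}: empty gene id in first column")
    raw = df.to_numpy(dtype=object)
    cleaned = np.where(raw == missing, "nan", raw)
    try:
        # numpy's strtod is correctly rounded: repr-written values round-trip
        numeric = cleaned.astype(np.float64)
    except ValueError:
        for (g, s), cell in np.ndenumerate(cleaned):
            try:
                float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {raw[g, s]!r} at gene {df.index[g]!r}, "
                    f"sample {df.columns[s]!r} (missing token is {missing!r})"
                ) from None
        raise
    return ExpressionMatrix(numeric, df.index, df.columns)


def write_expression(em: ExpressionMatrix, path, *, missing: str = "NA", sep: str = "\t") -> None:
    """Write a matrix in the dialect :func:`read_expression` reads.

    Values are written with ``repr`` (shortest round-tripping decimal), so
    read → write → read is lossless to the bit.
    """
    em.to_frame().to_csv(path, sep=sep, na_rep=missing, float_format=lambda v: repr(float(v)))


@dataclass
class Taxonomy:
    """Class taxonomy for the relaxed accuracy categories.

    ``organ_groups`` maps a class label to an organ group (two classes in the
    same group are "similar", e.g. the two lung carcinoma types).
    ``site_representatives`` maps a metastasis-site label to the reference
    class that represents tumors of that site.  ``classes`` is an optional
    explicit roster; when present, category evaluation against a truth label
    outside the roster is an error rather than silently "incorrect".
    """

    organ_groups: dict = field(default_factory=dict)
    site_representatives: dict = field(default_factory=dict)
    classes: tuple = ()

    def known_classes(self) -> set:
        known = set(self.classes)
        known |= set(self.organ_groups)
        known |= set(self.site_representatives.values())
        return known

    def similar(self, a: str, b: str) -> bool:
        ga = self.organ_groups.get(a)
        return ga is not None and ga == self.organ_groups.get(b)

    @classmethod
    def from_yaml(cls, path) -> "Taxonomy":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            organ_groups=dict(doc.get("organ_groups") or {}),
            site_representatives=dict(doc.get("site_representatives") or {}),
            classes=tuple(doc.get("classes") or ()),
        )


@dataclass
class SampleAnnotation:
    """sample → class labels, with optional metastasis-site labels."""

    classes: dict
    sites: dict = field(default_factory=dict)

    def __post_init__(self):
        self.classes = dict(self.classes)
        self.sites = {k: v for k, v in dict(self.sites).items() if v not in (None, "", "NA")}
        for sid, lab in self.classes.items():
            if not isinstance(lab, str) or not lab:
                raise ParseError(f"sample {sid!r}: class label must be a non-empty string")

    def class_of(self, sample_id: str) -> str:
        return self.classes[sample_id]

    def site_of(self, sample_id: str):
        return self.sites.get(sample_id)

    @property
    def class_labels(self) -> list:
        return sorted(set(self.classes.values()))

    def samples_of(self, class_label: str) -> list:
        return [s for s, c in self.classes.items() if c == class_label]

    def validate_against(self, em: ExpressionMatrix) -> None:
        missing = [s for s in self.classes if s not in em.sample_ids]
        if missing:
            raise ParseError(f"annotated sample(s) absent from matrix: {missing[:5]}")

    def require_complete(self, em: ExpressionMatrix) -> None:
        unannotated = [s for s in em.sample_ids if s not in self.classes]
        if unannotated:
            raise ParseError(f"sample(s) without class annotation: {unannotated[:5]}")


def read_annotation(path, *, sep: str = "\t") -> SampleAnnotation:
    """Read a sample annotation TSV with columns ``sample_id``, ``class_label``
    and optionally ``site``."""
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse annotation table: {exc}") from exc
    cols = list(df.columns)
    if "sample_id" not in cols or "class_label" not in cols:
        if len(cols) >= 2:  # headerless fallback: positional columns
            df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, header=None)
            df.columns = ["sample_id", "class_label", "site"][: len(df.columns)]
        else:
            raise ParseError(f"{path}: need columns sample_id, class_label[, site]")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    classes = dict(zip(df["sample_id"], df["class_label"]))
    sites = dict(zip(df["sample_id"], df["site"])) if "site" in df.columns else {}
    return SampleAnnotation(classes=classes, sites=sites)


def write_annotation(annot: SampleAnnotation, path, *, sep: str = "\t") -> None:
    rows = [
        {"sample_id": s, "class_label": c, "site": annot.sites.get(s, "")}
        for s, c in annot.classes.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "class_label", "site"]).to_csv(
        path, sep=sep, index=False
    )
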