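"""Core in-memory containers shared by every analysis stage.

The working substrate of the whole pipeline is a genes x samples expression
matrix on the log2(TPM + pseudocount) scale, together with a sample sheet and
a trio table joining each F1 hybrid to its two inbred parents.  Containers
here are thin, validated wrappers around pandas objects; all heavy lifting
stays in numpy/scipy/statsmodels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_trio_table",
    "write_trio_table",
    "validate_trios",
    "AlignmentError",
    "ConfigurationError",
    "InsufficientDataError",
    "AnnotationError",
]


class ConfigurationError(ValueError):
    """A parameter value violates its documented constraint."""


class AlignmentError(ValueError):
    """Two inputs that must share labels do not."""


class InsufficientDataError(ValueError):
    """Too few samples/trios/accessions for the statistic to be defined."""


class AnnotationError(KeyError):
    """Genes present in the matrix are missing from the annotation."""


#: metadata columns expected by the statistical stages
SAMPLE_COLUMNS = [
    "sample_id", "genotype_id", "is_hybrid", "treatment",
    "library_batch", "plant_batch", "replicate", "rosette_area",
    "mapped_reads",
]


class ExpressionMatrix:
    """Genes x samples abundance matrix with an explicit scale tag.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by gene id, columns by sample id.
    scale : {"linear", "log2"}
        ``"linear"`` means TPM; ``"log2"`` means log2(TPM + pseudocount).
    pseudocount : float
        TPM pseudocount used (or to be used) for the log transform.
    """

    def __init__(self, data: pd.DataFrame, scale: str = "log2",
                 pseudocount: float = 1.0):
        if scale not in ("linear", "log2"):
            raise ConfigurationError(f"scale must be linear or log2, got {scale!r}")
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ConfigurationError("gene and sample labels must be unique")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("expression values must be finite")
        self.data = data
        self.scale = scale
        self.pseudocount = float(pseudocount)

    # -- basic protocol ----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - cosmetic
        g, s = self.data.shape
        return f"<ExpressionMatrix {g} genes x {s} samples, scale={self.scale}>"

    # -- scale conversions -------------------------------------------------
    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2(TPM + pseudocount) view (no-op if already log2)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.data + self.pseudocount),
                                scale="log2", pseudocount=self.pseudocount)

    def to_linear(self) -> "ExpressionMatrix":
        """Invert the log transform back to the TPM scale."""
        if self.scale == "linear":
            return self
        linear = np.exp2(self.data) - self.pseudocount
        return ExpressionMatrix(linear.clip(lower=0.0), scale="linear",
                                pseudocount=self.pseudocount)

    # -- selection helpers -------------------------------------------------
    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale,
                                self.pseudocount)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.scale,
                                self.pseudocount)

    def sorted(self) -> "ExpressionMatrix":
        """Deterministic gene/sample order (lexicographic by id)."""
        return ExpressionMatrix(
            self.data.sort_index(axis=0).sort_index(axis=1),
            self.scale, self.pseudocount)

    # -- IO ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path, scale: str = "log2",
                 pseudocount: float = 1.0) -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
        return cls(data, scale=scale, pseudocount=pseudocount)


def read_sample_sheet(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ConfigurationError("sample sheet must have a sample_id column")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if "is_hybrid" in meta.columns:
        meta["is_hybrid"] = meta["is_hybrid"].astype(bool)
    return meta.set_index("sample_id", drop=False)


def write_sample_sheet(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trio_table(path) -> pd.DataFrame:
    trios = pd.read_csv(path, sep="\t", dtype=str)
    validate_trios(trios)
    return trios


def write_trio_table(trios: pd.DataFrame, path) -> None:
    trios.to_csv(path, sep="\t", index=False)


def validate_trios(trios: pd.DataFrame) -> None:
    required = {"trio_id", "parent_a", "parent_b", "f1"}
    missing = required - set(trios.columns)
    if missing:
        raise ConfigurationError(f"trio table missing columns: {sorted(missing)}")
    if (trios["parent_a"] == trios["parent_b"]).any():
        raise ConfigurationError("selfed trio: parent_a == parent_b")
    if trios["f1"].duplicated().any():
        raise ConfigurationError("F1 ids must be unique across trios")
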