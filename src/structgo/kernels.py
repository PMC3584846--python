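"""Input-space kernel construction, normalization and combination.

Every data view (BLAST profiles, PPI score vectors, expression, co-mention
counts...) enters the model as a kernel matrix over proteins.  Feature
tables are turned into linear kernels, each kernel is cosine-normalized so
that different feature spaces contribute on a comparable scale, and the
kernels of a view are combined by unweighted summation.  The joint kernel
over (protein, label) pairs is the product of the input-space and
output-space kernels.

Kernel matrices are stored dense; the intended problem scale (thousands of
proteins per view) fits comfortably in memory.

File dialects
-------------
Kernel TSV: first row and first column are protein ids; square numeric body.
Feature TSV: header row = feature names, first column = protein id.
Both accept ``#`` comment lines.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9


class KernelMatrix:
    """A symmetric similarity matrix with protein ids on both axes."""

    def __init__(self, ids: Sequence[str], values: np.ndarray, *, check: bool = True):
        self.ids: tuple[str, ...] = tuple(ids)
        self.values = np.asarray(values, dtype=float)
        if check:
            if len(set(self.ids)) != len(self.ids):
                raise ValidationError("kernel ids are not unique")
            n = len(self.ids)
            if self.values.shape != (n, n):
                raise ValidationError(
                    f"kernel shape {self.values.shape} does not match "
                    f"{n} ids"
                )
            asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
            if asym > SYMMETRY_TOL:
                raise ValidationError(
                    f"kernel is not symmetric (max asymmetry {asym:.3g})"
                )
        self._pos = {pid: i for i, pid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, pid: str) -> int:
        try:
            return self._pos[pid]
        except KeyError:
            raise KeyError(f"protein {pid!r} not in kernel") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.position(a), self.position(b)])

    def column(self, pid: str) -> np.ndarray:
        """Similarities of ``pid`` against all rows, in id order."""
        return self.values[:, self.position(pid)].copy()

    def columns(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        """Rectangular block ``K[row_ids, col_ids]``."""
        r = [self.position(p) for p in row_ids]
        c = [self.position(p) for p in col_ids]
        return self.values[np.ix_(r, c)]

    def subset(self, ids: Sequence[str]) -> "KernelMatrix":
        idx = [self.position(p) for p in ids]
        return KernelMatrix(ids, self.values[np.ix_(idx, idx)], check=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def linear_kernel(features: pd.DataFrame) -> KernelMatrix:
    """Linear kernel ``K[i, j] = x_i · x_j`` from a protein × feature table."""
    bad = [c for c in features.columns if not np.issubdtype(features[c].dtype, np.number)]
    if bad:
        raise ParseError(f"non-numeric feature columns: {bad!r}")
    if features.isna().any().any():
        raise ValidationError("feature table contains missing values")
    X = features.to_numpy(dtype=float)
    return KernelMatrix(list(features.index.astype(str)), X @ X.T, check=False)


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Cosine normalization ``K'(a,b) = K(a,b)/√(K(a,a)·K(b,b))``.

    Diagonal entries become exactly 1 where the original diagonal is
    positive.  Proteins with a zero self-similarity (all-zero features) get
    all-zero rows/columns rather than NaN; they are logged.  Idempotent.
    """
    d = np.diag(K.values).copy()
    if np.any(d < -SYMMETRY_TOL):
        raise ValidationError("kernel has a negative diagonal entry")
    d = np.maximum(d, 0.0)
    zero = d == 0.0
    if zero.any():
        names = [K.ids[i] for i in np.flatnonzero(zero)[:10]]
        logger.info(
            "normalize_kernel: %d proteins with zero self-similarity become "
            "zero rows (e.g. %r)", int(zero.sum()), names
        )
    s = np.sqrt(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        V = K.values / np.outer(s, s)
    V[zero, :] = 0.0
    V[:, zero] = 0.0
    np.fill_diagonal(V, np.where(zero, 0.0, 1.0))
    V = (V + V.T) / 2.0  # remove round-off asymmetry
    return KernelMatrix(K.ids, V, check=False)


def sum_kernels(kernels: Sequence[KernelMatrix]) -> KernelMatrix:
    """Unweighted entrywise sum of kernels sharing one id set.

    The result follows the first kernel's id order; the sum is *not*
    renormalized.
    """
    if not kernels:
        raise ValidationError("no kernels to sum")
    base = kernels[0]
    total = base.values.copy()
    base_set = set(base.ids)
    for K in kernels[1:]:
        if set(K.ids) != base_set:
            diff = sorted(base_set.symmetric_difference(K.ids))
            raise ValidationError(
                f"kernel id mismatch; symmetric difference {diff[:10]!r}"
            )
        if K.ids == base.ids:
            total += K.values
        else:
            perm = [K.position(p) for p in base.ids]
            total += K.values[np.ix_(perm, perm)]
    return KernelMatrix(base.ids, total, check=False)


def joint_kernel(kx_value: float, ky_value: float) -> float:
    """Joint input–output kernel: the product ``K_X · K_Y``."""
    return kx_value * ky_value


def align_features(features: pd.DataFrame, ids: Sequence[str]) -> pd.DataFrame:
    """Reindex a feature table to ``ids``, zero-filling absent proteins.

    Proteins missing from one feature source keep all-zero rows (hence zero
    kernel rows) instead of being dropped, so the id set of a view stays
    aligned across its sources.
    """
    frame = features.copy()
    frame.index = frame.index.astype(str)
    missing = [p for p in ids if p not in frame.index]
    if missing:
        logger.info(
            "align_features: %d proteins absent from source get zero rows",
            len(missing),
        )
    return frame.reindex(list(ids), fill_value=0.0)


ViewSource = Union[pd.DataFrame, KernelMatrix]


def build_view_kernel(
    sources: Sequence[ViewSource],
    ids: Sequence[str] | None = None,
    *,
    renormalize_sum: bool = False,
) -> KernelMatrix:
    """Build one view kernel: normalize each source kernel, then sum.

    ``sources`` are feature tables (turned into linear kernels) and/or
    precomputed kernel matrices.  ``ids`` fixes the protein universe
    (defaults to the union over sources, in first-seen order).  The summed
    kernel is not renormalized unless ``renormalize_sum`` is set.
    """
    if not sources:
        raise ValidationError("view has no sources")
    if ids is None:
        seen: list[str] = []
        have: set[str] = set()
        for src in sources:
            src_ids = src.ids if isinstance(src, KernelMatrix) else [
                str(i) for i in src.index
            ]
            for p in src_ids:
                if p not in have:
                    have.add(p)
                    seen.append(p)
        ids = seen
    parts: list[KernelMatrix] = []
    for src in sources:
        if isinstance(src, KernelMatrix):
            if set(src.ids) != set(ids):
                # embed into the full id set, zero-filling absent proteins
                frame = src.to_frame().reindex(index=list(ids), columns=list(ids), fill_value=0.0)
                frame = frame.fillna(0.0)
                src = KernelMatrix(list(ids), frame.to_numpy(), check=False)
            elif src.ids != tuple(ids):
                src = src.subset(list(ids))
            parts.append(normalize_kernel(src))
        else:
            aligned = align_features(src, ids)
            parts.append(normalize_kernel(linear_kernel(aligned)))
    total = sum_kernels(parts)
    if renormalize_sum:
        total = normalize_kernel(total)
    return total


# -- tabular I/O -------------------------------------------------------------


def _check_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        if np.issubdtype(df[col].dtype, np.number):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.flatnonzero(bad)[0]]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at row "
                f"{row!r}, column {col!r}"
            )
        df[col] = coerced


def read_feature_tsv(path) -> pd.DataFrame:
    """Read a feature table (header = feature names, first col = protein id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    _check_numeric(df, path)
    return df


def write_feature_tsv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index_label="protein")


def read_kernel_tsv(path) -> KernelMatrix:
    """Read a square kernel TSV with ids on the first row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column ids differ")
    _check_numeric(df, path)
    return KernelMatrix(list(df.index), df.to_numpy())


def write_kernel_tsv(K: KernelMatrix, path) -> None:
    K.to_frame().to_csv(path, sep="\t", index_label="protein")
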