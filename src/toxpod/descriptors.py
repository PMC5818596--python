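"""Chemical descriptor matrices and the feature-reduction pipeline.

Descriptors arrive in blocks (physchem, padel, toxprint, toxcast, httk),
keyed by chemical id. Before modeling the pipeline runs, in fixed order:

1. near-constant removal (frequency-ratio rule),
2. greedy pairwise-correlation filtering at |r| > 0.9,
3. column-median imputation of missing cells.

A PCA summary (on the centered/scaled reduced matrix) characterises the
residual redundancy of the descriptor space; it is diagnostic only and feeds
nothing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "remove_near_constant",
    "reduce_correlated",
    "impute_median",
    "pca_summary",
    "prepare_descriptors",
    "concat_blocks",
]


class DescriptorInputError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Chemicals x descriptors with a block label per column.

    ``data`` is a float DataFrame (rows indexed by chemical id, NaN marks
    missing cells); ``blocks`` maps every column to its block label.
    """

    data: pd.DataFrame
    blocks: pd.Series  # column name -> block label

    def __post_init__(self) -> None:
        if not isinstance(self.blocks, pd.Series):
            self.blocks = pd.Series(self.blocks)
        if self.data.index.has_duplicates:
            raise DescriptorInputError("duplicate chemical ids in descriptor matrix")
        if self.data.columns.has_duplicates:
            raise DescriptorInputError("duplicate descriptor names")
        missing = self.data.columns.difference(self.blocks.index)
        if len(missing):
            raise DescriptorInputError(f"columns without block label: {list(missing)[:5]}")
        self.blocks = self.blocks.loc[self.data.columns]

    @property
    def chemicals(self) -> pd.Index:
        return self.data.index

    def subset(self, columns: Iterable[str]) -> "DescriptorMatrix":
        cols = list(columns)
        return DescriptorMatrix(self.data[cols], self.blocks.loc[cols])

    def block_columns(self, block: str) -> list[str]:
        return list(self.blocks.index[self.blocks == block])

    def to_files(self, matrix_path, manifest_path) -> None:
        self.data.to_csv(matrix_path, sep="\t", index_label="chemical_id")
        self.blocks.rename("block").to_csv(manifest_path, sep="\t", index_label="descriptor")

    @classmethod
    def from_files(cls, matrix_path, manifest_path) -> "DescriptorMatrix":
        data = pd.read_csv(matrix_path, sep="\t", index_col="chemical_id")
        manifest = pd.read_csv(manifest_path, sep="\t", index_col="descriptor")
        return cls(data, manifest["block"])


def concat_blocks(blocks: Mapping[str, DescriptorMatrix]) -> DescriptorMatrix:
    """Outer-join descriptor blocks on chemical id.

    Chemicals lacking a block get NaN for that block's columns; per-block
    availability is recovered from the missing pattern by the modeling layer.
    """
    if not blocks:
        raise DescriptorInputError("no descriptor blocks given")
    frames = []
    labels = []
    for name, dm in blocks.items():
        frames.append(dm.data)
        labels.append(dm.blocks)
    data = pd.concat(frames, axis=1, join="outer")
    return DescriptorMatrix(data, pd.concat(labels))


def remove_near_constant(matrix: DescriptorMatrix, freq_cut: float = 95 / 5) -> DescriptorMatrix:
    """Drop constant and near-constant descriptors.

    A column is removed when it has a single distinct observed value, or when
    the count ratio of its most frequent to second most frequent value
    exceeds ``freq_cut`` (default 95/5 = 19).
    """
    if matrix.data.shape[1] == 0 or matrix.data.shape[0] == 0:
        raise DescriptorInputError("empty descriptor matrix")
    keep = []
    for col in matrix.data.columns:
        counts = matrix.data[col].dropna().value_counts()
        if len(counts) <= 1:
            continue
        if counts.iloc[0] / counts.iloc[1] > freq_cut:
            continue
        keep.append(col)
    return matrix.subset(keep)


def reduce_correlated(
    matrix: DescriptorMatrix, cutoff: float = 0.9
) -> tuple[DescriptorMatrix, list[str]]:
    """Greedily remove descriptors until no pair has |r| > cutoff.

    At each step the most correlated remaining pair is found and the member
    with the larger mean absolute correlation to all other remaining columns
    is removed (ties: the lexicographically later name goes). Correlations
    use pairwise-complete observations, so the filter can run before
    imputation.
    """
    if not 0 < cutoff <= 1:
        raise DescriptorInputError(f"cutoff must be in (0, 1], got {cutoff}")
    stds = matrix.data.std(ddof=0)
    zero_var = list(stds.index[(stds == 0) | stds.isna()])
    if zero_var:
        raise DescriptorInputError(
            f"zero-variance columns present (run remove_near_constant first): {zero_var[:5]}"
        )
    corr = matrix.data.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    corr = corr.fillna(0.0)
    removed: list[str] = []
    while True:
        flat = corr.values
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        if flat[i, j] <= cutoff:
            break
        a, b = corr.columns[i], corr.columns[j]
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        removed.append(drop)
        corr = corr.drop(index=drop, columns=drop)
    kept = [c for c in matrix.data.columns if c not in set(removed)]
    return matrix.subset(kept), removed


def impute_median(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Replace every missing cell by its descriptor's median.

    Observed cells are preserved bit-exactly. Raises when a column has no
    observed value at all (its median is undefined).
    """
    data = matrix.data
    all_missing = data.columns[data.isna().all()]
    if len(all_missing):
        raise DescriptorInputError(f"all-missing columns: {list(all_missing)[:5]}")
    filled = data.fillna(data.median())
    return DescriptorMatrix(filled, matrix.blocks)


@dataclass
class PCASummary:
    cumulative_variance: np.ndarray  # fraction explained by first k components
    components_for: dict[float, int] = field(default_factory=dict)


def pca_summary(matrix: DescriptorMatrix, thresholds=(0.25, 0.50, 0.75)) -> PCASummary:
    """Cumulative explained-variance profile of the centered, scaled matrix."""
    data = matrix.data
    if data.shape[0] < 2:
        raise DescriptorInputError("need at least 2 rows for PCA")
    if data.isna().any().any():
        raise DescriptorInputError("impute before PCA")
    X = data.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = X / sd
    s = np.linalg.svd(X, compute_uv=False)
    var = s**2
    cum = np.cumsum(var) / var.sum()
    comps = {t: int(np.searchsorted(cum, t) + 1) for t in thresholds}
    return PCASummary(cumulative_variance=cum, components_for=comps)


@dataclass
class PreparationReport:
    n_input: int
    near_constant_removed: list[str]
    correlated_removed: list[str]
    n_output: int
    pca: PCASummary | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"descriptor": c, "reason": "near_constant"} for c in self.near_constant_removed]
        rows += [{"descriptor": c, "reason": "correlated"} for c in self.correlated_removed]
        return pd.DataFrame(rows, columns=["descriptor", "reason"])


def prepare_descriptors(
    blocks: Mapping[str, DescriptorMatrix],
    freq_cut: float = 95 / 5,
    corr_cutoff: float = 0.9,
    with_pca: bool = True,
) -> tuple[DescriptorMatrix, PreparationReport]:
    """Run the full reduction pipeline on the combined descriptor space.

    Fixed order: near-constant removal -> correlation filter (pairwise
    complete, pre-imputation) -> median imputation. The reduction is fit on
    the full chemical set, as is conventional for unsupervised filters; a
    caller wanting split-hygienic reduction can pass pre-subset blocks.
    """
    combined = concat_blocks(blocks)
    reduced = remove_near_constant(combined, freq_cut)
    near_const = [c for c in combined.data.columns if c not in set(reduced.data.columns)]
    reduced, correlated = reduce_correlated(reduced, corr_cutoff)
    imputed = impute_median(reduced)
    report = PreparationReport(
        n_input=combined.data.shape[1],
        near_constant_removed=near_const,
        correlated_removed=correlated,
        n_output=imputed.data.shape[1],
        pca=pca_summary(imputed) if with_pca else None,
    )
    return imputed, report
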