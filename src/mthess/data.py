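"""Data containers and tab-delimited I/O for genotype and multi-condition response panels.

The genotype panel holds an ``n x p`` dosage matrix (individuals by markers);
for recombinant-inbred panels the dosages are binary.  Responses measured in
``r`` conditions (tissues, cell types, ...) are re-stacked per response: each
response ``k`` becomes an ``n x r`` matrix ``Y_k`` whose columns are the
conditions, aligned on the shared sample ordering of the genotype panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "ResponsePanel",
    "read_genotypes",
    "read_responses",
    "write_matrix",
    "dedupe_markers",
]


@dataclass
class GenotypePanel:
    """Predictor matrix with marker and sample identifiers.

    Attributes
    ----------
    values : (n, p) float array
        Numeric dosages, no missing values.
    sample_ids : list of str
    marker_ids : list of str
    marker_pos : optional list of (chromosome, position) tuples, one per marker.
    """

    values: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    marker_pos: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 3:
            raise ValueError(f"need at least 3 individuals, got {n}")
        if len(self.sample_ids) != n or len(self.marker_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype matrix contains missing/non-finite values")
        if self.marker_pos is not None and len(self.marker_pos) != p:
            raise ValueError("marker_pos length does not match number of markers")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class ResponsePanel:
    """Per-response stacks ``Y_k`` of shape ``n x r`` sharing the genotype sample order."""

    stacks: np.ndarray  # (q, n, r)
    response_ids: list[str]
    condition_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.stacks = np.asarray(self.stacks, dtype=float)
        if self.stacks.ndim != 3:
            raise ValueError("stacks must have shape (q, n, r)")
        q, n, r = self.stacks.shape
        if len(self.response_ids) != q:
            raise ValueError("response_ids length mismatch")
        if len(self.condition_ids) != r:
            raise ValueError("condition_ids length mismatch")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if not np.all(np.isfinite(self.stacks)):
            raise ValueError("response stacks contain missing/non-finite values")

    @property
    def q(self) -> int:
        return self.stacks.shape[0]

    @property
    def n(self) -> int:
        return self.stacks.shape[1]

    @property
    def r(self) -> int:
        return self.stacks.shape[2]

    @classmethod
    def from_condition_matrices(
        cls,
        matrices: Sequence[pd.DataFrame],
        condition_ids: Sequence[str],
        sample_ids: Sequence[str] | None = None,
    ) -> "ResponsePanel":
        """Assemble per-response stacks from ``r`` condition matrices (each n x q).

        Rows are realigned on sample identifiers; a sample missing from any
        condition is an error.  Column (response) sets must agree.
        """
        if len(matrices) == 0:
            raise ValueError("need at least one condition matrix")
        ref = matrices[0]
        if sample_ids is None:
            sample_ids = list(ref.index.astype(str))
        response_ids = list(ref.columns.astype(str))
        aligned = []
        for cid, m in zip(condition_ids, matrices):
            m = m.copy()
            m.index = m.index.astype(str)
            missing = [s for s in sample_ids if s not in m.index]
            if missing:
                raise ValueError(f"condition {cid!r} is missing samples: {missing}")
            if list(m.columns.astype(str)) != response_ids:
                raise ValueError(f"condition {cid!r} has mismatched response columns")
            aligned.append(m.loc[list(sample_ids)].to_numpy(dtype=float))
        # (r, n, q) -> (q, n, r)
        arr = np.stack(aligned, axis=0).transpose(2, 1, 0)
        return cls(arr, response_ids, list(condition_ids), list(sample_ids))

    def condition_matrix(self, ell: int) -> np.ndarray:
        """Return the n x q matrix of condition ``ell`` (all responses)."""
        return self.stacks[:, :, ell].T.copy()

    def single_condition(self, ell: int) -> "ResponsePanel":
        """Restrict the panel to one condition (stacks become n x 1)."""
        return ResponsePanel(
            self.stacks[:, :, ell : ell + 1].copy(),
            list(self.response_ids),
            [self.condition_ids[ell]],
            list(self.sample_ids),
        )


def read_genotypes(path: str | Path) -> GenotypePanel:
    """Read a tab-delimited genotype file: first row marker IDs, first column sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing value in {path} at row {df.index[i]!r}, column {df.columns[j]!r}")
    return GenotypePanel(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def read_responses(
    paths: Sequence[str | Path],
    condition_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ResponsePanel:
    """Read one tab-delimited file per condition and assemble the response panel."""
    if condition_ids is None:
        condition_ids = [Path(p).stem for p in paths]
    frames = [pd.read_csv(p, sep="\t", index_col=0, float_precision="round_trip") for p in paths]
    for p, f in zip(paths, frames):
        vals = f.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing value in {p}")
    return ResponsePanel.from_condition_matrices(frames, list(condition_ids), sample_ids)


def write_matrix(path: str | Path, values: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str]) -> None:
    """Write a labelled matrix as tab-delimited text (row IDs in first column)."""
    # %.17g round-trips float64 exactly through text
    pd.DataFrame(values, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def dedupe_markers(panel: GenotypePanel, r2_threshold: float | None = None) -> tuple[GenotypePanel, dict[str, str]]:
    """Remove redundant marker columns, keeping the first occurrence.

    A column is redundant when it is identical to an earlier retained column or
    perfectly anticorrelated with it (|r| = 1; for binary dosages this is the
    complement).  Optionally an LD pruning threshold ``r2_threshold`` removes
    columns whose squared correlation with a retained column reaches it.

    Returns the pruned panel and a map from removed marker ID to the retained
    marker it aliases.
    """
    X = panel.values
    n, p = X.shape
    sd = X.std(axis=0)
    keep: list[int] = []
    alias: dict[str, str] = {}
    # standardized columns for correlation tests; constant columns only match constants
    Z = np.zeros_like(X)
    nz = sd > 0
    Z[:, nz] = (X[:, nz] - X[:, nz].mean(axis=0)) / (sd[nz] * np.sqrt(n))
    thr = 1.0 - 1e-12 if r2_threshold is None else r2_threshold
    for j in range(p):
        redundant_with = None
        if keep:
            if sd[j] == 0:
                for i in keep:
                    if sd[i] == 0 and np.array_equal(X[:, i], X[:, j]):
                        redundant_with = i
                        break
            else:
                kept_nz = [i for i in keep if sd[i] > 0]
                if kept_nz:
                    r2 = (Z[:, kept_nz].T @ Z[:, j]) ** 2
                    hit = np.nonzero(r2 >= thr)[0]
                    if hit.size:
                        redundant_with = kept_nz[int(hit[0])]
        if redundant_with is None:
            keep.append(j)
        else:
            alias[panel.marker_ids[j]] = panel.marker_ids[redundant_with]
    pruned = GenotypePanel(
        X[:, keep],
        list(panel.sample_ids),
        [panel.marker_ids[j] for j in keep],
        None if panel.marker_pos is None else [panel.marker_pos[j] for j in keep],
    )
    return pruned, alias
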