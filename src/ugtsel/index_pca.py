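"""Orthogonalization of the seven raw residue indices by principal components.

The raw indices covary strongly (size-like measures especially), so the
working residue encoding is their correlation-PCA score table: each index
column is z-scored across the 20 residues, the 7x7 correlation structure is
eigendecomposed, and residues are projected onto the ordered components.
Columns PC1..PC7 are orthogonal with variances equal to the eigenvalues;
downstream loop/index searches use the first five.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAModel", "fit_pca", "project", "inverse_project", "pc_columns"]


def pc_columns(n: int = 7) -> list[str]:
    return [f"PC{i}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PCAModel:
    """Correlation-PCA model of a residue index table.

    loadings columns are unit eigenvectors ordered by decreasing explained
    variance, with a deterministic sign convention (the largest-magnitude
    loading of each component is positive).
    """

    columns: tuple[str, ...]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.columns)
        if self.loadings.shape != (p, p):
            raise ValueError("loadings must be square")
        if not np.allclose(self.loadings.T @ self.loadings, np.eye(p), atol=1e-10):
            raise ValueError("loadings are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12) or np.any(
            self.explained_variance < -1e-12
        ):
            raise ValueError("explained_variance must be non-negative and non-increasing")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# ugtsel PCA model\n")
            fh.write("columns\t" + "\t".join(self.columns) + "\n")
            for name, vec in (("means", self.means), ("scales", self.scales),
                              ("explained_variance", self.explained_variance)):
                fh.write(name + "\t" + "\t".join(f"{v:.17g}" for v in vec) + "\n")
            for row in self.loadings:
                fh.write("loading\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "PCAModel":
        columns, vectors, loadings = None, {}, []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                key, *vals = line.rstrip("\n").split("\t")
                if key == "columns":
                    columns = tuple(vals)
                elif key == "loading":
                    loadings.append([float(v) for v in vals])
                else:
                    vectors[key] = np.array([float(v) for v in vals])
        return cls(
            columns=columns,
            means=vectors["means"],
            scales=vectors["scales"],
            loadings=np.array(loadings),
            explained_variance=vectors["explained_variance"],
        )


def fit_pca(table: pd.DataFrame) -> PCAModel:
    """Fit correlation PCA to a residue index table (rows = residues)."""
    x = table.to_numpy(dtype=float)
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        names = [table.columns[i] for i in zero]
        raise ValueError(f"zero-variance column(s) {names}: correlation PCA is undefined")
    z = (x - means) / scales
    corr = (z.T @ z) / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]
    # sign convention: largest-magnitude loading of each component is positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return PCAModel(
        columns=tuple(table.columns),
        means=means,
        scales=scales,
        loadings=eigvec,
        explained_variance=eigval,
    )


def project(table: pd.DataFrame, model: PCAModel) -> pd.DataFrame:
    """Project an index table onto the model's components (PC score table)."""
    if tuple(table.columns) != model.columns:
        raise ValueError(
            f"table columns {tuple(table.columns)} do not match model columns {model.columns}"
        )
    z = (table.to_numpy(dtype=float) - model.means) / model.scales
    scores = z @ model.loadings
    return pd.DataFrame(scores, index=table.index, columns=pc_columns(scores.shape[1]))


def inverse_project(scores: pd.DataFrame, model: PCAModel) -> pd.DataFrame:
    """Map PC scores back to the standardized index space (round-trip check)."""
    z = scores.to_numpy(dtype=float) @ model.loadings.T
    return pd.DataFrame(z, index=scores.index, columns=list(model.columns))
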