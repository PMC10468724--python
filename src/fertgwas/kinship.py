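"""Genomic relationship matrix (VanRaden method 1) and Gower centering."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix

__all__ = ["Grm", "compute_grm", "gower_scale", "write_grm", "read_grm"]


@dataclass
class Grm:
    """Symmetric n x n genomic relationship matrix.

    ``scaling`` records whether the matrix is the raw VanRaden G or has
    been Gower-centered (double-centered and rescaled to trace n - 1).
    The eigendecomposition is computed lazily and cached because every
    downstream mixed-model fit reuses it.
    """

    values: np.ndarray
    ids: list[str]
    scaling: str = "raw"
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.ids) != n:
            raise ValueError("id count does not match GRM dimension")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GRM contains non-finite entries")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("GRM is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (ascending eigenvalues)."""
        if self._eig is None:
            lam, U = np.linalg.eigh(self.values)
            self._eig = (lam, U)
        return self._eig

    def subset(self, idx) -> "Grm":
        idx = np.asarray(idx)
        return Grm(self.values[np.ix_(idx, idx)], [self.ids[i] for i in idx], self.scaling)


def compute_grm(genotypes: GenotypeMatrix) -> Grm:
    """VanRaden method-1 GRM: G = W W' / (2 sum p_j (1 - p_j)).

    W is the dosage matrix with missing entries mean-imputed and each
    column centered by twice the in-sample allele frequency.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    X = genotypes.imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs; GRM undefined")
    W = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (W @ W.T) / denom
    return Grm(values=G, ids=list(genotypes.ids), scaling="raw")


def gower_scale(grm: Grm, target_trace: float | None = None) -> Grm:
    """Gower-center a GRM: G* = c J G J with trace(G*) = n - 1.

    J = I - 11'/n double-centers; c rescales so the average diagonal
    matches the conventional trace of n - 1 (``target_trace``
    overridable).  The result has zero row sums and is invariant to any
    positive rescaling of the input.
    """
    G = grm.values
    n = grm.n
    target = float(n - 1) if target_trace is None else float(target_trace)
    row_mean = G.mean(axis=0)
    grand = G.mean()
    C = G - row_mean[None, :] - row_mean[:, None] + grand
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("centered GRM has non-positive trace; cannot Gower-scale")
    out = C * (target / tr)
    return Grm(values=out, ids=list(grm.ids), scaling="gower")


def write_grm(grm: Grm, path) -> None:
    """Square tab-separated export with an id header row/column."""
    df = pd.DataFrame(grm.values, index=grm.ids, columns=grm.ids)
    df.to_csv(path, sep="\t", index_label="iid")


def read_grm(path, scaling: str = "raw") -> Grm:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Grm(values=df.to_numpy(), ids=list(df.columns), scaling=scaling)
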