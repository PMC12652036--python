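"""Repeated-measures correlation screening of taxa against host factors.

The common within-subject association between two repeatedly measured
variables is estimated with subject-specific intercepts: both variables are
centered on their subject means and the Pearson correlation of the centered
values is taken.  This equals the ANCOVA common-slope association with a
subject factor; the degrees of freedom are N - k - 1 for N paired
observations from k subjects, and the two-sided p-value comes from
t = r * sqrt(df / (1 - r^2)).

Measurements are strongly right-skewed, so a 10th-root transform is applied
upstream of the screen (bounded clinical indices are left untransformed by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RmCorrResult",
    "CorrelationScreen",
    "root_transform",
    "rmcorr",
    "screen",
    "rmcorr_matrix",
    "NINE_FACTORS",
]

#: The nine clinical/biomarker factors screened against every taxon.
NINE_FACTORS = (
    "IL-1b",
    "endotoxin",
    "TLR-SEAP",
    "TLR-ATP",
    "PAD",
    "MMP-1",
    "MMP-9",
    "GBI",
    "MGI",
)


@dataclass(frozen=True)
class RmCorrResult:
    """Repeated-measures correlation for one variable pair."""

    r: float
    df: int
    p: float
    n_obs: int
    n_subjects: int


@dataclass
class CorrelationScreen:
    """Taxa x factors matrices of repeated-measures r and p values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_obs: int
    n_subjects: int

    def __post_init__(self) -> None:
        if not (self.r.index.equals(self.p.index) and self.r.columns.equals(self.p.columns)):
            raise ValueError("r and p matrices must share labels")

    @property
    def taxa(self) -> pd.Index:
        return self.r.index

    @property
    def factors(self) -> pd.Index:
        return self.r.columns

    def to_csv(self, r_path, p_path) -> None:
        self.r.to_csv(r_path)
        self.p.to_csv(p_path)

    @classmethod
    def from_csv(cls, r_path, p_path) -> "CorrelationScreen":
        r = pd.read_csv(r_path, index_col=0)
        p = pd.read_csv(p_path, index_col=0)
        return cls(r, p, n_obs=-1, n_subjects=-1)


def root_transform(values, k: int = 10):
    """Elementwise k-th root (default 10th) of non-negative values."""
    v = np.asarray(values, dtype=float)
    if np.nanmin(v, initial=0.0) < 0:
        raise ValueError("root transform requires non-negative input")
    out = v ** (1.0 / k)
    return out


def _p_from_r(r: np.ndarray, df) -> np.ndarray:
    rr = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(df / np.maximum(1.0 - rr**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def rmcorr(subject_ids, x, y) -> RmCorrResult:
    """Repeated-measures correlation between paired measurements x and y.

    Incomplete pairs are dropped; every remaining subject must contribute at
    least two complete pairs and there must be at least two subjects.
    """
    subj = np.asarray(subject_ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(subj) == len(x) == len(y)):
        raise ValueError("subject_ids, x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    subj, x, y = subj[ok], x[ok], y[ok]

    codes, counts = np.unique(subj, return_counts=True)
    keep = np.isin(subj, codes[counts >= 2])
    subj, x, y = subj[keep], x[keep], y[keep]
    codes = np.unique(subj)
    k = len(codes)
    n = len(x)
    if k < 2:
        raise ValueError("rmcorr requires >= 2 subjects with >= 2 complete pairs each")
    idx = np.searchsorted(codes, subj)
    xc = x - np.bincount(idx, weights=x)[idx] / np.bincount(idx)[idx]
    yc = y - np.bincount(idx, weights=y)[idx] / np.bincount(idx)[idx]
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= 0 or syy <= 0:
        raise ValueError("zero within-subject variance; rmcorr undefined")
    r = float(xc @ yc / np.sqrt(sxx * syy))
    df = n - k - 1
    if df < 1:
        raise ValueError("insufficient degrees of freedom for rmcorr")
    p = float(_p_from_r(r, df))
    return RmCorrResult(r=r, df=df, p=p, n_obs=n, n_subjects=k)


def _center_by_subject(M: np.ndarray, idx: np.ndarray, k: int) -> np.ndarray:
    counts = np.bincount(idx, minlength=k).astype(float)
    sums = np.zeros((k, M.shape[1]))
    np.add.at(sums, idx, M)
    return M - (sums / counts[:, None])[idx]


def screen(
    taxa_matrix: pd.DataFrame,
    factor_table: pd.DataFrame,
    subject_ids,
    root_k: int | None = 10,
    skip_root: tuple[str, ...] = ("GBI", "MGI"),
) -> CorrelationScreen:
    """Repeated-measures correlation of every taxon against every factor.

    Parameters
    ----------
    taxa_matrix : DataFrame
        Samples x taxa (absolute biomass by default in the pipeline).
    factor_table : DataFrame
        Samples x factors, aligned row-wise with ``taxa_matrix``.
    subject_ids : array-like
        Subject of each sample row.
    root_k : int or None
        Apply the k-th root transform to taxa and to factors not listed in
        ``skip_root``; None disables the transform entirely.

    P-values are reported without adjustment for multiple comparisons.
    """
    if len(taxa_matrix) != len(factor_table):
        raise ValueError("taxa and factor tables must be row-aligned")
    X = taxa_matrix.to_numpy(dtype=float)
    F = factor_table.to_numpy(dtype=float).copy()
    if root_k is not None:
        X = root_transform(X, root_k)
        for j, name in enumerate(factor_table.columns):
            if name not in skip_root:
                F[:, j] = root_transform(F[:, j], root_k)

    subj = np.asarray(subject_ids)
    if np.isnan(X).any() or np.isnan(F).any():
        # incomplete pairs: fall back to pairwise complete-case rmcorr
        r = np.full((X.shape[1], F.shape[1]), np.nan)
        p = np.full_like(r, np.nan)
        n_obs = n_subj = 0
        for i in range(X.shape[1]):
            for j in range(F.shape[1]):
                try:
                    res = rmcorr(subj, X[:, i], F[:, j])
                except ValueError:
                    continue
                r[i, j], p[i, j] = res.r, res.p
                n_obs, n_subj = res.n_obs, res.n_subjects
    else:
        codes = np.unique(subj)
        idx = np.searchsorted(codes, subj)
        k = len(codes)
        Xc = _center_by_subject(X, idx, k)
        Fc = _center_by_subject(F, idx, k)
        sx = np.sqrt((Xc**2).sum(axis=0))
        sf = np.sqrt((Fc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc.T @ Fc) / np.outer(sx, sf)
        df = len(X) - k - 1
        p = _p_from_r(r, df)
        n_obs, n_subj = len(X), k
    rdf = pd.DataFrame(r, index=taxa_matrix.columns, columns=factor_table.columns)
    pdf = pd.DataFrame(p, index=taxa_matrix.columns, columns=factor_table.columns)
    return CorrelationScreen(rdf, pdf, n_obs=n_obs, n_subjects=n_subj)


def rmcorr_matrix(
    matrix: pd.DataFrame, subject_ids, root_k: int | None = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric taxon-taxon repeated-measures r and p matrices."""
    sc = screen(matrix, matrix, subject_ids, root_k=root_k, skip_root=())
    r = sc.r
    p = sc.p
    np.fill_diagonal(r.values, 1.0)
    np.fill_diagonal(p.values, 0.0)
    return r, p
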