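"""Covariate adjustment, outlier screening and the dispersion transform.

Each trait is adjusted by ordinary least squares for the SNP's genotype
(two dummy variables) and the covariates; the squared deviation of each
residual from its trait-wise *median* is the dispersion measure the scale
tests operate on.  The median is used instead of the mean for robustness,
as in the Brown-Forsythe variant of Levene's test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CollinearityError
from .data_io import SampleTable


@dataclass
class ResidualMatrix:
    """n x K matrix of per-trait OLS residuals plus their column medians."""

    e: np.ndarray
    medians: np.ndarray
    trait_names: list[str]


@dataclass
class DispersionMatrix:
    """n x K matrix D with D[i, k] = (e[i, k] - median_k)**2."""

    D: np.ndarray
    trait_names: list[str]

    @property
    def n(self) -> int:
        return self.D.shape[0]

    @property
    def K(self) -> int:
        return self.D.shape[1]


def _check_rank(design: np.ndarray, names: Sequence[str]) -> None:
    """Raise CollinearityError naming the first linearly dependent column."""
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1:
            raise CollinearityError(names[j])
    raise CollinearityError(names[-1])


def _ols_residuals(y: np.ndarray, design: np.ndarray,
                   names: Sequence[str]) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        _check_rank(design, names)
    return y - design @ beta


def build_design(n: int, dummies: np.ndarray | None = None,
                 X: np.ndarray | None = None) -> tuple[np.ndarray, list[str]]:
    """Assemble [1 | genotype dummies | covariates] with column names."""
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    if dummies is not None and dummies.size:
        cols.append(np.atleast_2d(dummies.T).T)
        names += [f"G{j + 1}" for j in range(cols[-1].shape[1])]
    if X is not None and np.size(X):
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        cols.append(X)
        names += [f"X{j + 1}" for j in range(X.shape[1])]
    return np.hstack(cols), names


def fit_mean_model(y: np.ndarray, dummies: np.ndarray | None,
                   X: np.ndarray | None = None,
                   names: Sequence[str] | None = None) -> np.ndarray:
    """Residuals of one trait regressed on [1, G1, G2, covariates].

    ``dummies`` holds one column per non-reference genotype group (one
    column when only two groups are observed); the intercept is always
    included.  Raises :class:`CollinearityError` for rank-deficient designs,
    naming the offending column.
    """
    y = np.asarray(y, dtype=float)
    design, auto_names = build_design(y.size, dummies, X)
    return _ols_residuals(y, design, list(names) if names else auto_names)


def residualize(Y: np.ndarray, dummies: np.ndarray | None,
                X: np.ndarray | None = None,
                trait_names: Sequence[str] | None = None) -> ResidualMatrix:
    """Column-wise OLS residuals of an n x K trait matrix on one design."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    design, names = build_design(Y.shape[0], dummies, X)
    e = _ols_residuals(Y, design, names)
    tn = list(trait_names) if trait_names else [f"trait{k+1}" for k in range(Y.shape[1])]
    return ResidualMatrix(e=e, medians=np.median(e, axis=0), trait_names=tn)


def residualize_covariates_only(table: SampleTable) -> ResidualMatrix:
    """Per-trait residuals on [1, covariates] only (no genotype terms).

    Used for the single outlier-screening pass: exclusion happens once per
    trait set, not per SNP.  Rows with any missing trait or covariate are
    excluded from the fit and carry NaN residuals.
    """
    Y = table.Y.to_numpy(dtype=float)
    X = table.X.to_numpy(dtype=float) if table.X.shape[1] else None
    complete = ~np.isnan(Y).any(axis=1)
    if X is not None:
        complete &= ~np.isnan(X).any(axis=1)
    e = np.full_like(Y, np.nan)
    names = ["intercept"] + list(table.X.columns)
    design, _ = build_design(int(complete.sum()),
                             X=X[complete] if X is not None else None)
    e[complete] = _ols_residuals(Y[complete], design, names)
    med = np.nanmedian(e, axis=0) if complete.any() else np.full(Y.shape[1], np.nan)
    return ResidualMatrix(e=e, medians=med, trait_names=list(table.Y.columns))


def covariates_for_domain(table: SampleTable, traits: Sequence[str],
                          bmi_col: str = "BMI",
                          obesity_domain: str = "obesity") -> list[str]:
    """Covariate columns to adjust for when analysing ``traits``.

    BMI is a default covariate but is dropped whenever any analysed trait
    belongs to the obesity domain — adjusting an adiposity trait for BMI
    would remove the signal under study.
    """
    names = list(table.X.columns)
    if bmi_col in names and any(table.domain_labels.get(t) == obesity_domain
                                for t in traits):
        names.remove(bmi_col)
    return names


def remove_outliers(R: ResidualMatrix, k_sd: float = 5.0) -> np.ndarray:
    """Boolean keep-mask excluding samples > k_sd SDs from the mean on ANY trait.

    A single pass: the mean and SD are computed once over the input
    residuals and the mask is not re-iterated.  NaN residuals (samples not
    in the fit) are excluded as well.
    """
    e = R.e
    mean = np.nanmean(e, axis=0)
    sd = np.nanstd(e, axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        outlying = np.abs(e - mean) > k_sd * sd
    return ~(outlying.any(axis=1) | np.isnan(e).any(axis=1))


def dispersion(R: ResidualMatrix) -> DispersionMatrix:
    """Median-centered squared residuals D[i, k] = (e[i, k] - med_k)^2.

    The median is numpy's interpolated (midpoint) median for even n.
    """
    med = np.median(R.e, axis=0)
    return DispersionMatrix(D=(R.e - med) ** 2, trait_names=R.trait_names)
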