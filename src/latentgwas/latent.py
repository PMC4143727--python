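"""Liability-scale latent genotype preprocessing.

An observed dosage X_ij in {0,1,2} is treated as a categorised version of a
standard-normal liability U_ij: category boundaries are the normal quantiles of
the genotype-category probabilities (by default the Hardy-Weinberg expansion of
the minor allele frequency).  The preprocessing replaces each dosage with the
conditional mean of the liability given its category, Uhat = E[U | X], then
removes linkage-disequilibrium correlation per block with Zhat = C^-1 Uhat
(or the whitening alternative C^-1/2 Uhat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import norm

from .io import DataError

DECORRELATE_MODES = ("inverse", "inv_sqrt")


@dataclass
class LiabilityThresholds:
    """Standard-normal cut points of the three genotype categories.

    t1 : upper bound of the dosage-0 category (Phi(t1) = p0)
    t2 : upper bound of the dosage-1 category (Phi(t2) = p0 + p1)
    """

    t1: float
    t2: float
    category_probs: tuple[float, float, float]

    def interval(self, genotype: int) -> tuple[float, float]:
        """Liability interval (a, b] of a genotype category."""
        return ((-np.inf, self.t1), (self.t1, self.t2), (self.t2, np.inf))[genotype]


@dataclass
class LatentGenotypes:
    """Per-block latent-genotype bundle: Uhat, correlation C and decorrelated Zhat."""

    U_hat: np.ndarray
    C: np.ndarray
    Z_hat: np.ndarray
    mode: str
    shrinkage: float


def hwe_category_probs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2) at allele frequency q."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    q = float(maf)
    return ((1 - q) ** 2, 2 * q * (1 - q), q * q)


def liability_thresholds(probs) -> LiabilityThresholds:
    """Normal quantile cut points for given category probabilities."""
    p0, p1, p2 = (float(v) for v in probs)
    if min(p0, p1, p2) < 0:
        raise ValueError("category probabilities must be non-negative")
    if abs(p0 + p1 + p2 - 1.0) > 1e-9:
        raise ValueError("category probabilities must sum to 1")
    t1 = norm.ppf(p0)  # ppf(0) = -inf, ppf(1) = +inf
    t2 = norm.ppf(p0 + p1)
    return LiabilityThresholds(t1=float(t1), t2=float(t2), category_probs=(p0, p1, p2))


def truncated_normal_mean(a: float, b: float) -> float:
    """Mean of a standard normal truncated to (a, b): (phi(a) - phi(b)) / (Phi(b) - Phi(a))."""
    if not a < b:
        raise ValueError("require a < b")
    # evaluate the mass in the tail that loses less precision
    if a >= 0:
        mass = norm.sf(a) - norm.sf(b)
    else:
        mass = norm.cdf(b) - norm.cdf(a)
    if mass <= 0:
        raise FloatingPointError(f"zero probability mass on ({a}, {b})")
    num = (0.0 if np.isinf(a) else norm.pdf(a)) - (0.0 if np.isinf(b) else norm.pdf(b))
    return float(num / mass)


def empirical_category_probs(x_col) -> tuple[float, float, float]:
    """Observed genotype category frequencies of one dosage column."""
    x = np.asarray(x_col)
    n = x.size
    return tuple(float((x == k).sum()) / n for k in (0, 1, 2))


def conditional_liability(X_block: np.ndarray, thresholds: list[LiabilityThresholds]) -> np.ndarray:
    """Map each dosage to the conditional liability mean of its category, Uhat = E[U|X]."""
    X_block = np.asarray(X_block)
    n, p = X_block.shape
    if len(thresholds) != p:
        raise ValueError("one LiabilityThresholds required per SNP column")
    U = np.empty((n, p), dtype=float)
    for j, th in enumerate(thresholds):
        col = X_block[:, j]
        means = np.full(3, np.nan)
        for k in np.unique(col):
            a, b = th.interval(int(k))
            try:
                means[int(k)] = truncated_normal_mean(a, b)
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"SNP column {j}: genotype {int(k)} observed but its liability "
                    f"category has zero probability"
                ) from exc
        U[:, j] = means[col.astype(np.intp)]
    return U


def sample_correlation(M: np.ndarray, shrinkage: float = 0.0) -> np.ndarray:
    """Shrunk Pearson correlation of columns: (1 - lambda) R + lambda I."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise DataError("need at least 2 samples for a sample correlation")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    if np.any(M.std(axis=0) == 0):
        j = int(np.flatnonzero(M.std(axis=0) == 0)[0])
        raise DataError(f"zero-variance column {j}; filter monomorphic SNPs first")
    R = np.corrcoef(M, rowvar=False)
    R = np.atleast_2d(R)
    C = (1.0 - shrinkage) * R + shrinkage * np.eye(R.shape[0])
    return (C + C.T) / 2.0


def decorrelate(U_hat: np.ndarray, C: np.ndarray, mode: str = "inverse") -> np.ndarray:
    """Remove LD correlation from the latent genotypes.

    mode='inverse'  : each row z_i solves C z_i = u_i  (Zhat = Uhat C^-1, rows)
    mode='inv_sqrt' : z_i = C^-1/2 u_i with the symmetric square root (whitening)
    """
    if mode not in DECORRELATE_MODES:
        raise ValueError(f"mode must be one of {DECORRELATE_MODES}")
    U_hat = np.asarray(U_hat, dtype=float)
    C = np.asarray(C, dtype=float)
    try:
        if mode == "inverse":
            cho = linalg.cho_factor(C)
            return linalg.cho_solve(cho, U_hat.T).T
        w, Q = linalg.eigh(C)
        if w.min() <= 0:
            raise linalg.LinAlgError("non-positive eigenvalue")
        inv_sqrt = (Q / np.sqrt(w)) @ Q.T
        return U_hat @ inv_sqrt  # symmetric, so right-multiplication acts on rows
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; increase the shrinkage lambda"
        ) from exc


def latent_block(X_block: np.ndarray, maf_block: np.ndarray, shrinkage: float = 0.1,
                 mode: str = "inverse", probs: str = "hwe") -> LatentGenotypes:
    """Full per-block preprocessing: thresholds -> Uhat -> C -> Zhat.

    probs='hwe' derives category probabilities from the MAF under
    Hardy-Weinberg equilibrium; probs='empirical' uses the observed genotype
    frequencies (guaranteed to give every observed category positive mass).
    """
    X_block = np.asarray(X_block)
    if probs == "hwe":
        th = [liability_thresholds(hwe_category_probs(q)) for q in np.asarray(maf_block)]
    elif probs == "empirical":
        th = [liability_thresholds(empirical_category_probs(X_block[:, j]))
              for j in range(X_block.shape[1])]
    else:
        raise ValueError("probs must be 'hwe' or 'empirical'")
    U_hat = conditional_liability(X_block, th)
    if X_block.shape[1] == 1:
        C = np.eye(1)
    else:
        C = sample_correlation(U_hat, shrinkage=shrinkage)
    Z_hat = decorrelate(U_hat, C, mode=mode)
    return LatentGenotypes(U_hat=U_hat, C=C, Z_hat=Z_hat, mode=mode, shrinkage=shrinkage)
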