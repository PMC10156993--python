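"""Occurrence frequencies, gene-flow conversion, Mantel test, t comparison,
and PCA-based covariate selection.

The Mantel test is implemented from first principles: Pearson correlation of
the upper-triangle entries of two labelled distance matrices, with a null
distribution built by jointly permuting the rows and columns of the second
matrix. An exact mode enumerates all n! permutations for small n.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DistanceMatrix

__all__ = [
    "of_site",
    "of_sample",
    "gene_flow",
    "gene_flow_matrix",
    "GeneFlowSummary",
    "mantel",
    "MantelResult",
    "one_sample_t",
    "two_sample_t",
    "TTestResult",
    "pca_select",
    "PCASelection",
]

logger = logging.getLogger(__name__)


def of_site(n: int, N: int) -> float:
    """Site occurrence frequency: percentage of sites where the species occurs.

    ``n`` occupied sites out of ``N`` surveyed; returns 100·n/N.
    """
    if N <= 0:
        raise ValueError("total site count N must be positive")
    if not 0 <= n <= N:
        raise ValueError(f"occupied count n={n} must lie in [0, N={N}]")
    return 100.0 * n / N


def of_sample(s: int, S: int) -> float:
    """Within-site sample occurrence frequency: 100·s/S positive samples."""
    if S <= 0:
        raise ValueError("total sample count S must be positive")
    if not 0 <= s <= S:
        raise ValueError(f"positive count s={s} must lie in [0, S={S}]")
    return 100.0 * s / S


def gene_flow(theta: float, M: float, x: float = 4.0) -> float:
    """Effective migrants per generation: Nm = θ·M/x.

    θ is the mutation-scaled effective population size of the receiving
    population, M the mutation-scaled immigration rate, and x the fixation
    factor (4 for nuclear loci, 1 for haploid/organellar loci).
    """
    if x <= 0:
        raise ValueError("fixation factor x must be positive")
    if theta < 0 or M < 0:
        raise ValueError("theta and M must be non-negative")
    return theta * M / x


@dataclass
class GeneFlowSummary:
    """Per-pair Nm values with mean/sd of the off-diagonal entries."""

    nm: pd.DataFrame  # rows = source, columns = receiving population
    mean: float
    sd: float
    min_pair: tuple[str, str]
    max_pair: tuple[str, str]


def gene_flow_matrix(theta: pd.Series | dict, M: pd.DataFrame,
                     x: float = 4.0) -> GeneFlowSummary:
    """Nm over all ordered population pairs: Nm(i→j) = θ_j · M(i→j) / x.

    ``M`` is indexed by source (rows) and receiving (columns) population;
    the receiving population's θ scales each entry, following the
    coalescent-migration convention. The diagonal is ignored. Summary mean
    and standard deviation (population sd) cover the off-diagonal entries.
    """
    theta = pd.Series(theta, dtype=float)
    M = M.astype(float)
    if list(M.index) != list(M.columns):
        raise ValueError("migration matrix must have identical row/column labels")
    missing = set(M.columns) - set(theta.index)
    if missing:
        raise ValueError(f"theta missing for populations: {sorted(missing)}")
    if x <= 0:
        raise ValueError("fixation factor x must be positive")
    nm = M.mul(theta[M.columns], axis="columns") / x
    labels = list(M.columns)
    off = np.array([nm.loc[i, j] for i in labels for j in labels if i != j])
    pairs = [(i, j) for i in labels for j in labels if i != j]
    return GeneFlowSummary(
        nm=nm,
        mean=float(off.mean()),
        sd=float(off.std(ddof=0)),
        min_pair=pairs[int(np.argmin(off))],
        max_pair=pairs[int(np.argmax(off))],
    )


@dataclass
class MantelResult:
    """Mantel correlation between two distance matrices."""

    r: float
    p_value: float
    n_perm: int
    method: str
    n: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"MantelResult(r={self.r:.4f}, p={self.p_value:.4g}, "
                f"n={self.n}, n_perm={self.n_perm}, method={self.method!r})")


def _triangle_r(v1: np.ndarray, m2: np.ndarray, iu) -> float:
    return float(np.corrcoef(v1, m2[iu])[0, 1])


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None, method: str = "monte-carlo") -> MantelResult:
    """Two-sided Mantel test of matrix correlation.

    r is the Pearson correlation of the upper-triangle entries after aligning
    ``d2`` to ``d1``'s label order. The permutation null jointly permutes the
    rows and columns of ``d2``. With ``method="exact"`` all n! permutations
    are enumerated (small n only) and p is the exact fraction with
    |r_perm| ≥ |r_obs|; the Monte-Carlo p uses the standard add-one rule
    p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm).
    """
    if set(d1.labels) != set(d2.labels):
        raise ValueError("distance matrices must carry identical label sets")
    n = len(d1)
    if n < 3:
        raise ValueError("Mantel test requires at least 3 objects")
    d2 = d2.reorder(d1.labels)
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    v2 = d2.values[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("Mantel r undefined: zero variance in a distance triangle")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    m2 = d2.values
    if method == "exact":
        total = math.factorial(n)
        hits = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            r_p = _triangle_r(v1, m2[np.ix_(idx, idx)], iu)
            if abs(r_p) >= abs(r_obs) - 1e-12:
                hits += 1
        return MantelResult(r=r_obs, p_value=hits / total, n_perm=total,
                            method="exact", n=n)
    if method != "monte-carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_p = _triangle_r(v1, m2[np.ix_(idx, idx)], iu)
        if abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, method="monte-carlo", n=n)


@dataclass
class TTestResult:
    """Student's t comparison result.

    ``mean_diff`` is the discrepancy (sample mean − reference, or difference
    of group means); ``t`` is signed, ``abs_t`` its magnitude.
    """

    t: float
    df: float
    mean_diff: float
    p_value: float

    @property
    def abs_t(self) -> float:
        return abs(self.t)


def one_sample_t(values, mu0: float) -> TTestResult:
    """One-sample two-sided t-test of mean(values) against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("t-test requires at least two observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("t statistic undefined: sample variance is zero")
    res = sps.ttest_1samp(x, popmean=mu0)
    return TTestResult(t=float(res.statistic), df=float(x.size - 1),
                       mean_diff=float(x.mean() - mu0), p_value=float(res.pvalue))


def two_sample_t(a, b, equal_var: bool = True) -> TTestResult:
    """Independent two-sample t-test (provided for completeness; the unit
    comparison uses the one-sample form by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test requires at least two observations per group")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(a.size + b.size - 2)
    else:  # Welch–Satterthwaite
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = float((va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1)))
    return TTestResult(t=float(res.statistic), df=df,
                       mean_diff=float(a.mean() - b.mean()), p_value=float(res.pvalue))


@dataclass
class PCASelection:
    """Covariates chosen as max-|loading| representatives of leading PCs."""

    selected: list[str]
    loadings: pd.DataFrame  # covariates × components
    explained_variance_ratio: np.ndarray


def pca_select(table: pd.DataFrame, k: int = 4) -> PCASelection:
    """Pick one representative covariate per leading principal component.

    Covariates are standardised (PCA on the correlation matrix); for each of
    the first ``k`` components the covariate with the largest absolute
    loading is selected, skipping covariates already chosen, yielding ``k``
    distinct names. Constant covariates are dropped with a warning.
    """
    table = table.select_dtypes(include=[np.number])
    constant = [c for c in table.columns if table[c].std(ddof=0) == 0]
    if constant:
        logger.warning("dropping constant covariate(s) before PCA: %s", constant)
        table = table.drop(columns=constant)
    names = list(table.columns)
    if len(names) < k:
        raise ValueError(f"need at least k={k} non-constant covariates, have {len(names)}")
    if len(table) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} observations, have {len(table)}")
    z = (table - table.mean()) / table.std(ddof=1)
    # SVD of the standardised matrix == eigendecomposition of the correlation matrix
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s ** 2 / (len(table) - 1)
    evr = var / var.sum()
    loadings = pd.DataFrame(vt.T * np.sqrt(var), index=names,
                            columns=[f"PC{i + 1}" for i in range(len(s))])
    selected: list[str] = []
    for i in range(k):
        order = loadings.iloc[:, i].abs().sort_values(ascending=False).index
        for name in order:
            if name not in selected:
                selected.append(name)
                break
    return PCASelection(selected=selected, loadings=loadings,
                        explained_variance_ratio=evr)
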