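"""Community ecology statistics.

Alpha diversity (Shannon in bits, Gini-Simpson, richness), sample
dissimilarity (Jensen-Shannon divergence, Bray-Curtis), classical
principal-coordinate analysis, symmetric Procrustes with a permutation
test (PROTEST), and the within- versus between-producer rank-sum
comparison.

Conventions: abundance matrices are features x samples; Simpson is
reported in Gini-Simpson form 1 - sum(p^2); Shannon defaults to log
base 2 (bits).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DiversityResult",
    "Ordination",
    "ProcrustesResult",
    "alpha_diversity",
    "diversity_table",
    "jensen_shannon",
    "bray_curtis",
    "distance_matrix",
    "pcoa",
    "procrustes_protest",
    "rank_sum_test",
]


@dataclass
class DiversityResult:
    sample_id: str
    shannon: float
    simpson: float  # Gini-Simpson, 1 - sum(p^2)
    richness: int


@dataclass
class Ordination:
    labels: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray


@dataclass
class ProcrustesResult:
    correlation: float  # sqrt(1 - m^2)
    m_squared: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# alpha diversity

def alpha_diversity(
    abundances: np.ndarray | pd.Series, sample_id: str = "", log_base: float = 2.0
) -> DiversityResult:
    """Shannon (log ``log_base``), Gini-Simpson and richness of one sample."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total == 0:
        raise ValueError(f"sample {sample_id or '<unnamed>'} has all-zero abundances")
    p = a / total
    pos = p[p > 0]
    shannon = float(-(pos * (np.log(pos) / math.log(log_base))).sum())
    simpson = float(1.0 - (p**2).sum())
    return DiversityResult(sample_id, shannon, simpson, int((a > 0).sum()))


def diversity_table(counts: pd.DataFrame, log_base: float = 2.0) -> pd.DataFrame:
    """Alpha diversity per sample (column) of a features x samples matrix."""
    rows = []
    for sample in counts.columns:
        r = alpha_diversity(counts[sample].to_numpy(), sample, log_base)
        rows.append(
            {"sample_id": sample, "shannon": r.shannon, "simpson": r.simpson, "richness": r.richness}
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# dissimilarity

def jensen_shannon(p, q, log_base: float = 2.0) -> float:
    """Jensen-Shannon divergence (not its square root).

    Inputs are renormalized to probability vectors; in base 2 the
    divergence lies in [0, 1], reaching 1 on disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be nonnegative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("cannot normalize an all-zero vector")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    def _kl(x, y):
        mask = x > 0
        return float((x[mask] * np.log(x[mask] / y[mask])).sum())
    return (0.5 * _kl(p, m) + 0.5 * _kl(q, m)) / math.log(log_base)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum(x)+sum(y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundance vectors must be nonnegative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def distance_matrix(
    counts: pd.DataFrame,
    metric: str = "jsd",
    log_base: float = 2.0,
    sqrt_jsd: bool = False,
) -> pd.DataFrame:
    """Square sample-by-sample dissimilarity matrix of a features x
    samples abundance table; ``metric`` is "jsd" or "braycurtis"."""
    samples = list(counts.columns)
    n = len(samples)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        x = counts.iloc[:, i].to_numpy()
        y = counts.iloc[:, j].to_numpy()
        if metric == "jsd":
            v = jensen_shannon(x, y, log_base)
            if sqrt_jsd:
                v = math.sqrt(v)
        elif metric == "braycurtis":
            v = bray_curtis(x, y)
        else:
            raise ValueError(f"unknown metric: {metric}")
        d[i, j] = d[j, i] = v
    return pd.DataFrame(d, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# ordination

def pcoa(d: pd.DataFrame, eig_tol: float = 1e-10) -> Ordination:
    """Classical scaling (principal-coordinate analysis).

    Double-centers -d^2/2, eigendecomposes, and keeps axes with
    eigenvalue > ``eig_tol`` (negative axes are dropped; a note is
    emitted when negative inertia exceeds 5% of positive inertia).
    Axis signs are fixed so each axis's first nonzero loading is
    positive.
    """
    values = d.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = values.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (values**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    neg = -eigvals[eigvals < 0].sum()
    pos = eigvals[eigvals > 0].sum()
    if pos > 0 and neg > 0.05 * pos:
        warnings.warn(
            f"negative inertia is {100 * neg / pos:.1f}% of positive inertia; "
            "consider the sqrt-JSD metric",
            stacklevel=2,
        )
    keep = eigvals > eig_tol
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    coords = eigvecs * np.sqrt(eigvals)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return Ordination(list(d.index), coords, eigvals)


def _procrustes_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes correlation of two centered, unit-scaled
    configurations: sum of singular values of X'Y."""
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(min(s.sum(), 1.0))


def _center_scale(m: np.ndarray) -> np.ndarray:
    c = m - m.mean(axis=0, keepdims=True)
    norm = np.sqrt((c**2).sum())
    if norm == 0:
        raise ValueError("degenerate (all-identical) configuration")
    return c / norm


def procrustes_protest(
    x: Ordination | np.ndarray,
    y: Ordination | np.ndarray,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes comparison of two ordinations (PROTEST).

    Both configurations are centered and scaled to unit sum of squares;
    the optimal rotation gives m^2 = 1 - (sum of singular values)^2 and
    correlation sqrt(1 - m^2).  The p-value permutes the row (sample)
    assignment of the second configuration, with the add-one estimator,
    so the smallest attainable p is 1/(n_permutations+1).
    """
    xm = x.coordinates if isinstance(x, Ordination) else np.asarray(x, dtype=float)
    ym = y.coordinates if isinstance(y, Ordination) else np.asarray(y, dtype=float)
    if isinstance(x, Ordination) and isinstance(y, Ordination) and x.labels != y.labels:
        raise ValueError("ordinations must share sample labels in the same order")
    if xm.shape[0] != ym.shape[0]:
        raise ValueError("configurations must have the same number of samples")
    if xm.shape[0] < 3:
        raise ValueError("need at least 3 samples for Procrustes")
    rank = min(xm.shape[1], ym.shape[1])
    xm = _center_scale(xm[:, :rank])
    ym = _center_scale(ym[:, :rank])
    observed = _procrustes_correlation(xm, ym)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ym.shape[0])
        # strict exceedance: a permutation that reproduces the observed
        # labelling (e.g. the identity, drawn with probability 1/n!) is
        # already represented by the add-one term
        if _procrustes_correlation(xm, ym[perm]) > observed + 1e-9:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return ProcrustesResult(
        correlation=observed,
        m_squared=1.0 - observed**2,
        p_value=p,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# rank-sum comparison

def rank_sum_test(within, between, exact_max_n: int = 12) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Exact enumeration of all label assignments when the pooled size is
    at most ``exact_max_n`` (ties handled through average ranks);
    normal approximation with tie correction otherwise.
    """
    w = np.asarray(within, dtype=float)
    b = np.asarray(between, dtype=float)
    n1, n2 = len(w), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([w, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2
    if n1 + n2 <= exact_max_n:
        total = 0
        hits = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                hits += 1
        return hits / total
    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var_u == 0:
        return 1.0
    from scipy.stats import norm

    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)  # continuity correction
    return float(2 * norm.sf(max(z, 0.0)))
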