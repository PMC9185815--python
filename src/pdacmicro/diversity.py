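"""Alpha diversity (rarefied Hill numbers), Bray-Curtis beta diversity and
single-factor PERMANOVA with optional permutation strata.

Hill numbers give the effective number of taxa at order q: q=0 is richness,
q=1 the exponential of Shannon entropy, q=2 the inverse Simpson index; they
are non-increasing in q.  Rarefaction draws reads without replacement
(multivariate hypergeometric) to a common depth and averages over iterations,
removing the depth dependence of richness.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "hill_number",
    "hill_diversity",
    "evenness",
    "bray_curtis",
    "PermanovaResult",
    "permanova",
]


def hill_number(counts: np.ndarray, q: int) -> float:
    """Effective number of taxa of a single community at order q in {0, 1, 2}."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2:
        return float(1.0 / np.sum(p**2))
    raise ValueError("q must be 0, 1 or 2")


def hill_diversity(
    counts: pd.DataFrame,
    q: int,
    depth: int | None = None,
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefied Hill diversity per sample (taxa x samples count table).

    Each iteration subsamples ``depth`` reads without replacement and computes
    the Hill number; the reported value is the mean over ``n_iter``
    iterations.  Samples with fewer than ``depth`` reads are skipped with a
    warning.  ``depth`` defaults to the minimum sample depth.
    """
    colsums = counts.sum(axis=0).to_numpy()
    if depth is None:
        depth = int(colsums.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    mat = counts.to_numpy(dtype=np.int64)
    for s, sample in enumerate(counts.columns):
        if colsums[s] < depth:
            warnings.warn(f"sample {sample} has fewer than {depth} reads; skipped",
                          stacklevel=2)
            continue
        vals = [
            hill_number(rng.multivariate_hypergeometric(mat[:, s], depth), q)
            for _ in range(n_iter)
        ]
        rows.append({"sample_id": sample, "q": q, "value": float(np.mean(vals)),
                     "rarefaction_depth": depth, "n_iterations": n_iter})
    return pd.DataFrame(rows)


def evenness(counts: pd.DataFrame, q: int, **kwargs) -> pd.DataFrame:
    """Evenness as the ratio Hill(q)/Hill(0) of rarefied diversities (q in {1, 2})."""
    if q not in (1, 2):
        raise ValueError("evenness is defined here for q in {1, 2}")
    hq = hill_diversity(counts, q, **kwargs).set_index("sample_id")["value"]
    h0 = hill_diversity(counts, 0, **kwargs).set_index("sample_id")["value"]
    out = (hq / h0).rename("evenness").reset_index()
    out["q"] = q
    return out


def bray_curtis(table: pd.DataFrame, sqrt_transform: bool = False) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample columns, optionally on
    square-root transformed values.  A pair of all-zero samples gets distance
    0 (with a warning) rather than NaN."""
    x = table.to_numpy(dtype=float).T
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    if sqrt_transform:
        x = np.sqrt(x)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair; distance set to 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


@dataclass(frozen=True)
class PermanovaResult:
    R2: float
    F: float
    p: float
    n_perm: int
    strata_label: str | None = None


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(F, R2) from squared distances for one labelling.

    Uses the classical partition: SS_total = sum_{i<j} d_ij^2 / n and
    SS_within = sum over groups of within-group pairwise d^2 / group size.
    """
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        if ng:
            ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    ss_between = ss_total - ss_within
    F = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return float(F), float(ss_between / ss_total)


def permanova(
    dist: pd.DataFrame,
    grouping,
    strata=None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Single-factor PERMANOVA on a distance matrix.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``; permutations shuffle the
    group labels, restricted to *within* each stratum when ``strata`` is
    given, so stratum-wise label multisets are invariant.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = np.asarray(pd.Series(list(grouping)).astype(str))
    if len(labels) != d.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("grouping must have at least two levels")
    d2 = d**2
    f_obs, r2 = _permanova_stats(d2, codes, len(uniq))

    if strata is not None:
        strata = np.asarray(pd.Series(list(strata)).astype(str))
        if len(strata) != len(labels):
            raise ValueError("strata length does not match grouping")
        blocks = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    else:
        blocks = [np.arange(len(labels))]

    rng = np.random.default_rng(seed)
    hits = 0
    perm = np.arange(len(labels))
    for _ in range(n_perm):
        for idx in blocks:
            perm[idx] = rng.permutation(idx)
        f_p, _ = _permanova_stats(d2, codes[perm], len(uniq))
        if f_p >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(R2=r2, F=f_obs, p=float(p), n_perm=n_perm,
                           strata_label=None if strata is None else "strata")


def permanova_exact(dist: pd.DataFrame, grouping) -> PermanovaResult:
    """Exhaustive-permutation PERMANOVA for very small samples (n <= 9)."""
    d = dist.to_numpy(dtype=float)
    labels = np.asarray(pd.Series(list(grouping)).astype(str))
    uniq, codes = np.unique(labels, return_inverse=True)
    d2 = d**2
    f_obs, r2 = _permanova_stats(d2, codes, len(uniq))
    n = len(codes)
    if n > 9:
        raise ValueError("exhaustive enumeration limited to n <= 9")
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        f_p, _ = _permanova_stats(d2, codes[list(perm)], len(uniq))
        total += 1
        if f_p >= f_obs:
            hits += 1
    return PermanovaResult(R2=r2, F=f_obs, p=hits / total, n_perm=total)
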