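"""Permutation tests (plain and stratified), Spearman correlation and
per-animal morphometric summaries.

The two-sample statistic is the difference of group means, two-sided.
When the number of distinct label assignments is small enough the null
distribution is enumerated exactly; otherwise Monte-Carlo sampling is
used with the add-one estimator p = (1 + #{|t*| >= |t|}) / (n_perm + 1),
which never returns zero. The stratified variant permutes labels only
within strata (fixed per-stratum group counts), conditioning out a
confounding factor such as pre/postnatal stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12


@dataclass
class PermTestResult:
    statistic: float           # mean(x) - mean(y)
    p_value: float
    n_perm: object             # int for Monte-Carlo, "exact" for enumeration
    seed: int | None = None
    strata: tuple | None = None
    n_x: int = 0
    n_y: int = 0

    @property
    def exact(self) -> bool:
        return self.n_perm == "exact"


@lru_cache(maxsize=128)
def _choose_indices(n: int, k: int) -> np.ndarray:
    """All k-subsets of range(n) as an array (cached across calls)."""
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def perm_test(x, y, n_perm: int = 100_000, seed: int | None = None,
              exact_limit: int = 200_000) -> PermTestResult:
    """Two-sample permutation test on the difference of means.

    Enumerates all C(n_x + n_y, n_x) label assignments when that count is
    at most ``exact_limit``; otherwise Monte-Carlo samples ``n_perm``
    permutations with the given seed.
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    return _perm_engine([(x, y)], n_perm, seed, exact_limit, strata=None)


def stratified_perm_test(x, y, strata, n_perm: int = 100_000,
                         seed: int | None = None,
                         exact_limit: int = 200_000) -> PermTestResult:
    """Permutation test with label shuffling restricted to strata.

    ``strata`` is aligned with the concatenation of ``x`` then ``y``.
    Strata containing only one group are dropped with a warning; with a
    single stratum the test reduces exactly to :func:`perm_test`.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    strata = np.asarray(strata)
    if len(strata) != len(x) + len(y):
        raise ValueError("strata must align with concat(x, y)")
    sx, sy = strata[:len(x)], strata[len(x):]
    pairs, labels = [], []
    for s in pd.unique(strata):
        xs, ys = _clean(x[sx == s]), _clean(y[sy == s])
        if len(xs) == 0 or len(ys) == 0:
            warnings.warn(f"stratum {s!r} lacks one group; dropped")
            continue
        pairs.append((xs, ys))
        labels.append(s)
    if not pairs:
        raise ValueError("no stratum contains both groups")
    return _perm_engine(pairs, n_perm, seed, exact_limit,
                        strata=tuple(labels))


def _perm_engine(pairs, n_perm, seed, exact_limit, strata) -> PermTestResult:
    """Shared core: pairs is a list of per-stratum (x, y) value arrays."""
    nx = sum(len(p[0]) for p in pairs)
    ny = sum(len(p[1]) for p in pairs)
    obs = (sum(p[0].sum() for p in pairs) / nx
           - sum(p[1].sum() for p in pairs) / ny)

    n_assign = 1
    for px, py in pairs:
        n_assign *= comb(len(px) + len(py), len(px))
        if n_assign > exact_limit:
            break

    if n_assign <= exact_limit:
        # exact: enumerate per-stratum x-sums, combine additively
        sums = np.zeros(1)
        for px, py in pairs:
            pooled = np.concatenate([px, py])
            idx = _choose_indices(len(pooled), len(px))
            stratum_sums = pooled[idx].sum(axis=1)
            sums = (sums[:, None] + stratum_sums[None, :]).ravel()
        total = sum(p[0].sum() + p[1].sum() for p in pairs)
        diffs = sums / nx - (total - sums) / ny
        count = int(np.sum(np.abs(diffs) >= np.abs(obs) - _TIE_EPS))
        p = count / len(diffs)
        return PermTestResult(float(obs), float(p), "exact", seed, strata,
                              nx, ny)

    rng = np.random.default_rng(seed)
    x_sums = np.zeros(n_perm)
    for px, py in pairs:
        pooled = np.concatenate([px, py])
        mat = np.tile(pooled, (n_perm, 1))
        mat = rng.permuted(mat, axis=1)
        x_sums += mat[:, :len(px)].sum(axis=1)
    total = sum(p[0].sum() + p[1].sum() for p in pairs)
    diffs = x_sums / nx - (total - x_sums) / ny
    count = int(np.sum(np.abs(diffs) >= np.abs(obs) - _TIE_EPS))
    p = (1.0 + count) / (n_perm + 1.0)
    return PermTestResult(float(obs), float(p), int(n_perm), seed, strata,
                          nx, ny)


def spearman_corr(x, y):
    """Spearman rank correlation with pairwise deletion of missing pairs.

    Returns (r, p); p is two-sided from the t approximation with n - 2
    degrees of freedom. Constant inputs give (nan, nan) with a warning.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def summarize_morphometry(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean and CV for each histomorphometric parameter.

    ``measurements`` is tidy: columns animal_id, parameter, value, with
    repeated measurements per animal x parameter (>= 2 required). CV is
    the sample standard deviation (n-1) over the mean; it is left missing
    when the mean is zero or negative (the scale quantities measured here
    are positive, so a non-positive mean marks invalid input).
    """
    rows = []
    for (animal, param), grp in measurements.groupby(["animal_id", "parameter"]):
        vals = _clean(grp["value"])
        if len(vals) < 2:
            raise ValueError(
                f"animal {animal!r}, parameter {param!r}: need >= 2 measurements")
        mean = vals.mean()
        if mean <= 0:
            warnings.warn(f"non-positive mean for {animal!r}/{param!r}; CV missing")
            cv = float("nan")
        else:
            cv = vals.std(ddof=1) / mean
        rows.append({"animal_id": animal, "parameter": param,
                     "mean": float(mean), "cv": float(cv), "n": len(vals)})
    return pd.DataFrame(rows)
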