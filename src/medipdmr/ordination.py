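"""Multivariate layer: MCA, rank-PCA, MFA, axis correlations, ellipses.

Three ordinations drive the phenotype/methylome integration:

* MCA — correspondence analysis of the complete disjunctive (indicator)
  coding of the lesion-score table, after merging rare severity
  categories; total inertia is J/Q - 1 for J observed categories over Q
  variables, and variance percentages are reported on raw eigenvalues.
* rank-PCA — PCA on the correlation matrix of rank-converted variables
  (average ranks for ties), which makes the result invariant to any
  strictly monotone transform of the inputs.
* MFA — a global PCA over several variable sets measured on the same
  individuals, each set pre-scaled by the inverse square root of its own
  first eigenvalue so no single set dominates the compromise; a
  categorical illustrative variable is projected as the squared
  correlation ratio (eta^2) of each global axis against its categories.

Axes are oriented so the loading of largest magnitude on each dimension
is positive, making output deterministic across linear-algebra backends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# category merging


def _severity_key(code: str):
    """Order category codes like R0 < R1 < R2 by their numeric suffix."""
    digits = "".join(ch for ch in code if ch.isdigit())
    return (int(digits) if digits else 0, code)


def merge_rare_categories(table: pd.DataFrame, min_count: int = 4) -> pd.DataFrame:
    """Merge observed categories with fewer than ``min_count`` individuals.

    A rare category joins its adjacent observed severity category,
    preferring the next-higher severity (so a rare present-grade never
    collapses into the absent grade when a higher grade exists), else the
    next-lower; merging iterates, rarest first, until every observed
    category reaches ``min_count`` or only one category remains (the
    variable is then dropped with a warning). Merged labels concatenate
    the constituent codes in severity order, e.g. ``S1`` + ``S2`` ->
    ``S1S2``. Unobserved categories never produce a label.
    """
    out = {}
    for col in table.columns:
        values = table[col].dropna()
        groups = [[c] for c in sorted(values.unique(), key=_severity_key)]

        def count(g):
            return int(values.isin(g).sum())

        while len(groups) > 1:
            rare = [i for i, g in enumerate(groups) if count(g) < min_count]
            if not rare:
                break
            i = min(rare, key=lambda j: (count(groups[j]), -j))
            j = i + 1 if i + 1 < len(groups) else i - 1
            merged = sorted(groups[i] + groups[j], key=_severity_key)
            lo, hi = min(i, j), max(i, j)
            groups[lo:hi + 1] = [merged]
        if len(groups) == 1:
            warnings.warn(f"variable {col!r} collapsed to one category; dropped")
            continue
        label = {c: "".join(g) for g in groups for c in g}
        out[col] = table[col].map(label)
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# results containers


@dataclass
class OrdinationResults:
    """Eigen-structure and coordinates of a fitted ordination."""

    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    contributions: pd.DataFrame | None = None
    cos2: pd.DataFrame | None = None
    total_inertia: float | None = None
    method: str = ""

    @property
    def n_dims(self) -> int:
        return len(self.eigenvalues)

    def summary(self) -> str:
        lines = [f"{self.method}: {self.n_dims} dimensions"]
        for s in range(min(5, self.n_dims)):
            lines.append(f"  dim {s + 1}: eigenvalue {self.eigenvalues[s]:.4f}"
                         f"  ({self.pct_variance[s]:.1f}% of variance)")
        return "\n".join(lines)


@dataclass
class MFAResults(OrdinationResults):
    """MFA adds per-set weights/coordinates and an illustrative projection."""

    set_first_eigenvalues: dict = field(default_factory=dict)
    group_coords: pd.DataFrame | None = None
    illustrative_coords: pd.DataFrame | None = None
    var_correlations: pd.DataFrame | None = None


def _orient_axes(row_scores: np.ndarray, loadings: np.ndarray):
    """Flip each axis so its largest-magnitude loading is positive."""
    for s in range(loadings.shape[1]):
        col = loadings[:, s]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            loadings[:, s] = -col
            row_scores[:, s] = -row_scores[:, s]
    return row_scores, loadings


def _dims(k):
    return [f"dim{s + 1}" for s in range(k)]


# ---------------------------------------------------------------------------
# MCA


class MCA:
    """Multiple correspondence analysis of a categorical table.

    Correspondence analysis of the indicator (complete disjunctive)
    matrix; coordinates in principal normalisation, percentages on raw
    eigenvalues (no Benzecri correction).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, table: pd.DataFrame) -> OrdinationResults:
        if table.isna().any().any():
            bad = table.index[table.isna().any(axis=1)].tolist()
            raise ValueError(
                f"missing cells for rows {bad}; remove incomplete rows first")
        if table.shape[1] < 2:
            raise ValueError("MCA needs at least two variables")
        Z = pd.get_dummies(table.astype(str), prefix_sep=".").astype(float)
        n, J = Z.shape
        Q = table.shape[1]
        P = Z.to_numpy() / (n * Q)
        r = np.full(n, 1.0 / n)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        keep = sv > 1e-12
        U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
        eig = sv ** 2
        total = J / Q - 1.0
        row = (U * sv) / np.sqrt(r)[:, None]
        col = (Vt.T * sv) / np.sqrt(c)[:, None]
        row, col = _orient_axes(row, col)
        k = self.n_components or len(eig)
        dims = _dims(len(eig))
        contrib = pd.DataFrame(
            (c[:, None] * col ** 2) / eig[None, :] * 100.0,
            index=Z.columns, columns=dims)
        sqdist = (S ** 2).sum(axis=1) / r  # row chi-square distance to centroid
        with np.errstate(invalid="ignore", divide="ignore"):
            cos2 = pd.DataFrame(row ** 2 / sqdist[:, None],
                                index=table.index, columns=dims)
        return OrdinationResults(
            eigenvalues=eig[:k], pct_variance=(eig / eig.sum() * 100.0)[:k],
            row_coords=pd.DataFrame(row, index=table.index, columns=dims).iloc[:, :k],
            col_coords=pd.DataFrame(col, index=Z.columns, columns=dims).iloc[:, :k],
            contributions=contrib.iloc[:, :k], cos2=cos2.iloc[:, :k],
            total_inertia=total, method="MCA")


def mca(table: pd.DataFrame, n_components: int | None = None) -> OrdinationResults:
    return MCA(n_components).fit(table)


# ---------------------------------------------------------------------------
# rank-PCA


def rank_pca(table: pd.DataFrame, drop: list | None = None) -> OrdinationResults:
    """PCA on the correlation matrix of rank-converted variables.

    Rows with any missing value are excluded (logged); zero-variance
    columns are excluded with a warning. Ties receive average ranks.
    """
    df = table.drop(columns=list(drop or []))
    complete = df.dropna(axis=0)
    if len(complete) < len(df):
        logger.info("rank_pca: excluded %d incomplete rows",
                    len(df) - len(complete))
    keep = complete.std(ddof=0) > 0
    if not keep.all():
        warnings.warn(f"zero-variance columns excluded: "
                      f"{list(complete.columns[~keep])}")
        complete = complete.loc[:, keep]
    if complete.shape[1] < 2:
        raise ValueError("rank_pca needs >= 2 variables with variance")
    ranks = complete.apply(lambda col: stats.rankdata(col, method="average"))
    Z = (ranks - ranks.mean()) / ranks.std(ddof=0)
    n = len(Z)
    U, sv, Vt = np.linalg.svd(Z.to_numpy() / np.sqrt(n), full_matrices=False)
    eig = sv ** 2
    row = np.sqrt(n) * U * sv          # principal scores, var = eigenvalue
    load = Vt.T * sv                   # variable loadings (correlations)
    row, load = _orient_axes(row, load)
    dims = _dims(len(eig))
    return OrdinationResults(
        eigenvalues=eig, pct_variance=eig / eig.sum() * 100.0,
        row_coords=pd.DataFrame(row, index=complete.index, columns=dims),
        col_coords=pd.DataFrame(load, index=complete.columns, columns=dims),
        total_inertia=float(eig.sum()), method="rank-PCA")


# ---------------------------------------------------------------------------
# MFA


class MFA:
    """Multiple factor analysis over named sets of quantitative variables.

    Every variable is centred and unit-scaled; each set's variables are
    then divided by the square root of the set's first PCA eigenvalue,
    and a global PCA of the concatenated weighted matrix yields the
    compromise axes F_s. The coordinate of active set j on dimension s is
    (1/lambda1_j) * sum_k cor^2(x_k, F_s) over the set's variables, which
    lies in [0, 1] and sums to lambda_s over sets. A categorical
    illustrative variable is projected as eta^2(F_s | categories).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, sets: dict, illustrative: pd.Series | None = None) -> MFAResults:
        names = list(sets)
        if not names:
            raise ValueError("MFA needs at least one variable set")
        idx = sets[names[0]].index
        for name in names[1:]:
            if not sets[name].index.equals(idx):
                raise ValueError(f"set {name!r} has mismatched row ids")
        stacked = pd.concat(sets.values(), axis=1, keys=names)
        complete = stacked.dropna(axis=0)
        if len(complete) < len(stacked):
            logger.info("MFA: excluded %d individuals with missing data",
                        len(stacked) - len(complete))
        n = len(complete)
        if n < 3:
            raise ValueError("MFA needs >= 3 complete individuals")

        blocks, lam1 = {}, {}
        for name in names:
            X = complete[name]
            sd = X.std(ddof=0)
            if (sd == 0).any():
                raise ValueError(
                    f"constant variable(s) in set {name!r}: "
                    f"{list(X.columns[sd == 0])}")
            Z = (X - X.mean()) / sd
            sv1 = np.linalg.svd(Z.to_numpy() / np.sqrt(n), compute_uv=False)[0]
            lam1[name] = float(sv1 ** 2)
            blocks[name] = Z / np.sqrt(lam1[name])

        Xw = pd.concat(blocks.values(), axis=1, keys=names)
        U, sv, Vt = np.linalg.svd(Xw.to_numpy() / np.sqrt(n), full_matrices=False)
        keep = sv > 1e-10
        U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
        set_slices = _set_slices(Xw.columns, names)
        U, Vt = _resolve_degenerate_axes(sv, U, Vt, set_slices)
        eig = sv ** 2
        F = np.sqrt(n) * U * sv
        load = Vt.T * sv
        F, load = _orient_axes(F, load)
        dims = _dims(len(eig))
        row_coords = pd.DataFrame(F, index=complete.index, columns=dims)

        # correlation of every (unweighted, standardised) variable with F_s
        corrs = {}
        for name in names:
            Z = (complete[name] - complete[name].mean()) / complete[name].std(ddof=0)
            c = (Z.to_numpy().T @ F) / n / np.sqrt(eig)[None, :]
            corrs[name] = pd.DataFrame(c, index=Z.columns, columns=dims)
        var_corr = pd.concat(corrs, names=["set", "variable"])

        group = pd.DataFrame(
            {name: (corrs[name] ** 2).sum(axis=0) / lam1[name] for name in names}
        ).T
        group.index.name = "set"

        illus = None
        if illustrative is not None:
            cats = illustrative.reindex(complete.index)
            coords = [_eta_squared(F[:, s], cats.to_numpy())
                      for s in range(len(eig))]
            illus = pd.DataFrame([coords], index=[illustrative.name or "group"],
                                 columns=dims)

        k = self.n_components or len(eig)
        return MFAResults(
            eigenvalues=eig[:k], pct_variance=(eig / eig.sum() * 100.0)[:k],
            row_coords=row_coords.iloc[:, :k],
            col_coords=pd.DataFrame(load, index=Xw.columns, columns=dims).iloc[:, :k],
            total_inertia=float(eig.sum()), method="MFA",
            set_first_eigenvalues=lam1, group_coords=group.iloc[:, :k],
            illustrative_coords=None if illus is None else illus.iloc[:, :k],
            var_correlations=var_corr.iloc[:, :k])


def _set_slices(columns: pd.MultiIndex, names: list) -> dict:
    idx = columns.get_level_values(0).to_numpy()
    return {name: np.flatnonzero(idx == name) for name in names}


def _resolve_degenerate_axes(sv, U, Vt, set_slices, rtol: float = 1e-9):
    """Deterministic basis within (numerically) tied singular values.

    When several global eigenvalues coincide — as they do whenever two
    variable sets are mutually orthogonal, since weighting normalises
    every set's first eigenvalue to one — the SVD basis inside the tied
    subspace is arbitrary. Axes are rotated so they align with the
    variable sets in declaration order, making coordinates reproducible;
    distinct eigenvalues are untouched.
    """
    eig = sv ** 2
    i = 0
    while i < len(eig):
        j = i
        while j + 1 < len(eig) and abs(eig[j + 1] - eig[i]) <= rtol * max(1.0, eig[i]):
            j += 1
        if j > i:
            m = j - i + 1
            Vg = Vt[i:j + 1, :].T          # p x m subspace basis
            R = np.eye(m)
            remaining = list(range(m))
            for rows in set_slices.values():
                if not remaining:
                    break
                A = (Vg @ R)[rows][:, remaining]
                _, s_loc, W = np.linalg.svd(A, full_matrices=True)
                R[:, remaining] = R[:, remaining] @ W.T
                n_claim = int(np.sum(s_loc > 1 - 1e-6))
                remaining = remaining[n_claim:]
            Vt[i:j + 1, :] = (Vg @ R).T
            U[:, i:j + 1] = U[:, i:j + 1] @ R
        i = j + 1
    return U, Vt


def mfa(sets: dict, illustrative: pd.Series | None = None,
        n_components: int | None = None) -> MFAResults:
    return MFA(n_components).fit(sets, illustrative)


def _eta_squared(scores: np.ndarray, categories: np.ndarray) -> float:
    """Squared correlation ratio of a numeric score against categories."""
    grand = scores.mean()
    ss_total = ((scores - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for cat in pd.unique(categories):
        grp = scores[categories == cat]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
    return float(ss_between / ss_total)


# ---------------------------------------------------------------------------
# axis-variable correlation screening and group ellipses


def dim_correlations(result: OrdinationResults, variables: pd.DataFrame,
                     dim: int = 1, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each variable with axis ``dim`` (1-based).

    Two-sided t-test p-values, flagged at ``alpha``; no multiplicity
    correction. Variables with fewer than 3 complete pairs are skipped.
    """
    scores = result.row_coords[f"dim{dim}"]
    rows = []
    for var in variables.columns:
        pair = pd.concat([scores, variables[var]], axis=1, join="inner").dropna()
        if len(pair) < 3:
            warnings.warn(f"variable {var!r}: fewer than 3 complete pairs; skipped")
            continue
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"variable": var, "r": float(r), "p": float(p),
                     "n": len(pair), "significant": bool(p < alpha)})
    return pd.DataFrame(rows, columns=["variable", "r", "p", "n", "significant"])


@dataclass
class GroupEllipse:
    """95% confidence ellipse of a group mean in an ordination plane."""

    group: str
    center: np.ndarray          # (2,)
    dispersion: np.ndarray      # 2x2, sample covariance / n_g
    scale: float                # chi^2(2) quantile at the confidence level
    degenerate: bool = False


def group_ellipses(row_coords: pd.DataFrame, groups: pd.Series,
                   level: float = 0.95, dims=(1, 2)) -> list:
    """Confidence ellipses of group means on a pair of dimensions.

    Groups with fewer than 3 members are skipped with a warning; groups
    with zero dispersion are flagged degenerate.
    """
    cols = [f"dim{d}" for d in dims]
    coords = row_coords[cols]
    out = []
    for grp, members in coords.groupby(groups.reindex(coords.index)):
        if len(members) < 3:
            warnings.warn(f"group {grp!r} has < 3 members; ellipse skipped")
            continue
        center = members.mean().to_numpy()
        cov = np.cov(members.to_numpy(), rowvar=False, ddof=1) / len(members)
        out.append(GroupEllipse(
            group=str(grp), center=center, dispersion=cov,
            scale=float(stats.chi2.ppf(level, df=2)),
            degenerate=bool(np.allclose(cov, 0.0))))
    return out
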