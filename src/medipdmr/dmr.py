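"""Age- and cloning-related DMR inference by nested-model comparison.

For every region of interest the binary probe x individual enrichment
calls are modelled as independent Bernoulli draws with

    logit P(call = 1) = b0 + b_age * 1[adult] + b_clone * 1[clone]

(no age x cloning interaction: with 26 animals a two-parameter effect
structure is the robust choice). Three nested models are maximised:

* full        : b0 + b_age + b_clone
* age-only    : b0 + b_age          (drop cloning)
* clone-only  : b0 + b_clone        (drop age)

A region is a cloning-related DMR when the full model beats the age-only
model (LRT, chi^2 with 1 df), and an age-related DMR when the full model
beats the clone-only model, after Benjamini-Hochberg adjustment across
all tested regions (one family per factor).

Because every probe in a region shares its sample's covariates, the
likelihood collapses onto the four (age-class x clone-status) cells;
fitting works on aggregated success/trial counts. The full model is
maximised with bounded L-BFGS-B (bounds keep perfectly separated regions
finite and deterministic); the two reduced models are saturated on their
single binary factor and have closed-form maxima.

Per-individual summaries: P_ri = 100 * E_ri / T_r is the percentage of
enriched probes in region r for individual i (E_ri enriched probes, T_r
probes in the region); Pi_age_i and Pi_cloning_i average P_ri over the
age-related and cloning-related DMR sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_expit, xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .regions import RegionSet

logger = logging.getLogger(__name__)

_BETA_BOUND = 15.0  # |logit| cap; handles separation without divergence

# design matrix of the four cells: intercept, adult, clone
_CELLS = ["perinatal_AI", "perinatal_clone", "adult_AI", "adult_clone"]
_X_FULL = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=float)


def _cell_of(meta_row) -> str:
    return f"{meta_row.age_class}_{meta_row.clone_status}"


def aggregate_counts(calls: pd.DataFrame, probe_ids, meta: pd.DataFrame):
    """Success/trial counts per (age x clone) cell for one region.

    Missing calls are excluded from the likelihood (trials shrink).
    """
    block = calls.loc[probe_ids]
    cells = np.array([_cell_of(meta.loc[s]) for s in calls.columns])
    k = np.zeros(4)
    n = np.zeros(4)
    arr = block.to_numpy(dtype=float)
    for j, cell in enumerate(_CELLS):
        cols = np.flatnonzero(cells == cell)
        sub = arr[:, cols]
        k[j] = np.nansum(sub)
        n[j] = np.isfinite(sub).sum()
    return k, n


def _nll_and_grad(beta, X, k, n):
    eta = X @ beta
    ll = k @ log_expit(eta) + (n - k) @ log_expit(-eta)
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (k - n * p)
    return -ll, -grad


def _fit_binomial_logit(X, k, n) -> float:
    """Maximised Bernoulli log-likelihood for counts k of n under logit Xb."""
    res = optimize.minimize(
        _nll_and_grad, np.zeros(X.shape[1]), args=(X, k, n), jac=True,
        method="L-BFGS-B",
        bounds=[(-_BETA_BOUND, _BETA_BOUND)] * X.shape[1],
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    return -res.fun, res.x


def _saturated_loglik(k, n) -> float:
    """Closed-form maximum when each design cell has its own probability."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    return float(np.sum(xlogy(k, p) + xlogy(n - k, 1.0 - p)))


def _reduced_loglik(k, n, levels) -> float:
    """MLE log-likelihood of a single-binary-factor model (saturated on it)."""
    k2 = np.array([k[levels == 0].sum(), k[levels == 1].sum()])
    n2 = np.array([n[levels == 0].sum(), n[levels == 1].sum()])
    return _saturated_loglik(k2, n2)


_ADULT = np.array([0, 0, 1, 1])
_CLONE = np.array([0, 1, 0, 1])


def fit_region_models(probe_ids, calls: pd.DataFrame, meta: pd.DataFrame,
                      region_id: str = "") -> dict:
    """Fit full / age-only / clone-only models for one region.

    Returns a dict with log-likelihoods, LRT statistics (clipped at 0)
    and raw chi^2(1) p-values. Regions whose observed calls are constant
    (all 0 or all 1) are untestable and get p_age = p_clone = 1.
    """
    k, n = aggregate_counts(calls, probe_ids, meta)
    total_k, total_n = k.sum(), n.sum()
    out = {"region_id": region_id, "n_obs": int(total_n)}
    if total_n == 0 or total_k == 0 or total_k == total_n:
        logger.info("region %s has constant response; not tested", region_id)
        ll = _saturated_loglik(np.array([total_k]), np.array([total_n]))
        out.update(loglik_full=ll, loglik_age_only=ll, loglik_clone_only=ll,
                   lrt_age=0.0, lrt_clone=0.0, p_age=1.0, p_clone=1.0,
                   beta=(np.nan, np.nan, np.nan), tested=False)
        return out

    ll_full, beta = _fit_binomial_logit(_X_FULL, k, n)
    ll_age = _reduced_loglik(k, n, _ADULT)     # model (ii): age only
    ll_clone = _reduced_loglik(k, n, _CLONE)   # model (iii): cloning only
    lrt_clone = max(0.0, 2.0 * (ll_full - ll_age))
    lrt_age = max(0.0, 2.0 * (ll_full - ll_clone))
    out.update(
        loglik_full=ll_full, loglik_age_only=ll_age, loglik_clone_only=ll_clone,
        lrt_age=lrt_age, lrt_clone=lrt_clone,
        p_age=float(chi2.sf(lrt_age, 1)), p_clone=float(chi2.sf(lrt_clone, 1)),
        beta=tuple(beta), tested=True,
    )
    return out


def adjust_and_classify(fits: pd.DataFrame, alpha: float = 0.05,
                        method: str = "fdr_bh") -> pd.DataFrame:
    """BH-adjust the two p-value families and classify regions.

    The age family and the cloning family are adjusted separately across
    all tested regions; a region is an age-related (cloning-related) DMR
    when its adjusted p-value is below ``alpha``.
    """
    if len(fits) == 0:
        return pd.DataFrame(columns=["region_id", "p_age", "adj_p_age",
                                     "p_clone", "adj_p_clone",
                                     "is_age_dmr", "is_clone_dmr", "dmr_class"])
    out = fits[["region_id", "p_age", "p_clone"]].copy()
    out["adj_p_age"] = multipletests(out["p_age"], method=method)[1]
    out["adj_p_clone"] = multipletests(out["p_clone"], method=method)[1]
    out["is_age_dmr"] = out["adj_p_age"] < alpha
    out["is_clone_dmr"] = out["adj_p_clone"] < alpha
    out["dmr_class"] = np.select(
        [out.is_age_dmr & out.is_clone_dmr, out.is_age_dmr, out.is_clone_dmr],
        ["both", "age", "cloning"], default="none")
    return out


@dataclass
class PiTable:
    """Per-region per-individual enrichment percentages and their DMR means."""

    P: pd.DataFrame          # regions x individuals, P_ri in [0, 100]
    summary: pd.DataFrame    # individuals x {Pi_age, Pi_cloning}
    n_age_dmrs: int
    n_clone_dmrs: int


def compute_pi(calls: pd.DataFrame, regions: RegionSet,
               dmr_table: pd.DataFrame, rescale_missing: bool = False) -> PiTable:
    """P_ri = 100 * E_ri / T_r and the per-individual DMR-set averages.

    Missing calls count as not enriched in E_ri while T_r stays fixed
    (default), keeping P_ri comparable across individuals; with
    ``rescale_missing`` T_r shrinks to the observed probe count instead.
    """
    rows = {}
    for rid in regions.df["region_id"]:
        block = calls.loc[regions.probes[rid]]
        e = block.sum(axis=0, skipna=True)
        t = block.notna().sum(axis=0) if rescale_missing else float(len(block))
        rows[rid] = 100.0 * e / t
    P = pd.DataFrame(rows).T
    P.index.name = "region_id"

    cls = dmr_table.set_index("region_id")
    age_ids = cls.index[cls["is_age_dmr"]].intersection(P.index)
    clone_ids = cls.index[cls["is_clone_dmr"]].intersection(P.index)
    summary = pd.DataFrame(index=P.columns)
    summary.index.name = "animal_id"
    if len(age_ids):
        summary["Pi_age"] = P.loc[age_ids].mean(axis=0)
    else:
        logger.warning("no age-related DMRs: Pi_age not computed")
    if len(clone_ids):
        summary["Pi_cloning"] = P.loc[clone_ids].mean(axis=0)
    else:
        logger.warning("no cloning-related DMRs: Pi_cloning not computed")
    return PiTable(P=P, summary=summary,
                   n_age_dmrs=len(age_ids), n_clone_dmrs=len(clone_ids))


class DifferentialMethylationModel:
    """Nested binomial-logit model of binary enrichment over regions.

    Parameters
    ----------
    calls : DataFrame
        Probes x samples binary enrichment matrix (NaN = missing).
    regions : RegionSet
        Regions of interest whose probes index into ``calls``.
    meta : DataFrame
        Sample metadata indexed by animal_id with ``age_class`` in
        {perinatal, adult} and ``clone_status`` in {AI, clone}.
    """

    def __init__(self, calls: pd.DataFrame, regions: RegionSet, meta: pd.DataFrame):
        missing = [s for s in calls.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing}")
        for rid, pids in regions.probes.items():
            absent = set(pids) - set(calls.index)
            if absent:
                raise ValueError(f"region {rid} references unknown probes: "
                                 f"{sorted(absent)[:3]}")
        self.calls = calls
        self.regions = regions
        self.meta = meta

    def fit(self, alpha: float = 0.05, method: str = "fdr_bh") -> "DMRResults":
        fits = pd.DataFrame([
            fit_region_models(self.regions.probes[rid], self.calls, self.meta,
                              region_id=rid)
            for rid in self.regions.df["region_id"]
        ])
        dmr_table = adjust_and_classify(fits, alpha=alpha, method=method)
        return DMRResults(self, fits, dmr_table, alpha)


class DMRResults:
    """Fitted per-region models, classified DMR table and Pi summaries."""

    def __init__(self, model, region_fits, dmr_table, alpha):
        self.model = model
        self.region_fits = region_fits
        self.dmr_table = dmr_table
        self.alpha = alpha

    @property
    def n_age_dmrs(self) -> int:
        return int(self.dmr_table["is_age_dmr"].sum())

    @property
    def n_clone_dmrs(self) -> int:
        return int(self.dmr_table["is_clone_dmr"].sum())

    def pi_table(self, rescale_missing: bool = False) -> PiTable:
        return compute_pi(self.model.calls, self.model.regions,
                          self.dmr_table, rescale_missing=rescale_missing)

    def to_bed_frame(self) -> pd.DataFrame:
        """BED-like export: coordinates, counts, raw/adjusted p, class."""
        reg = self.model.regions.df.set_index("region_id")
        tab = self.dmr_table.set_index("region_id")
        out = reg.join(tab[["p_age", "adj_p_age", "p_clone", "adj_p_clone",
                            "dmr_class"]])
        return out.reset_index()[["chrom", "start", "end", "region_id",
                                  "n_probes", "p_age", "adj_p_age",
                                  "p_clone", "adj_p_clone", "dmr_class"]]

    def summary(self) -> str:
        both = int((self.dmr_table["dmr_class"] == "both").sum())
        lines = [
            "Differential methylation: nested binomial-logit LRT",
            f"  regions tested:        {len(self.dmr_table)}",
            f"  alpha (BH-adjusted):   {self.alpha}",
            f"  age-related DMRs:      {self.n_age_dmrs}",
            f"  cloning-related DMRs:  {self.n_clone_dmrs}",
            f"  in both classes:       {both}",
        ]
        return "\n".join(lines)
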