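"""Probe-level enrichment calls and anchor-extension region delineation.

The MeDIP-chip workflow starts from per-probe log2(MeDIP/input) ratios
measured in replicate for every animal. Probes whose mean replicate
log-ratio clears a threshold are called *enriched* (binary). Probes
enriched in at least one condition (the four age-class x clone-status
groups) seed an anchor-extension pass that clusters nearby anchor probes
into regions of interest, the unit at which differential methylation is
then tested.

All coordinates are 0-based half-open. A region spans from the start of
its first probe to the end of its last probe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end"]


@dataclass
class RegionSet:
    """Non-overlapping probe clusters (regions of interest).

    Attributes
    ----------
    df : DataFrame
        Columns ``region_id, chrom, start, end, n_probes``, sorted by
        (chrom, start), non-overlapping within a chromosome.
    probes : dict
        region_id -> ordered list of member probe_ids.
    """

    df: pd.DataFrame
    probes: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out["probe_ids"] = [",".join(self.probes[r]) for r in out["region_id"]]
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        probes = {r.region_id: r.probe_ids.split(",") for r in df.itertuples()}
        return cls(df=df.drop(columns=["probe_ids"]).reset_index(drop=True),
                   probes=probes)


def validate_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Check probe-table invariants; sort by (chrom, start) if needed.

    Raises on duplicate probe ids or non-positive intervals; emits a
    warning (and sorts) if the input is unsorted.
    """
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe table lacks columns: {missing}")
    if probes["probe_id"].duplicated().any():
        dup = probes.loc[probes["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id: {dup!r}")
    if (probes["start"] >= probes["end"]).any():
        bad = probes.loc[probes["start"] >= probes["end"], "probe_id"].iloc[0]
        raise ValueError(f"probe {bad!r} has end <= start")
    sorted_df = probes.sort_values(["chrom", "start"], kind="mergesort")
    if not sorted_df.index.equals(probes.index):
        warnings.warn("probe table was unsorted; sorting by (chrom, start)")
        probes = sorted_df.reset_index(drop=True)
    return probes


def call_enriched_probes(log_ratios: pd.DataFrame, threshold: float = 1.0,
                         min_replicates: int = 2) -> pd.DataFrame:
    """Binary enrichment calls from replicate log-ratio measurements.

    Parameters
    ----------
    log_ratios : DataFrame
        Probes x replicates with a two-level column MultiIndex
        (sample, replicate); values are log2(MeDIP/input), NaN allowed.
    threshold : float
        Call a probe enriched when the mean of its available replicate
        log-ratios is >= this value (default 1.0, i.e. 2-fold).
    min_replicates : int
        Minimum available replicates per probe x sample; below it the
        call is missing (NaN).

    Returns
    -------
    DataFrame, probes x samples, values in {0.0, 1.0, NaN}.
    """
    if not isinstance(log_ratios.columns, pd.MultiIndex):
        raise ValueError("log_ratios needs MultiIndex columns (sample, replicate)")
    values = log_ratios.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("non-numeric values in log-ratio table")
    samples = log_ratios.columns.get_level_values(0).unique()
    calls = {}
    for sample in samples:
        block = log_ratios[sample]
        n_avail = block.notna().sum(axis=1)
        mean = block.mean(axis=1)
        call = (mean >= threshold).astype(float)
        call[n_avail < min_replicates] = np.nan
        calls[sample] = call
    return pd.DataFrame(calls, index=log_ratios.index)


def condition_level_calls(calls: pd.DataFrame, meta: pd.DataFrame,
                          majority: float = 0.5) -> pd.DataFrame:
    """Collapse per-sample calls to per-condition (group) calls.

    A probe is enriched in a condition iff strictly more than ``majority``
    of the condition's non-missing sample calls are 1. Conditions with no
    non-missing call at a probe are not enriched there (logged).
    """
    unknown = [s for s in calls.columns if s not in meta.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown}")
    groups = meta.loc[calls.columns, "group"]
    out = {}
    for cond, cols in calls.columns.to_series().groupby(groups.values):
        block = calls[list(cols)]
        n_obs = block.notna().sum(axis=1)
        frac = block.sum(axis=1, min_count=1) / n_obs
        enriched = (frac > majority).fillna(False)
        n_empty = int((n_obs == 0).sum())
        if n_empty:
            logger.info("condition %s: %d probes with no observed call", cond, n_empty)
        out[cond] = enriched.astype(int)
    return pd.DataFrame(out, index=calls.index)


def anchor_extend(probes: pd.DataFrame, anchor_mask: pd.Series,
                  max_gap: int = 500, min_probes: int = 3) -> RegionSet:
    """Delineate regions by extending across nearby anchor probes.

    Anchor probes on the same chromosome are chained while the genomic
    gap between consecutive anchors (next.start - prev.end) is at most
    ``max_gap``; chains shorter than ``min_probes`` are discarded.

    Returns a :class:`RegionSet`, sorted and non-overlapping; region ids
    are ``roi_000001`` ... in genomic order.
    """
    if max_gap < 0 or min_probes < 1:
        raise ValueError("max_gap must be >= 0 and min_probes >= 1")
    probes = validate_probes(probes)
    mask = anchor_mask.reindex(probes["probe_id"]).fillna(False).astype(bool)
    anchors = probes.loc[mask.to_numpy()]

    rows, members = [], []
    for chrom, sub in anchors.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        if len(sub) == 0:
            continue
        gap = starts[1:] - ends[:-1]
        breaks = np.flatnonzero(gap > max_gap)
        run_bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for lo, hi in zip(run_bounds[:-1], run_bounds[1:]):
            if hi - lo < min_probes:
                continue
            rows.append((chrom, int(starts[lo]), int(ends[hi - 1]), hi - lo))
            members.append(list(ids[lo:hi]))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes"])
    df.insert(0, "region_id", [f"roi_{i + 1:06d}" for i in range(len(df))])
    probe_map = {rid: m for rid, m in zip(df["region_id"], members)}
    return RegionSet(df=df, probes=probe_map)
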