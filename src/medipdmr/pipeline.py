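"""End-to-end orchestration: simulate/load -> regions -> DMRs -> Pi ->
ordinations -> permutation tests -> JSON report.

Every stage persists its output as plain text with a provenance header
(stage name, seed, config hash); re-running with an identical
configuration reproduces byte-identical files. One master seed drives
all stages through fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .dmr import DifferentialMethylationModel
from .ordination import MCA, MFA, dim_correlations, merge_rare_categories, rank_pca
from .regions import RegionSet, anchor_extend, condition_level_calls, validate_probes
from .resampling import perm_test, stratified_perm_test
from .simulate import (SimConfig, config_to_dict, default_phenotype_spec,
                       load_lesion_fixture, simulate_enrichment,
                       simulate_phenotypes)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the master seed
_STAGE_OFFSET = {"simulate": 0, "phenotypes": 1, "permtest": 2}


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run."""

    out_dir: str = "medipdmr_run"
    seed: int = 0
    # inputs; when calls_path is None a synthetic cohort is generated
    probes_path: str | None = None
    calls_path: str | None = None
    meta_path: str | None = None
    # stage parameters
    threshold: float = 1.0
    majority: float = 0.5
    max_gap: int = 500
    min_probes: int = 3
    alpha: float = 0.05
    adjust_method: str = "fdr_bh"
    n_perm: int = 10_000
    # synthetic cohort size
    n_regions: int = 500
    probes_per_region: tuple = (20, 20)
    # toggles
    run_dmr: bool = True
    run_mca: bool = True
    run_pca: bool = True
    run_mfa: bool = True
    run_report: bool = True

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 <= self.majority < 1.0):
            raise ValueError("majority must be in [0, 1)")
        if self.max_gap < 0 or self.min_probes < 1 or self.n_perm < 1:
            raise ValueError("max_gap >= 0, min_probes >= 1, n_perm >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text config."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _coerce(raw, fields[key].type)
        return cls(**kwargs)


def _coerce(raw: str, typ):
    s = str(typ)
    if raw.lower() in {"none", ""}:
        return None
    if "bool" in s:
        return raw.lower() in {"1", "true", "yes"}
    if "tuple" in s:
        return tuple(int(v) for v in raw.replace(",", " ").split())
    if "int" in s:
        return int(raw)
    if "float" in s:
        return float(raw)
    return raw


def validate_inputs(probes_path=None, calls_path=None, meta_path=None,
                    fa_path=None) -> dict:
    """Cross-check input files; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    probes = calls = meta = None
    if probes_path:
        try:
            probes = io.read_probes_bed(probes_path)
            validate_probes(probes)
        except Exception as exc:  # noqa: BLE001 - reported, not raised
            errors.append(f"probes: {exc}")
    if calls_path:
        calls = io.read_matrix(calls_path)
        bad = calls.stack().dropna()
        if not bad.isin([0.0, 1.0]).all():
            errors.append("calls: values outside {0, 1, missing}")
        if probes is not None:
            unknown = set(calls.index) - set(probes["probe_id"])
            if unknown:
                errors.append(f"calls: {len(unknown)} probes absent from probe table")
    if meta_path:
        meta = io.read_sample_meta(meta_path)
        for col in ("age_class", "clone_status", "group"):
            if col not in meta.columns:
                errors.append(f"metadata: missing column {col!r}")
        if calls is not None and not errors:
            missing = [s for s in calls.columns if s not in meta.index]
            if missing:
                errors.append(f"metadata: samples missing: {missing}")
    if fa_path:
        fa = io.read_table(fa_path, sep=",", index_col=0)
        sums = fa.sum(axis=1)
        off = sums[(sums - 100.0).abs() > 5.0]
        if len(off):
            warnings_.append(
                f"FA percentages deviate from 100 by > 5 for {len(off)} animals")
    return {"errors": errors, "warnings": warnings_,
            "ok": not errors}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the report summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = dataclasses.asdict(config)
    hashed.pop("out_dir")  # output location is not analysis content
    cfg_hash = io.config_hash(hashed)
    prov = dict(seed=config.seed, cfg_hash=cfg_hash)
    report: dict = {"provenance": {"config_hash": cfg_hash, "seed": config.seed}}

    # ---- stage: inputs ----------------------------------------------------
    stage = "inputs"
    try:
        if config.calls_path is None:
            sim = simulate_enrichment(SimConfig(
                n_regions=config.n_regions,
                probes_per_region=tuple(config.probes_per_region),
                max_gap=config.max_gap,
                seed=config.seed + _STAGE_OFFSET["simulate"]))
            calls, probes, meta, truth = sim.calls, sim.probes, sim.meta, sim.truth
            io.write_probes_bed(probes, out / "probes.bed.tsv", stage="simulate", **prov)
            io.write_matrix(calls, out / "calls.tsv", stage="simulate", **prov)
            io.write_sample_meta(meta, out / "meta.csv", stage="simulate", **prov)
            io.write_table(truth, out / "truth.tsv", stage="simulate", **prov)
            io.write_table(sim.regions.to_frame(), out / "regions_true.tsv",
                           stage="simulate", **prov)
        else:
            probes = io.read_probes_bed(config.probes_path)
            calls = io.read_matrix(config.calls_path)
            meta = io.read_sample_meta(config.meta_path)
            truth = None
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: regions ---------------------------------------------------
    stage = "regions"
    try:
        cond = condition_level_calls(calls, meta, majority=config.majority)
        anchors = cond.any(axis=1)
        regions = anchor_extend(probes, anchors, max_gap=config.max_gap,
                                min_probes=config.min_probes)
        io.write_table(regions.to_frame(), out / "regions.tsv", stage=stage, **prov)
        report["counts"] = {"probes": len(probes), "regions": len(regions)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    pi = None
    if config.run_dmr:
        stage = "dmr"
        try:
            results = DifferentialMethylationModel(calls, regions, meta).fit(
                alpha=config.alpha, method=config.adjust_method)
            io.write_table(results.to_bed_frame(), out / "dmrs.tsv",
                           stage=stage, **prov)
            pi = results.pi_table()
            io.write_matrix(pi.P, out / "pi_regions.tsv", stage=stage, **prov)
            io.write_table(pi.summary.reset_index(), out / "pi_summary.csv",
                           sep=",", stage=stage, **prov)
            report["counts"].update(
                age_dmrs=results.n_age_dmrs, clone_dmrs=results.n_clone_dmrs,
                both=int((results.dmr_table["dmr_class"] == "both").sum()))
            if truth is not None:
                report["recovery"] = _confusion(results, regions, truth)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if config.run_mca:
        stage = "mca"
        try:
            scores, _ = load_lesion_fixture()
            merged = merge_rare_categories(scores.dropna())
            res = MCA().fit(merged)
            io.write_table(res.row_coords.reset_index(), out / "mca_rows.tsv",
                           stage=stage, **prov)
            report["mca"] = {"pct_variance": _round(res.pct_variance[:5]),
                             "total_inertia": round(res.total_inertia, 6)}
        except Exception as exc:
            raise StageError(stage, exc) from exc

    morpho = fa_tables = None
    if (config.run_pca or config.run_mfa) and pi is not None \
            and {"Pi_age", "Pi_cloning"} <= set(pi.summary.columns):
        morpho, fa_tables = simulate_phenotypes(
            meta, pi.summary, default_phenotype_spec(),
            seed=config.seed + _STAGE_OFFSET["phenotypes"])

    if config.run_pca and fa_tables:
        stage = "pca"
        try:
            from .fatty_acids import rank_pca_variables
            table = rank_pca_variables(fa_tables)
            res = rank_pca(table)
            io.write_table(res.row_coords.reset_index(), out / "pca_rows.tsv",
                           stage=stage, **prov)
            report["pca"] = {"n_variables": table.shape[1],
                             "pct_variance": _round(res.pct_variance[:5])}
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if config.run_mfa and fa_tables and pi is not None:
        stage = "mfa"
        try:
            from .fatty_acids import fa_variable_set
            dmr_vars = _dmr_variable_set(pi)
            sets = {"DMR": dmr_vars, "Morpho": morpho,
                    "FA": fa_variable_set(fa_tables)}
            res = MFA(n_components=5).fit(
                sets, illustrative=meta["group"].rename("Group"))
            io.write_table(res.row_coords.reset_index(), out / "mfa_rows.tsv",
                           stage=stage, **prov)
            io.write_table(res.group_coords.reset_index(), out / "mfa_groups.tsv",
                           stage=stage, **prov)
            corr = dim_correlations(res, dmr_vars, dim=1, alpha=config.alpha)
            io.write_table(corr, out / "mfa_dim1_dmr_correlations.tsv",
                           stage=stage, **prov)
            report["mfa"] = {
                "pct_variance": _round(res.pct_variance),
                "group_coords_dim1": _round(res.group_coords["dim1"]),
                "illustrative_dim1": round(
                    float(res.illustrative_coords.iloc[0, 0]), 6),
                "n_dim1_significant_dmr_vars": int(corr["significant"].sum()),
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if pi is not None and "Pi_cloning" in pi.summary.columns:
        stage = "permtest"
        try:
            joined = pi.summary.join(meta[["clone_status", "age_class"]])
            cl = joined[joined.clone_status == "clone"]["Pi_cloning"]
            ai = joined[joined.clone_status == "AI"]["Pi_cloning"]
            strata = np.concatenate([
                joined.loc[cl.index, "age_class"],
                joined.loc[ai.index, "age_class"]])
            plain = perm_test(cl, ai, n_perm=config.n_perm,
                              seed=config.seed + _STAGE_OFFSET["permtest"])
            strat = stratified_perm_test(
                cl, ai, strata, n_perm=config.n_perm,
                seed=config.seed + _STAGE_OFFSET["permtest"])
            report["perm_tests"] = {
                "pi_cloning_clone_vs_ai": _perm_dict(plain),
                "pi_cloning_clone_vs_ai_stratified": _perm_dict(strat),
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if config.run_report:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _dmr_variable_set(pi) -> pd.DataFrame:
    """Individuals x DMR-region P_ri matrix, constant columns dropped."""
    dmr_ids = pi.P.index
    X = pi.P.T
    keep = X.std(ddof=0) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("MFA DMR set: dropped %d constant columns", dropped)
    return X.loc[:, keep]


def _confusion(results, regions: RegionSet, truth: pd.DataFrame) -> dict:
    """Planted-vs-detected confusion counts, matched by probe membership."""
    truth_of_probe = {}
    tr = truth.set_index("region_id")
    prefix_len = len("reg_00000")
    out = {}
    for kind, col in (("age", "is_age_dmr"), ("cloning", "is_clone_dmr")):
        tp = fp = fn = tn = 0
        detected = results.dmr_table.set_index("region_id")[
            "is_age_dmr" if kind == "age" else "is_clone_dmr"]
        # map every detected region to the planted region of its first probe
        planted_hit = {}
        for rid in regions.df["region_id"]:
            first_probe = regions.probes[rid][0]
            planted = first_probe.rsplit("_p", 1)[0]
            if planted in tr.index and bool(detected.get(rid, False)):
                planted_hit.setdefault(planted, False)
                planted_hit[planted] = True
            elif planted in tr.index:
                planted_hit.setdefault(planted, False)
        for planted, hit in planted_hit.items():
            is_true = bool(tr.loc[planted, col])
            tp += hit and is_true
            fp += hit and not is_true
            fn += (not hit) and is_true
            tn += (not hit) and not is_true
        out[kind] = {"tp": int(tp), "fp": int(fp), "fn": int(fn), "tn": int(tn)}
    return out


def _perm_dict(res) -> dict:
    return {"statistic": round(res.statistic, 6), "p_value": round(res.p_value, 6),
            "n_perm": res.n_perm, "n_x": res.n_x, "n_y": res.n_y}


def _round(values, nd: int = 6) -> list:
    return [round(float(v), nd) for v in np.asarray(values)]
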