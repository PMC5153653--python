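"""Seeded synthetic cohorts with the statistical structure the pipeline
assumes, plus the packaged in-study lesion-score fixture.

The enrichment generator inverts the inference model: per-probe binary
calls are Bernoulli with logit p = baseline + age_effect * 1[adult] +
clone_effect * 1[clone], with both effects zeroed outside planted DMRs.
Probes are laid on one synthetic chromosome, evenly spaced within
regions, with inter-region gaps ten times the default anchor-extension
gap so that the layout guarantees exact region recoverability.

The default configuration mirrors the microarray cohort: 26 animals in
four groups (4 perinatal AI, 7 perinatal clones, 8 adult AI, 7 adult
clones), a two-factor effect structure without interaction, and planted
age/cloning DMR fractions of 10% each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .regions import RegionSet

DEFAULT_GROUP_SIZES = {
    "perinatal_AI": 4, "perinatal_clone": 7, "adult_AI": 8, "adult_clone": 7,
}

_DONOR_GENOTYPES = ["5538", "2251", "0029", "7711"]


@dataclass
class SimConfig:
    """Parameters of the synthetic enrichment cohort."""

    n_regions: int = 500
    probes_per_region: tuple = (20, 20)       # inclusive (min, max)
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    baseline_logit: float = -1.0
    age_effect: float = 2.0
    clone_effect: float = -2.0
    frac_age_dmr: float = 0.1
    frac_clone_dmr: float = 0.1
    frac_overlap: float = 0.0                 # share of DMRs in both classes
    probe_length: int = 60
    probe_spacing: int = 100                  # start-to-start, within regions
    max_gap: int = 500                        # anchor-extension default gap
    chrom: str = "chrS1"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.probes_per_region
        if lo < 1 or lo > hi:
            raise ValueError("probes_per_region must satisfy 1 <= min <= max")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("every group needs >= 1 sample")
        unknown = set(self.group_sizes) - set(DEFAULT_GROUP_SIZES)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        for name in ("frac_age_dmr", "frac_clone_dmr", "frac_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.probe_spacing < self.probe_length:
            raise ValueError("probe_spacing must be >= probe_length")


def _make_meta(config: SimConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for group, size in config.group_sizes.items():
        age_class, clone_status = group.split("_")
        for k in range(size):
            i += 1
            if age_class == "adult":
                stage = "adult"
            elif clone_status == "clone":
                # perinatal clones: foetuses first, remainder calves
                stage = "foetus" if k < max(1, size - 2) else "calf"
            else:
                stage = "foetus"
            rows.append({
                "animal_id": f"A{i:02d}", "stage": stage,
                "age_class": age_class, "clone_status": clone_status,
                "group": group,
                "genotype": (_DONOR_GENOTYPES[k % len(_DONOR_GENOTYPES)]
                             if clone_status == "clone" else ""),
                "age_days": {"foetus": 265, "calf": 283, "adult": 2200}[stage],
            })
    return pd.DataFrame(rows).set_index("animal_id")


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_enrichment`."""

    calls: pd.DataFrame       # probes x samples binary matrix (float 0/1)
    probes: pd.DataFrame      # probe_id, chrom, start, end, cpg_class
    regions: RegionSet        # the planted regions
    meta: pd.DataFrame        # sample metadata indexed by animal_id
    truth: pd.DataFrame       # per-region DMR status and true effects


def simulate_enrichment(config: SimConfig) -> SimulatedCohort:
    """Generate a synthetic cohort under the logistic enrichment model.

    Probe coordinates are laid out so that anchor-extension of the true
    region-membership mask recovers the planted regions exactly under
    the default gap settings; identical config + seed gives bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _make_meta(config)

    n = config.n_regions
    n_age = int(round(config.frac_age_dmr * n))
    n_clone = int(round(config.frac_clone_dmr * n))
    n_both = int(round(config.frac_overlap * min(n_age, n_clone)))
    if n_age + n_clone - n_both > n:
        raise ValueError("DMR fractions exceed the number of regions")
    order = rng.permutation(n)
    is_age = np.zeros(n, bool)
    is_clone = np.zeros(n, bool)
    is_age[order[:n_age]] = True
    # overlap regions are drawn from the age set, the rest are disjoint
    is_clone[order[:n_both]] = True
    is_clone[order[n_age:n_age + n_clone - n_both]] = True

    lo, hi = config.probes_per_region
    n_probes = rng.integers(lo, hi + 1, size=n)

    probe_rows = []
    region_rows = []
    probe_map = {}
    pos = 0
    gap_between = 10 * config.max_gap
    for r in range(n):
        rid = f"reg_{r + 1:05d}"
        ids = []
        start = pos
        for q in range(n_probes[r]):
            pid = f"{rid}_p{q + 1:03d}"
            probe_rows.append((pid, config.chrom, pos, pos + config.probe_length))
            ids.append(pid)
            pos += config.probe_spacing
        end = pos - config.probe_spacing + config.probe_length
        region_rows.append((rid, config.chrom, start, end, int(n_probes[r])))
        probe_map[rid] = ids
        pos = end + gap_between

    probes = pd.DataFrame(probe_rows,
                          columns=["probe_id", "chrom", "start", "end"])
    probes["cpg_class"] = "intermediate"
    regions = RegionSet(
        df=pd.DataFrame(region_rows,
                        columns=["region_id", "chrom", "start", "end",
                                 "n_probes"]),
        probes=probe_map)

    adult = (meta["age_class"] == "adult").to_numpy(float)
    clone = (meta["clone_status"] == "clone").to_numpy(float)
    region_of_probe = np.repeat(np.arange(n), n_probes)
    age_eff = np.where(is_age, config.age_effect, 0.0)[region_of_probe]
    clone_eff = np.where(is_clone, config.clone_effect, 0.0)[region_of_probe]
    logit = (config.baseline_logit
             + age_eff[:, None] * adult[None, :]
             + clone_eff[:, None] * clone[None, :])
    p = 1.0 / (1.0 + np.exp(-logit))
    calls = pd.DataFrame(rng.binomial(1, p).astype(float),
                         index=probes["probe_id"], columns=meta.index)

    truth = pd.DataFrame({
        "region_id": regions.df["region_id"],
        "is_age_dmr": is_age, "is_clone_dmr": is_clone,
        "true_age_effect": np.where(is_age, config.age_effect, 0.0),
        "true_clone_effect": np.where(is_clone, config.clone_effect, 0.0),
    })
    return SimulatedCohort(calls=calls, probes=probes, regions=regions,
                           meta=meta, truth=truth)


@dataclass
class PhenotypeSpec:
    """How one synthetic quantitative variable is generated."""

    group_means: dict                 # group label -> mean
    sd: float = 0.0                   # Gaussian noise SD
    coupling: float = 0.0             # slope on the methylation summary
    couple_to: str | None = None      # "Pi_age" or "Pi_cloning"
    fraction: str | None = None       # "PL"/"NL" for FA variables, else None


def simulate_phenotypes(meta: pd.DataFrame, pi_summary: pd.DataFrame,
                        effect_spec: dict, seed: int | None = None):
    """Group-structured phenotype tables coupled to methylation summaries.

    Each variable is group mean + coupling * Pi + Gaussian noise. FA
    variables (``fraction`` set) are renormalised to sum to 100 within
    each lipid fraction. Returns (morpho_table, fa_tables_by_fraction).
    """
    rng = np.random.default_rng(seed)
    morpho = {}
    fa = {}
    for var, spec in effect_spec.items():
        unknown = set(spec.group_means) - set(meta["group"].unique())
        if unknown:
            raise ValueError(f"unknown group label(s) for {var!r}: "
                             f"{sorted(unknown)}")
        base = meta["group"].map(spec.group_means)
        if base.isna().any():
            raise ValueError(f"variable {var!r}: no mean for group(s) "
                             f"{sorted(meta.loc[base.isna(), 'group'].unique())}")
        vals = base.astype(float)
        if spec.coupling and spec.couple_to:
            vals = vals + spec.coupling * pi_summary[spec.couple_to].reindex(meta.index)
        vals = vals + rng.normal(0.0, spec.sd, size=len(meta))
        if spec.fraction is None:
            morpho[var] = vals
        else:
            # "PL::C14:0" -> column "C14:0" in the PL fraction table
            name = var.split("::", 1)[-1]
            fa.setdefault(spec.fraction, {})[name] = vals
    morpho_df = pd.DataFrame(morpho, index=meta.index)
    fa_dfs = {}
    for fraction, cols in fa.items():
        df = pd.DataFrame(cols, index=meta.index).clip(lower=0.0)
        fa_dfs[fraction] = df.div(df.sum(axis=1), axis=0) * 100.0
    return morpho_df, fa_dfs


def default_phenotype_spec() -> dict:
    """Default synthetic phenotype structure for the four-group cohort.

    Morphometric variables follow the qualitative pattern seen in
    perinatal-pathology cohorts: smaller, more heterogeneous hepatocyte
    nuclei in perinatal clones, larger cells in animals with glycogen
    storage, and maturation shifts between perinatal and adult animals;
    each is weakly coupled to a methylation summary so that downstream
    correlation screens have signal to find. FA percentages are liver-like
    profiles per lipid fraction with an elevated C22:6w3 share in
    perinatal clones; rows are renormalised to sum to 100 per fraction.
    """
    g = lambda pAI, pCl, aAI, aCl: {  # noqa: E731 - compact group-mean maps
        "perinatal_AI": pAI, "perinatal_clone": pCl,
        "adult_AI": aAI, "adult_clone": aCl}
    spec = {
        # Morpho set (units: um^2 for areas, unitless shape/CV)
        "nucleus_mean_area": PhenotypeSpec(g(42, 35, 55, 54), sd=3.0,
                                           coupling=0.08, couple_to="Pi_age"),
        "nucleus_mean_shape": PhenotypeSpec(g(0.85, 0.78, 0.88, 0.87), sd=0.02),
        "nucleus_cv_area": PhenotypeSpec(g(0.25, 0.40, 0.22, 0.23), sd=0.03,
                                         coupling=-0.002, couple_to="Pi_cloning"),
        "nucleus_cv_shape": PhenotypeSpec(g(0.10, 0.16, 0.09, 0.09), sd=0.015),
        "cell_mean_area": PhenotypeSpec(g(247, 153, 260, 255), sd=20.0,
                                        coupling=0.5, couple_to="Pi_age"),
        "cell_mean_shape": PhenotypeSpec(g(0.72, 0.64, 0.75, 0.74), sd=0.03),
        "cell_cv_area": PhenotypeSpec(g(0.30, 0.45, 0.28, 0.29), sd=0.04),
        "cell_cv_shape": PhenotypeSpec(g(0.12, 0.18, 0.11, 0.11), sd=0.02),
    }
    pl = {  # phospholipid fraction, percentage means
        "C14:0": g(1.2, 2.0, 0.8, 0.9), "C16:0": g(24, 25, 20, 20),
        "C16:1ω7": g(1.5, 1.8, 1.0, 1.1), "C18:0": g(20, 19, 23, 23),
        "C18:1ω9": g(11, 12, 8, 8.5), "C18:2ω6": g(10, 9, 16, 15),
        "C18:3ω3": g(0.6, 0.6, 0.9, 0.9), "C20:3ω6": g(2.5, 2.2, 2.0, 2.0),
        "C20:4ω6": g(14, 10, 16, 16), "C20:5ω3": g(0.8, 1.0, 1.2, 1.2),
        "C22:4ω6": g(1.8, 1.5, 1.2, 1.2), "C22:5ω3": g(2.8, 3.0, 2.4, 2.4),
        "C22:6ω3": g(4.5, 7.5, 3.5, 3.6),
    }
    nl = {  # neutral-lipid fraction (intracellular stores)
        "C14:0": g(2.5, 3.5, 1.5, 1.6), "C16:0": g(28, 29, 26, 26),
        "C16:1ω7": g(3.0, 3.5, 2.0, 2.1), "C18:0": g(12, 11, 16, 16),
        "C18:1ω9": g(25, 26, 30, 29), "C18:2ω6": g(8, 7, 12, 12),
        "C18:3ω3": g(0.8, 0.8, 1.2, 1.2), "C20:3ω6": g(1.5, 1.3, 1.0, 1.0),
        "C20:4ω6": g(7, 5, 5.5, 5.5), "C20:5ω3": g(0.6, 0.8, 0.7, 0.7),
        "C22:4ω6": g(1.2, 1.0, 0.8, 0.8), "C22:5ω3": g(1.8, 2.0, 1.4, 1.4),
        "C22:6ω3": g(2.5, 4.5, 1.8, 1.9),
    }
    for name, means in pl.items():
        spec[f"PL::{name}"] = PhenotypeSpec(means, sd=0.35, fraction="PL")
    for name, means in nl.items():
        spec[f"NL::{name}"] = PhenotypeSpec(means, sd=0.35, fraction="NL")
    return spec


LESION_VARIABLES = ["R", "F", "G", "S", "C", "A", "I"]


def load_lesion_fixture():
    """The packaged lesion-score table and cohort metadata (36 animals).

    Returns (scores, meta): ``scores`` holds the seven severity-coded
    lesion variables with NaN rows for the six animals without
    histological characterisation; ``meta`` carries stage, age class,
    clone status, genotype and age.
    """
    with resources.files("medipdmr.data").joinpath("lesion_scores.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"animal_id": str, "genotype": str})
    df = df.set_index("animal_id")
    scores = df[LESION_VARIABLES]
    meta = df.drop(columns=LESION_VARIABLES)
    meta["genotype"] = meta["genotype"].fillna("")
    return scores, meta


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["probes_per_region"] = list(d["probes_per_region"])
    return d
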