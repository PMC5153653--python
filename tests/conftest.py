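import numpy as np
import pandas as pd
import pytest

from medipdmr import SimConfig, simulate_enrichment


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (26 animals, 500 regions, seed 0)."""
    return simulate_enrichment(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast structural tests."""
    return simulate_enrichment(SimConfig(
        n_regions=40, probes_per_region=(5, 12), seed=11))


@pytest.fixture()
def four_group_meta():
    """Minimal 8-animal metadata covering all four design cells."""
    rows = []
    i = 0
    for age in ("perinatal", "adult"):
        for status in ("AI", "clone"):
            for _ in range(2):
                i += 1
                rows.append({"animal_id": f"S{i}", "age_class": age,
                             "clone_status": status,
                             "group": f"{age}_{status}",
                             "stage": "adult" if age == "adult" else "foetus"})
    return pd.DataFrame(rows).set_index("animal_id")


@pytest.fixture()
def probe_frame():
    def make(starts, length=60, chrom="chr1"):
        starts = np.asarray(starts)
        return pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(len(starts))],
            "chrom": chrom, "start": starts, "end": starts + length,
        })
    return make
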