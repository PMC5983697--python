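import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tftarget.expression import ContrastSpec, compute_ratio, regulator_correlation
from tftarget.simulate import SimulationConfig, simulate_all

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")


SMALL_CONFIG = SimulationConfig(
    seed=11, n_genes=400, n_chromosomes=2, chrom_length_bp=5_000_000, n_peaks=500, cohort_n=60
)


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic study shared by read-only tests."""
    return simulate_all(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_contrast_results(small_sim):
    cfg = SMALL_CONFIG
    k = cfg.n_perturb_replicates
    oe_spec = ContrastSpec(
        "overexpression",
        tuple(f"OE_T{i + 1}" for i in range(k)),
        tuple(f"OE_C{i + 1}" for i in range(k)),
    )
    kd_spec = ContrastSpec(
        "knockdown",
        tuple(f"KD_T{i + 1}" for i in range(k)),
        tuple(f"KD_C{i + 1}" for i in range(k)),
    )
    oe = compute_ratio(small_sim["oe"], oe_spec)
    kd = compute_ratio(small_sim["kd"], kd_spec)
    corr = regulator_correlation(small_sim["cohort"], cfg.regulator_gene_id)
    return oe, kd, corr


def pearson_closed_form(x, y) -> float:
    """Independent textbook evaluation of Pearson r from raw sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt((n * np.sum(x**2) - np.sum(x) ** 2) * (n * np.sum(y**2) - np.sum(y) ** 2))
    return num / den
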