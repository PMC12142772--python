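import numpy as np
import pandas as pd
import pytest

from mrmediate import MediatorSpec, SimConfig, SumStats, simulate_chain
from mrmediate.sumstats import HarmonizedSet


def make_sumstats(name="trait", trait_type="continuous", **cols) -> SumStats:
    """Small well-formed summary table; any column overridable."""
    n = len(cols.get("snp", cols.get("beta", [0, 0, 0])))
    base = {
        "snp": [f"rs{i}" for i in range(1, n + 1)],
        "chr": ["1"] * n,
        "pos": list(range(1_000_000, 1_000_000 + n)),
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "eaf": [0.3] * n,
        "beta": [0.1] * n,
        "se": [0.01] * n,
        "pval": [1e-9] * n,
        "n": [50_000] * n,
    }
    base.update(cols)
    return SumStats(name, trait_type, pd.DataFrame(base))


def make_hset(gamma, Gamma, sigma_x=0.005, sigma_y=0.05) -> HarmonizedSet:
    gamma = np.asarray(gamma, dtype=float)
    J = gamma.shape[0]
    sx = np.broadcast_to(np.asarray(sigma_x, dtype=float), gamma.shape).copy()
    sy = np.broadcast_to(np.asarray(sigma_y, dtype=float), (J,)).copy()
    names = ("exposure",) if gamma.ndim == 1 else tuple(
        f"exposure{k + 1}" for k in range(gamma.shape[1]))
    return HarmonizedSet(names, "outcome",
                         np.array([f"rs{i + 1}" for i in range(J)]),
                         gamma, sx, np.asarray(Gamma, dtype=float), sy)


@pytest.fixture(scope="session")
def chain_sim():
    """One small seeded chain study shared across tests (true proportion 0.30)."""
    cfg = SimConfig(seed=3, n_exp=6000, n_med=6000, n_out=6000,
                    n_exposure_snps=14,
                    mediators=(MediatorSpec("m1", 0.3, 0.5, n_snps=10),))
    return simulate_chain(cfg)
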