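import numpy as np
import pandas as pd
import pytest

from exoprot import SimulationConfig
from exoprot.pipeline import simulate_bundle


@pytest.fixture()
def worked_matrix() -> pd.DataFrame:
    """The hand-calculable 2x2 matrix: means 3 and 12, medians 5 and 10."""
    return pd.DataFrame(
        [[2.0, 4.0], [8.0, 16.0]],
        index=pd.Index(["P1", "P2"], name="protein_id"),
        columns=["s1", "s2"],
    )


def random_abundance(rng: np.random.Generator, n: int, m: int, missing: float = 0.0) -> pd.DataFrame:
    """Log-normal-ish random matrix with optional missing cells; every row and
    column keeps at least one present value."""
    values = np.exp2(rng.normal(15.0, 2.0, size=(n, m)))
    if missing > 0:
        mask = rng.random((n, m)) < missing
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, 0] = False
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[0, j] = False
        values = np.where(mask, np.nan, values)
    return pd.DataFrame(
        values,
        index=[f"P{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(m)],
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> dict:
    """A small synthetic study written to disk once for pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(n_proteins=300, frac_diff=0.1, missing_rate=0.05, seed=11)
    truth = simulate_bundle(outdir, cfg)
    return {
        "dir": outdir,
        "abundance": outdir / "abundance.tsv",
        "metadata": outdir / "metadata.tsv",
        "network": outdir / "network.tsv",
        "truth": truth,
        "config": cfg,
    }
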