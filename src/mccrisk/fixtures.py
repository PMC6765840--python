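"""Small bundled example datasets, generated deterministically.

All fixtures are synthetic: a 200-subject 4-center cohort, a 17-center
incidence table, and a hand-checkable 5-subject dataset for verifying the
partial-likelihood maximiser against exhaustive grid search.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import write_cohort
from .simulate import SimulationConfig, simulate_cohort

#: 5-subject, 2-covariate dataset with distinct times and mixed outcomes,
#: small enough for a brute-force sweep of the partial likelihood over a
#: (beta_tc, beta_hdl) grid.  Fixed by hand, not drawn.
PL_EXAMPLE = pd.DataFrame(
    {
        "center_id": [1, 1, 1, 1, 1],
        "tc": [0.5, -0.2, 0.3, 0.8, -0.5],
        "hdl": [-0.3, 0.4, 0.1, -0.2, 0.2],
        "sbp": [0.0] * 5,
        "diabetes": [0] * 5,
        "smoking": [0] * 5,
        "time": [1.3, 2.1, 3.7, 4.2, 5.6],
        "outcome": [1, 2, 1, 0, 1],
        "age": [0.0] * 5,
    }
)


def make_incidence_fixture(seed: int, n_centers: int = 17) -> pd.DataFrame:
    """Per-center incidence table: log-normal spread around 1% per year."""
    rng = np.random.default_rng(seed)
    incidence = np.exp(np.log(0.01) + rng.normal(0.0, 0.5, size=n_centers))
    population = rng.integers(20_000, 200_000, size=n_centers)
    return pd.DataFrame(
        {
            "center_id": np.arange(1, n_centers + 1),
            "incidence": np.round(incidence, 6),
            "population": population,
        }
    )


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the bundled datasets under ``outdir`` and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cfg = SimulationConfig(
        n_total=200, censor_ratio=0.2, sdcp=0.5, n_centers=4, seed=seed
    )
    sim = simulate_cohort(cfg, np.random.default_rng(seed))
    paths["cohort"] = outdir / "cohort_200x4.csv"
    write_cohort(sim.cohort, paths["cohort"])

    paths["incidence"] = outdir / "incidence_17.csv"
    make_incidence_fixture(seed).to_csv(paths["incidence"], index=False)

    paths["pl_example"] = outdir / "pl_example_5.csv"
    PL_EXAMPLE.to_csv(paths["pl_example"], index=False)
    return paths
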