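import numpy as np
import pandas as pd
import pytest

from fruitprod import synthetic_data as synth


@pytest.fixture(scope="session")
def small_forest():
    """One plot, 3 species x 60 stems, with soil — shared read-only."""
    table = [
        synth.SpeciesConfig(f"SP{i + 1:02d}", 60, 2.6 + 0.15 * i, 0.5)
        for i in range(3)
    ]
    trees, soil = synth.generate_forest(
        n_plots=1, species_table=table, seed=42
    )
    return trees, soil


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated study under a DBH+ANCI truth (4 species x 100)."""
    table = [
        synth.SpeciesConfig(f"SP{i + 1:02d}", 100, 2.7 + 0.1 * i, 0.5)
        for i in range(4)
    ]
    truth = synth.make_truth(
        [s.name for s in table], covariate_set="dbh+anci", seed=9
    )
    return synth.simulate_dataset(
        n_plots=1, species_table=table, truth=truth, n_periods=3, seed=9,
        with_counts=True,
    )


def random_stem_map(rng, n, width=41.0, length=240.0, plot_id="P1"):
    """Uniform random stem map helper used by oracle tests."""
    return pd.DataFrame({
        "tree_id": [f"T{i:04d}" for i in range(n)],
        "plot_id": plot_id,
        "species": rng.choice(["A", "B", "C"], size=n),
        "x_m": rng.uniform(0, width, n),
        "y_m": rng.uniform(0, length, n),
        "dbh_cm": rng.uniform(5, 80, n),
    })
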