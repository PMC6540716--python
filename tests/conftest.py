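import numpy as np
import pandas as pd
import pytest

from exudomics import preprocess, simulate


@pytest.fixture()
def small_design():
    """3 species x ~8 samples, 6 plots, 4 blanks -- fast fixture."""
    return simulate.generate_design(
        n_species=3,
        n_plots=6,
        per_species_counts=[8, 7, 9],
        n_blanks=4,
        species=[("Alpha one", "forb"), ("Beta two", "forb"),
                 ("Gamma three", "grass")],
        seed=42,
    )


@pytest.fixture()
def small_truth_spec():
    return simulate.TruthSpec(
        n_shared=12,
        n_specific={"Alpha one": 5, "Beta two": 4, "Gamma three": 3},
        n_genus_specific={},
        n_background=30,
        n_blank_contaminants=6,
        n_singletons=5,
        plot_effect_sd=0.0,
    )


@pytest.fixture()
def small_table(small_design, small_truth_spec):
    table, truth = simulate.generate_feature_table(
        small_design, small_truth_spec, seed=11
    )
    return table, truth


def make_feature_table(intensities, species, sample_type=None, plot=None):
    """Hand-build a FeatureTable from a dense array and per-sample labels."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    idx = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "species": list(species),
            "growth_form": ["forb" if s else "" for s in species],
            "plot": list(plot) if plot is not None else ["p1"] * n,
            "region": ["r1"] * n,
            "sample_type": list(sample_type)
            if sample_type is not None
            else ["exudate"] * n,
        },
        index=idx,
    )
    df = pd.DataFrame(
        intensities,
        index=idx,
        columns=[f"f{j}" for j in range(intensities.shape[1])],
    )
    return preprocess.FeatureTable(intensities=df, metadata=meta)
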