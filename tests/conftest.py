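import pandas as pd
import pytest

from sirnascreen import (
    SimulationConfig,
    assign_effect_classes,
    call_hits,
    normalize_screen,
    simulate_campaign,
)


@pytest.fixture(scope="session")
def zero_noise_config():
    """Small all-class campaign in the exact zero-noise limit."""
    return SimulationConfig(
        n_genes=120,
        noise_sd_2d=0.0,
        noise_sd_3d=0.0,
        sphere_noise="lognormal",
        class_proportions={
            "neutral": 0.5,
            "common_essential": 0.1,
            "two_d_only": 0.1,
            "three_d_only": 0.1,
            "selective": 0.1,
            "count_down_viability_up": 0.1,
        },
        seed=42,
    )


@pytest.fixture(scope="session")
def zero_noise_campaign(zero_noise_config):
    truth = assign_effect_classes(zero_noise_config)
    raw = simulate_campaign(zero_noise_config, truth)
    return zero_noise_config, truth, raw


@pytest.fixture(scope="session")
def zero_noise_results(zero_noise_campaign):
    config, truth, raw = zero_noise_campaign
    norm = normalize_screen(raw)
    hits = call_hits(norm)
    return config, truth, raw, norm, hits


@pytest.fixture(scope="session")
def noisy_campaign():
    """Default-noise triplicate campaign, all effect classes planted."""
    config = SimulationConfig(n_genes=400, seed=5)
    truth = assign_effect_classes(config)
    raw = simulate_campaign(config, truth)
    return config, truth, raw


def make_result_table(rows):
    """Build a per-screen result table from (line, readout, gene, mean, p, hit)."""
    return pd.DataFrame(
        rows,
        columns=["cell_line", "readout", "gene_id", "log2fc_mean", "p_value", "hit_flag"],
    ).assign(log2fc_sd=0.1, n_replicates=3)[
        ["cell_line", "readout", "gene_id", "log2fc_mean", "log2fc_sd",
         "n_replicates", "p_value", "hit_flag"]
    ]


@pytest.fixture
def result_table_factory():
    return make_result_table
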