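import numpy as np
import pandas as pd
import pytest

import ventnet
import ventnet.expression as expr
import ventnet.simulate as sim


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline on the default planted configuration, seed 1."""
    return ventnet.run_pipeline(seed=1)


@pytest.fixture(scope="session")
def default_design():
    return sim.simulate_design(sim.SimulationConfig())


@pytest.fixture(scope="session")
def null_de_table():
    """Moderated DE on a 2,000-gene simulation with no planted effects."""
    cfg = sim.SimulationConfig(
        n_genes=2000, module_sizes=(), effect_sizes=(), seed_set_size=0, rng_seed=3
    )
    design = sim.simulate_design(cfg)
    counts, _ = sim.simulate_module_counts(cfg, design)
    filt = expr.filter_low_expression(counts)
    logexpr = expr.log_expression(filt, expr.tmm_factors(filt))
    x = expr.treatment_design(design)
    obs_w, sample_w = expr.precision_weights(logexpr, x)
    contrasts = expr.pairwise_contrasts(x, [("replete_a", "sulfide_limiting")])
    return expr.fit_and_moderate(
        logexpr, x, contrasts, obs_weights=obs_w, sample_weights=sample_w
    )


@pytest.fixture(scope="session")
def power_de():
    """6 vs 6 design with 50 genes carrying a planted 4-fold change."""
    layout = {
        "replete_a": {"sulfide": "replete", "oxygen": "replete",
                      "nitrate": "absent", "hydrogen": "absent"},
        "no_sulfide": {"sulfide": "absent", "oxygen": "replete",
                       "nitrate": "absent", "hydrogen": "absent"},
    }
    cfg = sim.SimulationConfig(
        n_genes=500, module_sizes=(50,),
        effect_sizes=({"sulfide": 2 * np.log(2)},),
        condition_layout=layout, n_replicates=6,
        loading_range=(1.0, 1.0), me_noise_sd=0.05, seed_set_size=0, rng_seed=5,
    )
    design = sim.simulate_design(cfg)
    counts, truth = sim.simulate_module_counts(cfg, design)
    filt = expr.filter_low_expression(counts)
    logexpr = expr.log_expression(filt, expr.tmm_factors(filt))
    x = expr.treatment_design(design)
    obs_w, sample_w = expr.precision_weights(logexpr, x)
    contrasts = expr.pairwise_contrasts(x, [("replete_a", "no_sulfide")])
    table = expr.fit_and_moderate(
        logexpr, x, contrasts, obs_weights=obs_w, sample_weights=sample_w
    )
    planted = {g for g, m in truth.gene_module.items() if m == 0}
    return table, planted
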