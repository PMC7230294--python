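import numpy as np
import pytest

from pairedpls import (
    EnsembleConfig,
    apply_quantitation_filter,
    generate_dataset,
    run_ensemble,
)
from pairedpls.panel import default_panel
from pairedpls.simulate import EffectSpec, SimulationConfig, demo_config


@pytest.fixture(scope="session")
def kit_panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_panel(kit_panel):
    """40-metabolite sub-panel (carnitines, hexose, amino acids, amines) for
    fast unit tests."""
    return kit_panel.subset(kit_panel.ids[:5] + kit_panel.ids[40:75])


def make_small_dataset(small_panel, n_pairs=12, effects=(), seed=0, corr=0.5):
    cfg = SimulationConfig(
        n_pairs=n_pairs,
        panel=small_panel,
        effects=[EffectSpec(m, e) for m, e in effects],
        within_patient_corr=corr,
        seed=seed,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_panel):
    ds, _ = make_small_dataset(small_panel, effects=[("Ala", 0.8), ("C2", -0.6)])
    return ds


@pytest.fixture(scope="session")
def strong_run(kit_panel):
    """Study-shaped strong-effect scenario run end to end (shared because it
    is the most expensive fixture: 40 pairs, 188 metabolites, ~2000 models)."""
    cfg, low_ids = demo_config("strong", n_pairs=40, seed=0, panel=kit_panel)
    dataset, truth = generate_dataset(cfg)
    filtered, report = apply_quantitation_filter(dataset, kit_panel)
    result = run_ensemble(filtered, EnsembleConfig(target_n_models=2000, seed=1))
    return {
        "config": cfg,
        "low_ids": low_ids,
        "dataset": dataset,
        "truth": truth,
        "filtered": filtered,
        "report": report,
        "result": result,
    }
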