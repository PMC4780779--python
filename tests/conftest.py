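import logging

import numpy as np
import pytest

from nichelimits import contrast_pipeline as cp
from nichelimits.backbone_tree import BranchLengthScheme
from nichelimits.synthetic_data import ScenarioConfig, make_scenario, simulate_yule_tree

# boundary-fit warnings from profile searches are expected in simulations
logging.getLogger("nichelimits.pgls_core").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """One small synthetic bundle (shared, read-only) plus its run config."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = ScenarioConfig(n_sampled=24, n_grafted=12, n_transitions=3, n_records=40)
    truth = make_scenario(cfg, seed=2024, out_dir=out)
    run_cfg = cp.RunConfig(
        occurrences=str(out / "occurrences.csv"),
        grids={v: str(out / f"grid_{v}.asc") for v in ("AI", "MTWQ", "MTCQ")},
        tree=str(out / "tree.nwk"),
        backbone_spec=str(out / "backbone.txt"),
        assignments=str(out / "assignments.csv"),
        output_dir=str(out),
        schemes=[BranchLengthScheme.CLADE_MEAN],
        seed=2024,
    )
    return {"dir": out, "truth": truth, "config": run_cfg, "scenario_config": cfg}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_trees():
    """Factory: n deterministic Yule trees of a given tip count."""

    def factory(count, n_tips, seed=99):
        r = np.random.default_rng(seed)
        return [simulate_yule_tree(n_tips, 1.0, r) for _ in range(count)]

    return factory
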