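import numpy as np
import pytest

from fcintel import synth, psychometrics
from fcintel.connectome import NodeAtlas
from fcintel.prediction import TrainConfig


@pytest.fixture(scope="session")
def small_atlas():
    """30-node / 7-network atlas with centroids (435 edges)."""
    return NodeAtlas.default(30, seed=0)


@pytest.fixture(scope="session")
def big_cohort():
    """n=5000 cohort for Monte-Carlo moment checks (no connectomes)."""
    cfg = synth.GeneratorConfig(n_subjects=5000, n_nodes=10, n_relevant=5)
    return synth.generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def scored_study(small_atlas):
    """A mid-size synthetic study (cohort, truth, connectomes for one
    state, estimated scores) shared across prediction-level tests."""
    cfg = synth.GeneratorConfig(n_subjects=400, n_nodes=30, n_relevant=150,
                                n_blocks=5, block_coherence=0.8, beta=0.05)
    cohort, truth = synth.generate_cohort(cfg, seed=1)
    conn = synth.generate_connectomes(truth, small_atlas, states=("wm",),
                                      cohort=cohort)
    scores = psychometrics.score_cohort(cohort)
    confounds = cohort[list(synth.CONFOUND_NAMES)].to_numpy(float)
    families = cohort["family_id"].to_numpy()
    return {"cohort": cohort, "truth": truth, "conn": conn,
            "scores": scores, "confounds": confounds, "families": families}


@pytest.fixture()
def fast_train():
    """Small training budget for unit-level model fits."""
    return TrainConfig(grid=((50,),), max_epochs=300, patience=40)


@pytest.fixture()
def tiny_train():
    return TrainConfig(grid=((10,),), max_epochs=60, patience=15)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
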