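"""Shared fixtures: a planted synthetic study, its fused kernels, CV reports.

The expensive session-scoped fixtures (kernel stacks, fusion, repeated
cross-validation) are computed once and shared between the unit tests and
the acceptance tests.
"""

import numpy as np
import pytest

from circlink.evaluation import cross_validate
from circlink.fusion import SkfConfig, skf_fuse
from circlink.io_net import build_network
from circlink.kernels import assemble_kernel_stacks
from circlink.model import CnnConfig
from circlink.synthetic import SyntheticSpec, generate_study

STUDY_SEED = 7
CV_FOLDS = 5
CV_REPS = 3


@pytest.fixture(scope="session")
def study():
    """The default planted-block study: 40 circRNAs, 15 diseases, 60 miRNAs."""
    return generate_study(SyntheticSpec(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def kernel_stacks(study):
    return assemble_kernel_stacks(
        study.network,
        expression=study.expression,
        sequences=study.sequences,
        dag=study.dag,
        precomputed=study.precomputed,
    )


@pytest.fixture(scope="session")
def fused(kernel_stacks):
    """Fused circRNA and disease similarity matrices (default SKF settings)."""
    circ_k, dis_k = kernel_stacks
    cfg = SkfConfig()
    return (
        skf_fuse(circ_k, cfg, name="Sc").kernel.matrix,
        skf_fuse(dis_k, cfg, name="Sd").kernel.matrix,
    )


@pytest.fixture(scope="session")
def cv_report(study, fused):
    """5-fold CV x 3 repetitions of the full stack on the planted study."""
    Sc, Sd = fused
    return cross_validate(
        study.network, Sc, Sd, cnn_config=CnnConfig(),
        folds=CV_FOLDS, repetitions=CV_REPS, seed=1,
    )


@pytest.fixture(scope="session")
def shuffled_report(study, fused):
    """Label-shuffled null control of the same CV protocol."""
    Sc, Sd = fused
    return cross_validate(
        study.network, Sc, Sd, cnn_config=CnnConfig(),
        folds=CV_FOLDS, repetitions=CV_REPS, seed=2, shuffle_labels=True,
    )


@pytest.fixture()
def toy_network():
    """Hand-sized network: 5 circRNAs, 3 diseases, 4 miRNAs."""
    cd = [("c1", "d1"), ("c2", "d1"), ("c3", "d2"), ("c4", "d3"), ("c5", "d2")]
    cm = [("c1", "m1"), ("c1", "m2"), ("c2", "m2"), ("c3", "m3"),
          ("c4", "m4"), ("c5", "m3"), ("c5", "m4")]
    dm = [("d1", "m1"), ("d2", "m3"), ("d3", "m4"), ("d1", "m2")]
    return build_network(cd, cm, dm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
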