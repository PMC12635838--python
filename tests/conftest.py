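"""Shared fixtures: small synthetic cohorts and fast classifier configs.

Heavy objects (cohorts, per-subject features, trained models) are session
scoped; problem sizes are kept at desk scale (10-25 ROIs, a few hundred
frames) so the whole suite runs on one CPU in minutes.
"""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from metaconn.connectivity import significance_mask
from metaconn.evaluation import GROUP_LABELS, PipelineConfig, compute_subject_features
from metaconn.linkgraph import build_link_graph
from metaconn.negat import NEGATConfig
from metaconn.synthetic import CohortSpec, gen_cohort

warnings.filterwarnings("ignore", category=UserWarning)


def fast_negat(seed: int = 0, epochs: int = 150) -> NEGATConfig:
    """Small-cohort training schedule: hotter LR, compact hidden sizes."""
    return NEGATConfig(
        learning_rate=1e-3, epochs=epochs, node_hidden=16, edge_hidden=16,
        final_hidden=32, mlp_hidden=16, seed=seed,
    )


def fast_pipeline(seed: int = 0, epochs: int = 150, **kw) -> PipelineConfig:
    return PipelineConfig(edge_threshold=0.25, negat=fast_negat(seed, epochs), **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects, 10 ROIs, planted within-module MC contrast 0.9 vs 0.55."""
    spec = CohortSpec(
        n_subjects_per_group=15, n_rois=10, n_timepoints=400,
        within_strength=0.9, group_effect=0.35, n_modules=2, seed=11,
    )
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    ts, _ = small_cohort
    return compute_subject_features(ts, fast_pipeline())


@pytest.fixture(scope="session")
def small_graphs(small_cohort, small_features):
    """Per-subject link graphs with a cohort-level significance mask."""
    _, pheno = small_cohort
    y = pheno["group"].map(GROUP_LABELS).to_numpy()
    streams = [f[0] for f in small_features]
    mcs = [f[1] for f in small_features]
    mask = significance_mask(mcs)
    graphs = [
        build_link_graph(mcs[i], streams[i], mask, edge_threshold=0.25, label=int(y[i]))
        for i in range(len(mcs))
    ]
    return graphs, y
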