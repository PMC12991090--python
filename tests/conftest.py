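"""Shared fixtures: one synthetic biopsy per session, with labels, features
and trained models reused across test modules to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rocit_lite.classifier import TrainConfig, train
from rocit_lite.features import build_feature_sets
from rocit_lite.io import compute_site_distribution
from rocit_lite.labeling import run_labeling
from rocit_lite.nn import ModelConfig, TransformerClassifier
from rocit_lite.simulate import SimulationConfig, simulate_biopsy

settings.register_profile("det", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("det")

BIOPSY_SEED = 1
TRAIN_CHROMS = ("chr1", "chr2")
VAL_CHROMS = ("chr4", "chr21")
TEST_CHROMS = ("chr5", "chr22")


@pytest.fixture(scope="session")
def biopsy():
    """The default synthetic biopsy (study conditions of the whole suite)."""
    return simulate_biopsy(SimulationConfig(seed=BIOPSY_SEED))


@pytest.fixture(scope="session")
def site_dist(biopsy):
    return compute_site_distribution(biopsy.reads)


@pytest.fixture(scope="session")
def pipeline_labels(biopsy):
    return run_labeling(
        biopsy.reads, biopsy.variants, biopsy.segments, biopsy.clusters, biopsy.purity
    )


@pytest.fixture(scope="session")
def truth_map(biopsy):
    return {r.read_id: int(biopsy.truth.origin[r.read_id] == "tumor") for r in biopsy.reads}


def _sample(pool, n, rng):
    idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    return [pool[i] for i in idx]


@pytest.fixture(scope="session")
def gt_sets(biopsy, site_dist, truth_map):
    """Ground-truth-labeled feature sets: train / val / eval reads + eval reads."""
    rng = np.random.default_rng(2024)
    pools = {
        "train": [r for r in biopsy.reads if r.chromosome in TRAIN_CHROMS],
        "val": [r for r in biopsy.reads if r.chromosome in VAL_CHROMS],
        "test": [r for r in biopsy.reads if r.chromosome in TEST_CHROMS],
    }
    tr = _sample(pools["train"], 2200, rng)
    va = _sample(pools["val"], 400, rng)
    te = _sample(pools["test"], 1500, rng)
    return {
        "train": build_feature_sets(tr, site_dist, biopsy.atlas, labels=truth_map),
        "val": build_feature_sets(va, site_dist, biopsy.atlas, labels=truth_map),
        "test": build_feature_sets(te, site_dist, biopsy.atlas),
        "test_reads": te,
    }


@pytest.fixture(scope="session")
def desk_model(gt_sets):
    """Desk-scale transformer (embed 64, 2 blocks) trained once per session."""
    model = TransformerClassifier(ModelConfig.desk(), seed=0)
    history = train(model, gt_sets["train"], gt_sets["val"], TrainConfig.desk(seed=0, batch_size=64))
    return model, history


@pytest.fixture(scope="session")
def pert_model(gt_sets):
    """Small interpretability model (embed 16, 1 block, 128-CpG cap)."""
    model = TransformerClassifier(ModelConfig.desk_small(), seed=0)
    # tiny models escape their initial plateau late; epochs are cheap here
    history = train(
        model, gt_sets["train"][:1500], gt_sets["val"],
        TrainConfig.desk(seed=0, batch_size=32, max_epochs=60, early_stop_patience=15),
    )
    return model, history


@pytest.fixture(scope="session")
def tiny_feature_sets(biopsy, site_dist, truth_map):
    """A small labeled feature-set pool for fast unit tests."""
    rng = np.random.default_rng(7)
    reads = _sample(biopsy.reads, 300, rng)
    return build_feature_sets(reads, site_dist, biopsy.atlas, labels=truth_map)
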