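import numpy as np
import pytest

from fcstates import (SynthConfig, build_group_targets, compute_fc,
                      simulate_timeseries)


def weight_stacks(config: SynthConfig):
    """Per-condition (subjects x edges) Fisher-z stacks via the public API.

    Returns (nc, bs, post, edges) with edges the upper-triangle index
    pairs; patient rows are aligned between bs and post.
    """
    targets, _ = build_group_targets(config)
    sessions = simulate_timeseries(targets, config)
    r = config.n_rois
    iu = np.triu_indices(r, k=1)
    rows = {"single": {}, "baseline": {}, "post": {}}
    for s in sessions:
        z = np.arctanh(np.clip(compute_fc(s), -0.999999, 0.999999))
        rows[s.session][s.subject_id] = z[iu]
    nc = np.array([rows["single"][sid] for sid in config.control_ids()])
    bs = np.array([rows["baseline"][sid] for sid in config.patient_ids()])
    post = np.array([rows["post"][sid] for sid in config.patient_ids()])
    edges = list(zip(*iu))
    return nc, bs, post, edges


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    return SynthConfig(n_controls=6, n_patients=7, n_rois=8, n_timepoints=60,
                       seed=11)


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.4):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
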