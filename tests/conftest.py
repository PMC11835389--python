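"""Shared fixtures: small synthetic studies with known ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from vishom import synthetic_data as sd
from vishom.display_model import build_display_responses


@pytest.fixture(scope="session")
def small_study():
    """16 objects, 3 latent dims, boundary-labeled decision data with noise."""
    gt, displays = sd.make_ground_truth(n_objects=16, k=3, seed=11)
    trials = sd.gen_decision_trials(gt, displays, label_mode="boundary")
    labels = np.array(trials["label"][: len(displays)])
    rts = sd.mean_decision_rts(trials, displays)
    responses = build_display_responses(gt, displays)
    return dict(gt=gt, displays=displays, labels=labels, rts=rts, responses=responses)


@pytest.fixture(scope="session")
def noiseless_study():
    """As small_study but with zero decision noise: within-group r is exactly +/-1."""
    gt, displays = sd.make_ground_truth(n_objects=16, k=3, seed=11)
    gt = replace(gt, rt_link=replace(gt.rt_link, sigma=0.0))
    trials = sd.gen_decision_trials(gt, displays, label_mode="boundary")
    labels = np.array(trials["label"][: len(displays)])
    rts = sd.mean_decision_rts(trials, displays)
    responses = build_display_responses(gt, displays)
    return dict(gt=gt, displays=displays, labels=labels, rts=rts, responses=responses)
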