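"""Shared fixtures: stimulus set and simulated studies.

Heavy objects are session-scoped; the simulated studies use compact sensor
layouts (the generator's spatial-contiguity and role structure do not depend
on array size) so the whole suite stays desk-scale.
"""

from __future__ import annotations

import numpy as np
import pytest

import tonepred.behavior as beh
import tonepred.shi as shi
import tonepred.stimuli as st
import tonepred.synthetic_data as sd

STIM_SEED = 7
DURATIONS = (150, 300, 600)


@pytest.fixture(scope="session")
def stimset():
    return st.build_stimulus_set(seed=STIM_SEED)


@pytest.fixture(scope="session")
def trials(stimset):
    return st.assign_final_tones(stimset, seed=1)


@pytest.fixture(scope="session")
def grid():
    return st.make_semitone_grid()


@pytest.fixture(scope="session")
def tiny_session(stimset, trials):
    """One subject, 16 sensors, all three durations (for unit tests)."""
    layout = sd.make_grid_layout(n_side=4)
    truth = sd.make_ground_truth(layout)
    recs, behavior = sd.simulate_session(trials, stimset, layout, truth,
                                         seed=3, subject=0)
    return {"layout": layout, "truth": truth, "recordings": recs,
            "behavior": behavior}


@pytest.fixture(scope="session")
def fixed_study(stimset, trials):
    """12 subjects with a fixed informational integration count (K_info = 7)
    and a fixed temporal span (T_int = 1200 ms), 8x8 sensor grid.

    Provides fold-averaged k' maps and shuffled nulls for the shared
    0-150 ms windows in all three duration conditions, tone-33 windowed
    activity for the 300 ms condition, and per-subject behavior.
    """
    layout = sd.make_grid_layout(n_side=8)
    study = sd.simulate_study(stimset, trials, n_subjects=12, layout=layout,
                              seed=42)
    kmaps = {d: [] for d in DURATIONS}
    knulls = {d: [] for d in DURATIONS}
    was300 = []
    behaviors = []
    for s in range(study.n_subjects):
        recs, behavior = study.subject_session(s)
        behaviors.append(behavior)
        for d in DURATIONS:
            wa = shi.window_average(recs[d], trials)
            if d == 300:
                was300.append(wa)
            kmaps[d].append(shi.fit_kprime(wa, stimset, seed=100 + s,
                                           windows=np.arange(3)))
            knulls[d].append(shi.fit_kprime_shuffled(
                wa, stimset, n_rep=100, seed=100 + s, shuffle_seed=500 + s,
                windows=np.arange(3)))
    return {
        "study": study, "layout": layout, "kmaps": kmaps, "knulls": knulls,
        "was300": was300, "behaviors": behaviors,
    }


@pytest.fixture(scope="session")
def coupled_study(stimset, trials):
    """12 subjects with per-subject K_subj coupled to informational sensors
    and to rating sharpness (gamma ~ 1/K_subj), 6x6 sensor grid."""
    layout = sd.make_grid_layout(n_side=6)
    study = sd.simulate_study(stimset, trials, n_subjects=12, layout=layout,
                              seed=77, couple_k_subj=True)
    kmaps = {d: [] for d in DURATIONS}
    f_values = []
    for s in range(study.n_subjects):
        recs, behavior = study.subject_session(s)
        f_values.append(beh.subject_interaction_F(behavior))
        for d in DURATIONS:
            wa = shi.window_average(recs[d], trials)
            kmaps[d].append(shi.fit_kprime(wa, stimset, seed=100 + s,
                                           windows=np.arange(3)))
    return {"study": study, "layout": layout, "kmaps": kmaps,
            "f_values": np.array(f_values)}
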