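"""Shared fixtures: analytic plane-wave movies and a simulated cohort.

Session-scoped because the reaction-diffusion cohort is the expensive
part of the suite; every test that needs simulated physiology shares
one cohort (5 control + 5 failing-heart subjects on a 64 x 64 grid,
full five-CL pacing protocol, SNR-20 acquisition noise).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import voltmap as vm


@pytest.fixture(scope="session")
def plane_movie():
    """Clean plane wave, cv = 60 cm/s, APD80 = 75 ms, default geometry."""
    movie, truth = vm.plane_wave_movie(cv=60.0, apd80=75.0)
    return movie, truth


@pytest.fixture(scope="session")
def plane_maps(plane_movie):
    """Activation/APD maps of the clean plane wave at CL 400."""
    movie, truth = plane_movie
    norm, mask = vm.normalize_movie(movie)
    windows = vm.segment_beats(norm)
    maps = vm.build_maps(norm, windows, mask=mask,
                         roi=vm.default_roi(norm.shape))
    return maps[400.0]


@pytest.fixture(scope="session")
def noisy_plane_result(plane_movie):
    """Full-pipeline analysis of the plane wave at acquisition SNR 10."""
    movie, _ = plane_movie
    noisy = vm.add_acquisition_noise(movie, snr=10.0, seed=42)
    return vm.analyze_movie(noisy)


@pytest.fixture(scope="session")
def cohort():
    """Simulated two-phenotype cohort, analyzed.

    Returns dict with 'df' (tidy per-subject per-CL measurements),
    'results' (subject_id -> MovieResult) and 'truths'
    (subject_id -> GroundTruth).
    """
    rows, results, truths = [], {}, {}
    for phenotype, seed in (("control", 101), ("hf", 202)):
        subjects = vm.simulate_cohort(phenotype, n_subjects=5, grid=64,
                                      snr=20.0, seed=seed)
        for sid, movie, truth in subjects:
            res = vm.analyze_movie(movie)
            results[sid] = res
            truths[sid] = truth
            rows.extend(res.as_records(subject_id=sid, group=phenotype))
    return {"df": pd.DataFrame(rows), "results": results, "truths": truths}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
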