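"""Shared fixtures: small synthetic recordings with known ground truth."""

import numpy as np
import pytest

from flyheart.synth import (
    BeatModelParams,
    ImagingParams,
    TubeGeometry,
    render_kymograph,
    simulate_intervals,
    simulate_wall_trace,
)


@pytest.fixture(scope="session")
def regular_recording():
    """Noiseless 30 s recording with a perfectly regular 0.5 s beat."""
    params = BeatModelParams(mean_period=0.5, period_cv=0.0, duration=30.0, seed=11)
    series, truth = simulate_intervals(params)
    geometry = TubeGeometry()
    imaging = ImagingParams()
    trace = simulate_wall_trace(series, geometry, imaging)
    kymo = render_kymograph(trace)
    return {
        "params": params,
        "series": series,
        "truth": truth,
        "geometry": geometry,
        "imaging": imaging,
        "trace": trace,
        "kymo": kymo,
    }


@pytest.fixture(scope="session")
def noisy_recording():
    """Seeded recording with interval variability and contrast/noise = 10."""
    params = BeatModelParams(mean_period=0.5, period_cv=0.1, duration=30.0, seed=23)
    series, truth = simulate_intervals(params)
    geometry = TubeGeometry()
    imaging = ImagingParams(noise_sd=0.08)  # wall_contrast 0.8 -> SNR 10
    trace = simulate_wall_trace(series, geometry, imaging)
    kymo = render_kymograph(trace, seed=99)
    return {
        "params": params,
        "series": series,
        "truth": truth,
        "geometry": geometry,
        "imaging": imaging,
        "trace": trace,
        "kymo": kymo,
    }
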