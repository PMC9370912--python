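import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecgsim.integrator as itg
import ecgsim.models as models
from ecgsim import presets

settings.register_profile(
    "ecgsim", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ecgsim")


def compose_for(model, params, channel="II"):
    """Default single-channel (lead II) composition for each model."""
    if model == "heterogeneous":
        return lambda s: models.compose_ecg_heterogeneous(s, params, channel)
    if model == "reaction_diffusion":
        return lambda s: models.compose_ecg_rd(s, params)
    if model == "ring":
        return lambda s: models.compose_ecg_ring(s, params)
    return models.compose_ecg_qp


@pytest.fixture(scope="session")
def run_preset():
    """Session-cached preset integration + rendering helper."""
    cache = {}

    def run(model, rhythm, duration=30.0, seed=1, fs=500.0):
        key = (model, rhythm, duration, seed, fs)
        if key not in cache:
            preset = presets.get_preset(model, rhythm)
            config = itg.IntegrationConfig(
                duration=duration * preset.time_scale, seed=seed)
            traj = itg.integrate(model, preset.params, config)
            compose = compose_for(model, preset.params)
            raw = np.asarray(compose(traj.states), dtype=float)
            trace = itg.render_trace(traj, compose,
                                     time_scale=preset.time_scale,
                                     gain=preset.gain, fs=fs)
            cache[key] = (preset, traj, raw, trace)
        return cache[key]

    return run
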