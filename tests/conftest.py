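import numpy as np
import pytest

from switchfret import SimConfig, simulate_photon_stream, wt_mdomain_model
from switchfret.burst_processing import detect_bursts, donor_excitation_records
from switchfret.kinetics import KineticModel


@pytest.fixture(scope="session")
def wt_model():
    return wt_mdomain_model()


@pytest.fixture(scope="session")
def two_state_model():
    return KineticModel.from_rates(E=[0.9, 0.1],
                                   rates={(1, 2): 5300.0, (2, 1): 5700.0})


def clean_config(**overrides):
    """Artifact-free simulation settings (kinetics only, no contaminants)."""
    kwargs = dict(leakage=0.0, direct_excitation=0.0, donor_only_fraction=0.0,
                  acceptor_only_fraction=0.0, aa_brightness=1.0)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def wt_records(wt_model):
    """Donor-excitation photon records from a clean WT-like simulation."""
    cfg = clean_config(n_bursts=800, rng_seed=42)
    stream, truth = simulate_photon_stream(cfg, wt_model)
    bursts = detect_bursts(stream)
    return donor_excitation_records(stream, bursts)


@pytest.fixture(scope="session")
def tiny_records(wt_model):
    cfg = clean_config(n_bursts=60, rng_seed=3)
    stream, _ = simulate_photon_stream(cfg, wt_model)
    bursts = detect_bursts(stream)
    return donor_excitation_records(stream, bursts)


def synth_records(model, n_bursts, rate, duration, seed):
    """Photon records drawn directly from the hidden-chain emission model.

    Returns (records, true_state_paths) with per-photon ground truth,
    bypassing the burst-detection stage.
    """
    from switchfret.synthetic_data import simulate_state_path

    rng = np.random.default_rng(seed)
    recs, paths = [], []
    for _ in range(n_bursts):
        n = rng.poisson(rate * duration)
        if n < 2:
            continue
        t = np.sort(rng.uniform(0.0, duration, n))
        t = np.round(t / 25e-9) * 25e-9  # clock-tick resolution, as measured
        path = simulate_state_path(model, duration, rng)
        st = path.state_at(t)
        c = (rng.random(n) < model.E[st]).astype(np.int8)
        recs.append((t, c))
        paths.append(st)
    return recs, paths


def brute_force_loglik(model, times, colors, p0=None):
    """Independent likelihood oracle: exhaustive sum over hidden paths."""
    import itertools

    from scipy.linalg import expm

    p0 = model.pi if p0 is None else np.asarray(p0, float)
    B = np.vstack([1.0 - model.E, model.E])
    Ps = [expm(model.Q * dt) for dt in np.diff(times)]
    total = 0.0
    for path in itertools.product(range(model.K), repeat=len(times)):
        p = p0[path[0]] * B[colors[0], path[0]]
        for n in range(1, len(times)):
            p *= Ps[n - 1][path[n - 1], path[n]] * B[colors[n], path[n]]
        total += p
    return np.log(total)
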