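"""Synthetic photon streams, toy structures and kinetic curves.

The generator emulates a diffusion-based smFRET measurement with pulsed
interleaved excitation (PIE): molecules cross the confocal volume one at
a time and emit rectangular photon bursts (exponentially distributed
durations) at a configurable in-burst rate, while a hidden continuous-time
Markov chain switches the molecule between FRET states.  Donor-excitation
photons are colored by the state's transfer efficiency with optional
leakage (donor photons reclassified into the acceptor channel) and direct
acceptor excitation (extra acceptor photons in donor slots, in proportion
to the acceptor-excitation signal); acceptor-excitation slots report
acceptor presence for stoichiometry.  Donor-only and acceptor-only
contaminant species and uniform background photons complete the mixture.

Everything is driven by a single seeded generator, so streams are bitwise
reproducible.  Ground truth (per-photon state, per-photon burst id,
per-burst species) is returned alongside the stream to enable parameter
recovery and filter-purity tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burst_processing import ACCEPTOR, DONOR, PhotonStream
from .kinetics import KineticModel

__all__ = [
    "SimConfig",
    "GroundTruth",
    "StateTrajectory",
    "simulate_state_path",
    "simulate_photon_stream",
    "generate_toy_complex",
    "simulate_kinetic_curves",
]

# species codes in GroundTruth.burst_species
DOUBLE_LABELED = 0
DONOR_ONLY = 1
ACCEPTOR_ONLY = 2


@dataclass
class SimConfig:
    """Study conditions for a simulated PIE smFRET measurement.

    Defaults follow the measurement this package models: ~190,000
    photons/s inside bursts, 3:1 donor:acceptor pulse interleaving at a
    40 MHz repetition rate, millisecond bursts.  Background rates and the
    mean inter-burst gap are not constrained by that measurement and are
    set to typical confocal values.

    ``aa_brightness`` scales the emission rate in acceptor-excitation
    slots relative to the equal-per-pulse-brightness baseline of
    ``in_burst_photon_rate * (1 - donor_slot_fraction)``; the default of
    4 emulates the usual PIE practice of pumping the acceptor hard enough
    that acceptor-only molecules yield detectable bursts and doubly
    labeled molecules sit mid-range in stoichiometry.  Set it to 1 for a
    stream whose photon counts split between excitation slots exactly at
    the pulse ratio.
    """

    n_bursts: int = 1000
    burst_duration_mean: float = 1e-3
    in_burst_photon_rate: float = 190e3
    background_rate_donor: float = 2000.0
    background_rate_acceptor: float = 1000.0
    pie_ratio: tuple[int, int] = (3, 1)
    laser_rep_rate: float = 4.0e7
    leakage: float = 0.05
    direct_excitation: float = 0.03
    donor_only_fraction: float = 0.2
    acceptor_only_fraction: float = 0.1
    inter_burst_gap_mean: float = 5e-3
    aa_brightness: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.burst_duration_mean, self.in_burst_photon_rate,
                 self.background_rate_donor, self.background_rate_acceptor,
                 self.laser_rep_rate, self.inter_burst_gap_mean)
        if any(r < 0 for r in rates):
            raise ValueError("rates and durations must be non-negative")
        fracs = (self.leakage, self.direct_excitation,
                 self.donor_only_fraction, self.acceptor_only_fraction)
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.aa_brightness <= 0:
            raise ValueError("aa_brightness must be positive")
        if self.donor_only_fraction + self.acceptor_only_fraction > 1:
            raise ValueError("contaminant fractions exceed 1")
        if (len(self.pie_ratio) != 2
                or any(int(p) != p or p <= 0 for p in self.pie_ratio)):
            raise ValueError("pie_ratio must be two positive integers")
        if self.n_bursts < 1:
            raise ValueError("n_bursts must be >= 1")

    @property
    def clock_period(self) -> float:
        return 1.0 / self.laser_rep_rate

    @property
    def donor_slot_fraction(self) -> float:
        pd_, pa = self.pie_ratio
        return pd_ / (pd_ + pa)


@dataclass
class GroundTruth:
    """Generating truth for one simulated stream (test plumbing).

    photon_state : per-photon hidden state index into the generating model
        (-1 for background, direct-excitation and acceptor-slot photons);
    photon_burst : per-photon burst id (-1 for background);
    burst_species : per-burst species code (0 double-labeled, 1 donor-only,
        2 acceptor-only); burst_start_s / burst_duration_s : true envelopes.
    """

    photon_state: np.ndarray
    photon_burst: np.ndarray
    burst_species: np.ndarray
    burst_start_s: np.ndarray
    burst_duration_s: np.ndarray
    model: KineticModel

    def __post_init__(self) -> None:
        valid = self.photon_state[self.photon_state >= 0]
        if valid.size and valid.max() >= self.model.K:
            raise ValueError("state labels exceed the generating model's states")


@dataclass
class StateTrajectory:
    """Piecewise-constant trajectory: states[i] holds on [times[i], times[i+1])."""

    times: np.ndarray      # switch times, times[0] == 0
    states: np.ndarray
    duration: float

    def state_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def time_in_state(self, K: int | None = None) -> np.ndarray:
        K = K or int(self.states.max()) + 1
        bounds = np.append(self.times, self.duration)
        dwell = np.diff(bounds)
        return np.bincount(self.states, weights=dwell, minlength=K)


def simulate_state_path(model: KineticModel, duration: float,
                        seed: int | np.random.Generator | None = None,
                        initial_state: int | None = None) -> StateTrajectory:
    """Exact (Gillespie) simulation of the continuous-time Markov chain.

    The dwell in state i is exponential with the total exit rate of i; the
    initial state is drawn from the stationary distribution unless
    ``initial_state`` overrides it.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = model.Q
    s = int(initial_state) if initial_state is not None else int(rng.choice(model.K, p=model.pi))
    times = [0.0]
    states = [s]
    t = 0.0
    while True:
        lam = -Q[s, s]
        if lam <= 0:
            break  # absorbing / single state: dwell covers the rest
        t += rng.exponential(1.0 / lam)
        if t >= duration:
            break
        probs = Q[s].copy()
        probs[s] = 0.0
        probs = probs / lam
        s = int(rng.choice(model.K, p=probs))
        times.append(t)
        states.append(s)
    return StateTrajectory(times=np.array(times), states=np.array(states, dtype=np.int64),
                           duration=duration)


def simulate_photon_stream(config: SimConfig, model: KineticModel,
                           seed: int | None = None) -> tuple[PhotonStream, GroundTruth]:
    """Generate a full PIE photon stream plus ground truth.

    Draw order (single RNG): for each burst in sequence — inter-burst gap,
    duration, species, photon counts, photon times, state path, emission
    colors, leakage, direct/acceptor-slot photons — then global background
    counts, times, channels and slots, then slot-offset snapping.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    fD = config.donor_slot_fraction
    R = config.in_burst_photon_rate
    rate_fret = R * fD                      # FRET-pathway photons (donor slots)
    # acceptor-excitation emission; aa_brightness > 1 models a red laser
    # pumping acceptors harder per pulse than the equal-brightness baseline
    rate_aa = config.aa_brightness * R * (1.0 - fD)
    rate_dir = config.direct_excitation * rate_aa

    p_species = [1.0 - config.donor_only_fraction - config.acceptor_only_fraction,
                 config.donor_only_fraction, config.acceptor_only_fraction]

    times: list[np.ndarray] = []
    det: list[np.ndarray] = []
    slot: list[np.ndarray] = []
    state_lbl: list[np.ndarray] = []
    burst_lbl: list[np.ndarray] = []

    species = np.empty(config.n_bursts, dtype=np.int8)
    burst_start = np.empty(config.n_bursts)
    burst_dur = np.empty(config.n_bursts)

    t0 = 0.0
    for b in range(config.n_bursts):
        t0 += rng.exponential(config.inter_burst_gap_mean)
        dur = rng.exponential(config.burst_duration_mean)
        sp = int(rng.choice(3, p=p_species))
        species[b] = sp
        burst_start[b] = t0
        burst_dur[b] = dur

        if sp in (DOUBLE_LABELED, DONOR_ONLY):
            n_fret = rng.poisson(rate_fret * dur)
            tt = np.sort(rng.uniform(0.0, dur, n_fret))
            if sp == DOUBLE_LABELED:
                path = simulate_state_path(model, dur, rng)
                st = path.state_at(tt)
                e = model.E[st]
            else:
                st = np.full(n_fret, -1, dtype=np.int64)
                e = np.zeros(n_fret)
            acc = rng.random(n_fret) < e
            leak = (~acc) & (rng.random(n_fret) < config.leakage)
            ch = np.where(acc | leak, ACCEPTOR, DONOR).astype(np.int8)
            times.append(t0 + tt)
            det.append(ch)
            slot.append(np.zeros(n_fret, dtype=np.int8))
            state_lbl.append(st)
            burst_lbl.append(np.full(n_fret, b, dtype=np.int64))

        if sp in (DOUBLE_LABELED, ACCEPTOR_ONLY):
            n_aa = rng.poisson(rate_aa * dur)
            tt = np.sort(rng.uniform(0.0, dur, n_aa))
            times.append(t0 + tt)
            det.append(np.full(n_aa, ACCEPTOR, dtype=np.int8))
            slot.append(np.ones(n_aa, dtype=np.int8))
            state_lbl.append(np.full(n_aa, -1, dtype=np.int64))
            burst_lbl.append(np.full(n_aa, b, dtype=np.int64))

            n_dir = rng.poisson(rate_dir * dur)
            tt = np.sort(rng.uniform(0.0, dur, n_dir))
            times.append(t0 + tt)
            det.append(np.full(n_dir, ACCEPTOR, dtype=np.int8))
            slot.append(np.zeros(n_dir, dtype=np.int8))
            state_lbl.append(np.full(n_dir, -1, dtype=np.int64))
            burst_lbl.append(np.full(n_dir, b, dtype=np.int64))

        t0 += dur
    t_end = t0 + rng.exponential(config.inter_burst_gap_mean)

    for bg_rate, channel in ((config.background_rate_donor, DONOR),
                             (config.background_rate_acceptor, ACCEPTOR)):
        n_bg = rng.poisson(bg_rate * t_end)
        tt = rng.uniform(0.0, t_end, n_bg)
        times.append(tt)
        det.append(np.full(n_bg, channel, dtype=np.int8))
        slot.append((rng.random(n_bg) >= fD).astype(np.int8))
        state_lbl.append(np.full(n_bg, -1, dtype=np.int64))
        burst_lbl.append(np.full(n_bg, -1, dtype=np.int64))

    t_all = np.concatenate(times) if times else np.empty(0)
    det_all = np.concatenate(det) if det else np.empty(0, dtype=np.int8)
    slot_all = np.concatenate(slot) if slot else np.empty(0, dtype=np.int8)
    st_all = np.concatenate(state_lbl) if state_lbl else np.empty(0, dtype=np.int64)
    bl_all = np.concatenate(burst_lbl) if burst_lbl else np.empty(0, dtype=np.int64)

    period = sum(config.pie_ratio)
    n_frames = t_end / config.clock_period / period
    if n_frames >= 2 ** 62:
        raise OverflowError("measurement span overflows the 64-bit clock")

    # snap each photon to a laser pulse consistent with its excitation slot
    frame = np.floor(t_all / (config.clock_period * period)).astype(np.int64)
    p_d = config.pie_ratio[0]
    offs = np.where(slot_all == DONOR,
                    rng.integers(0, p_d, len(t_all)),
                    p_d + rng.integers(0, period - p_d, len(t_all)))
    ticks = frame * period + offs

    order = np.argsort(ticks, kind="stable")
    stream = PhotonStream(timestamps=ticks[order], detector=det_all[order],
                          excitation_slot=slot_all[order],
                          clock_period=config.clock_period)
    truth = GroundTruth(photon_state=st_all[order], photon_burst=bl_all[order],
                        burst_species=species, burst_start_s=burst_start,
                        burst_duration_s=burst_dur, model=model)
    return stream, truth


def generate_toy_complex(n_body_atoms: int = 80, n_domain_atoms: int = 12,
                         anchor_index: int | None = None, seed: int = 0):
    """Desk-scale rigid-body test system: a slab body with a rod domain.

    The body is a two-layer slab of carbon-like atoms on a ~3.5 A grid;
    the mobile domain is a jittered rod anchored to a body atom and
    pointing away from the slab.  Four labeled attachment sites (two on
    the body, two on the domain) provide three informative body<->domain
    FRET pairs, mirroring the labeling topology used for triangulating a
    mobile domain against a fixed scaffold.

    Returns a :class:`switchfret.structure_model.Structure`.
    """
    from .structure_model import Structure

    if n_body_atoms < 1 or n_domain_atoms < 1:
        raise ValueError("atom counts must be >= 1")
    rng = np.random.default_rng(seed)
    spacing = 3.5
    per_layer = int(np.ceil(n_body_atoms / 2))
    nx = int(np.ceil(np.sqrt(per_layer)))
    xs, ys = np.meshgrid(np.arange(nx), np.arange(nx), indexing="ij")
    layer = np.column_stack([xs.ravel(), ys.ravel()]) * spacing
    body = np.vstack([
        np.column_stack([layer, np.zeros(len(layer))]),
        np.column_stack([layer, np.full(len(layer), -spacing)]),
    ])[:n_body_atoms]
    body = body - body.mean(axis=0) + [0.0, 0.0, 0.0]
    body += rng.normal(0.0, 0.15, body.shape)

    if anchor_index is None:
        # top-layer atom closest to the slab center
        top = np.flatnonzero(body[:, 2] > -spacing / 2)
        anchor_index = int(top[np.argmin(np.linalg.norm(body[top, :2], axis=1))])
    if not (0 <= anchor_index < len(body)):
        raise ValueError("anchor_index outside the body")
    anchor = body[anchor_index]

    rod = np.zeros((n_domain_atoms, 3))
    rod[:, 2] = spacing * (np.arange(n_domain_atoms) + 1)
    rod[:, :2] += rng.normal(0.0, 0.3, (n_domain_atoms, 2))
    domain = anchor + rod

    coords = np.vstack([body, domain])
    n = len(coords)
    mask = np.zeros(n, dtype=bool)
    mask[len(body):] = True

    # labeled sites: two well-separated body atoms plus domain mid and tip
    corner_a = int(np.argmin(body[:, 0] + body[:, 1]))
    corner_b = int(np.argmax(body[:, 0] - body[:, 1]))
    sites = {
        "body_a": corner_a,
        "body_b": corner_b,
        "dom_mid": len(body) + n_domain_atoms // 2,
        "dom_tip": len(body) + n_domain_atoms - 1,
    }
    return Structure(
        coords=coords,
        radii=np.full(n, 1.7),
        elements=np.full(n, "C"),
        res_ids=np.arange(1, n + 1),
        chain_ids=np.where(mask, "B", "A"),
        atom_names=np.full(n, "CA"),
        domain_mask=mask,
        anchor=anchor.copy(),
        sites=sites,
    )


def _hill(s, vmax, k_half, n):
    s = np.asarray(s, dtype=float)
    return vmax * s ** n / (s ** n + k_half ** n)


def _isotherm(c, r0, amplitude, kd):
    c = np.asarray(c, dtype=float)
    return r0 + amplitude * c / (c + kd)


def simulate_kinetic_curves(kind: str, params: dict, noise_sd: float = 0.0,
                            n_points: int = 12, seed: int | None = 0,
                            x_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Noisy saturation curves for fit-recovery tests.

    kind="hill": v(S) = Vmax S^n / (S^n + K_half^n) with params
    ``vmax, k_half, n``; x spans 0.2-5x K_half by default.
    kind="isotherm": r(c) = r0 + amplitude * c / (c + Kd) with params
    ``r0, amplitude, kd``; x spans 0 to ~8x Kd by default (0-25 uM for
    the DnaK-titration-like Kd of 3 uM).
    """
    if any(v <= 0 for k, v in params.items() if k != "r0"):
        raise ValueError("model parameters must be positive")
    rng = np.random.default_rng(seed)
    if kind == "hill":
        if n_points < 3:
            raise ValueError("need at least as many points as free parameters")
        lo, hi = x_range or (0.2 * params["k_half"], 5.0 * params["k_half"])
        x = np.linspace(lo, hi, n_points)
        y = _hill(x, params["vmax"], params["k_half"], params["n"])
    elif kind == "isotherm":
        if n_points < 3:
            raise ValueError("need at least as many points as free parameters")
        lo, hi = x_range or (0.0, 25.0 * params["kd"] / 3.0)
        x = np.linspace(lo, hi, n_points)
        y = _isotherm(x, params["r0"], params["amplitude"], params["kd"])
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    y = y + rng.normal(0.0, noise_sd, n_points)
    return pd.DataFrame({"x": x, "y": y})
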