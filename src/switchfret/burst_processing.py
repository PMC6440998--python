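"""Burst detection and FRET-efficiency / stoichiometry processing.

Freely diffusing molecules produce short photon bursts as they cross the
confocal volume.  This module detects those bursts in a photon stream,
computes per-burst raw FRET efficiency E and stoichiometry S under pulsed
interleaved excitation (PIE/ALEX), estimates leakage and direct-excitation
correction factors from the donor-only and acceptor-only populations of
the E/S plane, applies them, filters doubly labeled molecules by
stoichiometry, and builds efficiency histograms together with the
shot-noise (static molecule) reference.

Conventions
-----------
Detectors and excitation slots are encoded as 0 = donor, 1 = acceptor.
Burst search follows the running-average interphoton-time criterion: the
interphoton intervals are smoothed with a centered 15-photon window, runs
of smoothed intervals below a 10 us cutoff seed a burst, burst edges are
then expanded while the *raw* adjacent interval is still below the
cutoff (deterministic edge rule), and only bursts with >= 30 photons in
total (both detectors, both excitation slots) are kept.  No background or
crosstalk correction is applied at the detection stage; corrections enter
only when computing corrected E/S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

DONOR = 0
ACCEPTOR = 1

__all__ = [
    "DONOR",
    "ACCEPTOR",
    "PhotonStream",
    "Burst",
    "CorrectionFactors",
    "EfficiencyHistogram",
    "detect_bursts",
    "compute_raw_es",
    "estimate_corrections",
    "apply_corrections_and_filter",
    "fret_histogram",
    "shot_noise_reference",
    "donor_excitation_records",
]


@dataclass
class PhotonStream:
    """Timestamped, channel- and excitation-tagged photons of one measurement.

    timestamps are integer clock ticks at the laser repetition period
    (``clock_period`` seconds per tick) and must be sorted.
    """

    timestamps: np.ndarray
    detector: np.ndarray
    excitation_slot: np.ndarray
    clock_period: float = 25e-9

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.detector = np.asarray(self.detector, dtype=np.int8)
        self.excitation_slot = np.asarray(self.excitation_slot, dtype=np.int8)
        if not (len(self.timestamps) == len(self.detector) == len(self.excitation_slot)):
            raise ValueError("timestamps, detector and excitation_slot must align")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be sorted (non-decreasing)")
        for name, arr in (("detector", self.detector), ("excitation_slot", self.excitation_slot)):
            if np.any((arr != DONOR) & (arr != ACCEPTOR)):
                raise ValueError(f"{name} entries must be 0 (donor) or 1 (acceptor)")
        if self.clock_period <= 0:
            raise ValueError("clock_period must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps * self.clock_period


@dataclass
class Burst:
    """One detected single-molecule transit.

    ``start``/``stop`` are indices into the parent stream (stop inclusive).
    Raw E/S are left unclipped; corrected E/S may fall slightly outside
    [0, 1] and are reported as-is with ``out_of_range`` set.
    """

    start: int
    stop: int
    n_DD: int
    n_DA: int
    n_AA: int
    duration: float
    E_raw: float = np.nan
    S_raw: float = np.nan
    E_corr: float = np.nan
    S_corr: float = np.nan
    valid: bool = True
    out_of_range: bool = False

    @property
    def n_photons(self) -> int:
        return self.stop - self.start + 1

    @property
    def size_DX(self) -> int:
        """Photons after donor excitation (the HMM-relevant count)."""
        return self.n_DD + self.n_DA


@dataclass
class CorrectionFactors:
    """Leakage and direct-excitation fractions with estimation diagnostics."""

    leakage: float
    direct_excitation: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (("leakage", self.leakage), ("direct_excitation", self.direct_excitation)):
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")


@dataclass
class EfficiencyHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_bursts: int
    overlays: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def density(self) -> np.ndarray:
        width = np.diff(self.bin_edges)
        total = self.counts.sum()
        return self.counts / (total * width) if total else self.counts * 0.0

    def mean(self) -> float:
        return float(np.sum(self.centers * self.counts) / self.counts.sum())

    def variance(self) -> float:
        mu = self.mean()
        return float(np.sum((self.centers - mu) ** 2 * self.counts) / self.counts.sum())

    def peak_positions(self, min_prominence: float = 0.05) -> np.ndarray:
        """Locate local maxima (modes) of the normalized histogram."""
        from scipy.signal import find_peaks

        dens = self.density
        peaks, _ = find_peaks(dens, prominence=min_prominence * dens.max())
        return self.centers[peaks]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_left": self.bin_edges[:-1],
                           "bin_right": self.bin_edges[1:],
                           "count": self.counts})
        for name, counts in self.overlays.items():
            df[name] = counts
        return df


def detect_bursts(stream: PhotonStream, window: int = 15, cutoff: float = 1e-5,
                  min_photons: int = 30) -> list[Burst]:
    """Find single-molecule bursts by the running-average interphoton criterion.

    Parameters
    ----------
    stream : PhotonStream
    window : photons in the centered running average of interphoton times.
    cutoff : seconds; smoothed interphoton times below this mark a burst.
    min_photons : minimum total photons per kept burst (all channels/slots).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(stream) == 0:
        raise ValueError("empty photon stream")
    n = len(stream)
    if n < 2:
        return []
    # diff in integer ticks first: exact, invariant to any global offset
    dt = np.diff(stream.timestamps) * stream.clock_period
    smooth = uniform_filter1d(dt, size=window, mode="nearest")
    dense = smooth < cutoff

    bursts: list[Burst] = []
    i = 0
    m = len(dt)
    while i < m:
        if not dense[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and dense[j + 1]:
            j += 1
        first, last = i, j + 1  # photon indices spanned by the dense run
        # deterministic edge rule: expand while the raw adjacent interval
        # is itself below the cutoff
        while first > 0 and dt[first - 1] < cutoff:
            first -= 1
        while last < n - 1 and dt[last] < cutoff:
            last += 1
        if bursts and first <= bursts[-1].stop:
            # expansion merged into the previous burst
            prev = bursts.pop()
            first = prev.start
        bursts.append(_make_burst(stream, first, last))
        i = max(j + 1, last)
    return [b for b in bursts if b.n_photons >= min_photons]


def _make_burst(stream: PhotonStream, first: int, last: int) -> Burst:
    det = stream.detector[first:last + 1]
    exc = stream.excitation_slot[first:last + 1]
    n_DD = int(np.sum((exc == DONOR) & (det == DONOR)))
    n_DA = int(np.sum((exc == DONOR) & (det == ACCEPTOR)))
    n_AA = int(np.sum((exc == ACCEPTOR) & (det == ACCEPTOR)))
    duration = float((stream.timestamps[last] - stream.timestamps[first]) * stream.clock_period)
    b = Burst(start=first, stop=last, n_DD=n_DD, n_DA=n_DA, n_AA=n_AA, duration=duration)
    compute_raw_es(b)
    return b


def compute_raw_es(burst: Burst) -> tuple[float, float]:
    """Raw FRET efficiency and stoichiometry from uncorrected counts.

    E_raw uses photons after donor excitation only; S_raw uses photons from
    both excitation slots.  A zero denominator flags the burst invalid
    rather than silently dropping it.
    """
    den_e = burst.n_DD + burst.n_DA
    den_s = den_e + burst.n_AA
    if den_e == 0 or den_s == 0:
        burst.valid = False
        burst.E_raw = np.nan if den_e == 0 else burst.E_raw
        burst.S_raw = np.nan if den_s == 0 else burst.S_raw
        if den_e > 0:
            burst.E_raw = burst.n_DA / den_e
        if den_s > 0:
            burst.S_raw = den_e / den_s
        return burst.E_raw, burst.S_raw
    burst.E_raw = burst.n_DA / den_e
    burst.S_raw = den_e / den_s
    return burst.E_raw, burst.S_raw


def estimate_corrections(bursts: list[Burst], s_donor_only: float = 0.9,
                         s_acceptor_only: float = 0.2) -> CorrectionFactors:
    """Estimate leakage and direct excitation from the E/S populations.

    Leakage is the apparent FRET efficiency of the donor-only population
    (S above ``s_donor_only``); direct excitation is the donor-excitation
    acceptor signal of the acceptor-only population (S below
    ``s_acceptor_only``) expressed relative to its acceptor-excitation
    signal.  Both use photon-weighted (pooled count) estimators.
    """
    donly = [b for b in bursts if b.valid and b.S_raw > s_donor_only]
    # bursts with zero donor-excitation photons are E-invalid but carry
    # S_raw = 0: they are the purest acceptor-only examples and must count
    aonly = [b for b in bursts
             if np.isfinite(b.S_raw) and b.S_raw < s_acceptor_only]
    if not donly:
        raise ValueError("no donor-only population found (high-S bursts absent); "
                         "cannot estimate leakage")
    if not aonly:
        raise ValueError("no acceptor-only population found (low-S bursts absent); "
                         "cannot estimate direct excitation")
    n_da_d = sum(b.n_DA for b in donly)
    n_dd_d = sum(b.n_DD for b in donly)
    leakage = n_da_d / (n_da_d + n_dd_d)
    n_da_a = sum(b.n_DA for b in aonly)
    n_aa_a = sum(b.n_AA for b in aonly)
    direct = n_da_a / n_aa_a if n_aa_a else 0.0
    diag = {
        "n_donor_only": len(donly),
        "n_acceptor_only": len(aonly),
        "s_window_donor_only": (s_donor_only, 1.0),
        "s_window_acceptor_only": (0.0, s_acceptor_only),
    }
    return CorrectionFactors(leakage=float(leakage), direct_excitation=float(direct),
                             diagnostics=diag)


def apply_corrections_and_filter(bursts: list[Burst], factors: CorrectionFactors,
                                 s_window: tuple[float, float] = (0.3, 0.8),
                                 ) -> list[Burst]:
    """Correct counts for leakage/direct excitation and select by stoichiometry.

    Corrected donor-excitation counts::

        n_DD' = n_DD / (1 - l)
        n_DA' = n_DA - n_DD * l / (1 - l) - d * n_AA

    which inverts the generative convention that each emitted donor photon
    is reclassified into the acceptor channel with probability ``l`` and
    that direct excitation adds ``d * n_AA`` acceptor photons in donor
    slots.  Bursts whose corrected S falls outside ``s_window`` are removed.
    """
    l = factors.leakage
    d = factors.direct_excitation
    lo, hi = s_window
    out: list[Burst] = []
    for b in bursts:
        if not b.valid:
            continue
        n_dd_c = b.n_DD / (1.0 - l)
        n_da_c = b.n_DA - b.n_DD * l / (1.0 - l) - d * b.n_AA
        den_e = n_dd_c + n_da_c
        den_s = den_e + b.n_AA
        if den_e <= 0 or den_s <= 0:
            b.valid = False
            continue
        b.E_corr = n_da_c / den_e
        b.S_corr = den_e / den_s
        b.out_of_range = not (0.0 <= b.E_corr <= 1.0 and 0.0 <= b.S_corr <= 1.0)
        if lo <= b.S_corr <= hi:
            out.append(b)
    if not out:
        import warnings

        warnings.warn("stoichiometry filter removed every burst", stacklevel=2)
    return out


def fret_histogram(bursts: list[Burst], n_bins: int = 41,
                   use_corrected: bool = False) -> EfficiencyHistogram:
    """Histogram of per-burst FRET efficiency over [0, 1]."""
    if not bursts:
        raise ValueError("need at least one burst")
    e = np.array([b.E_corr if use_corrected else b.E_raw for b in bursts])
    e = e[np.isfinite(e)]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(e, 0.0, 1.0), bins=edges)
    return EfficiencyHistogram(bin_edges=edges, counts=counts, n_bursts=len(e))


def shot_noise_reference(bursts: list[Burst], E_mean: float, n_bins: int = 41,
                         seed: int | None = 0) -> EfficiencyHistogram:
    """Static-molecule reference histogram expected from shot noise alone.

    For each burst the acceptor count is resampled binomially at fixed
    ``E_mean`` with that burst's donor-excitation photon number, so the
    reference has exactly the measured burst-size distribution but no
    conformational dynamics.
    """
    rng = np.random.default_rng(seed)
    sizes = np.array([b.size_DX for b in bursts if b.valid and b.size_DX > 0])
    n_acc = rng.binomial(sizes, E_mean)
    e = n_acc / sizes
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(e, bins=edges)
    return EfficiencyHistogram(bin_edges=edges, counts=counts, n_bursts=len(e))


def donor_excitation_records(stream: PhotonStream, bursts: list[Burst],
                             ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-burst (arrival times [s], colors) of donor-excitation photons.

    This is the photon record consumed by the photon-by-photon HMM stage:
    colors are 0 (donor channel) / 1 (acceptor channel), times are seconds
    at clock-tick resolution.
    """
    out = []
    for b in bursts:
        sl = slice(b.start, b.stop + 1)
        exc = stream.excitation_slot[sl]
        keep = exc == DONOR
        times = stream.timestamps[sl][keep] * stream.clock_period
        colors = stream.detector[sl][keep].astype(np.int8)
        if len(times) >= 2:
            out.append((times, colors))
    return out


def bursts_to_frame(bursts: list[Burst]) -> pd.DataFrame:
    """Burst table, one row per burst (the CSV export schema)."""
    return pd.DataFrame([{
        "start": b.start, "stop": b.stop,
        "n_DD": b.n_DD, "n_DA": b.n_DA, "n_AA": b.n_AA,
        "duration_s": b.duration,
        "E_raw": b.E_raw, "S_raw": b.S_raw,
        "E_corr": b.E_corr, "S_corr": b.S_corr,
        "valid": b.valid, "out_of_range": b.out_of_range,
    } for b in bursts])
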