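"""Photon-HDF5-style storage for photon streams and ground truth.

Follows the Photon-HDF5 field layout (``photon_data/timestamps``,
``photon_data/detectors``, ``photon_data/timestamps_specs/timestamps_unit``,
``photon_data/measurement_specs``) written directly with h5py.  Because
this package tags each photon's excitation slot explicitly (instead of
deriving it from TCSPC nanotimes), the slot array is stored as
``photon_data/excitation_slots``.  Simulated files carry a sidecar
``ground_truth`` group so recovery tests can read back the generating
labels.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .burst_processing import PhotonStream
from .kinetics import KineticModel
from .synthetic_data import GroundTruth

__all__ = ["write_photon_hdf5", "read_photon_hdf5"]


def write_photon_hdf5(path, stream: PhotonStream, truth: GroundTruth | None = None,
                      description: str = "simulated PIE smFRET measurement") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["description"] = description
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.timestamps, compression="gzip")
        g.create_dataset("detectors", data=stream.detector, compression="gzip")
        g.create_dataset("excitation_slots", data=stream.excitation_slot,
                         compression="gzip")
        g.create_group("timestamps_specs").create_dataset(
            "timestamps_unit", data=stream.clock_period)
        ms = g.create_group("measurement_specs")
        ms.create_dataset("measurement_type", data="smFRET-PIE")
        ms.create_dataset("alex_period", data=np.int64(0))
        if truth is not None:
            t = f.create_group("ground_truth")
            t.create_dataset("photon_state", data=truth.photon_state, compression="gzip")
            t.create_dataset("photon_burst", data=truth.photon_burst, compression="gzip")
            t.create_dataset("burst_species", data=truth.burst_species)
            t.create_dataset("burst_start_s", data=truth.burst_start_s)
            t.create_dataset("burst_duration_s", data=truth.burst_duration_s)
            t.attrs["model_json"] = json.dumps(truth.model.to_dict())


def read_photon_hdf5(path) -> tuple[PhotonStream, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        stream = PhotonStream(
            timestamps=g["timestamps"][:],
            detector=g["detectors"][:],
            excitation_slot=g["excitation_slots"][:],
            clock_period=float(g["timestamps_specs/timestamps_unit"][()]),
        )
        truth = None
        if "ground_truth" in f:
            t = f["ground_truth"]
            truth = GroundTruth(
                photon_state=t["photon_state"][:],
                photon_burst=t["photon_burst"][:],
                burst_species=t["burst_species"][:],
                burst_start_s=t["burst_start_s"][:],
                burst_duration_s=t["burst_duration_s"][:],
                model=KineticModel.from_dict(json.loads(t.attrs["model_json"])),
            )
    return stream, truth
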