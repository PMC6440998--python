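"""FRET-restrained rigid-body modelling of a mobile domain.

The triangulation scheme: enumerate rigid-body rotations of a mobile
domain about its anchor point on a fixed scaffold (a uniform grid over
three Euler angles, 25 points per axis = 15,625 conformers by default),
discard conformers with van der Waals clashes (two atoms clash when
``d < Rv_i + Rv_j - 0.3`` with a 0.3 A overlap allowance), model each
dye as an accessible-volume (AV) cloud of sterically allowed positions
around its attachment atom, predict the efficiency of each FRET pair as
the average of ``1 / (1 + (r / R0)^6)`` over all donor x acceptor
position pairs, and rank conformers by ``chi2 = sum_i (E_measured(i) -
E_model(i))^2`` over the pairs, keeping the top scorers per measured
state.  Isotropic dye averaging (kappa^2 = 2/3) is implied by the AV
treatment; R0 is supplied per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "VDW_RADII",
    "Structure",
    "Conformer",
    "DyeCloud",
    "FretPairConfig",
    "ChiSquaredRanking",
    "read_structure",
    "write_structure",
    "generate_conformers",
    "clash_filter",
    "accessible_volume",
    "predict_pair_efficiency",
    "rank_conformers",
    "rmsd_to_reference",
    "tilt_angle",
    "triangulate",
]

# Bondi-type van der Waals radii (A)
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}


@dataclass
class Structure:
    """Coordinates plus the bookkeeping needed for rigid-body modelling.

    ``domain_mask`` marks the mobile domain's atoms; ``anchor`` is the
    pivot point of the rigid-body rotation; ``sites`` maps label-site
    names to atom indices (dye attachment points).
    """

    coords: np.ndarray
    radii: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    atom_names: np.ndarray
    domain_mask: np.ndarray
    anchor: np.ndarray
    sites: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def body_coords(self) -> np.ndarray:
        return self.coords[~self.domain_mask]

    @property
    def domain_coords(self) -> np.ndarray:
        return self.coords[self.domain_mask]

    def with_domain(self, domain_coords: np.ndarray) -> np.ndarray:
        """Full coordinate array with the domain replaced."""
        out = self.coords.copy()
        out[self.domain_mask] = domain_coords
        return out

    def site_index(self, site) -> int:
        if isinstance(site, str):
            return self.sites[site]
        return int(site)


@dataclass
class Conformer:
    """One rigid-body placement of the mobile domain."""

    index: int
    angles: np.ndarray                 # intrinsic z-y-z Euler angles (rad)
    domain_coords: np.ndarray
    clash: bool | None = None
    min_margin: float = np.inf         # min d - (Ri + Rj - threshold) over pairs
    predicted_E: np.ndarray | None = None


@dataclass
class DyeCloud:
    """Accessible-volume dye model: sterically allowed dye positions."""

    attachment_index: int
    positions: np.ndarray
    linker_length: float
    linker_width: float
    dye_radius: float
    grid_spacing: float
    empty: bool = False

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class FretPairConfig:
    donor_site: str | int
    acceptor_site: str | int
    R0: float

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("Forster radius must be positive")


@dataclass
class ChiSquaredRanking:
    chi2: np.ndarray            # per surviving conformer, NaN if excluded
    order: np.ndarray           # conformer list indices, ascending chi2
    top: np.ndarray             # first top_m of order
    excluded: list = field(default_factory=list)


def read_structure(path, domain_residues: tuple[int, int] | None = None,
                   anchor_residue: int | None = None,
                   sites: dict | None = None,
                   domain_chain: str | None = None) -> Structure:
    """Load a PDB file into a :class:`Structure`.

    ``domain_residues`` is an inclusive residue-id range defining the
    mobile domain (optionally restricted to ``domain_chain``);
    ``anchor_residue`` names the residue whose CA (or first atom) is the
    rotation pivot; ``sites`` maps site names to residue ids whose CA (or
    first atom) becomes the attachment atom.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    elements = np.char.upper(atoms.element.astype(str))
    unknown = [e for e in np.unique(elements) if e not in VDW_RADII]
    if unknown:
        raise ValueError(f"unknown elements without van der Waals radii: {unknown}")
    radii = np.array([VDW_RADII[e] for e in elements])
    res_ids = atoms.res_id
    chain_ids = atoms.chain_id.astype(str)
    mask = np.zeros(len(res_ids), dtype=bool)
    if domain_residues is not None:
        lo, hi = domain_residues
        mask = (res_ids >= lo) & (res_ids <= hi)
        if domain_chain is not None:
            mask &= chain_ids == domain_chain
    anchor = atoms.coord.mean(axis=0)
    if anchor_residue is not None:
        anchor = _residue_point(atoms, anchor_residue)
    site_idx = {}
    if sites:
        for name, res in sites.items():
            site_idx[name] = _residue_atom_index(atoms, res)
    return Structure(coords=atoms.coord.astype(float), radii=radii, elements=elements,
                     res_ids=res_ids, chain_ids=chain_ids,
                     atom_names=atoms.atom_name.astype(str),
                     domain_mask=mask, anchor=np.asarray(anchor, dtype=float),
                     sites=site_idx)


def _residue_atom_index(atoms, res_id: int) -> int:
    sel = np.flatnonzero(atoms.res_id == res_id)
    if len(sel) == 0:
        raise ValueError(f"residue {res_id} not found")
    ca = sel[atoms.atom_name[sel] == "CA"]
    return int(ca[0] if len(ca) else sel[0])


def _residue_point(atoms, res_id: int) -> np.ndarray:
    return atoms.coord[_residue_atom_index(atoms, res_id)].astype(float)


def write_structure(structure: Structure, path) -> None:
    """Write a Structure to PDB (one atom per record, CA-style naming)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = structure.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.element = structure.elements.astype("U2")
    atoms.res_id = structure.res_ids.astype(int)
    atoms.chain_id = structure.chain_ids.astype("U4")
    atoms.atom_name = structure.atom_names.astype("U6")
    atoms.res_name = np.full(n, "GLY", dtype="U5")
    atoms.hetero = np.zeros(n, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def write_conformers_pdb(structure: Structure, conformers: list[Conformer],
                         path) -> None:
    """Export conformers as a multi-model PDB (full complex per model)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = structure.n_atoms
    template = struc.AtomArray(n)
    template.element = structure.elements.astype("U2")
    template.res_id = structure.res_ids.astype(int)
    template.chain_id = structure.chain_ids.astype("U4")
    template.atom_name = structure.atom_names.astype("U6")
    template.res_name = np.full(n, "GLY", dtype="U5")
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([template] * len(conformers))
    stack.coord = np.array([structure.with_domain(c.domain_coords)
                            for c in conformers], dtype=np.float32)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def generate_conformers(structure: Structure, grid_points_per_axis: int = 25,
                        angle_ranges: tuple | None = None) -> list[Conformer]:
    """Rigid-body rotation grid of the mobile domain about the anchor.

    Intrinsic z-y-z Euler angles sampled on a uniform grid: the two
    azimuthal angles over [0, 2 pi) (periodic, endpoint excluded) and the
    polar angle over [0, pi].  The identity rotation (0, 0, 0) is always
    on the grid, and the conformer count is ``grid_points_per_axis ** 3``.
    """
    n = grid_points_per_axis
    if angle_ranges is None:
        a = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        b = np.linspace(0.0, np.pi, n)
        c = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    else:
        (a0, a1), (b0, b1), (c0, c1) = angle_ranges
        a = np.linspace(a0, a1, n)
        b = np.linspace(b0, b1, n)
        c = np.linspace(c0, c1, n)
    dom = structure.domain_coords - structure.anchor
    aa, bb, cc = np.meshgrid(a, b, c, indexing="ij")
    angles = np.column_stack([aa.ravel(), bb.ravel(), cc.ravel()])
    # intrinsic Z-Y-Z: R = Rz(alpha) Ry(beta) Rz(gamma)
    mats = Rotation.from_euler("ZYZ", angles).as_matrix()
    return [Conformer(index=i, angles=angles[i],
                      domain_coords=dom @ mats[i].T + structure.anchor)
            for i in range(len(angles))]


def clash_filter(conformers: list[Conformer], structure: Structure,
                 threshold: float = 0.3) -> tuple[list[Conformer], dict]:
    """Reject conformers with any domain/body van der Waals clash.

    Atoms i (domain) and j (body) clash when ``d_ij < Rv_i + Rv_j -
    threshold``.  A k-d tree over the fixed body atoms restricts the test
    to pairs within the largest possible contact distance; the result is
    identical to the all-pairs check.  Returns surviving conformers and
    statistics including the survival fraction.
    """
    body = structure.body_coords
    body_r = structure.radii[~structure.domain_mask]
    dom_r = structure.radii[structure.domain_mask]
    cut = float(body_r.max() + dom_r.max() - threshold)
    tree = cKDTree(body)
    survivors = []
    for conf in conformers:
        neigh = tree.query_ball_point(conf.domain_coords, cut)
        margin = np.inf
        for i, nb in enumerate(neigh):
            if not nb:
                continue
            d = np.linalg.norm(body[nb] - conf.domain_coords[i], axis=1)
            m = d - (dom_r[i] + body_r[nb] - threshold)
            margin = min(margin, float(m.min()))
        conf.min_margin = margin
        conf.clash = margin < 0
        if not conf.clash:
            survivors.append(conf)
    stats = {
        "n_total": len(conformers),
        "n_clashing": len(conformers) - len(survivors),
        "survival_fraction": len(survivors) / len(conformers) if conformers else 0.0,
        "threshold": threshold,
    }
    return survivors, stats


def accessible_volume(coords: np.ndarray, radii: np.ndarray, attachment_index: int,
                      linker_length: float = 20.0, linker_width: float = 4.5,
                      dye_radius: float = 3.5, grid_spacing: float | None = None,
                      target_points: tuple[int, int] = (600, 1200)) -> DyeCloud:
    """Accessible-volume cloud of allowed dye positions around a site.

    Candidate positions on a cubic grid within the linker length of the
    attachment atom are kept when they do not overlap any protein atom:
    a position is excluded if it lies within ``Rv_atom + clearance`` of
    an atom, with clearance = max(dye radius, linker width / 2).  The
    attachment atom itself does not block its own dye.  When
    ``grid_spacing`` is not given it is auto-tuned so the cloud holds a
    number of positions inside ``target_points``.
    """
    coords = np.asarray(coords, dtype=float)
    attach = coords[attachment_index]
    others = np.delete(coords, attachment_index, axis=0)
    r_others = np.delete(np.asarray(radii, dtype=float), attachment_index)
    clearance = max(dye_radius, linker_width / 2.0)
    target_mid = float(np.sqrt(target_points[0] * target_points[1]))
    ball_volume = 4.0 / 3.0 * np.pi * linker_length ** 3

    def build(spacing: float) -> np.ndarray:
        half = int(np.floor(linker_length / spacing))
        ax = np.arange(-half, half + 1) * spacing
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + attach
        keep = np.linalg.norm(pts - attach, axis=1) <= linker_length
        pts = pts[keep]
        if len(others):
            near = others[np.linalg.norm(others - attach, axis=1)
                          <= linker_length + clearance + r_others.max()]
            rr = r_others[np.linalg.norm(others - attach, axis=1)
                          <= linker_length + clearance + r_others.max()]
            if len(near):
                d = cdist(pts, near)
                keep2 = np.all(d >= rr[None, :] + clearance, axis=1)
                pts = pts[keep2]
        return pts

    if grid_spacing is not None:
        pts = build(grid_spacing)
        spacing = grid_spacing
    else:
        spacing = (ball_volume / target_mid) ** (1.0 / 3.0)
        pts = build(spacing)
        for _ in range(6):
            if target_points[0] <= len(pts) <= target_points[1]:
                break
            if len(pts) == 0:
                break
            spacing *= (len(pts) / target_mid) ** (1.0 / 3.0)
            pts = build(spacing)
    return DyeCloud(attachment_index=attachment_index, positions=pts,
                    linker_length=linker_length, linker_width=linker_width,
                    dye_radius=dye_radius, grid_spacing=spacing, empty=len(pts) == 0)


def predict_pair_efficiency(donor_cloud: DyeCloud, acceptor_cloud: DyeCloud,
                            R0: float, max_pairs: int = 4_000_000,
                            seed: int = 0) -> float:
    """Mean FRET efficiency over all donor x acceptor dye positions.

    E = mean over position pairs of 1 / (1 + (r / R0)^6); the mean is over
    efficiencies, not distances.  If the pair count exceeds ``max_pairs``
    both clouds are subsampled with a seeded generator (documented error
    ~ 1/sqrt(n_pairs) of the efficiency spread).
    """
    if donor_cloud.empty or acceptor_cloud.empty:
        raise ValueError("cannot predict efficiency from an empty dye cloud")
    dpos, apos = donor_cloud.positions, acceptor_cloud.positions
    if len(dpos) * len(apos) > max_pairs:
        rng = np.random.default_rng(seed)
        n_each = int(np.sqrt(max_pairs))
        if len(dpos) > n_each:
            dpos = dpos[rng.choice(len(dpos), n_each, replace=False)]
        if len(apos) > n_each:
            apos = apos[rng.choice(len(apos), n_each, replace=False)]
    r = cdist(dpos, apos)
    return float(np.mean(1.0 / (1.0 + (r / R0) ** 6)))


def rank_conformers(conformers: list[Conformer], measured_E: np.ndarray,
                    top_m: int = 10) -> ChiSquaredRanking:
    """Rank conformers by chi2 against measured pair efficiencies.

    Each conformer must carry ``predicted_E`` (one value per FRET pair,
    set by :func:`triangulate` or by hand); conformers with missing
    predictions are excluded with a notice.  Ties break by list position
    (stable sort).
    """
    measured_E = np.asarray(measured_E, dtype=float)
    chi2 = np.full(len(conformers), np.nan)
    excluded = []
    for i, conf in enumerate(conformers):
        if conf.predicted_E is None or np.any(~np.isfinite(conf.predicted_E)):
            excluded.append(i)
            continue
        if len(conf.predicted_E) != len(measured_E):
            excluded.append(i)
            continue
        chi2[i] = float(np.sum((measured_E - conf.predicted_E) ** 2))
    valid = np.flatnonzero(np.isfinite(chi2))
    order = valid[np.argsort(chi2[valid], kind="stable")]
    return ChiSquaredRanking(chi2=chi2, order=order, top=order[:top_m],
                             excluded=excluded)


def rmsd_to_reference(conformer: Conformer, reference_domain: np.ndarray) -> float:
    """Coordinate RMSD of the domain against a reference, no refitting.

    Conformers share the fixed body frame, so no superposition is applied.
    """
    ref = np.asarray(reference_domain, dtype=float)
    if conformer.domain_coords.shape != ref.shape:
        raise ValueError("atom-count mismatch between conformer and reference")
    diff = conformer.domain_coords - ref
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(s) > 1 and s[0] < 1.1 * s[1]:
        raise ValueError("degenerate domain axis (near-spherical atom distribution)")
    return vt[0]


def tilt_angle(conformer: Conformer, reference_domain: np.ndarray) -> float:
    """Angle (degrees, in [0, 90]) between domain principal axes.

    The domain axis is the first principal axis of its atom coordinates;
    the convention folds the axis sign ambiguity into [0, 90] degrees.
    Symmetric in its arguments.
    """
    u = _principal_axis(conformer.domain_coords)
    v = _principal_axis(np.asarray(reference_domain, dtype=float))
    cosang = np.clip(abs(float(np.dot(u, v))), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def predictions_for_conformer(structure: Structure, conf: Conformer,
                              pairs: list[FretPairConfig], **av_kwargs) -> np.ndarray:
    """Per-pair AV-averaged efficiencies for one conformer."""
    coords = structure.with_domain(conf.domain_coords)
    clouds: dict[int, DyeCloud] = {}
    out = np.empty(len(pairs))
    for ip, pair in enumerate(pairs):
        di = structure.site_index(pair.donor_site)
        ai = structure.site_index(pair.acceptor_site)
        for s in (di, ai):
            if s not in clouds:
                clouds[s] = accessible_volume(coords, structure.radii, s, **av_kwargs)
        if clouds[di].empty or clouds[ai].empty:
            out[ip] = np.nan
        else:
            out[ip] = predict_pair_efficiency(clouds[di], clouds[ai], pair.R0)
    return out


@dataclass
class TriangulationResult:
    survivors: list[Conformer]
    clash_stats: dict
    rankings: dict              # state name -> ChiSquaredRanking

    def table(self, structure_reference: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for state, ranking in self.rankings.items():
            for rank_pos, ci in enumerate(ranking.top):
                conf = self.survivors[ci]
                row = {"state": state, "rank": rank_pos + 1,
                       "conformer": conf.index,
                       "alpha": conf.angles[0], "beta": conf.angles[1],
                       "gamma": conf.angles[2],
                       "chi2": ranking.chi2[ci]}
                if structure_reference is not None:
                    row["rmsd"] = rmsd_to_reference(conf, structure_reference)
                    row["tilt_deg"] = tilt_angle(conf, structure_reference)
                rows.append(row)
        return pd.DataFrame(rows)


def triangulate(structure: Structure, pairs: list[FretPairConfig],
                measured_E_by_state: dict, grid_points_per_axis: int = 25,
                clash_threshold: float = 0.3, top_m: int = 10,
                av_kwargs: dict | None = None) -> TriangulationResult:
    """Full pipeline: grid, clash filter, AV prediction, chi2 ranking.

    ``measured_E_by_state`` maps a state name to its per-pair measured
    efficiencies; a separate ranking is produced per state, as when the
    active and inactive conformations are triangulated from the same
    conformer pool.
    """
    av_kwargs = av_kwargs or {}
    conformers = generate_conformers(structure, grid_points_per_axis)
    survivors, stats = clash_filter(conformers, structure, clash_threshold)
    for conf in survivors:
        conf.predicted_E = predictions_for_conformer(structure, conf, pairs, **av_kwargs)
    rankings = {state: rank_conformers(survivors, np.asarray(me, float), top_m)
                for state, me in measured_E_by_state.items()}
    return TriangulationResult(survivors=survivors, clash_stats=stats,
                               rankings=rankings)
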