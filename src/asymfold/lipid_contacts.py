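"""Lipid–protein contact statistics from coarse-grained trajectories.

Post-processes frame-indexed bead coordinates into the interaction measures
used for CG-MD analysis:

* contact counts — a residue–lipid-molecule pair contributes one contact
  per frame when any of their particle pairs lies within 0.55 nm (minimum
  image under an orthorhombic periodic box),
* normalization by lipid count per species and by frame number, making
  counts comparable across species concentrations and run lengths,
* site occupancy under a dual-cutoff hysteresis scheme: a lipid becomes
  bound to a residue site when its minimum distance drops to 0.475 nm and
  stays bound until it exceeds 0.8 nm; occupancy is the fraction of frames
  with at least one bound lipid of the species.

Distances are in nm.  Running the simulations themselves is out of scope;
trajectories arrive as in-memory arrays or a plain frame table (columns:
frame, kind, group, species, x, y, z) that standard readers can adapt to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "ContactConfig",
    "Trajectory",
    "ContactProfile",
    "contact_counts",
    "normalize_contacts",
    "site_occupancy",
    "trajectory_from_frame_table",
]


@dataclass(frozen=True)
class ContactConfig:
    contact_cutoff: float = 0.55  # nm
    occupancy_cutoff_short: float = 0.475  # nm
    occupancy_cutoff_long: float = 0.8  # nm

    def __post_init__(self):
        if not 0 < self.occupancy_cutoff_short < self.occupancy_cutoff_long:
            raise DomainError("cutoffs must satisfy 0 < short < long")
        if self.contact_cutoff <= 0:
            raise DomainError("contact cutoff must be positive")


@dataclass
class Trajectory:
    """Frame-indexed bead coordinates, grouped by residue / lipid molecule.

    protein_xyz: (n_frames, n_protein_particles, 3); protein_residues maps
    each protein particle to its residue label.  lipid_xyz analogous;
    lipid_molecule maps each lipid particle to a molecule id and
    lipid_species to its species name.  box is the orthorhombic periodic
    box (3 lengths, nm) or None for a non-periodic system; triclinic boxes
    are not supported.
    """

    protein_xyz: np.ndarray
    protein_residues: np.ndarray
    lipid_xyz: np.ndarray
    lipid_molecule: np.ndarray
    lipid_species: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        self.protein_xyz = np.asarray(self.protein_xyz, dtype=float)
        self.lipid_xyz = np.asarray(self.lipid_xyz, dtype=float)
        self.protein_residues = np.asarray(self.protein_residues)
        self.lipid_molecule = np.asarray(self.lipid_molecule)
        self.lipid_species = np.asarray(self.lipid_species)
        if self.protein_xyz.ndim != 3 or self.lipid_xyz.ndim != 3:
            raise DomainError("coordinate arrays must be (frames, particles, 3)")
        if self.protein_xyz.shape[0] != self.lipid_xyz.shape[0]:
            raise DomainError("protein and lipid frame counts differ")
        if self.protein_residues.size != self.protein_xyz.shape[1]:
            raise DomainError("protein_residues length mismatch")
        if (
            self.lipid_molecule.size != self.lipid_xyz.shape[1]
            or self.lipid_species.size != self.lipid_xyz.shape[1]
        ):
            raise DomainError("lipid grouping length mismatch")
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.shape == (3, 3):
                if not np.allclose(box, np.diag(np.diag(box))):
                    raise DomainError("triclinic boxes are not supported")
                box = np.diag(box)
            if box.shape != (3,) or np.any(box <= 0):
                raise DomainError("box must be three positive lengths")
            self.box = box

    @property
    def n_frames(self) -> int:
        return self.protein_xyz.shape[0]


@dataclass
class ContactProfile:
    """Raw and concentration/time-normalized contact counts.

    normalized(residue, species) = raw/(n_lipids(species) · n_frames);
    species declared with zero lipids are reported as NaN.
    """

    raw_counts: pd.DataFrame  # index: residue, columns: species
    normalized: pd.DataFrame
    n_lipids_per_species: Dict[str, int]
    n_frames: int


def _pair_distances(p: np.ndarray, l: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    diff = p[:, None, :] - l[None, :, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    return np.sqrt((diff**2).sum(axis=-1))


def contact_counts(
    traj: Trajectory, cfg: Optional[ContactConfig] = None
) -> pd.DataFrame:
    """Per-residue, per-species contact counts accumulated over frames.

    A residue and a lipid molecule are "in contact" in a frame when any of
    their particle pairs is within the contact cutoff; each such pair adds
    one count to that residue for the molecule's species.
    """
    cfg = cfg or ContactConfig()
    if traj.n_frames == 0:
        raise DomainError("empty trajectory")
    residues = pd.unique(traj.protein_residues)
    species = pd.unique(traj.lipid_species)
    res_idx = {r: i for i, r in enumerate(residues)}
    # one species per molecule
    mol_species: Dict = {}
    for mol, sp in zip(traj.lipid_molecule, traj.lipid_species):
        prev = mol_species.setdefault(mol, sp)
        if prev != sp:
            raise DomainError(f"lipid molecule {mol!r} spans two species")
    sp_idx = {s: i for i, s in enumerate(species)}
    counts = np.zeros((residues.size, species.size))
    res_of_particle = np.array([res_idx[r] for r in traj.protein_residues])
    mols = pd.unique(traj.lipid_molecule)
    mol_of_particle = np.searchsorted(np.sort(mols), traj.lipid_molecule)
    mol_order = np.sort(mols)
    sp_of_mol = np.array([sp_idx[mol_species[m]] for m in mol_order])

    for f in range(traj.n_frames):
        d = _pair_distances(traj.protein_xyz[f], traj.lipid_xyz[f], traj.box)
        pi, li = np.nonzero(d <= cfg.contact_cutoff)
        if pi.size == 0:
            continue
        pairs = np.unique(
            np.stack([res_of_particle[pi], mol_of_particle[li]], axis=1), axis=0
        )
        np.add.at(counts, (pairs[:, 0], sp_of_mol[pairs[:, 1]]), 1)
    return pd.DataFrame(counts, index=residues, columns=species)


def normalize_contacts(
    raw: pd.DataFrame, n_lipids_per_species: Mapping[str, int], n_frames: int
) -> ContactProfile:
    """Normalize raw contact counts by lipid count and frame number."""
    if n_frames < 1:
        raise DomainError("n_frames must be >= 1")
    norm = raw.astype(float).copy()
    counts: Dict[str, int] = {}
    for sp in raw.columns:
        n = int(n_lipids_per_species.get(sp, 0))
        counts[sp] = n
        if n < 1:
            norm[sp] = np.nan  # declared species with no lipids: undefined
        else:
            norm[sp] = raw[sp] / (n * n_frames)
    return ContactProfile(
        raw_counts=raw,
        normalized=norm,
        n_lipids_per_species=counts,
        n_frames=n_frames,
    )


def site_occupancy(
    traj: Trajectory,
    site_residues: Sequence,
    species: str,
    cfg: Optional[ContactConfig] = None,
) -> float:
    """Fraction of frames with >= 1 lipid of ``species`` bound at the site.

    Binding follows dual-cutoff hysteresis per lipid molecule: a bound
    interval starts when the molecule's minimum distance to any site
    particle drops to the short cutoff and ends only when it exceeds the
    long cutoff, suppressing rapid rebinding artefacts at the boundary.
    """
    cfg = cfg or ContactConfig()
    if len(site_residues) == 0:
        raise DomainError("site must contain at least one residue")
    present = set(traj.protein_residues.tolist())
    missing = [r for r in site_residues if r not in present]
    if missing:
        raise DomainError(f"unknown site residue(s): {missing}")
    site_mask = np.isin(traj.protein_residues, list(site_residues))
    lip_mask = traj.lipid_species == species
    if not lip_mask.any():
        raise DomainError(f"no lipids of species {species!r}")
    mols = pd.unique(traj.lipid_molecule[lip_mask])

    bound = {m: False for m in mols}
    occupied = 0
    site_xyz = traj.protein_xyz[:, site_mask, :]
    for f in range(traj.n_frames):
        d = _pair_distances(site_xyz[f], traj.lipid_xyz[f][lip_mask], traj.box)
        mol_labels = traj.lipid_molecule[lip_mask]
        any_bound = False
        for m in mols:
            dmin = d[:, mol_labels == m].min()
            if not bound[m] and dmin <= cfg.occupancy_cutoff_short:
                bound[m] = True
            elif bound[m] and dmin > cfg.occupancy_cutoff_long:
                bound[m] = False
            any_bound = any_bound or bound[m]
        if any_bound:
            occupied += 1
    return occupied / traj.n_frames


def trajectory_from_frame_table(
    df: pd.DataFrame, box: Optional[Sequence[float]] = None
) -> Trajectory:
    """Build a Trajectory from a plain frame table.

    Expected columns: frame, kind ("protein"/"lipid"), group (residue label
    or lipid molecule id), species (lipids; ignored for protein rows),
    x, y, z.  Particle ordering must be identical in every frame.
    """
    required = {"frame", "kind", "group", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"frame table missing column(s): {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    prot_frames, lip_frames = [], []
    prot_groups = lip_groups = lip_species = None
    for f in frames:
        sub = df[df["frame"] == f]
        prot = sub[sub["kind"] == "protein"]
        lip = sub[sub["kind"] == "lipid"]
        prot_frames.append(prot[["x", "y", "z"]].to_numpy(dtype=float))
        lip_frames.append(lip[["x", "y", "z"]].to_numpy(dtype=float))
        if prot_groups is None:
            prot_groups = prot["group"].to_numpy()
            lip_groups = lip["group"].to_numpy()
            lip_species = (
                lip["species"].to_numpy()
                if "species" in lip.columns
                else np.full(len(lip), "lipid")
            )
    return Trajectory(
        protein_xyz=np.stack(prot_frames),
        protein_residues=prot_groups,
        lipid_xyz=np.stack(lip_frames),
        lipid_molecule=lip_groups,
        lipid_species=lip_species,
        box=None if box is None else np.asarray(box, dtype=float),
    )
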