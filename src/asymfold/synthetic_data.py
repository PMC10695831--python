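"""Synthetic inputs with known ground truth for every pipeline stage.

Every experimental input class the package analyses can be generated here
with a planted, machine-readable truth, so each fitter and detector is
testable end to end without downloads.  Named presets anchor their truth
parameters to the headline systems of the study:

* ``s-DMPC-folding`` — one-phase folding trace, k_obs = 5×10⁻⁴ s⁻¹ (the
  DMPC magnitude),
* ``s-DMPG-folding`` — k_obs = 2.2×10⁻² s⁻¹, i.e. 44-fold faster than the
  DMPC preset (the ">40-fold" regime),
* ``s-DMPG-stability`` / ``s-DMPC-stability`` — urea titrations with
  midpoints P_m = 4.5 M and 2.3 M,
* ``DMPC`` / ``DMPG`` laurdan curves with melting midpoints 24 °C and 23 °C,
* ``liposome-dye-mixture`` — an absorbance spectrum mixing a λ⁻⁴
  scattering liposome reference with a Gaussian fluorophore band.

All generators are deterministic for a fixed seed.  The geometry of the
membrane cohort and trajectory generators is statistical, not physical: it
reproduces the count statistics the analyses consume, not molecular detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError
from .lipid_contacts import ContactConfig, Trajectory
from .pep_enrichment import (
    AMINO_ACIDS,
    MembraneAlignedStructure,
    ResidueRecord,
    TopologySequence,
)
from .spectro_kinetics import Spectrum

__all__ = [
    "PRESETS",
    "Preset",
    "BarrelSpec",
    "PatchSpec",
    "gen_zeta_table",
    "gen_curves",
    "gen_membrane_cohort",
    "gen_trajectory",
    "reference_spectra",
]


@dataclass(frozen=True)
class Preset:
    """A named generator parameter set with its truth and tolerances."""

    kind: str
    truth: Mapping[str, float]
    default_noise: float
    recovery_tolerance: float  # |fit − truth| bound at default noise
    note: str = ""


PRESETS: Dict[str, Preset] = {
    "s-DMPC-folding": Preset(
        kind="kinetics",
        truth={"k_obs": 5e-4, "baseline": 1.0, "amplitude": 1.0},
        default_noise=0.01,
        recovery_tolerance=0.05,  # relative, on k_obs
        note="slow folding into fluid zwitterionic membranes",
    ),
    "s-DMPG-folding": Preset(
        kind="kinetics",
        truth={"k_obs": 2.2e-2, "baseline": 1.0, "amplitude": 1.0},
        default_noise=0.01,
        recovery_tolerance=0.05,
        note="44-fold faster folding into anionic membranes",
    ),
    "s-DMPC-stability": Preset(
        kind="titration",
        truth={"Pm": 2.3, "slope": 0.3, "lower": 0.05, "upper": 0.95},
        default_noise=0.03,
        recovery_tolerance=0.15,  # M urea
    ),
    "s-DMPG-stability": Preset(
        kind="titration",
        truth={"Pm": 4.5, "slope": 0.3, "lower": 0.05, "upper": 0.95},
        default_noise=0.03,
        recovery_tolerance=0.15,
    ),
    "DMPC": Preset(
        kind="laurdan",
        truth={"Tm": 24.0, "gp_high": 0.45, "gp_low": -0.25, "width": 0.8},
        default_noise=0.002,
        recovery_tolerance=0.25,  # °C
    ),
    "DMPG": Preset(
        kind="laurdan",
        truth={"Tm": 23.0, "gp_high": 0.45, "gp_low": -0.25, "width": 0.8},
        default_noise=0.002,
        recovery_tolerance=0.25,
    ),
    "liposome-dye-mixture": Preset(
        kind="spectrum",
        truth={"liposome": 1.5, "fluorophore": 0.3},
        default_noise=1e-4,
        recovery_tolerance=0.01,  # relative, on scales
    ),
}


def _rng(seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# ζ-potential training tables


def gen_zeta_table(
    n: int = 315,
    effect: Optional[Mapping[str, float]] = None,
    noise_sd: float = 1.0,
    hetero_sd_range: Optional[Tuple[float, float]] = (0.5, 2.0),
    seed: Optional[int] = 0,
) -> Tuple[pd.DataFrame, dict]:
    """A ζ-potential training table with a planted linear feature effect.

    By default the effect is charge-dominant: ζ = 30 mV/e · mean_charge,
    plus Gaussian measurement noise.  ``hetero_sd_range`` draws a per-row
    measurement sd uniformly from that range (recorded in zeta_sd_mV and
    used as the actual noise scale); pass None for homoscedastic noise of
    ``noise_sd`` mV.  Returns (table, truth sidecar).
    """
    if n < 20:
        raise DomainError("need n >= 20")
    rng = _rng(seed)
    effect = dict(effect) if effect is not None else {"mean_charge": 30.0}
    degenerate = all(v == 0 for v in effect.values())

    df = pd.DataFrame(
        {
            "salt_mono_M": rng.uniform(0.0, 0.5, n),
            "salt_di_M": rng.uniform(0.0, 0.05, n),
            "pH": rng.uniform(3.0, 10.0, n),
            "rh_nm": rng.uniform(30.0, 100.0, n),
            "temp_C": rng.uniform(10.0, 40.0, n),
            "mean_charge": rng.uniform(-1.0, 1.0, n),
            "mean_tm_C": rng.uniform(-20.0, 60.0, n),
            "chol_frac": rng.uniform(0.0, 0.5, n),
        }
    )
    signal = np.zeros(n)
    for feat, coef in effect.items():
        if feat not in df.columns:
            raise DomainError(f"unknown effect feature {feat!r}")
        signal += coef * df[feat].to_numpy()
    if hetero_sd_range is not None:
        lo, hi = hetero_sd_range
        sds = rng.uniform(lo, hi, n)
    else:
        sds = np.full(n, float(noise_sd))
    df["zeta_mV"] = signal + rng.normal(0.0, sds)
    df["zeta_sd_mV"] = sds
    truth = {
        "effect": effect,
        "noise_sd": noise_sd,
        "hetero_sd_range": hetero_sd_range,
        "degenerate_effect": degenerate,
        "seed": seed,
    }
    return df, truth


# ---------------------------------------------------------------------------
# curves


def reference_spectra() -> Dict[str, Spectrum]:
    """Built-in reference shapes for absorbance deconvolution (300–600 nm).

    "liposome": Rayleigh-like λ⁻⁴ scattering tail; "fluorophore": Gaussian
    absorbance band centred at 495 nm.  Both normalized to unit maximum.
    """
    wl = np.arange(300.0, 601.0)
    lipo = (wl / 300.0) ** -4
    fluo = np.exp(-0.5 * ((wl - 495.0) / 20.0) ** 2)
    return {
        "liposome": Spectrum(wl, lipo / lipo.max()),
        "fluorophore": Spectrum(wl, fluo / fluo.max()),
    }


def _default_grid(kind: str, truth: Mapping[str, float]) -> np.ndarray:
    if kind == "kinetics":
        k = truth["k_obs"]
        t_max = 8.0 / k  # run well past completion
        return np.linspace(0.0, t_max, 400)
    if kind == "titration":
        return np.arange(0.0, 8.0 + 1e-9, 0.5)
    if kind == "laurdan":
        tm = truth["Tm"]
        return np.arange(tm - 10.0, tm + 10.0 + 1e-9, 0.25)
    if kind == "spectrum":
        return np.arange(300.0, 601.0)
    raise DomainError(f"unknown curve kind {kind!r}")


def gen_curves(
    kind: str,
    preset: Optional[str] = None,
    truth: Optional[Mapping[str, float]] = None,
    noise: Optional[float] = None,
    seed: Optional[int] = 0,
    grid: Optional[Sequence[float]] = None,
) -> Tuple[pd.DataFrame, dict]:
    """Generate a synthetic curve of the given kind with Gaussian noise.

    ``kind`` is one of kinetics / titration / laurdan / spectrum.  Either a
    preset name or an explicit truth mapping must be given.  ``noise`` is
    the Gaussian sd — for kinetics it is relative to the total amplitude,
    for titrations in folded-fraction units, for laurdan in GP units and
    for spectra in absorbance units.  Returns (curve table, truth sidecar).
    """
    if preset is not None:
        p = PRESETS.get(preset)
        if p is None:
            raise DomainError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
        if p.kind != kind:
            raise DomainError(f"preset {preset!r} is of kind {p.kind!r}, not {kind!r}")
        truth = dict(p.truth)
        if noise is None:
            noise = p.default_noise
    elif truth is None:
        raise DomainError("either preset or explicit truth required")
    else:
        truth = dict(truth)
    if noise is None:
        noise = 0.0
    if noise < 0:
        raise DomainError("noise sd cannot be negative")
    rng = _rng(seed)
    x = np.asarray(grid if grid is not None else _default_grid(kind, truth), dtype=float)

    if kind == "kinetics":
        f0 = truth.get("baseline", 1.0)
        phases = truth.get("phases")
        if phases:  # list of (amplitude, k) for multi-phase truths
            y = f0 + sum(a * (1.0 - np.exp(-k * x)) for a, k in phases)
            a_total = sum(a for a, _ in phases)
        else:
            a = truth.get("amplitude", 1.0)
            k = truth["k_obs"]
            y = f0 + a * (1.0 - np.exp(-k * x))
            a_total = a
        y = y + rng.normal(0.0, noise * abs(a_total), x.size)
        df = pd.DataFrame({"time_s": x, "signal": y})
    elif kind == "titration":
        lo, hi = truth.get("lower", 0.0), truth.get("upper", 1.0)
        pm, s = truth["Pm"], truth.get("slope", 0.3)
        y = lo + (hi - lo) / (1.0 + np.exp((x - pm) / s))
        y = y + rng.normal(0.0, noise, x.size)
        df = pd.DataFrame({"urea_M": x, "fraction_folded": y})
    elif kind == "laurdan":
        tm, w = truth["Tm"], truth.get("width", 0.8)
        gh, gl = truth.get("gp_high", 0.45), truth.get("gp_low", -0.25)
        gp = gl + (gh - gl) / (1.0 + np.exp((x - tm) / w))
        gp = gp + rng.normal(0.0, noise, x.size)
        # back out consistent I440/I490 with I440 + I490 = 1
        i440 = (1.0 + gp) / 2.0
        df = pd.DataFrame({"temp_C": x, "I440": i440, "I490": 1.0 - i440, "gp": gp})
    elif kind == "spectrum":
        refs = reference_spectra()
        y = np.zeros(x.size)
        for name, scale in truth.items():
            if name not in refs:
                raise DomainError(f"unknown spectral component {name!r}")
            y += scale * refs[name].resampled(x).values
        y = y + rng.normal(0.0, noise, x.size)
        df = pd.DataFrame({"wavelength_nm": x, "absorbance": y})
    else:
        raise DomainError(f"unknown curve kind {kind!r}")

    sidecar = {"kind": kind, "preset": preset, "truth": truth, "noise": noise, "seed": seed}
    return df, sidecar


# ---------------------------------------------------------------------------
# membrane cohorts


@dataclass(frozen=True)
class BarrelSpec:
    """Idealized β-barrel geometry: strand count and membrane half-thickness."""

    n_strands: int = 8
    half_thickness: float = 15.0  # Å
    strand_rise: float = 1.5  # Å per residue along the membrane normal
    loop_length_range: Tuple[int, int] = (8, 14)
    loop_apex: float = 14.0  # Å above the outer leaflet reached by loops
    turn_length_range: Tuple[int, int] = (3, 5)
    turn_depth: float = 4.0  # Å below the inner leaflet reached by turns

    def __post_init__(self):
        if self.n_strands < 8 or self.n_strands % 2:
            raise DomainError("strand count must be even and >= 8")


@dataclass(frozen=True)
class PatchSpec:
    """A plantable Lys/Arg excess band in the extracellular loops.

    centre/width are in Å above the outer-leaflet plane; excess multiplies
    the K and R draw probability inside the band (1 = null cohort).
    """

    centre: float = 8.0
    width: float = 4.0
    excess: float = 3.0

    def __post_init__(self):
        if self.excess < 0 or self.width <= 0:
            raise DomainError("invalid patch spec")


# TM composition biased to the hydrophobics + aromatic girdle residues
_TM_WEIGHTS = {
    "A": 2.0, "V": 3.0, "L": 4.0, "I": 3.0, "F": 2.5, "G": 2.0,
    "Y": 2.0, "W": 1.5, "T": 1.0, "S": 1.0, "M": 1.0,
}


def _draw_aa(rng, weights: Mapping[str, float]) -> str:
    aas = list(AMINO_ACIDS)
    w = np.array([weights.get(a, 0.5) for a in aas])
    return rng.choice(aas, p=w / w.sum())


def gen_membrane_cohort(
    n_structures: int,
    barrel: Optional[BarrelSpec] = None,
    patch: Optional[PatchSpec] = None,
    seed: Optional[int] = 0,
) -> Tuple[List[MembraneAlignedStructure], List[TopologySequence], dict]:
    """Idealized membrane-aligned β-barrels with a plantable positive patch.

    Each structure alternates TM strands spanning ±half_thickness
    (hydrophobic-biased composition) with extracellular loops arcing above
    the outer leaflet and short periplasmic turns below the inner one.
    Loop/turn composition is uniform over the 20 amino acids, except inside
    the planted extracellular band, where the K/R probability is multiplied
    by ``patch.excess``.  Matched topology-labelled sequences are returned
    alongside the structures; the truth sidecar records the planted band.
    """
    barrel = barrel or BarrelSpec()
    patch = patch or PatchSpec(excess=1.0)
    if patch.centre - patch.width / 2 < 0 or (
        patch.centre + patch.width / 2 > barrel.loop_apex
    ):
        raise DomainError(
            "patch band outside modelled loop reach "
            f"(loops rise to {barrel.loop_apex} Å above the leaflet)"
        )
    rng = _rng(seed)
    h = barrel.half_thickness
    band = (h + patch.centre - patch.width / 2, h + patch.centre + patch.width / 2)

    uniform = {a: 1.0 for a in AMINO_ACIDS}
    patched = dict(uniform)
    patched["K"] = patch.excess
    patched["R"] = patch.excess

    structures: List[MembraneAlignedStructure] = []
    seqrecs: List[TopologySequence] = []
    strand_len = int(round(2 * h / barrel.strand_rise))
    for si in range(n_structures):
        residues: List[ResidueRecord] = []
        seq: List[str] = []
        topo: List[str] = []
        idx = 1

        def add(aa: str, z: float, region: str, side: str, label: str):
            nonlocal idx
            residues.append(ResidueRecord(aa, "A", idx, float(z), region, side))
            seq.append(aa)
            topo.append(label)
            idx += 1

        for strand in range(barrel.n_strands):
            up = strand % 2 == 0  # alternate strand direction
            zs = np.linspace(-h, h, strand_len) if up else np.linspace(h, -h, strand_len)
            for z in zs:
                add(_draw_aa(rng, _TM_WEIGHTS), z + rng.normal(0, 0.3), "TM", "membrane", "S")
            last = barrel.n_strands - 1
            if strand == last:
                break
            if up:  # extracellular loop back down to the next strand top
                L = int(rng.integers(*barrel.loop_length_range))
                apex = barrel.loop_apex * rng.uniform(0.85, 1.0)
                for j in range(L):
                    z = h + apex * np.sin(np.pi * (j + 1) / (L + 1))
                    comp = patched if band[0] <= z < band[1] else uniform
                    add(_draw_aa(rng, comp), z, "soluble", "extracellular", "L")
            else:  # periplasmic turn
                T = int(rng.integers(*barrel.turn_length_range))
                for j in range(T):
                    z = -h - barrel.turn_depth * np.sin(np.pi * (j + 1) / (T + 1))
                    add(_draw_aa(rng, uniform), z, "soluble", "periplasmic", "T")
        structures.append(MembraneAlignedStructure(residues, half_thickness=h))
        seqrecs.append(
            TopologySequence(f"synthetic_barrel_{si:03d}", "".join(seq), "".join(topo))
        )

    truth = {
        "half_thickness": h,
        "patch_centre_above_leaflet": patch.centre,
        "patch_width": patch.width,
        "patch_excess": patch.excess,
        "patch_band_absolute_z": band,
        "n_structures": n_structures,
        "seed": seed,
    }
    return structures, seqrecs, truth


# ---------------------------------------------------------------------------
# trajectories


def gen_trajectory(
    n_frames: int,
    bound_fraction: float,
    n_binders: int = 1,
    n_lipids: Optional[Mapping[str, int]] = None,
    box: Sequence[float] = (10.0, 10.0, 10.0),
    cfg: Optional[ContactConfig] = None,
    seed: Optional[int] = 0,
) -> Tuple[Trajectory, dict]:
    """A trajectory with a planted lipid-binding site of known occupancy.

    A small single-bead-per-residue protein sits at the box centre with a
    designated three-residue site.  ``n_binders`` lipids of species "DMPG"
    follow independent per-frame telegraph schedules with bound fraction
    ``bound_fraction``: on bound frames they sit within the short occupancy
    cutoff of a site bead, on unbound frames (and for all other lipids,
    always) they sit beyond the long cutoff, so the planted per-binder
    occupancy equals the realized bound-frame fraction exactly.
    """
    if not 0 <= bound_fraction <= 1:
        raise DomainError("bound_fraction must lie in [0, 1]")
    cfg = cfg or ContactConfig()
    box = np.asarray(box, dtype=float)
    if np.any(box <= 4 * cfg.occupancy_cutoff_long):
        raise DomainError("box too small to place unbound lipids beyond the long cutoff")
    rng = _rng(seed)
    n_lipids = dict(n_lipids or {"DMPG": max(n_binders, 1) + 3, "DMPC": 4})
    if n_lipids.get("DMPG", 0) < n_binders:
        raise DomainError("n_lipids['DMPG'] must cover the binder copies")

    centre = box / 2.0
    # protein: 6 residues on a small ring, one bead each; site = first 3
    offsets = np.array(
        [[0.4, 0, 0], [-0.4, 0, 0], [0, 0.4, 0], [0, -0.4, 0], [0, 0, 0.4], [0, 0, -0.4]]
    )
    protein_ref = centre + offsets
    residues = np.array(["R81", "K94", "R124", "A10", "G20", "S30"])
    site = ["R81", "K94", "R124"]

    lipid_ids: List[int] = []
    lipid_sp: List[str] = []
    mol = 0
    for sp, count in n_lipids.items():
        for _ in range(count):
            lipid_ids.append(mol)
            lipid_sp.append(sp)
            mol += 1
    lipid_ids = np.array(lipid_ids)
    lipid_sp = np.array(lipid_sp)
    binder_mols = lipid_ids[lipid_sp == "DMPG"][:n_binders]

    def far_point() -> np.ndarray:
        for _ in range(1000):
            p = rng.uniform(0, box)
            diff = protein_ref - p
            diff -= box * np.round(diff / box)
            if np.sqrt((diff**2).sum(axis=1)).min() > cfg.occupancy_cutoff_long + 0.05:
                return p
        raise DomainError("box too small to place unbound lipids beyond the long cutoff")

    def near_point() -> np.ndarray:
        anchor = protein_ref[rng.integers(0, 3)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = rng.uniform(0.15, cfg.occupancy_cutoff_short - 0.01)
        return anchor + r * direction

    schedules = {m: rng.random(n_frames) < bound_fraction for m in binder_mols}

    prot = np.empty((n_frames, len(residues), 3))
    lip = np.empty((n_frames, len(lipid_ids), 3))
    for f in range(n_frames):
        prot[f] = protein_ref
        for j, m in enumerate(lipid_ids):
            if m in schedules and schedules[m][f]:
                lip[f, j] = near_point()
            else:
                lip[f, j] = far_point()

    traj = Trajectory(
        protein_xyz=prot,
        protein_residues=residues,
        lipid_xyz=lip,
        lipid_molecule=lipid_ids,
        lipid_species=lipid_sp,
        box=box,
    )
    realized = (
        float(np.mean(np.any([schedules[m] for m in binder_mols], axis=0)))
        if len(binder_mols)
        else 0.0
    )
    truth = {
        "bound_fraction": bound_fraction,
        "realized_any_bound_fraction": realized,
        "site_residues": site,
        "binder_species": "DMPG",
        "n_binders": n_binders,
        "n_lipids": dict(n_lipids),
        "seed": seed,
    }
    return traj, truth
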