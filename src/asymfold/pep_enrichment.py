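"""Membrane-depth residue-enrichment analysis for β-barrel OMPs.

Membrane-aligned structures (membrane normal along z, origin at the bilayer
centre, extracellular side positive) are pooled and sliced into 1 Å slabs
parallel to the membrane plane; each residue is assigned to a slab by its Cα
z-coordinate.  Per-slab amino-acid frequencies are compared with a
background composition — either the whole protein or its soluble (non-TM)
regions only — as a log₂ enrichment, with pseudocounts guarding zero cells.
Significance thresholds are computed separately for enrichment and
depletion: σ_enrich is the standard deviation of all positive enrichment
values and σ_deplete that of all negative ones, with 2σ and 3σ flags.

The same machinery runs on bare sequences with per-residue topology labels:
a residue-count→distance calibration (median |z| at each residue offset
from the membrane boundary, made monotone by isotonic regression) converts
chain positions into pseudo-depths.

The headline output is the "patch of external positive" (PEP): a contiguous
band of >2σ Lys/Arg enrichment in the extracellular loops a few Å above the
outer-leaflet plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "ResidueRecord",
    "MembraneAlignedStructure",
    "TopologySequence",
    "SlabProfile",
    "EnrichmentProfile",
    "DistanceCalibration",
    "PatchReport",
    "build_slab_profile",
    "compute_enrichment",
    "detect_positive_patch",
    "calibrate_distance",
    "sequence_enrichment",
    "load_membrane_structure",
    "load_topology_records",
]

AMINO_ACIDS: Tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a membrane-aligned structure.

    ca_z is the Cα position along the membrane normal (Å), origin at the
    bilayer centre, extracellular side positive.  region is "TM" or
    "soluble"; side is "extracellular", "periplasmic" or "membrane".
    """

    resname: str  # 1-letter code
    chain: str
    index: int
    ca_z: float
    region: str
    side: str


@dataclass
class MembraneAlignedStructure:
    residues: List[ResidueRecord]
    half_thickness: float

    def __post_init__(self):
        if self.half_thickness <= 0:
            raise DomainError("half_thickness must be positive")


@dataclass(frozen=True)
class TopologySequence:
    """A sequence with per-residue topology labels.

    topology characters: S = transmembrane strand, L = extracellular loop,
    T = periplasmic turn, X = soluble (termini / soluble domain).
    """

    name: str
    sequence: str
    topology: str

    def __post_init__(self):
        if len(self.sequence) != len(self.topology):
            raise DomainError(f"{self.name}: sequence/topology length mismatch")
        bad = set(self.topology) - set("SLTX")
        if bad:
            raise DomainError(f"{self.name}: unknown topology label(s) {sorted(bad)}")


@dataclass
class SlabProfile:
    """Pooled per-slab, per-amino-acid residue counts plus background totals.

    counts_all includes every residue; counts_soluble excludes TM-region
    residues (for the soluble-only background mode).  Slab index i covers
    the half-open interval [i, i+1)·slab_width Å.
    """

    counts_all: pd.DataFrame  # index: slab int, columns: AMINO_ACIDS
    counts_soluble: pd.DataFrame
    background_whole: pd.Series
    background_soluble: pd.Series
    slab_width: float
    n_skipped: int


@dataclass
class EnrichmentProfile:
    """log₂ enrichment per slab × amino acid, with separate σ thresholds."""

    enrichment: pd.DataFrame  # NaN marks slabs with no assigned residues
    sigma_enrich: float
    sigma_deplete: float
    flags_2s: pd.DataFrame
    flags_3s: pd.DataFrame
    background_mode: str
    slab_width: float


@dataclass
class PatchReport:
    """Location of the strongest contiguous >2σ Lys/Arg band, if any."""

    found: bool
    band_above_leaflet: Optional[Tuple[float, float]]  # Å above +half_thickness
    band_absolute_z: Optional[Tuple[float, float]]
    peak_slab_above_leaflet: Optional[float]
    peak_enrichment: Optional[float]
    centroid_above_leaflet: Optional[float]  # enrichment-weighted, all >2σ slabs
    n_slabs: int


def build_slab_profile(
    structures: Sequence[MembraneAlignedStructure], slab_width: float = 1.0
) -> SlabProfile:
    """Pool residues from all structures into 1 Å depth slabs by Cα z."""
    if slab_width <= 0:
        raise DomainError("slab_width must be positive")
    rows_all: Dict[int, np.ndarray] = {}
    rows_sol: Dict[int, np.ndarray] = {}
    bg_whole = pd.Series(0.0, index=list(AMINO_ACIDS))
    bg_sol = pd.Series(0.0, index=list(AMINO_ACIDS))
    aa_pos = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n_skipped = 0
    n_assigned = 0
    for struct in structures:
        for res in struct.residues:
            if res.resname not in aa_pos or not np.isfinite(res.ca_z):
                n_skipped += 1
                continue
            slab = int(np.floor(res.ca_z / slab_width))
            j = aa_pos[res.resname]
            rows_all.setdefault(slab, np.zeros(20))[j] += 1
            bg_whole[res.resname] += 1
            if res.region != "TM":
                rows_sol.setdefault(slab, np.zeros(20))[j] += 1
                bg_sol[res.resname] += 1
            n_assigned += 1
    if n_assigned == 0:
        raise DomainError("no residues could be assigned to slabs")
    if n_skipped:
        logger.info("build_slab_profile: skipped %d residues without usable Cα", n_skipped)

    def frame(rows):
        if not rows:
            return pd.DataFrame(columns=list(AMINO_ACIDS), dtype=float)
        idx = sorted(rows)
        return pd.DataFrame(
            [rows[i] for i in idx], index=idx, columns=list(AMINO_ACIDS)
        )

    return SlabProfile(
        counts_all=frame(rows_all),
        counts_soluble=frame(rows_sol),
        background_whole=bg_whole,
        background_soluble=bg_sol,
        slab_width=slab_width,
        n_skipped=n_skipped,
    )


def compute_enrichment(
    profile: SlabProfile,
    background: str = "whole_protein",
    pseudocount: float = 0.5,
    sigma_z_bound: float = 50.0,
) -> EnrichmentProfile:
    """log₂ slab-vs-background frequency enrichment with 2σ/3σ flags.

    enrichment(s, r) = log₂[ ((n_sr + pc)/(n_s· + 20·pc)) /
                             ((B_r + pc)/(B_· + 20·pc)) ]
    In soluble_only mode TM residues are excluded from both the slabs and
    the background.  σ_enrich (σ_deplete) is the standard deviation of all
    positive (negative) enrichment values among slabs whose centre lies
    within ``sigma_z_bound`` Å of the membrane centre, so sparse far-field
    slabs do not dominate the thresholds.
    """
    if background == "whole_protein":
        counts, bg = profile.counts_all, profile.background_whole
    elif background == "soluble_only":
        counts, bg = profile.counts_soluble, profile.background_soluble
    else:
        raise DomainError(f"unknown background mode {background!r}")
    if counts.empty or bg.sum() == 0:
        raise DomainError("empty slab profile")

    pc = pseudocount
    slab_tot = counts.sum(axis=1)
    bg_freq = (bg + pc) / (bg.sum() + 20 * pc)
    obs_freq = (counts + pc).div(slab_tot + 20 * pc, axis=0)
    enr = np.log2(obs_freq.div(bg_freq, axis=1))
    enr[slab_tot == 0] = np.nan  # undefined, never 0

    centres = (enr.index.to_numpy() + 0.5) * profile.slab_width
    in_bound = np.abs(centres) <= sigma_z_bound
    vals = enr.loc[in_bound].to_numpy().ravel()
    vals = vals[np.isfinite(vals)]
    pos, neg = vals[vals > 0], vals[vals < 0]
    sigma_enrich = float(pos.std()) if pos.size > 1 else float("inf")
    sigma_deplete = float(neg.std()) if neg.size > 1 else float("inf")

    flags_2s = (enr > 2 * sigma_enrich) | (enr < -2 * sigma_deplete)
    flags_3s = (enr > 3 * sigma_enrich) | (enr < -3 * sigma_deplete)
    return EnrichmentProfile(
        enrichment=enr,
        sigma_enrich=sigma_enrich,
        sigma_deplete=sigma_deplete,
        flags_2s=flags_2s.fillna(False),
        flags_3s=flags_3s.fillna(False),
        background_mode=background,
        slab_width=profile.slab_width,
    )


def _contiguous_runs(slabs: np.ndarray, hot: np.ndarray) -> List[List[int]]:
    """Index runs of hot slabs that are contiguous in slab index."""
    runs: List[List[int]] = []
    run: List[int] = []
    for i, (s, h) in enumerate(zip(slabs, hot)):
        if h and (not run or s == slabs[run[-1]] + 1):
            run.append(i)
        elif h:
            runs.append(run)
            run = [i]
        elif run:
            runs.append(run)
            run = []
    if run:
        runs.append(run)
    return runs


def detect_positive_patch(
    profile: EnrichmentProfile, half_thickness: float, min_slabs: int = 2
) -> PatchReport:
    """Locate the strongest contiguous >2σ Lys/Arg band above the outer leaflet.

    Lys and Arg enrichments are pooled (averaged) per slab on the
    extracellular side (slab centre above +half_thickness); the maximal run
    of contiguous slabs whose pooled enrichment exceeds 2σ_enrich is
    reported relative to the outer-leaflet plane.  A run shorter than
    ``min_slabs`` is not reported as a patch — with ~dozens of
    extracellular slabs a lone-slab 2σ excursion arises by chance even in
    null data, while a physical band spans several Å.  Sequence-mode
    profiles collapse each residue offset onto a single pseudo-distance
    slab, so callers analysing them should pass ``min_slabs=1``.  An empty
    report (not an error) is returned when no qualifying run exists.
    """
    enr = profile.enrichment
    w = profile.slab_width
    pooled = enr[["K", "R"]].mean(axis=1)
    centres = (pooled.index.to_numpy() + 0.5) * w
    extracellular = centres > half_thickness
    slabs = pooled.index.to_numpy()[extracellular]
    values = pooled.to_numpy()[extracellular]
    hot = np.isfinite(values) & (values > 2 * profile.sigma_enrich)
    if not hot.any():
        return PatchReport(False, None, None, None, None, None, 0)
    hot_runs = _contiguous_runs(slabs, hot)
    if max((len(r) for r in hot_runs), default=0) < min_slabs:
        return PatchReport(False, None, None, None, None, None, 0)

    best_run = max(hot_runs, key=len)
    lo_slab, hi_slab = slabs[best_run[0]], slabs[best_run[-1]]
    band_abs = (lo_slab * w, (hi_slab + 1) * w)
    peak_i = best_run[int(np.argmax(values[best_run]))]
    peak_centre = (slabs[peak_i] + 0.5) * w
    hot_centres = (slabs[hot] + 0.5) * w
    hot_vals = values[hot]
    centroid = float(np.average(hot_centres, weights=hot_vals))
    return PatchReport(
        found=True,
        band_above_leaflet=(band_abs[0] - half_thickness, band_abs[1] - half_thickness),
        band_absolute_z=band_abs,
        peak_slab_above_leaflet=float(peak_centre - half_thickness),
        peak_enrichment=float(values[peak_i]),
        centroid_above_leaflet=centroid - half_thickness,
        n_slabs=len(best_run),
    )


# ---------------------------------------------------------------------------
# sequence mode


@dataclass
class DistanceCalibration:
    """Residue-count-from-membrane-boundary → median Å distance mapping.

    Built from structures: for each residue offset k along the chain from
    the last TM residue, the median |Cα z| over all loops/turns, forced
    monotone non-decreasing by isotonic regression.  Offsets observed fewer
    than ``min_observations`` times are flagged low-confidence.
    """

    offsets: np.ndarray
    distances: np.ndarray  # monotone, Å
    counts: np.ndarray
    low_confidence: np.ndarray
    min_observations: int = 10

    def __call__(self, k: int) -> float:
        k = int(np.clip(k, self.offsets[0], self.offsets[-1]))
        return float(self.distances[np.searchsorted(self.offsets, k)])


def _offsets_from_tm(regions: Sequence[bool]) -> np.ndarray:
    """Residue-count distance to the nearest TM residue along the chain."""
    n = len(regions)
    INF = n + 1
    fwd = np.full(n, INF)
    last = -INF
    for i, tm in enumerate(regions):
        if tm:
            last = i
        fwd[i] = i - last
    bwd = np.full(n, INF)
    nxt = INF * 2
    for i in range(n - 1, -1, -1):
        if regions[i]:
            nxt = i
        bwd[i] = nxt - i
    return np.minimum(fwd, bwd)


def calibrate_distance(
    structures: Sequence[MembraneAlignedStructure],
    min_observations: int = 10,
    side: Optional[str] = None,
) -> DistanceCalibration:
    """Derive the residue-count → Å mapping from membrane-aligned structures.

    ``side`` optionally restricts the non-TM observations to one membrane
    side ("extracellular" or "periplasmic").  Extracellular loops reach much
    further than the short periplasmic turns, so a side-specific calibration
    is sharper when the downstream analysis concerns one side only (as the
    extracellular positive-patch search does).
    """
    samples: Dict[int, List[float]] = {}
    for struct in structures:
        by_chain: Dict[str, List[ResidueRecord]] = {}
        for res in struct.residues:
            by_chain.setdefault(res.chain, []).append(res)
        for chain_res in by_chain.values():
            chain_res.sort(key=lambda r: r.index)
            tm = [r.region == "TM" for r in chain_res]
            if not any(tm):
                continue
            offs = _offsets_from_tm(tm)
            n_chain = len(chain_res)
            for i, (r, k) in enumerate(zip(chain_res, offs)):
                if not np.isfinite(r.ca_z) or k > n_chain:
                    continue
                if k == 0:
                    # anchor: only boundary TM residues (chain-adjacent to a
                    # loop/turn) sample the membrane boundary distance
                    at_boundary = (i > 0 and not tm[i - 1]) or (
                        i + 1 < n_chain and not tm[i + 1]
                    )
                    if not at_boundary:
                        continue
                elif side is not None and r.side != side:
                    continue
                samples.setdefault(int(k), []).append(abs(r.ca_z))
    if not samples:
        raise DomainError("no chains with TM annotations; cannot calibrate")
    ks = np.array(sorted(samples))
    med = np.array([np.median(samples[k]) for k in ks])
    counts = np.array([len(samples[k]) for k in ks])
    iso = IsotonicRegression(increasing=True)
    mono = iso.fit_transform(ks, med, sample_weight=counts)
    return DistanceCalibration(
        offsets=ks,
        distances=mono,
        counts=counts,
        low_confidence=counts < min_observations,
        min_observations=min_observations,
    )


def _pseudo_structure(
    record: TopologySequence, calibration: DistanceCalibration, half_thickness: float
) -> MembraneAlignedStructure:
    """Place a topology-labelled sequence at calibrated pseudo-depths."""
    topo = record.topology
    tm = [c == "S" for c in topo]
    offs = _offsets_from_tm(tm) if any(tm) else np.zeros(len(topo), dtype=int)
    residues = []
    for i, (aa, lab) in enumerate(zip(record.sequence, topo)):
        if lab == "S":
            # spread TM residues through the membrane span for completeness;
            # soluble-only mode (the patch analysis mode) ignores them anyway
            z = np.interp(i % 7, [0, 6], [-half_thickness, half_thickness])
            region, side = "TM", "membrane"
        else:
            dist = calibration(int(offs[i]))
            if lab == "L":
                z, side = dist, "extracellular"
            else:  # T (periplasmic turn) and X (soluble termini, periplasmic)
                z, side = -dist, "periplasmic"
            region = "soluble"
        residues.append(ResidueRecord(aa, "A", i + 1, float(z), region, side))
    return MembraneAlignedStructure(residues=residues, half_thickness=half_thickness)


def sequence_enrichment(
    records: Sequence[TopologySequence],
    calibration: DistanceCalibration,
    half_thickness: float,
    background: str = "soluble_only",
    slab_width: float = 1.0,
    pseudocount: float = 0.5,
) -> EnrichmentProfile:
    """Run the depth-enrichment analysis on topology-labelled sequences.

    Each loop/turn residue is assigned a pseudo-depth from the calibration
    (positive for extracellular loops, negative for periplasmic turns), and
    slab profiling plus enrichment run exactly as in structure mode.
    """
    for rec in records:
        unlabeled = set(rec.topology) - set("SLTX")
        if unlabeled:
            raise DomainError(f"record {rec.name}: unlabelled residues")
    structs = [_pseudo_structure(r, calibration, half_thickness) for r in records]
    profile = build_slab_profile(structs, slab_width=slab_width)
    return compute_enrichment(profile, background=background, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# I/O


def load_membrane_structure(
    pdb_path: str,
    half_thickness: float,
    annotations: Optional[pd.DataFrame] = None,
) -> MembraneAlignedStructure:
    """Read a membrane-aligned PDB (z = membrane normal, origin at centre).

    ``annotations`` is an optional per-residue table with columns
    chain, resnum, region, side; when absent, region/side are inferred from
    the Cα z-coordinate (|z| <= half_thickness → TM).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", pdb_path)[0]
    ann = None
    if annotations is not None:
        ann = {
            (str(r["chain"]), int(r["resnum"])): (str(r["region"]), str(r["side"]))
            for _, r in annotations.iterrows()
        }
    residues = []
    for chain in model:
        for res in chain:
            if res.id[0] != " " or "CA" not in res:
                continue
            one = THREE_TO_ONE.get(res.get_resname())
            if one is None:
                continue
            z = float(res["CA"].coord[2])
            key = (chain.id, res.id[1])
            if ann is not None and key in ann:
                region, side = ann[key]
            else:
                if abs(z) <= half_thickness:
                    region, side = "TM", "membrane"
                else:
                    region = "soluble"
                    side = "extracellular" if z > 0 else "periplasmic"
            residues.append(ResidueRecord(one, chain.id, res.id[1], z, region, side))
    if not residues:
        raise DomainError(f"no usable residues in {pdb_path}")
    return MembraneAlignedStructure(residues=residues, half_thickness=half_thickness)


def load_topology_records(fasta_path: str, topology_path: str) -> List[TopologySequence]:
    """Pair a FASTA file with a same-order FASTA-like topology-string file."""
    from Bio import SeqIO

    seqs = list(SeqIO.parse(fasta_path, "fasta"))
    topos = list(SeqIO.parse(topology_path, "fasta"))
    if len(seqs) != len(topos):
        raise DomainError("FASTA and topology files differ in record count")
    return [
        TopologySequence(name=s.id, sequence=str(s.seq), topology=str(t.seq))
        for s, t in zip(seqs, topos)
    ]
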