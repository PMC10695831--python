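import numpy as np
import pandas as pd
import pytest

from asymfold.errors import DomainError
from asymfold.pep_enrichment import (
    AMINO_ACIDS,
    MembraneAlignedStructure,
    ResidueRecord,
    TopologySequence,
    build_slab_profile,
    calibrate_distance,
    compute_enrichment,
    detect_positive_patch,
    load_membrane_structure,
    sequence_enrichment,
)
from asymfold.synthetic_data import BarrelSpec, PatchSpec, gen_membrane_cohort


def uniform_structure(n_slabs=10, half_thickness=15.0):
    """Each 1 Å slab in [0, n_slabs) contains every amino acid exactly once."""
    residues = []
    i = 0
    for slab in range(n_slabs):
        for aa in AMINO_ACIDS:
            residues.append(ResidueRecord(aa, "A", i + 1, slab + 0.5, "soluble",
                                          "extracellular"))
            i += 1
    return MembraneAlignedStructure(residues, half_thickness=half_thickness)


class TestSlabProfile:
    @pytest.mark.parametrize("z,slab", [(0.5, 0), (-0.5, -1), (1.0, 1)])
    def test_half_open_slab_convention(self, z, slab):
        s = MembraneAlignedStructure(
            [ResidueRecord("G", "A", 1, z, "soluble", "extracellular")], 15.0)
        prof = build_slab_profile([s])
        assert prof.counts_all.loc[slab, "G"] == 1

    def test_uniform_grid_counting(self):
        # 100 Gly on a 0.1 A grid over [0, 10) -> 10 per slab
        residues = [ResidueRecord("G", "A", i + 1, i * 0.1, "soluble", "extracellular")
                    for i in range(100)]
        prof = build_slab_profile([MembraneAlignedStructure(residues, 15.0)])
        assert (prof.counts_all["G"] == 10).all()

    def test_residue_conservation(self):
        structs, _, _ = gen_membrane_cohort(3, seed=0)
        n_residues = sum(len(s.residues) for s in structs)
        prof = build_slab_profile(structs)
        assert prof.counts_all.to_numpy().sum() + prof.n_skipped == n_residues

    def test_nonfinite_ca_skipped(self):
        residues = [ResidueRecord("G", "A", 1, np.nan, "soluble", "extracellular"),
                    ResidueRecord("A", "A", 2, 1.5, "soluble", "extracellular")]
        prof = build_slab_profile([MembraneAlignedStructure(residues, 15.0)])
        assert prof.n_skipped == 1
        assert prof.counts_all.to_numpy().sum() == 1


class TestEnrichment:
    def test_uniform_composition_is_exactly_zero(self):
        # slab composition identical to background -> pseudocounts cancel
        prof = build_slab_profile([uniform_structure()])
        ep = compute_enrichment(prof, background="whole_protein")
        vals = ep.enrichment.to_numpy()
        assert np.nanmax(np.abs(vals)) == pytest.approx(0.0, abs=1e-12)
        assert not ep.flags_2s.to_numpy().any()

    def test_duplication_invariance(self):
        structs, _, _ = gen_membrane_cohort(4, seed=1)
        ep1 = compute_enrichment(build_slab_profile(structs), "soluble_only")
        ep2 = compute_enrichment(build_slab_profile(structs * 2), "soluble_only")
        # frequencies unchanged; pseudocount influence shrinks, so compare loosely
        common = ep1.enrichment.index.intersection(ep2.enrichment.index)
        a = ep1.enrichment.loc[common].to_numpy()
        b = ep2.enrichment.loc[common].to_numpy()
        mask = np.isfinite(a) & np.isfinite(b)
        assert np.corrcoef(a[mask], b[mask])[0, 1] > 0.99

    def test_single_residue_slab_finite(self):
        residues = [ResidueRecord("K", "A", 1, 20.5, "soluble", "extracellular")]
        residues += [ResidueRecord(aa, "A", i + 2, 0.5, "soluble", "extracellular")
                     for i, aa in enumerate(AMINO_ACIDS)]
        prof = build_slab_profile([MembraneAlignedStructure(residues, 15.0)])
        ep = compute_enrichment(prof)
        assert np.isfinite(ep.enrichment.loc[20, "K"])

    def test_planted_lysine_band_flagged(self):
        rng = np.random.default_rng(0)
        residues = []
        i = 0
        # background: uniform composition across z in [15, 30)
        for _ in range(4000):
            z = rng.uniform(15, 30)
            aa = AMINO_ACIDS[rng.integers(0, 20)]
            in_band = 21 <= z < 25
            if in_band and rng.random() < 0.5:
                aa = "K"
            residues.append(ResidueRecord(aa, "A", i + 1, z, "soluble",
                                          "extracellular"))
            i += 1
        prof = build_slab_profile([MembraneAlignedStructure(residues, 15.0)])
        ep = compute_enrichment(prof, background="whole_protein")
        band_flags = ep.flags_2s.loc[21:24, "K"]
        assert band_flags.all()

    def test_empty_profile_errors(self):
        prof = build_slab_profile([uniform_structure()])
        prof.counts_soluble = prof.counts_soluble.iloc[0:0]
        prof.background_soluble[:] = 0
        with pytest.raises(DomainError):
            compute_enrichment(prof, background="soluble_only")


class TestPatchDetection:
    def test_planted_patch_recovered(self):
        structs, _, truth = gen_membrane_cohort(
            30, patch=PatchSpec(centre=8, width=4, excess=3), seed=5)
        ep = compute_enrichment(build_slab_profile(structs), "soluble_only")
        rep = detect_positive_patch(ep, truth["half_thickness"])
        assert rep.found
        lo, hi = rep.band_above_leaflet
        assert lo < 10 and hi > 6  # overlaps the planted 6-10 A band
        assert abs(rep.centroid_above_leaflet - 8.0) <= 1.5

    def test_null_cohort_empty_report(self):
        structs, _, truth = gen_membrane_cohort(30, patch=PatchSpec(excess=1.0),
                                                seed=6)
        ep = compute_enrichment(build_slab_profile(structs), "soluble_only")
        rep = detect_positive_patch(ep, truth["half_thickness"])
        assert not rep.found

    def test_periplasmic_patch_not_reported_extracellular(self):
        # plant K/R below the membrane only; extracellular report stays empty
        rng = np.random.default_rng(2)
        residues = []
        for i in range(6000):
            if rng.random() < 0.5:
                z = rng.uniform(-25, -15)
                aa = "K" if (-23 <= z < -19 and rng.random() < 0.5) else \
                    AMINO_ACIDS[rng.integers(0, 20)]
                side = "periplasmic"
            else:
                z = rng.uniform(15, 25)
                aa = AMINO_ACIDS[rng.integers(0, 20)]
                side = "extracellular"
            residues.append(ResidueRecord(aa, "A", i + 1, float(z), "soluble", side))
        ep = compute_enrichment(
            build_slab_profile([MembraneAlignedStructure(residues, 15.0)]),
            "soluble_only")
        rep = detect_positive_patch(ep, 15.0)
        assert not rep.found


class TestDistanceCalibration:
    def test_extended_chain_geometry(self):
        # chain rising 3 A per residue from the boundary
        residues = []
        idx = 1
        for rep in range(12):  # several loops for the sample-count threshold
            for k in range(10):  # TM stretch rising to the boundary at +15 A
                residues.append(ResidueRecord("A", chr(65 + rep), idx, 6.0 + k,
                                              "TM", "membrane"))
                idx += 1
            for k in range(1, 8):  # loop climbing 3 A per residue
                residues.append(ResidueRecord("A", chr(65 + rep), idx, 15.0 + 3 * k,
                                              "soluble", "extracellular"))
                idx += 1
        cal = calibrate_distance([MembraneAlignedStructure(residues, 15.0)])
        assert cal(0) == pytest.approx(15.0, abs=0.5)
        for k in (1, 3, 5):
            assert cal(k) == pytest.approx(15.0 + 3 * k, abs=0.5)

    def test_isotonic_output_monotone(self):
        structs, _, _ = gen_membrane_cohort(10, seed=3)
        cal = calibrate_distance(structs)
        assert np.all(np.diff(cal.distances) >= -1e-9)

    def test_low_confidence_flagging(self):
        structs, _, _ = gen_membrane_cohort(1, seed=4)
        cal = calibrate_distance(structs, min_observations=10**6)
        assert cal.low_confidence.all()


class TestSequenceMode:
    def test_agrees_with_structure_mode(self):
        diffs = []
        for seed in range(3):
            structs, seqs, truth = gen_membrane_cohort(
                40, patch=PatchSpec(centre=8, width=4, excess=3), seed=seed)
            h = truth["half_thickness"]
            ep_s = compute_enrichment(build_slab_profile(structs), "soluble_only")
            rep_s = detect_positive_patch(ep_s, h)
            cal = calibrate_distance(structs, side="extracellular")
            ep_q = sequence_enrichment(seqs, cal, h)
            rep_q = detect_positive_patch(ep_q, h, min_slabs=1)
            assert rep_s.found and rep_q.found
            diffs.append(abs(rep_s.centroid_above_leaflet - rep_q.centroid_above_leaflet))
        assert np.median(diffs) <= 2.0

    def test_all_loop_polyala_flat(self):
        recs = [TopologySequence(f"r{i}", "A" * 30, "L" * 30) for i in range(5)]
        structs, _, _ = gen_membrane_cohort(5, seed=0)
        cal = calibrate_distance(structs)
        ep = sequence_enrichment(recs, cal, 15.0)
        vals = ep.enrichment.to_numpy()
        assert np.nanmax(np.abs(vals)) == pytest.approx(0.0, abs=1e-9)

    def test_unlabelled_residue_rejected(self):
        with pytest.raises(DomainError):
            TopologySequence("bad", "AAAA", "LLZZ")


def test_pdb_roundtrip(tmp_path):
    # a tiny membrane-aligned PDB: two residues straddling the leaflet plane
    pdb = tmp_path / "mini.pdb"
    pdb.write_text(
        "ATOM      1  CA  LYS A   1       0.000   0.000  20.500  1.00  0.00           C\n"
        "ATOM      2  CA  ALA A   2       0.000   0.000   5.000  1.00  0.00           C\n"
        "END\n"
    )
    s = load_membrane_structure(str(pdb), half_thickness=15.0)
    assert len(s.residues) == 2
    lys, ala = s.residues
    assert lys.resname == "K" and lys.region == "soluble" and lys.side == "extracellular"
    assert ala.resname == "A" and ala.region == "TM"
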