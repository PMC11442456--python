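import numpy as np
import pytest

from amyloidsim import chemshift, model_io, peaksim, synthetic
from amyloidsim.peaksim import (
    LabelingScheme,
    PeakList,
    count_sheet_residues,
    enumerate_cc_peaks,
    enumerate_nc_peaks,
    enumerate_pain_peaks,
)

from conftest import brute_force_cc_pairs


def _merged_positions(pairs, tol=0.01):
    return {(round(a / tol), round(b / tol)) for a, b in pairs}


class TestCCPeaks:
    def test_toy_residue_four_peaks(self, one_residue_structure, toy_shifts):
        peaks = enumerate_cc_peaks(one_residue_structure, toy_shifts, cutoff=5.0)
        assert len(peaks) == 4
        positions = {(round(p.omega1, 1), round(p.omega2, 1)) for p in peaks}
        assert positions == {(55.1, 18.6), (18.6, 55.1), (55.1, 55.1), (18.6, 18.6)}

    def test_cutoff_excludes_distant_pairs(self, toy_shifts):
        far = model_io.Structure(
            atoms=[
                model_io.Atom("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
                model_io.Atom("A", 1, "ALA", "CB", "C", (6.0, 0.0, 0.0)),
            ]
        )
        peaks = enumerate_cc_peaks(far, toy_shifts, cutoff=5.0)
        assert all(p.residue_relation == "diagonal" for p in peaks)
        assert len(peaks) == 2

    def test_intra_residue_filter(self):
        seq = "AC"
        s = synthetic.build_backbone(seq + "G", -120, 120)
        shifts = chemshift.predict_shifts(seq + "G", None)
        peaks = enumerate_cc_peaks(s, shifts, filter="intra_residue_only", include_diagonal=False)
        assert peaks
        for p in peaks:
            a, b = p.atoms
            assert a.residue_number == b.residue_number

    def test_symmetry(self, helix12):
        shifts = chemshift.predict_shifts("A" * 12, None)
        peaks = enumerate_cc_peaks(helix12, shifts, include_diagonal=False)
        index = {(round(p.omega1, 4), round(p.omega2, 4)): p.amplitude for p in peaks}
        for (w1, w2), amp in index.items():
            assert index.get((w2, w1)) == pytest.approx(amp)

    def test_monotone_in_cutoff(self, helix12):
        shifts = chemshift.predict_shifts("A" * 12, None)
        counts = [
            len(enumerate_cc_peaks(helix12, shifts, cutoff=c)) for c in (2.0, 4.0, 5.0, 7.0)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("filter_", ["all", "intra_residue_only", "inter_residue_only"])
    def test_matches_brute_force_oracle(self, filter_):
        """Enumeration equals an independent O(n^2) all-pairs scan exactly."""
        seq = "AGSVLTKEQN"  # 10 residues x 5 atoms = 50 atoms, < 200
        model = synthetic.build_backbone(seq, -57, -47)
        shifts = chemshift.predict_shifts(seq, None)
        peaks = enumerate_cc_peaks(model, shifts, cutoff=5.0, filter=filter_, include_diagonal=False)
        oracle = brute_force_cc_pairs(model, shifts, 5.0, filter=filter_)
        assert _merged_positions([(p.omega1, p.omega2) for p in peaks]) == _merged_positions(oracle)
        assert sum(len(p.contributor_pairs()) for p in peaks) == len(oracle)

    def test_central_layer_convention_matches_oracle(self, ala_stack5, strand_shifts20):
        peaks = enumerate_cc_peaks(ala_stack5, strand_shifts20, cutoff=5.0, include_diagonal=False)
        central = set(ala_stack5.metadata["central_chains"])
        oracle = brute_force_cc_pairs(
            ala_stack5, strand_shifts20, 5.0, source_chains=central
        )
        assert _merged_positions([(p.omega1, p.omega2) for p in peaks]) == _merged_positions(oracle)
        assert sum(len(p.contributor_pairs()) for p in peaks) == len(oracle)

    def test_in_register_intra_and_inter_chain_peaks_coincide(self, ala_stack5, strand_shifts20):
        """In-register stacking: inter-chain CC peaks superpose on intra-chain ones."""
        peaks = enumerate_cc_peaks(ala_stack5, strand_shifts20, include_diagonal=False)
        for p in peaks:
            mols = {m for _, m in p.contributor_pairs()}
            if len(mols) == 2:
                break
        else:
            pytest.fail("no merged peak carries both intra- and inter-chain contributors")

    def test_missing_shift_counted(self, one_residue_structure):
        table = chemshift.ShiftTable([chemshift.ShiftEntry(1, "ALA", "CA", "C13", 55.1)])
        peaks = enumerate_cc_peaks(one_residue_structure, table)
        assert peaks.skipped == 1


class TestNCPeaks:
    def test_one_nca_peak_per_residue(self):
        s = synthetic.build_backbone("AAA", -57, -47)
        shifts = chemshift.predict_shifts("AAA", None)
        # identical Ala shifts merge into a single position; count contributors
        peaks = enumerate_nc_peaks(s, shifts, mode="NCA")
        n = sum(len(p.contributor_pairs()) for p in peaks)
        assert n == 3

    def test_gly_skipped_in_ncb(self):
        s = synthetic.build_backbone("AGSV", -120, 120)
        shifts = chemshift.predict_shifts("AGSV", None)
        peaks = enumerate_nc_peaks(s, shifts, mode="NCB")
        n = sum(len(p.contributor_pairs()) for p in peaks)
        assert n == 3  # 4 residues - 1 Gly
        assert peaks.skipped == 0

    def test_missing_shift_reported(self):
        s = synthetic.build_backbone("ASV", -57, -47)
        shifts = chemshift.predict_shifts("ASV", None)
        shifts = chemshift.ShiftTable([e for e in shifts.entries if not (e.residue_number == 1 and e.atom_name == "N")])
        peaks = enumerate_nc_peaks(s, shifts, mode="NCA")
        n = sum(len(p.contributor_pairs()) for p in peaks)
        assert n == 2
        assert peaks.skipped == 1


class TestPainPeaks:
    def test_single_n15_chain_gives_no_peaks(self, helix12):
        shifts = chemshift.predict_shifts("A" * 12, None)
        scheme = LabelingScheme({"A": {"N15"}})
        peaks = enumerate_pain_peaks(helix12, shifts, scheme)
        assert len(peaks) == 0

    def test_mixed_labeling_yields_only_inter_chain(self, ala_stack5, strand_shifts20):
        scheme = LabelingScheme.mixed(ala_stack5.chain_ids)
        peaks = enumerate_pain_peaks(ala_stack5, strand_shifts20, scheme)
        assert peaks
        for p in peaks:
            for _, mol in p.contributor_pairs():
                assert mol == "inter_chain"

    def test_uniform_labeling_matches_brute_force(self, helix12):
        shifts = chemshift.predict_shifts("A" * 12, None)
        scheme = LabelingScheme.uniform(["A"])
        peaks = enumerate_pain_peaks(helix12, shifts, scheme, cutoff=5.0)
        n_atoms = [a for a in helix12.atoms if a.atom_name.startswith("N")]
        c_atoms = [a for a in helix12.atoms if a.element == "C"]
        oracle = 0
        for an in n_atoms:
            for ac in c_atoms:
                if np.linalg.norm(np.subtract(an.xyz, ac.xyz)) <= 5.0:
                    oracle += 1
        assert sum(len(p.contributor_pairs()) for p in peaks) == oracle

    def test_unlabeled_chain_errors(self, ala_stack5, strand_shifts20):
        with pytest.raises(ValueError, match="labeling"):
            enumerate_pain_peaks(ala_stack5, strand_shifts20, LabelingScheme({"A0": {"N15"}}))

    def test_sheet_residue_count_on_synthetic_stack(self, ala_stack5, strand_shifts20):
        scheme = LabelingScheme.mixed(ala_stack5.chain_ids)
        peaks = enumerate_pain_peaks(ala_stack5, strand_shifts20, scheme)
        assert count_sheet_residues(peaks) == 20

    def test_count_on_empty_and_intra_only(self):
        assert count_sheet_residues(PeakList(peaks=[])) == 0
        p = peaksim.Peak2D(
            120.0,
            55.0,
            atoms=(
                peaksim.AtomRef("A", 1, "ALA", "N"),
                peaksim.AtomRef("A", 1, "ALA", "CA"),
            ),
            molecularity="intra_chain",
        )
        assert count_sheet_residues(PeakList(peaks=[p])) == 0

    def test_antiparallel_registry_changes_interlayer_geometry(self):
        par = synthetic.generate_beta_stack("A" * 10, 3)
        anti = synthetic.generate_beta_stack("A" * 10, 3, registry="antiparallel")

        def nca_dist(stack, res):
            n = stack.atom("A1", res, "N").xyz
            ca = stack.atom("A0", res, "CA").xyz
            return np.linalg.norm(np.subtract(n, ca))

        dists_par = [nca_dist(par, r) for r in range(2, 9)]
        dists_anti = [nca_dist(anti, r) for r in range(2, 9)]
        assert not np.allclose(dists_par, dists_anti, atol=0.1)


class TestPeakListIO:
    def test_tsv_round_trip(self, one_residue_structure, toy_shifts, tmp_path):
        peaks = enumerate_cc_peaks(one_residue_structure, toy_shifts)
        p = tmp_path / "peaks.tsv"
        peaks.write_tsv(p)
        back = PeakList.read_tsv(p)
        assert len(back) == len(peaks)
        a = sorted((pk.omega1, pk.omega2, pk.amplitude) for pk in peaks)
        b = sorted((pk.omega1, pk.omega2, pk.amplitude) for pk in back)
        assert np.allclose(a, b)
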