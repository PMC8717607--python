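import numpy as np
import pytest
from scipy import stats

from mudia.acquisition import SpectrumScan
from mudia.chem import InputError, theoretical_ions
from mudia.ident import (DECOY_PREFIX, PSM, assign_razor, build_search_space,
                         compute_coverage, deduplicate_scan_psms, fdr_filter,
                         match_spectrum)


def _scan(mz, intensity=None, rt=100.0):
    mz = np.asarray(mz, float)
    inten = np.ones_like(mz) if intensity is None else np.asarray(intensity)
    return SpectrumScan(2, rt, mz, inten, bin_index=0)


class TestSearchSpace:
    def test_decoy_proteins_one_to_one(self):
        space = build_search_space([("P1", "AAAWAAKGGGYGGRCCCFCCK")])
        target_prots = {a for i in space.ions if not i.is_decoy
                        for a in i.parent_accessions}
        decoy_prots = {a for i in space.ions if i.is_decoy
                       for a in i.parent_accessions}
        assert target_prots == {"P1"}
        assert decoy_prots == {DECOY_PREFIX + "P1"}

    def test_unmodifiable_peptide_has_single_variant(self):
        # internal peptide, no Met, no N-terminal Gln/Glu
        space = build_search_space([("P1", "WWWWKAAAGGGAKYYYYR")])
        variants = {(i.sequence, i.modifications) for i in space.ions
                    if i.sequence == "AAAGGGAK"}
        assert variants == {("AAAGGGAK", ())}

    def test_colliding_decoy_peptide_excluded(self):
        # "GGGGGGKAAAAAAK" reversed is "KAAAAAAKGGGGGG", whose digest
        # regenerates the target peptide AAAAAAK -> must be dropped.
        space = build_search_space([("P1", "GGGGGGKAAAAAAK")])
        decoy_seqs = {i.sequence for i in space.ions if i.is_decoy}
        target_seqs = {i.sequence for i in space.ions if not i.is_decoy}
        assert "AAAAAAK" in target_seqs
        assert not decoy_seqs & target_seqs
        assert space.n_decoy_collisions >= 1

    def test_empty_database_rejected(self):
        with pytest.raises(InputError):
            build_search_space([])


class TestMatchSpectrum:
    def test_perfect_match_retained_with_hand_computed_evalue(self):
        ion = theoretical_ions("SAMPLEPEPTIDEK", precursor_charges=(2,),
                               fragment_charges=(1,))[0]
        y_ions = sorted(f.mz for f in ion.fragments if f.series == "y")[:9]
        scan = _scan(y_ions)
        psms = match_spectrum(scan, [ion])
        assert len(psms) == 1
        psm = psms[0]
        assert psm.matched_fragments == 9
        # independent binomial-tail oracle with the same p_random construction
        frag = ion.fragment_mz_array(140.0, 1500.0)
        p_rand = 9 * 2 * 10e-6 * frag.mean() / (1500 - 140)
        expected = 1 * stats.binom.sf(8, frag.size, p_rand)
        assert psm.expectation == pytest.approx(expected, rel=1e-12)
        assert psm.expectation < 0.05

    def test_six_fragments_insufficient(self):
        ion = theoretical_ions("SAMPLEPEPTIDEK", precursor_charges=(2,),
                               fragment_charges=(1,))[0]
        y_ions = sorted(f.mz for f in ion.fragments if f.series == "y")[:6]
        assert match_spectrum(_scan(y_ions), [ion]) == []

    def test_evalue_decreases_with_matched_fragments(self):
        ion = theoretical_ions("SAMPLEPEPTIDEK", precursor_charges=(2,),
                               fragment_charges=(1,))[0]
        mz = sorted(f.mz for f in ion.fragments)
        pad = [1400.0 + i for i in range(len(mz) - 9)]
        e = []
        for k in (7, 8, 9):
            scan = _scan(sorted(mz[:k] + pad[:len(mz) - k]))
            (psm,) = match_spectrum(scan, [ion])
            assert psm.matched_fragments == k
            e.append(psm.expectation)
        assert e[0] > e[1] > e[2]

    def test_dedup_keeps_most_significant_of_overlapping_pair(self):
        ion_a = theoretical_ions("SAMPLEPEPTIDEK", precursor_charges=(2,),
                                 fragment_charges=(1,))[0]
        ion_b = theoretical_ions("SAMPLEPEPTIDER", precursor_charges=(2,),
                                 fragment_charges=(1,))[0]
        # b-series of the two peptides is identical (shared prefix), so the
        # scan matches both; the full y+b content favours ion_a.
        mz = sorted(f.mz for f in ion_a.fragments)
        psms = match_spectrum(_scan(mz), [ion_a, ion_b])
        assert [p.peptide_ion.sequence for p in psms] == ["SAMPLEPEPTIDEK"]

    def test_dedup_idempotent(self):
        ion_a = theoretical_ions("SAMPLEPEPTIDEK", precursor_charges=(2,),
                                 fragment_charges=(1,))[0]
        ion_b = theoretical_ions("SAMPLEPEPTIDER", precursor_charges=(2,),
                                 fragment_charges=(1,))[0]
        mz = sorted(set(f.mz for f in ion_a.fragments)
                    | set(f.mz for f in ion_b.fragments))
        scan = _scan(mz)
        once = match_spectrum(scan, [ion_a, ion_b])
        twice = deduplicate_scan_psms(once, scan)
        assert [p.ion_id for p in twice] == [p.ion_id for p in once]


class TestFdrFilter:
    def _entries(self, n_targets, decoy_ranks, n=101):
        """PSMs for distinct peptides with E increasing in rank."""
        psms = []
        rank = 0
        seqs = self._sequences(n)
        for i in range(n):
            decoy = (i + 1) in decoy_ranks
            ion = theoretical_ions(seqs[i], precursor_charges=(2,),
                                   parent_accessions=[f"P{i}"],
                                   is_decoy=decoy)[0]
            psms.append(PSM(ion, ("r", i), 10.0, 8, 1e-6 * (i + 1),
                            np.arange(8)))
        return psms

    @staticmethod
    def _sequences(n):
        out = []
        aas = "ACDEFGHILMNPQSTVWY"
        for i in range(n):
            out.append(aas[i % len(aas)] * 4 + aas[(i // len(aas)) % len(aas)]
                       * 4 + "K")
        return out

    def test_decoy_at_last_rank_excluded_by_strict_threshold(self):
        psms = self._entries(100, decoy_ranks={101})
        retained, report = fdr_filter(psms, "peptide")
        assert report["cutoff_rank"] == 100
        assert len(retained) == 100
        assert all(not p.is_decoy for p in retained)

    def test_no_decoys_retains_all_targets(self):
        psms = self._entries(10, decoy_ranks=set(), n=10)
        retained, _ = fdr_filter(psms, "peptide")
        assert len(retained) == 10

    def test_all_decoys_retains_nothing(self):
        psms = self._entries(0, decoy_ranks=set(range(1, 11)), n=10)
        retained, _ = fdr_filter(psms, "peptide")
        assert retained == []

    def test_protein_level_uses_5_percent_inclusive(self):
        # 20 target proteins + 1 decoy at the last rank: 1/20 = 5% allowed
        psms = self._entries(20, decoy_ranks={21}, n=21)
        retained, report = fdr_filter(psms, "protein")
        assert report["cutoff_rank"] == 21
        assert {a for p in retained for a in p.peptide_ion.parent_accessions} \
            == {f"P{i}" for i in range(20)}


class TestRazor:
    def test_higher_coverage_wins(self):
        parents = {"PEPK": frozenset({"A", "B"})}
        assert assign_razor(parents, {"A": 0.40, "B": 0.25}) == {"PEPK": "A"}

    def test_coverage_tie_breaks_lexicographically(self):
        parents = {"PEPK": frozenset({"P2", "P1"})}
        assert assign_razor(parents, {"P1": 0.3, "P2": 0.3}) == {"PEPK": "P1"}

    def test_unique_peptide_keeps_sole_parent(self):
        assert assign_razor({"PEPK": frozenset({"X"})}, {}) == {"PEPK": "X"}

    def test_empty_parent_set_is_internal_error(self):
        with pytest.raises(RuntimeError):
            assign_razor({"PEPK": frozenset()}, {})

    def test_coverage_fraction(self):
        cov = compute_coverage(
            ["AAK"], {"P": "AAKGGG"}, {"AAK": frozenset({"P"})})
        assert cov["P"] == pytest.approx(0.5)
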