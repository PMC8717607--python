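import numpy as np
import pandas as pd
import pytest

from mudia.acquisition import ParameterError
from mudia.chem import theoretical_ions
from mudia.prm import (MAX_LIST_SIZE, InclusionList, build_inclusion_lists,
                       quantify_prm, run_tic)
from mudia.prm import test_prm as prm_test
from mudia.synthdata import SimConfig, generate_proteome, simulate_prm_run

SAMPLES = ["A1", "A2", "B1", "B2"]
DESIGN = ["A", "A", "B", "B"]


def _discovery(n_proteins, peptides_per_protein=5):
    """Synthetic discovery summary: intensities and peptide info."""
    intensity, info = {}, {}
    aas = "ACDEFGHILMNQSTVWY"
    for p in range(n_proteins):
        acc = f"P{p:02d}"
        for j in range(peptides_per_protein):
            seq = aas[p % len(aas)] * 3 + aas[j % len(aas)] * 4 + "K"
            ion_id = f"{acc}_pep{j}"
            intensity[ion_id] = 1000.0 * (j + 1) + p
            info[ion_id] = (seq, 500.0 + p + j / 10.0, 2, frozenset({acc}))
    return intensity, info


class TestInclusionLists:
    def test_top3_by_mean_intensity(self):
        intensity, info = _discovery(1, peptides_per_protein=5)
        lists, report = build_inclusion_lists(intensity, info, ["P00"])
        entries = lists[0].entries
        assert len(entries) == 3
        chosen = {e.sequence for e in entries}
        best = {info[f"P00_pep{j}"][0] for j in (2, 3, 4)}
        assert chosen == best

    def test_catalog_fills_shortfall(self):
        intensity, info = _discovery(1, peptides_per_protein=2)
        catalog = {"P00": [("AAAAGGGGK", 401.2, 2)]}
        lists, report = build_inclusion_lists(intensity, info, ["P00"],
                                              catalog=catalog)
        entries = lists[0].entries
        assert len(entries) == 3
        assert sum(e.origin == "catalog" for e in entries) == 1

    def test_twenty_proteins_pack_into_30_plus_30(self):
        intensity, info = _discovery(20, peptides_per_protein=3)
        lists, report = build_inclusion_lists(
            intensity, info, [f"P{p:02d}" for p in range(20)])
        assert [len(l) for l in lists] == [30, 30]
        # protein groups never straddle lists
        for ilist in lists:
            accs = [e.accession for e in ilist.entries]
            assert all(accs.count(a) == 3 for a in set(accs))

    def test_shared_peptide_needs_allowlist(self):
        intensity = {"i1": 1000.0}
        info = {"i1": ("SEFYADEISK", 600.8, 2, frozenset({"Acot1", "Acot2"}))}
        lists, report = build_inclusion_lists(intensity, info, ["Acot1"])
        assert report["undesignable"] == ["Acot1"]
        lists2, report2 = build_inclusion_lists(
            intensity, info, ["Acot1"],
            shared_allowlist={"SEFYADEISK": "Acot1"})
        assert lists2[0].entries[0].sequence == "SEFYADEISK"

    def test_too_many_targets_rejected(self):
        intensity, info = _discovery(21, peptides_per_protein=3)
        with pytest.raises(ParameterError):
            build_inclusion_lists(intensity, info,
                                  [f"P{p:02d}" for p in range(21)])

    def test_list_capacity_enforced(self):
        with pytest.raises(ParameterError):
            InclusionList(entries=[object()] * (MAX_LIST_SIZE + 1))


@pytest.fixture(scope="module")
def prm_setup():
    truth = generate_proteome(6, seed=21, pathway_size=0, n_null_pathways=0,
                              up_fraction=0.2, down_fraction=0.0,
                              up_log2fc=1.0)
    config = SimConfig(gradient_length=120.0, noise_peaks_per_scan=5,
                       missing_rate=0.0)
    peps = [p for p in truth.peptides.values()][:3]
    ilist = InclusionList(entries=[], list_index=1)
    from mudia.prm import InclusionEntry
    for p in peps:
        ilist.entries.append(InclusionEntry(
            p.ion.sequence, p.ion.precursor_mz, p.ion.charge, p.accession))
    run = simulate_prm_run(truth, ilist.target_mz, config, "A", 0)
    return truth, config, ilist, run


class TestQuantifyPRM:
    def test_targets_quantified_with_enough_transitions(self, prm_setup):
        truth, config, ilist, run = prm_setup
        intensities, tic = quantify_prm(run, ilist)
        assert tic == pytest.approx(run_tic(run))
        assert len(intensities) >= 1
        assert all(v > 0 for v in intensities.values())

    def test_global_scaling_leaves_normalized_values_unchanged(self, prm_setup):
        truth, config, ilist, run = prm_setup
        i1, tic1 = quantify_prm(run, ilist)
        doubled = []
        for s in run:
            import copy
            s2 = copy.copy(s)
            s2.intensity = s.intensity * 2.0
            doubled.append(s2)
        i2, tic2 = quantify_prm(doubled, ilist)
        assert tic2 == pytest.approx(2 * tic1)
        for k in i1:
            assert i2[k] == pytest.approx(2 * i1[k], rel=1e-12)
            assert i2[k] / tic2 == pytest.approx(i1[k] / tic1, rel=1e-12)

    def test_insufficient_high_mz_transitions_not_quantified(self):
        # peptide whose fragments are mostly below 300 m/z
        ion = theoretical_ions("GAGAGAK", precursor_charges=(2,),
                               fragment_charges=(2,))[0]
        high = ion.fragment_mz_array(min_mz=300.0)
        assert len(high) < 4  # fixture premise
        from mudia.prm import InclusionEntry
        ilist = InclusionList(entries=[InclusionEntry(
            "GAGAGAK", ion.precursor_mz, 2, "PX")])
        from mudia.acquisition import SpectrumScan
        frag = ion.fragment_mz_array()
        scans = [SpectrumScan(2, 10.0 * i, np.sort(frag),
                              np.full(frag.size, 50.0),
                              window=(ion.precursor_mz, 1.6), cycle_index=i)
                 for i in range(5)]
        out, tic = quantify_prm(scans, ilist)
        assert out == {}


class TestTestPRM:
    def test_normalized_value_arithmetic(self):
        peps = pd.DataFrame({s: [100.0, 200.0] for s in SAMPLES},
                            index=["pep1/2", "pep2/2"])
        tics = {s: 1e9 for s in SAMPLES}
        out = prm_test(peps, tics, {"pep1/2": "P", "pep2/2": "P"}, DESIGN)
        assert out.loc["P", "mean_normalized_a"] == pytest.approx(3e-7)
        assert out.loc["P", "n_peptides_used"] == 2
        assert out.loc["P", "fold_change_signed"] == pytest.approx(1.0)

    def test_protein_only_in_one_condition(self):
        peps = pd.DataFrame([[50.0, 60.0, 0.0, 0.0]], index=["pep1/2"],
                            columns=SAMPLES)
        out = prm_test(peps, {s: 1e8 for s in SAMPLES}, {"pep1/2": "P"},
                       DESIGN)
        assert out.loc["P", "status"] == "only_in_A"
        assert np.isnan(out.loc["P", "p_value"])

    def test_identical_conditions_fold_change_one(self):
        peps = pd.DataFrame({s: [10.0 + i for i in range(3)] for s in SAMPLES},
                            index=["a/2", "b/2", "c/2"])
        out = prm_test(peps, {s: 1e6 for s in SAMPLES},
                       {"a/2": "P", "b/2": "P", "c/2": "P"}, DESIGN)
        assert out.loc["P", "log2_fold_change"] == pytest.approx(0.0)
        assert out.loc["P", "p_value"] == 1.0
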