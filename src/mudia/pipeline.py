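"""End-to-end orchestration of the discovery and PRM arms.

``run_discovery`` chains the full label-free pipeline on simulated (or
pre-loaded) DIA runs: demultiplexing, peptide-centric search with per-run
peptide/protein FDR control, chromatogram extraction with cross-run RT
transfer, local intensity normalization, relative-scale quantification,
protein roll-up, differential testing, and pathway enrichment of the up-
and down-regulated lists. ``run_prm_verification`` designs inclusion
lists from the discovery output and quantifies simulated PRM runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import enrich as enrich_mod
from . import ident, prm, quant, synthdata, xic
from .acquisition import SpectrumScan, WindowScheme, demultiplex_run
from .chem import PeptideIon

logger = logging.getLogger(__name__)

__all__ = ["DiscoveryResult", "run_discovery", "run_prm_verification"]


@dataclass
class DiscoveryResult:
    scheme: WindowScheme
    sample_names: list[str]
    design: list[str]
    identifications: dict[str, dict[str, float]]  # run -> ion_id -> RT
    reference_run: str
    rt_models: dict[str, xic.RTModel]
    raw_intensity: pd.DataFrame
    normalized_intensity: pd.DataFrame
    provenance: pd.DataFrame
    quant_matrix: quant.QuantMatrix
    rollup: quant.RollupResult
    razor: dict[str, str]
    proteins: pd.DataFrame
    enrichment_up: pd.DataFrame
    enrichment_down: pd.DataFrame
    replicate_cv: dict[str, float]
    counts: dict[str, int]
    peptide_info: dict[str, tuple[str, float, int, frozenset]] = field(
        default_factory=dict)
    fdr_reports: dict[str, dict] = field(default_factory=dict)

    @property
    def called(self) -> pd.DataFrame:
        return self.proteins[self.proteins["called"]]


class _BinPrescreen:
    """Per-bin concatenated fragment index for fast candidate shortlisting.

    For one scan, counts each candidate's matched fragments with a single
    sorted-array query over all candidate fragments in the bin; only
    candidates reaching the fragment floor are passed to
    :func:`mudia.ident.match_spectrum` for scoring.
    """

    def __init__(self, candidates: Sequence[PeptideIon],
                 scan_range: tuple[float, float]):
        self.candidates = list(candidates)
        frags, owners = [], []
        for i, ion in enumerate(self.candidates):
            f = ion.fragment_mz_array(*scan_range)
            frags.append(f)
            owners.append(np.full(f.size, i))
        self.frag_mz = np.concatenate(frags) if frags else np.empty(0)
        self.owner = (np.concatenate(owners).astype(int)
                      if owners else np.empty(0, dtype=int))

    def shortlist(self, scan: SpectrumScan, tolerance_ppm: float,
                  min_fragments: int) -> list[PeptideIon]:
        if not len(scan.mz) or not self.frag_mz.size:
            return []
        tol = tolerance_ppm * 1e-6
        lo = np.searchsorted(scan.mz, self.frag_mz * (1 - tol), side="left")
        hi = np.searchsorted(scan.mz, self.frag_mz * (1 + tol), side="right")
        counts = np.bincount(self.owner[hi > lo],
                             minlength=len(self.candidates))
        return [self.candidates[int(i)]
                for i in np.flatnonzero(counts >= min_fragments)]


def _identify_run(
    binned: xic.BinnedRun,
    demux_scans: Sequence[SpectrumScan],
    prescreens: Mapping[int, _BinPrescreen],
    run_id: str,
    tolerance_ppm: float,
    scan_range: tuple[float, float],
) -> list[ident.PSM]:
    psms: list[ident.PSM] = []
    for idx, scan in enumerate(demux_scans):
        if scan.bin_index is None or scan.n_peaks < ident.MIN_MATCHED_FRAGMENTS:
            continue
        screen = prescreens.get(scan.bin_index)
        if screen is None:
            continue
        shortlist = screen.shortlist(scan, tolerance_ppm,
                                     ident.MIN_MATCHED_FRAGMENTS)
        if not shortlist:
            continue
        psms.extend(ident.match_spectrum(
            scan, shortlist, tolerance_ppm=tolerance_ppm,
            scan_range=scan_range, scan_ref=(run_id, idx),
            n_candidates=len(screen.candidates)))
    return psms


def run_discovery(
    truth: synthdata.GroundTruth,
    config: synthdata.SimConfig,
    conditions: Sequence[str] = ("A", "B"),
    search_space: ident.SearchSpace | None = None,
    runs: Mapping[str, Sequence[SpectrumScan]] | None = None,
    demux_tolerance_ppm: float = 15.0,
    search_tolerance_ppm: float = 10.0,
    xic_tolerance_ppm: float = 15.0,
) -> DiscoveryResult:
    """Run the full discovery pipeline on simulated or supplied DIA runs.

    ``runs`` may pre-supply raw scans per sample name (e.g. loaded from
    mzML); otherwise each run is simulated from ``truth``/``config``.
    Sample names are ``A1..An, B1..Bn`` in design order.
    """
    scheme = config.scheme()
    sample_names, design, run_keys = [], [], []
    for cond in conditions:
        for rep in range(config.n_replicates_per_condition):
            sample_names.append(f"{cond}{rep + 1}")
            design.append(cond)
            run_keys.append((cond, rep))

    if search_space is None:
        search_space = ident.build_search_space(truth.proteins)
    by_bin = search_space.ions_by_bin(scheme)
    prescreens = {
        b: _BinPrescreen(cands, config.ms2_range)
        for b, cands in by_bin.items()
    }

    binned_runs: dict[str, xic.BinnedRun] = {}
    identifications: dict[str, dict[str, float]] = {}
    ion_objects: dict[str, PeptideIon] = {}
    fdr_reports: dict[str, dict] = {}
    for name, (cond, rep) in zip(sample_names, run_keys):
        scans = (runs[name] if runs is not None
                 else synthdata.simulate_dia_run(truth, config, cond, rep))
        demux = demultiplex_run(scans, scheme, demux_tolerance_ppm)
        binned = xic.BinnedRun(demux, scheme, run_id=name)
        binned_runs[name] = binned
        psms = _identify_run(binned, demux, prescreens, name,
                             search_tolerance_ppm, config.ms2_range)
        pep_retained, pep_report = ident.fdr_filter(psms, "peptide")
        prot_retained, prot_report = ident.fdr_filter(pep_retained, "protein")
        fdr_reports[name] = {"peptide": pep_report, "protein": prot_report}
        ids: dict[str, float] = {}
        ids_e: dict[str, float] = {}
        for psm in prot_retained:
            cur = ids_e.get(psm.ion_id)
            if cur is None or psm.expectation < cur:
                ids[psm.ion_id] = psm.rt
                ids_e[psm.ion_id] = psm.expectation
                ion_objects[psm.ion_id] = psm.peptide_ion
        identifications[name] = ids
        logger.info("run %s: %d PSMs, %d peptide ions after FDR",
                    name, len(psms), len(ids))

    reference = xic.pick_reference_run(
        {name: len(ids) for name, ids in identifications.items()})

    # Reference RT coordinate per ion: the reference run's RT when
    # identified there, else the RT mapped from the best available run.
    to_ref_models: dict[str, xic.RTModel] = {}
    from_ref_models: dict[str, xic.RTModel] = {}
    ref_ids = identifications[reference]
    for name in sample_names:
        shared = [
            (ref_ids[i], identifications[name][i])
            for i in identifications[name] if i in ref_ids
        ]
        from_ref_models[name] = xic.fit_rt_model(shared)
        to_ref_models[name] = xic.fit_rt_model([(b, a) for a, b in shared])

    run_order = sorted(sample_names,
                       key=lambda n: -len(identifications[n]))
    reference_rt: dict[str, float] = dict(ref_ids)
    for name in run_order:
        for ion_id, rt in identifications[name].items():
            if ion_id not in reference_rt:
                reference_rt[ion_id] = float(to_ref_models[name].predict(rt))

    per_run_obs: dict[str, dict[str, tuple[float, float]]] = {}
    provenance_rows: dict[str, dict[str, str]] = {}
    for name in sample_names:
        binned = binned_runs[name]
        obs: dict[str, tuple[float, float]] = {}
        prov: dict[str, str] = {}
        for ion_id, ref_rt in reference_rt.items():
            ion = ion_objects[ion_id]
            if ion_id in identifications[name]:
                chrom = xic.extract_ms2_chromatogram(
                    ion, binned, rt_center=identifications[name][ion_id],
                    tolerance_ppm=xic_tolerance_ppm)
            else:
                chrom = xic.transfer_ids(
                    ion, binned, from_ref_models[name], ref_rt,
                    tolerance_ppm=xic_tolerance_ppm)
            if chrom is not None:
                obs[ion_id] = (chrom.apex_rt, chrom.summed_intensity)
                prov[ion_id] = chrom.source
        per_run_obs[name] = obs
        provenance_rows[name] = prov

    normalized = xic.normalize_intensities_local(per_run_obs, reference)

    ion_ids = sorted(reference_rt)
    raw_df = pd.DataFrame(
        {name: [per_run_obs[name].get(i, (0, 0.0))[1] for i in ion_ids]
         for name in sample_names}, index=ion_ids)
    norm_df = pd.DataFrame(
        {name: [normalized[name].get(i, 0.0) for i in ion_ids]
         for name in sample_names}, index=ion_ids)
    prov_df = pd.DataFrame(
        {name: [provenance_rows[name].get(i, "") for i in ion_ids]
         for name in sample_names}, index=ion_ids)

    qm = quant.build_quant_matrix(norm_df, prov_df)

    sequences = {i: ion_objects[i].sequence for i in qm.values.index}
    coverage = ident.compute_coverage(
        sequences.values(), search_space.protein_sequences,
        search_space.peptide_parents)
    seq_razor = ident.assign_razor(
        {s: search_space.peptide_parents[s] for s in set(sequences.values())},
        coverage)
    razor = {ion_id: seq_razor[seq] for ion_id, seq in sequences.items()}

    rollup = quant.rollup_proteins(qm, razor)
    proteins = quant.test_differential(rollup, design)
    gene_of = truth.gene_of
    proteins["gene"] = [gene_of.get(a, a) for a in proteins.index]

    annotation = enrich_mod.AnnotationTable.from_memberships(
        truth.pathway_membership, proteins["gene"])
    called = proteins[proteins["called"]]
    up_genes = called.loc[called["log2_fold_change"] > 0, "gene"]
    down_genes = called.loc[called["log2_fold_change"] < 0, "gene"]
    enrichment_up = enrich_mod.enrich_pathways(up_genes, annotation)
    enrichment_down = enrich_mod.enrich_pathways(down_genes, annotation)

    replicate_cv = {}
    for cond in conditions:
        cols = [n for n, d in zip(sample_names, design) if d == cond]
        block = norm_df[cols].to_numpy()
        full = block[(block > 0).all(axis=1)]
        if len(full):
            cvs = full.std(axis=1, ddof=1) / full.mean(axis=1)
            replicate_cv[cond] = float(cvs.mean() * 100)
        else:
            replicate_cv[cond] = float("nan")

    peptide_info = {
        ion_id: (ion.sequence, ion.precursor_mz, ion.charge,
                 ion.parent_accessions)
        for ion_id, ion in ion_objects.items()
    }
    counts = {
        "n_peptide_ions_quantified": int(len(qm.values)),
        "n_proteins_quantified": int(len(proteins)),
        "n_differential": int(proteins["called"].sum()),
        "n_identified_union": len(reference_rt),
    }
    return DiscoveryResult(
        scheme=scheme, sample_names=sample_names, design=design,
        identifications=identifications, reference_run=reference,
        rt_models=from_ref_models, raw_intensity=raw_df,
        normalized_intensity=norm_df, provenance=prov_df, quant_matrix=qm,
        rollup=rollup, razor=razor, proteins=proteins,
        enrichment_up=enrichment_up, enrichment_down=enrichment_down,
        replicate_cv=replicate_cv, counts=counts,
        peptide_info=peptide_info, fdr_reports=fdr_reports)


def run_prm_verification(
    truth: synthdata.GroundTruth,
    config: synthdata.SimConfig,
    discovery: DiscoveryResult,
    target_proteins: Sequence[str],
    catalog: Mapping[str, Sequence[tuple[str, float, int]]] | None = None,
    shared_allowlist: Mapping[str, str] | None = None,
    conditions: Sequence[str] = ("A", "B"),
) -> tuple[pd.DataFrame, list[prm.InclusionList], dict]:
    """Design inclusion lists from discovery output and run the PRM arm.

    Each inclusion list is acquired as its own run per sample (matching a
    two-list PRM design), quantified against its own run TIC, and tested
    per protein; since a protein's peptides never straddle lists, results
    from the two lists concatenate cleanly.
    """
    mean_intensity = {
        ion_id: float(vals[vals > 0].mean())
        for ion_id, vals in discovery.normalized_intensity.iterrows()
        if (vals > 0).any()
    }
    lists, report = prm.build_inclusion_lists(
        mean_intensity, discovery.peptide_info, target_proteins,
        catalog=catalog, shared_allowlist=shared_allowlist)

    results = []
    for ilist in lists:
        if not len(ilist):
            continue
        table: dict[str, dict[str, float]] = {}
        tics: dict[str, float] = {}
        for cond in conditions:
            for rep in range(config.n_replicates_per_condition):
                sample = f"{cond}{rep + 1}"
                scans = synthdata.simulate_prm_run(
                    truth, ilist.target_mz, config, cond, rep,
                    run_tag=ilist.list_index)
                intensities, tic = prm.quantify_prm(scans, ilist)
                table[sample] = intensities
                tics[sample] = tic
        keys = sorted({k for v in table.values() for k in v})
        if not keys:
            continue
        pep_df = pd.DataFrame(
            {s: [table[s].get(k, 0.0) for k in keys]
             for s in discovery.sample_names}, index=keys)
        pep_protein = {
            f"{e.sequence}/{e.charge}": e.accession for e in ilist.entries
        }
        results.append(prm.test_prm(pep_df, tics, pep_protein,
                                    discovery.design))
    combined = (pd.concat(results) if results
                else pd.DataFrame())
    return combined, lists, report
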