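"""Synthetic-benchmark harnesses for pipeline validation.

These routines generate data with known ground truth and measure how well
the pipeline recovers it: realized peptide FDR at the 1% decoy threshold,
planted log2-fold-change recovery and null p-value uniformity through the
quantification stack, and full end-to-end recovery of a planted coherent
pathway. They are used by the test suite and the acceptance script; all
randomness derives from the caller's seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import ident, quant, synthdata
from .acquisition import SpectrumScan, build_window_scheme
from .pipeline import DiscoveryResult, run_discovery
from .synthdata import PLANTED_PATHWAY_ID, SimConfig, generate_proteome

__all__ = [
    "fdr_calibration",
    "foldchange_recovery",
    "end_to_end",
]


def fdr_calibration(
    seed: int,
    n_proteins: int = 80,
    n_true: int = 500,
    noise_peaks: int = 60,
    n_noise_scans: int = 200,
) -> dict:
    """Realized false-match proportion at the <1% peptide-FDR threshold.

    Builds a proteome and its target+reversed-decoy search space, renders
    one demultiplexed-style MS2 scan per true peptide ion (its fragment
    pattern plus uniform noise peaks) plus noise-only scans, identifies
    them, applies the peptide FDR filter, and compares the retained ion
    ids against the planted truth.
    """
    truth = generate_proteome(n_proteins, seed=seed, up_fraction=0.0,
                              down_fraction=0.0, pathway_size=0,
                              n_null_pathways=0)
    scheme = build_window_scheme(436, 900, 8, 12)
    space = ident.build_search_space(truth.proteins)
    by_bin = space.ions_by_bin(scheme)
    rng = np.random.default_rng([seed, 7])
    ms2_range = (140.0, 1500.0)

    true_ids = sorted(truth.base_abundance)
    if len(true_ids) < n_true:
        raise ValueError(
            f"only {len(true_ids)} true peptide ions; need {n_true}")
    chosen = [true_ids[int(i)] for i in
              rng.choice(len(true_ids), size=n_true, replace=False)]

    psms: list[ident.PSM] = []
    scan_idx = 0

    def _match(mz_parts, int_parts, bin_index):
        nonlocal scan_idx
        scan = SpectrumScan(ms_level=2, rt=float(scan_idx),
                            mz=np.concatenate(mz_parts),
                            intensity=np.concatenate(int_parts),
                            bin_index=bin_index)
        cands = by_bin.get(bin_index, [])
        if cands:
            psms.extend(ident.match_spectrum(
                scan, cands, scan_ref=("bench", scan_idx)))
        scan_idx += 1

    for ion_id in chosen:
        pep = truth.peptides[ion_id]
        frag_mz, frag_rel = synthdata._fragment_pattern(pep.ion, ms2_range)
        bin_index = scheme.bin_index_for_mz(pep.ion.precursor_mz)
        if bin_index is None or frag_mz.size == 0:
            continue
        abundance = truth.base_abundance[ion_id]
        _match(
            [frag_mz, rng.uniform(*ms2_range, size=noise_peaks)],
            [frag_rel * abundance,
             rng.lognormal(np.log(abundance * 0.01), 0.5, size=noise_peaks)],
            bin_index)

    for _ in range(n_noise_scans):
        bin_index = int(rng.integers(0, scheme.n_bins))
        _match(
            [rng.uniform(*ms2_range, size=noise_peaks)],
            [rng.lognormal(np.log(1e4), 0.5, size=noise_peaks)],
            bin_index)

    retained, report = ident.fdr_filter(psms, "peptide")
    true_set = set(chosen)
    n_false = sum(1 for p in retained if p.ion_id not in true_set)
    n_retained = len(retained)
    return {
        "n_true": len(chosen),
        "n_retained": n_retained,
        "n_false": n_false,
        "false_match_rate": n_false / n_retained if n_retained else 0.0,
        "recall": sum(1 for p in retained if p.ion_id in true_set) / len(chosen),
        "fdr_report": report,
    }


def foldchange_recovery(
    seed: int,
    n_proteins: int = 200,
    config: SimConfig | None = None,
) -> dict:
    """Planted log2-fold-change recovery through the quantification stack.

    Uses the generator's peptide intensity layer (the identical noise and
    missingness model the spectral simulator applies to apex intensities)
    and runs it through relative scaling, universal-peptide protein
    roll-up, and the unpaired t-test. Reports the median absolute log2
    fold-change error and, for null proteins, a Kolmogorov-Smirnov
    uniformity p-value and the differential call rate -- both restricted
    to proteins quantified from >=2 universal (no-missing) peptides, where
    the mean is untouched by zero imputation.
    """
    config = config or SimConfig()
    truth = generate_proteome(n_proteins, seed=seed)
    table = synthdata.peptide_intensity_table(truth, config)
    table.columns = [f"{c}{r + 1}" for c, r in table.columns]
    design = ["A"] * config.n_replicates_per_condition + \
             ["B"] * config.n_replicates_per_condition

    qm = quant.build_quant_matrix(table)
    razor = {i: truth.peptides[i].accession for i in qm.values.index}
    rollup = quant.rollup_proteins(qm, razor)
    results = quant.test_differential(rollup, design)

    universal_counts = (
        (qm.values > 0).all(axis=1)
        .groupby(pd.Series(razor))
        .sum()
    )
    eligible = universal_counts[universal_counts >= 2].index
    eligible = [a for a in eligible if a in results.index]

    planted = pd.Series(truth.condition_log2fc)
    errors = (results.loc[eligible, "log2_fold_change"]
              - planted.loc[eligible]).abs()
    nulls = [a for a in eligible if planted[a] == 0.0]
    null_p = results.loc[nulls, "p_value"]
    ks = stats.kstest(null_p, "uniform")
    return {
        "n_proteins": len(results),
        "n_eligible": len(eligible),
        "median_abs_log2fc_error": float(errors.median()),
        "n_null": len(nulls),
        "null_ks_pvalue": float(ks.pvalue),
        "null_call_rate": float(results.loc[nulls, "called"].mean()),
        "null_pvalues": null_p.to_numpy(),
    }


def end_to_end(
    seed: int,
    n_proteins: int = 50,
    config: SimConfig | None = None,
) -> tuple[dict, DiscoveryResult]:
    """Full pipeline on simulated DIA runs with a planted coherent pathway.

    Simulates 2 conditions x 4 replicates, runs demultiplexing through
    enrichment, and reports whether the planted pathway is recovered at
    EASE p < 0.01 in the upregulated list, plus dataset-level summaries.
    """
    config = config or SimConfig()
    truth = generate_proteome(
        n_proteins, seed=seed, pathway_size=max(n_proteins // 5, 5),
        pathway_log2fc=1.0, n_null_pathways=5)
    result = run_discovery(truth, config)

    if PLANTED_PATHWAY_ID in result.enrichment_up.index:
        pathway_p = float(result.enrichment_up.loc[PLANTED_PATHWAY_ID, "ease_p"])
    else:
        pathway_p = 1.0

    planted = pd.Series(truth.condition_log2fc)
    genes = result.proteins["gene"]
    est = result.proteins["log2_fold_change"]
    acc_planted = planted.reindex(result.proteins.index).fillna(0.0)
    errors = (est - acc_planted).abs()
    summary = {
        "n_proteins_quantified": result.counts["n_proteins_quantified"],
        "n_peptide_ions_quantified": result.counts["n_peptide_ions_quantified"],
        "n_differential": result.counts["n_differential"],
        "planted_pathway_ease_p": pathway_p,
        "pathway_recovered": pathway_p < 0.01,
        "median_abs_log2fc_error": float(errors.median()),
        "replicate_cv_percent": result.replicate_cv,
    }
    return summary, result
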