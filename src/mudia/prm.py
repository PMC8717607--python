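"""Parallel reaction monitoring: inclusion-list design and targeted quant.

Inclusion lists carry up to 30 precursor masses each (two lists per
sample), with up to three proteotypic peptides per targeted protein chosen
from the discovery data by mean MS2-chromatogram intensity; peptides
shared between proteins are excluded unless explicitly allow-listed, and
shortfalls are filled from a user-supplied external peptide catalog.
Targeted quantification extracts fragment transitions at 20 ppm, applies
the same 70%/+/-20 s co-elution filter and five-scan apex summation as the
discovery arm, requires >=4 surviving transitions with m/z >= 300, sums
peptides per protein, and normalizes to each run's total ion current (TIC)
before log2 transform and an unpaired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import ParameterError, SpectrumScan
from .chem import PeptideIon, theoretical_ions
from .quant import LOG2_FLOOR, signed_fold_change
from .xic import BinnedRun, extract_ms2_chromatogram

logger = logging.getLogger(__name__)

__all__ = [
    "InclusionEntry",
    "InclusionList",
    "build_inclusion_lists",
    "quantify_prm",
    "test_prm",
    "run_tic",
]

MAX_LIST_SIZE = 30
MAX_PEPTIDES_PER_PROTEIN = 3


@dataclass(frozen=True)
class InclusionEntry:
    sequence: str
    precursor_mz: float
    charge: int
    accession: str
    origin: str = "discovery"  # or "catalog"


@dataclass
class InclusionList:
    entries: list[InclusionEntry] = field(default_factory=list)
    list_index: int = 1

    def __post_init__(self) -> None:
        if len(self.entries) > MAX_LIST_SIZE:
            raise ParameterError(
                f"inclusion list holds at most {MAX_LIST_SIZE} entries")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def target_mz(self) -> list[float]:
        return [e.precursor_mz for e in self.entries]


def build_inclusion_lists(
    discovery_intensity: Mapping[str, float],
    peptide_info: Mapping[str, tuple[str, float, int, frozenset[str]]],
    target_proteins: Sequence[str],
    catalog: Mapping[str, Sequence[tuple[str, float, int]]] | None = None,
    shared_allowlist: Mapping[str, str] | None = None,
) -> tuple[list[InclusionList], dict]:
    """Design two PRM inclusion lists from discovery quantification.

    ``discovery_intensity`` maps ion id -> mean discovery chromatogram
    intensity; ``peptide_info`` maps ion id -> (sequence, precursor m/z,
    charge, parent accessions). Per target protein the three most intense
    unique peptides are chosen; a peptide shared between proteins is
    skipped unless ``shared_allowlist`` maps its sequence to this target.
    Proteins with fewer than three usable discovery peptides are topped up
    from ``catalog`` (accession -> [(sequence, precursor m/z, charge)]);
    proteins with no usable peptide at all are reported as undesignable.
    """
    shared_allowlist = shared_allowlist or {}
    catalog = catalog or {}

    per_protein: dict[str, list[InclusionEntry]] = {}
    undesignable: list[str] = []
    for acc in target_proteins:
        candidates = []
        for ion_id, intensity in discovery_intensity.items():
            seq, mz, charge, parents = peptide_info[ion_id]
            if acc not in parents:
                continue
            unique = len(parents) == 1
            allowed = shared_allowlist.get(seq) == acc
            if not (unique or allowed):
                continue
            candidates.append((-intensity, seq, mz, charge))
        candidates.sort()
        chosen = [
            InclusionEntry(seq, mz, charge, acc)
            for _neg, seq, mz, charge in candidates[:MAX_PEPTIDES_PER_PROTEIN]
        ]
        have = {e.sequence for e in chosen}
        for seq, mz, charge in catalog.get(acc, []):
            if len(chosen) >= MAX_PEPTIDES_PER_PROTEIN:
                break
            if seq not in have:
                chosen.append(InclusionEntry(seq, mz, charge, acc, "catalog"))
                have.add(seq)
        if chosen:
            per_protein[acc] = chosen
        else:
            undesignable.append(acc)
            logger.warning("no unique or catalog peptide for %s", acc)

    total = sum(len(v) for v in per_protein.values())
    if total > 2 * MAX_LIST_SIZE:
        raise ParameterError(
            f"{total} targets exceed two {MAX_LIST_SIZE}-entry lists")

    lists = [InclusionList(list_index=1), InclusionList(list_index=2)]
    current = 0
    for acc in target_proteins:
        group = per_protein.get(acc, [])
        if not group:
            continue
        if len(lists[current].entries) + len(group) > MAX_LIST_SIZE:
            current += 1
        lists[current].entries.extend(group)
    report = {
        "n_targets": total,
        "per_protein": {a: len(v) for a, v in per_protein.items()},
        "undesignable": undesignable,
    }
    return lists, report


def run_tic(scans: Sequence[SpectrumScan]) -> float:
    """Total ion current: the sum of every peak intensity in the run."""
    return float(sum(s.intensity.sum() for s in scans))


class _PRMTargetRun(BinnedRun):
    """Scans of one PRM run grouped by inclusion-list target (bin = index)."""

    def __init__(self, scans: Sequence[SpectrumScan],
                 targets: Sequence[float], run_id: object = None):
        self.run_id = run_id
        self._targets = list(targets)
        self._bins = {}
        by_target: dict[int, list[SpectrumScan]] = {}
        for s in scans:
            if s.ms_level != 2 or s.window is None:
                continue
            for k, t in enumerate(self._targets):
                if abs(s.window[0] - t) < 1e-6:
                    by_target.setdefault(k, []).append(s)
                    break
        for k, bscans in by_target.items():
            bscans.sort(key=lambda s: s.rt)
            mz = np.concatenate([s.mz for s in bscans])
            inten = np.concatenate([s.intensity for s in bscans])
            scan_idx = np.concatenate([
                np.full(s.n_peaks, i) for i, s in enumerate(bscans)
            ]).astype(int)
            order = np.argsort(mz, kind="stable")
            self._bins[k] = {
                "rts": np.array([s.rt for s in bscans]),
                "mz": mz[order],
                "intensity": inten[order],
                "scan_idx": scan_idx[order],
            }

    def bin_for_ion(self, ion: PeptideIon) -> int | None:
        for k, t in enumerate(self._targets):
            if abs(ion.precursor_mz - t) <= 0.8:
                return k
        return None


def quantify_prm(
    scans: Sequence[SpectrumScan],
    inclusion_list: InclusionList,
    tolerance_ppm: float = 20.0,
    min_candidate_transitions: int = 6,
    min_quant_transitions: int = 4,
    min_transition_mz: float = 300.0,
) -> tuple[dict[str, float], float]:
    """Quantify one PRM run against its inclusion list.

    Per target, candidate transitions are the theoretical b2-b15/y2-y15
    ions at +1/+2; a target with fewer than ``min_candidate_transitions``
    detectable transitions is not quantified. Surviving transitions (the
    70%/+/-20 s co-elution rule around the apex over the full gradient,
    since PRM has no RT scheduling) must include at least
    ``min_quant_transitions`` with m/z >= ``min_transition_mz``, and the
    reported intensity is the five-scan apex sum over those. Returns
    (ion intensities keyed by "sequence/charge", run TIC); targets never
    observed are missing from the mapping (treated as 0 downstream).
    """
    target_run = _PRMTargetRun(scans, inclusion_list.target_mz)
    tic = run_tic(scans)
    out: dict[str, float] = {}
    for entry in inclusion_list.entries:
        ion = theoretical_ions(entry.sequence,
                               precursor_charges=(entry.charge,))[0]
        key = f"{entry.sequence}/{entry.charge}"
        bin_index = target_run.bin_for_ion(ion)
        if bin_index is None:
            continue
        all_frag = ion.fragment_mz_array()
        traces, rts = target_run.traces(bin_index, all_frag, tolerance_ppm)
        if rts.size == 0:
            continue
        n_detectable = int((traces.max(axis=1) > 0).sum())
        if n_detectable < min_candidate_transitions:
            continue
        chrom = extract_ms2_chromatogram(
            ion, target_run, rt_center=None,
            tolerance_ppm=tolerance_ppm,
            min_fragment_mz=min_transition_mz,
            min_fragments=min_quant_transitions)
        if chrom is None:
            continue
        out[key] = chrom.summed_intensity
    return out, tic


def test_prm(
    peptide_intensities: pd.DataFrame,
    tics: Mapping[str, float],
    peptide_protein: Mapping[str, str],
    design: Sequence[str],
    equal_var: bool = True,
    fc_threshold: float = 1.3,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Protein-level PRM statistics across samples.

    ``peptide_intensities`` is peptides x samples (raw five-scan sums, 0 =
    missing); ``tics`` maps sample -> run TIC. Peptide intensities are
    summed per protein (restricted to peptides quantified in all samples
    when more than one is available), divided by the sample TIC, placed on
    the relative scale (smallest nonzero = 1, zeros stay 0 with a log2
    floor of -1), and compared B versus A with an unpaired t-test. A
    protein detected in only one condition is reported with status
    ``only_in_A``/``only_in_B`` and no p-value.
    """
    design = list(design)
    if len(design) != peptide_intensities.shape[1]:
        raise ParameterError("design length must match sample count")
    samples = list(peptide_intensities.columns)
    tic_vec = np.array([tics[s] for s in samples], dtype=float)
    if (tic_vec <= 0).any():
        raise ParameterError("all run TICs must be positive")

    groups: dict[str, list[str]] = {}
    for pep in peptide_intensities.index:
        groups.setdefault(peptide_protein[pep], []).append(pep)

    a_cols = [i for i, d in enumerate(design) if d == "A"]
    b_cols = [i for i, d in enumerate(design) if d == "B"]
    records = []
    for acc in sorted(groups):
        block = peptide_intensities.loc[groups[acc]].to_numpy(dtype=float)
        if not (block > 0).any():
            logger.info("protein %s absent from all samples; omitted", acc)
            continue
        use = block
        if len(block) > 1:
            universal = block[(block > 0).all(axis=1)]
            if len(universal) >= 1:
                use = universal
        raw = use.sum(axis=0)
        normalized = raw / tic_vec
        nonzero = normalized[normalized > 0]
        relative = np.where(normalized > 0, normalized / nonzero.min(), 0.0)
        log2_vals = np.where(relative > 0, np.log2(np.maximum(relative, 1e-300)),
                             LOG2_FLOOR)
        only_a = (raw[b_cols] == 0).all() and (raw[a_cols] > 0).any()
        only_b = (raw[a_cols] == 0).all() and (raw[b_cols] > 0).any()
        rec = {
            "accession": acc,
            "n_peptides_used": len(use),
            "mean_normalized_a": float(normalized[a_cols].mean()),
            "mean_normalized_b": float(normalized[b_cols].mean()),
        }
        if only_a or only_b:
            rec.update({
                "status": "only_in_A" if only_a else "only_in_B",
                "log2_fold_change": np.nan,
                "fold_change_signed": np.nan,
                "p_value": np.nan,
                "called": False,
            })
        else:
            a, b = log2_vals[a_cols], log2_vals[b_cols]
            log2fc = float(b.mean() - a.mean())
            if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(stats.ttest_ind(b, a, equal_var=equal_var).pvalue)
            fc = 2.0 ** log2fc
            rec.update({
                "status": "quantified",
                "log2_fold_change": log2fc,
                "fold_change_signed": signed_fold_change(log2fc),
                "p_value": p,
                "called": bool((fc >= fc_threshold or fc <= 1 / fc_threshold)
                               and p <= p_threshold),
            })
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("accession")
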