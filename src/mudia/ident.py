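"""Peptide-centric identification with target-decoy FDR control.

Candidate peptide ions (targets plus whole-protein-reversal decoys) are
matched against demultiplexed MS2 scans. A peptide-spectrum match needs at
least seven fragment ions within tolerance and an expectation score (a
binomial-tail E-value) of at most 0.05. FDR is controlled per sample at
<1% for peptides (strict) and <=5% for proteins using the decoy ranks, and
shared peptides are assigned to a single razor protein by sequence
coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .acquisition import ParameterError, SpectrumScan
from .chem import InputError, PeptideIon, digest, theoretical_ions

logger = logging.getLogger(__name__)

__all__ = [
    "DECOY_PREFIX",
    "PSM",
    "SearchSpace",
    "build_search_space",
    "match_spectrum",
    "fdr_filter",
    "compute_coverage",
    "assign_razor",
]

DECOY_PREFIX = "rev_"

MIN_MATCHED_FRAGMENTS = 7
MAX_EXPECTATION = 0.05


@dataclass
class PSM:
    """A retained peptide-spectrum match."""

    peptide_ion: PeptideIon
    scan_ref: tuple  # caller-defined (e.g. (run_id, scan index))
    rt: float
    matched_fragments: int
    expectation: float
    matched_peak_indices: np.ndarray  # indices into the scan's peak list

    @property
    def is_decoy(self) -> bool:
        return self.peptide_ion.is_decoy

    @property
    def ion_id(self) -> str:
        return self.peptide_ion.ion_id


@dataclass
class SearchSpace:
    """Target + decoy peptide ions with parent-protein bookkeeping."""

    ions: list[PeptideIon]
    peptide_parents: dict[str, frozenset[str]]  # target sequence -> accessions
    protein_sequences: dict[str, str]           # target accession -> sequence
    n_decoy_collisions: int = 0

    def ions_by_bin(self, scheme) -> dict[int, list[PeptideIon]]:
        """Group ions by the effective precursor bin holding their m/z."""
        out: dict[int, list[PeptideIon]] = {}
        for ion in self.ions:
            b = scheme.bin_index_for_mz(ion.precursor_mz)
            if b is not None:
                out.setdefault(b, []).append(ion)
        return out


def _read_fasta(path: str) -> list[tuple[str, str]]:
    from pyteomics import fasta

    entries = []
    for header, seq in fasta.read(path):
        acc = header.split()[0]
        # UniProt-style db|ACC|NAME headers
        if acc.count("|") == 2:
            acc = acc.split("|")[1]
        entries.append((acc, seq))
    return entries


def _peptide_variants(
    pep: str, start: int, protein_seq: str
) -> list[tuple[tuple[int, str], ...]]:
    """Modification variants of a tryptic peptide (at most one variable mod).

    Fixed carbamidomethyl-C is applied implicitly by the mass code. The
    variable set comprises Met oxidation (each site separately), protein
    N-terminal acetylation, N-terminal-Met-cleavage acetylation (the peptide
    starting at residue 2 of an M-initiated protein), and pyro-glu of an
    N-terminal Gln/Glu.
    """
    variants: list[tuple[tuple[int, str], ...]] = [()]
    for i, aa in enumerate(pep):
        if aa == "M":
            variants.append(((i, "oxidation"),))
    if start == 1 or (start == 2 and protein_seq.startswith("M")):
        variants.append(((0, "acetyl"),))
    if pep[0] == "Q":
        variants.append(((0, "pyro-glu-Q"),))
    elif pep[0] == "E":
        variants.append(((0, "pyro-glu-E"),))
    return variants


def build_search_space(
    fasta: str | Sequence,
    max_missed_cleavages: int = 1,
    peptide_length_range: tuple[int, int] = (6, 30),
    precursor_charges: tuple[int, ...] = (2, 3),
) -> SearchSpace:
    """Tryptic target + reversed-decoy peptide-ion search space.

    ``fasta`` is a FASTA path or an iterable of ``(accession, sequence)``
    pairs / objects with those attributes. Decoys are whole-protein sequence
    reversals with accessions prefixed ``rev_``; a decoy peptide whose
    sequence collides with any target peptide is excluded (counted in
    ``n_decoy_collisions``).
    """
    if isinstance(fasta, str):
        entries = _read_fasta(fasta)
    else:
        entries = [
            (getattr(p, "accession", None) or p[0],
             getattr(p, "sequence", None) or p[1])
            for p in fasta
        ]
    if not entries:
        raise InputError("empty protein database")

    lo, hi = peptide_length_range
    target_parents: dict[str, set[str]] = {}
    target_start: dict[str, int] = {}
    protein_sequences = dict(entries)
    for acc, seq in entries:
        for pep, start, _end in digest(seq, max_missed_cleavages,
                                       min_length=lo, max_length=hi):
            target_parents.setdefault(pep, set()).add(acc)
            target_start.setdefault(pep, start)

    decoy_parents: dict[str, set[str]] = {}
    decoy_start: dict[str, int] = {}
    n_collisions = 0
    for acc, seq in entries:
        rseq = seq[::-1]
        for pep, start, _end in digest(rseq, max_missed_cleavages,
                                       min_length=lo, max_length=hi):
            if pep in target_parents:
                n_collisions += 1
                continue
            decoy_parents.setdefault(pep, set()).add(DECOY_PREFIX + acc)
            decoy_start.setdefault(pep, start)

    ions: list[PeptideIon] = []
    for parents_map, starts, is_decoy, seqs in (
        (target_parents, target_start, False, protein_sequences),
        (decoy_parents, decoy_start, True,
         {DECOY_PREFIX + a: s[::-1] for a, s in entries}),
    ):
        for pep in sorted(parents_map):
            parents = parents_map[pep]
            any_parent = sorted(parents)[0]
            prot_seq = seqs[any_parent if not is_decoy else any_parent]
            for mods in _peptide_variants(pep, starts[pep], prot_seq):
                ions.extend(theoretical_ions(
                    pep, mods, precursor_charges=precursor_charges,
                    parent_accessions=parents, is_decoy=is_decoy))
    return SearchSpace(
        ions=ions,
        peptide_parents={p: frozenset(a) for p, a in target_parents.items()},
        protein_sequences=protein_sequences,
        n_decoy_collisions=n_collisions,
    )


def match_spectrum(
    scan: SpectrumScan,
    candidates: Sequence[PeptideIon],
    tolerance_ppm: float = 10.0,
    scan_range: tuple[float, float] = (140.0, 1500.0),
    scan_ref: tuple = (),
    min_fragments: int = MIN_MATCHED_FRAGMENTS,
    max_expectation: float = MAX_EXPECTATION,
    dedup_min_mz: float = 300.0,
    n_candidates: int | None = None,
) -> list[PSM]:
    """Score candidate peptide ions against one demultiplexed MS2 scan.

    The expectation score is ``E = N_candidates * P(X >= k)`` with
    ``X ~ Binomial(n_theoretical, p_random)`` where ``p_random`` is the
    chance a random scan peak lands in one fragment's tolerance window.
    Retained PSMs need ``k >= min_fragments`` and ``E <= max_expectation``;
    among retained PSMs sharing a matched fragment peak with m/z >=
    ``dedup_min_mz``, only the smallest-E match survives (ties broken by
    peptide sequence). ``n_candidates`` overrides the multiple-testing
    factor when ``candidates`` is a prescreened subset of a larger pool.
    """
    mz = scan.mz
    n_peaks = len(mz)
    if n_peaks == 0 or not candidates:
        return []
    tol = tolerance_ppm * 1e-6
    span = scan_range[1] - scan_range[0]
    n_cand = len(candidates) if n_candidates is None else n_candidates
    psms: list[PSM] = []
    for ion in candidates:
        frag = ion.fragment_mz_array(*scan_range)
        if frag.size < min_fragments:
            continue
        lo = np.searchsorted(mz, frag * (1 - tol), side="left")
        hi = np.searchsorted(mz, frag * (1 + tol), side="right")
        matched = hi > lo
        k = int(matched.sum())
        if k < min_fragments:
            continue
        p_random = min(n_peaks * 2 * tol * float(frag.mean()) / span, 1.0)
        expectation = n_cand * float(
            stats.binom.sf(k - 1, frag.size, p_random))
        if expectation > max_expectation:
            continue
        peak_idx = np.unique(np.concatenate(
            [np.arange(lo[i], hi[i]) for i in np.flatnonzero(matched)]))
        psms.append(PSM(
            peptide_ion=ion, scan_ref=scan_ref, rt=scan.rt,
            matched_fragments=k, expectation=expectation,
            matched_peak_indices=peak_idx))
    return deduplicate_scan_psms(psms, scan, dedup_min_mz)


def deduplicate_scan_psms(
    psms: list[PSM], scan: SpectrumScan, dedup_min_mz: float = 300.0
) -> list[PSM]:
    """Keep one peptide ion per set of shared matched fragments (>= min m/z)."""
    psms = sorted(psms, key=lambda p: (p.expectation, p.peptide_ion.sequence,
                                       p.ion_id))
    claimed: set[int] = set()
    kept: list[PSM] = []
    for psm in psms:
        high = [int(i) for i in psm.matched_peak_indices
                if scan.mz[i] >= dedup_min_mz]
        if any(i in claimed for i in high):
            continue
        claimed.update(high)
        kept.append(psm)
    return kept


def fdr_filter(
    psms: Iterable[PSM],
    level: str = "peptide",
    threshold: float | None = None,
) -> tuple[list[PSM], dict]:
    """Target-decoy FDR filtering at the peptide or protein level.

    Peptide level keeps the best (smallest-E) PSM per peptide ion and
    retains the largest E-ranked prefix whose decoy/target ratio is
    strictly below 1%. Protein level ranks proteins by their best peptide
    E-value and uses a <=5% ratio. Decoy entries are removed from the
    returned list.
    """
    psms = list(psms)
    if level == "peptide":
        thr = 0.01 if threshold is None else threshold
        strict = True
        best: dict[str, PSM] = {}
        for p in psms:
            cur = best.get(p.ion_id)
            if cur is None or p.expectation < cur.expectation:
                best[p.ion_id] = p
        entries = [(p.expectation, p.is_decoy, p) for p in best.values()]
    elif level == "protein":
        thr = 0.05 if threshold is None else threshold
        strict = False
        best_prot: dict[str, PSM] = {}
        for p in psms:
            for acc in p.peptide_ion.parent_accessions:
                cur = best_prot.get(acc)
                if cur is None or p.expectation < cur.expectation:
                    best_prot[acc] = p
        entries = [(p.expectation, acc.startswith(DECOY_PREFIX), (acc, p))
                   for acc, p in best_prot.items()]
    else:
        raise ParameterError(f"unknown FDR level {level!r}")

    entries.sort(key=lambda e: e[0])
    n_decoy = n_target = 0
    cutoff_rank = 0
    cutoff_e = 0.0
    for rank, (e, is_decoy, _payload) in enumerate(entries, start=1):
        if is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        ratio = n_decoy / max(n_target, 1)
        ok = ratio < thr if strict else ratio <= thr
        if ok:
            cutoff_rank = rank
            cutoff_e = e
    retained_payloads = [
        payload
        for e, is_decoy, payload in entries[:cutoff_rank]
        if not is_decoy
    ]
    report = {
        "level": level,
        "threshold": thr,
        "n_entries": len(entries),
        "cutoff_rank": cutoff_rank,
        "cutoff_expectation": cutoff_e,
        "n_retained": len(retained_payloads),
    }
    if level == "protein":
        accs = {acc for acc, _ in retained_payloads}
        kept = [p for p in psms if not p.is_decoy
                and p.peptide_ion.parent_accessions & accs]
        report["retained_accessions"] = sorted(accs)
        return kept, report
    return retained_payloads, report


def compute_coverage(
    peptides: Iterable[str],
    protein_sequences: Mapping[str, str],
    peptide_parents: Mapping[str, frozenset[str]],
) -> dict[str, float]:
    """Fraction of each protein's residues covered by identified peptides."""
    covered: dict[str, np.ndarray] = {
        acc: np.zeros(len(seq), dtype=bool)
        for acc, seq in protein_sequences.items()
    }
    for pep in set(peptides):
        for acc in peptide_parents.get(pep, ()):  # decoys have no entry
            seq = protein_sequences.get(acc)
            if seq is None:
                continue
            pos = seq.find(pep)
            while pos != -1:
                covered[acc][pos:pos + len(pep)] = True
                pos = seq.find(pep, pos + 1)
    return {acc: float(mask.mean()) for acc, mask in covered.items()}


def assign_razor(
    peptide_parents: Mapping[str, frozenset[str]],
    coverage: Mapping[str, float],
) -> dict[str, str]:
    """Assign each (shared) peptide to the parent with the highest coverage.

    Single pass, no iteration; coverage ties break lexicographically by
    accession. A peptide with an empty parent set is an internal error.
    """
    assignment: dict[str, str] = {}
    for pep, parents in peptide_parents.items():
        if not parents:
            raise RuntimeError(f"peptide {pep} has no parent proteins")
        assignment[pep] = max(
            sorted(parents), key=lambda acc: coverage.get(acc, 0.0))
    return assignment
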