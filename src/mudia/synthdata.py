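"""Synthetic ground-truth proteomes and simulated DIA / PRM acquisitions.

The generator emulates the study design this package targets: two conditions
(A = control, B = affected) with four biological replicates each, DIA cycles
of one MS1 survey scan plus one MS2 scan per overlapped isolation window
(59 windows, 12 m/z wide, stepped by 8 m/z from 436 to 900), lognormal
peptide-level intensity noise targeting ~15% replicate CV, planted protein
fold changes including one pathway-coherent set, stochastic whole-run
peptide missingness, and a PRM mode cycling over a <=30-entry inclusion
list without retention-time scheduling.

Every quantity is reproducible from ``GroundTruth.seed``: identical
(truth, config, seed) inputs produce identical runs.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition import ParameterError, SpectrumScan, WindowScheme, build_window_scheme
from .chem import AA_MONO, PeptideIon, digest, theoretical_ions

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "SimPeptide",
    "GroundTruth",
    "SimConfig",
    "generate_proteome",
    "simulate_dia_run",
    "simulate_prm_run",
    "peptide_intensity_table",
    "write_fasta",
    "write_ground_truth",
]

_AMINO_ACIDS = sorted(AA_MONO)

# Default MS1 / MS2 scan ranges (m/z) of the emulated instrument method.
MS1_RANGE = (430.0, 915.0)
MS2_RANGE = (140.0, 1500.0)

PLANTED_PATHWAY_ID = "PW_PLANTED"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    gene: str
    sequence: str


@dataclass(frozen=True)
class SimPeptide:
    """A detectable peptide ion with its simulation metadata."""

    ion: PeptideIon
    accession: str
    gene: str
    rt_fraction: float  # stable position along the gradient, in (0, 1)


@dataclass
class GroundTruth:
    """Planted truth for a simulated two-condition experiment."""

    proteins: list[ProteinRecord]
    condition_log2fc: dict[str, float]
    pathway_membership: dict[str, set[str]]
    base_abundance: dict[str, float]  # ion_id -> expected linear intensity (A)
    seed: int
    peptides: dict[str, SimPeptide] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = {p.accession for p in self.proteins}
        missing = set(self.condition_log2fc) - accs
        if missing:
            raise ParameterError(f"fold changes for unknown accessions: {missing}")
        if any(v <= 0 for v in self.base_abundance.values()):
            raise ParameterError("base_abundance values must be strictly positive")

    @property
    def gene_of(self) -> dict[str, str]:
        return {p.accession: p.gene for p in self.proteins}

    def ion_log2fc(self, ion_id: str) -> float:
        return self.condition_log2fc.get(self.peptides[ion_id].accession, 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and noise parameters for simulated runs.

    Defaults reflect the emulated study design where stated (4 replicates
    per condition, ~15% replicate CV, 59 overlapped windows) and a scaled
    gradient chosen to keep simulated runs small; see docs/methods.md.
    """

    n_replicates_per_condition: int = 4
    replicate_cv: float = 0.15
    missing_rate: float = 0.05
    noise_peaks_per_scan: int = 20
    noise_intensity: float = 1e3
    peak_fwhm: float = 6.0          # seconds
    gradient_length: float = 300.0  # seconds
    cycle_time: float = 3.0         # seconds (DIA duty cycle)
    prm_cycle_time: float = 3.2     # seconds (PRM duty cycle)
    rt_jitter_sd: float = 2.0       # seconds
    window_scheme_params: tuple[float, float, float, float] = (436.0, 900.0, 8.0, 12.0)
    ms1_range: tuple[float, float] = MS1_RANGE
    ms2_range: tuple[float, float] = MS2_RANGE

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise ParameterError("replicate_cv must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.peak_fwhm <= 0:
            raise ParameterError("peak_fwhm must be positive")
        if self.n_replicates_per_condition < 1:
            raise ParameterError("need at least one replicate per condition")

    def scheme(self) -> WindowScheme:
        return build_window_scheme(*self.window_scheme_params)


def _stable_fraction(key: str) -> float:
    """Deterministic uniform-(0,1) value from a string, stable across runs."""
    digest_bytes = hashlib.md5(key.encode()).digest()
    return int.from_bytes(digest_bytes[:8], "big") / 2**64


def _fragment_pattern(ion: PeptideIon, mz_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-fragment m/z and stable relative intensities in [0.2, 1.0]."""
    mz, rel = [], []
    for f in ion.fragments:
        if not mz_range[0] <= f.mz <= mz_range[1]:
            continue
        mz.append(f.mz)
        rel.append(0.2 + 0.8 * _stable_fraction(
            f"{ion.ion_id}|{f.series}{f.index}+{f.charge}"))
    return np.array(mz), np.array(rel)


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (240, 400),
    seed: int = 0,
    up_fraction: float = 0.06,
    down_fraction: float = 0.06,
    up_log2fc: float = 1.0,
    down_log2fc: float = -1.0,
    pathway_size: int = 12,
    pathway_log2fc: float = 0.8,
    n_null_pathways: int = 8,
    null_pathway_size: int = 12,
    max_peptides_per_protein: int = 8,
    precursor_range: tuple[float, float] = (430.0, 906.0),
    peptide_length_range: tuple[int, int] = (6, 30),
    base_log10_mean: float = 6.0,
    base_log10_sd: float = 0.4,
) -> GroundTruth:
    """Random proteome with planted fold changes and one coherent pathway.

    A ``pathway_size`` subset of proteins forms the planted pathway, all at
    ``pathway_log2fc``; of the remainder, fractions ``up_fraction`` /
    ``down_fraction`` receive ``up_log2fc`` / ``down_log2fc`` and the rest
    are null. Detectable peptide ions are fully tryptic 6-30-mers whose +2
    (else +3) precursor m/z falls inside ``precursor_range``; each receives
    a lognormal base abundance and a stable per-sequence retention-time
    position so RT is reproducible across runs.
    """
    if n_proteins < 1:
        raise ParameterError("n_proteins must be >= 1")
    if length_range[0] < 30 or length_range[0] > length_range[1]:
        raise ParameterError("length_range minimum must be >= 30 residues")
    if pathway_size > n_proteins:
        raise ParameterError("pathway_size cannot exceed n_proteins")
    rng = np.random.default_rng(seed)

    proteins: list[ProteinRecord] = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
        proteins.append(ProteinRecord(f"SYNP{i:04d}", f"SYNG{i:04d}", seq))

    order = rng.permutation(n_proteins)
    pathway_accs = [proteins[j].accession for j in order[:pathway_size]]
    rest = list(order[pathway_size:])
    n_up = int(round(up_fraction * n_proteins))
    n_down = int(round(down_fraction * n_proteins))
    if n_up + n_down > len(rest):
        raise ParameterError("regulated fractions exceed available proteins")
    up_accs = [proteins[j].accession for j in rest[:n_up]]
    down_accs = [proteins[j].accession for j in rest[n_up:n_up + n_down]]

    condition_log2fc = {p.accession: 0.0 for p in proteins}
    condition_log2fc.update({a: pathway_log2fc for a in pathway_accs})
    condition_log2fc.update({a: up_log2fc for a in up_accs})
    condition_log2fc.update({a: down_log2fc for a in down_accs})

    gene_of = {p.accession: p.gene for p in proteins}
    pathways: dict[str, set[str]] = {}
    if pathway_size:
        pathways[PLANTED_PATHWAY_ID] = {gene_of[a] for a in pathway_accs}
    genes = [p.gene for p in proteins]
    for k in range(n_null_pathways):
        size = min(null_pathway_size, n_proteins)
        pathways[f"PW_NULL{k:02d}"] = set(rng.choice(genes, size=size, replace=False))

    base_abundance: dict[str, float] = {}
    peptides: dict[str, SimPeptide] = {}
    seen_sequences: set[str] = set()
    for prot in proteins:
        candidates = []
        for pep, _start, _end in digest(prot.sequence, 0,
                                        min_length=peptide_length_range[0],
                                        max_length=peptide_length_range[1]):
            if pep in seen_sequences:
                continue
            ions2, ions3 = theoretical_ions(pep, precursor_charges=(2, 3),
                                            parent_accessions=[prot.accession])
            if precursor_range[0] <= ions2.precursor_mz <= precursor_range[1]:
                candidates.append(ions2)
            elif precursor_range[0] <= ions3.precursor_mz <= precursor_range[1]:
                candidates.append(ions3)
        if len(candidates) > max_peptides_per_protein:
            keep = rng.choice(len(candidates), size=max_peptides_per_protein,
                              replace=False)
            candidates = [candidates[int(j)] for j in sorted(keep)]
        for ion in candidates:
            seen_sequences.add(ion.sequence)
            abundance = float(10 ** rng.normal(base_log10_mean, base_log10_sd))
            base_abundance[ion.ion_id] = abundance
            peptides[ion.ion_id] = SimPeptide(
                ion=ion,
                accession=prot.accession,
                gene=prot.gene,
                rt_fraction=_stable_fraction(ion.sequence),
            )
    return GroundTruth(
        proteins=proteins,
        condition_log2fc=condition_log2fc,
        pathway_membership=pathways,
        base_abundance=base_abundance,
        seed=seed,
        peptides=peptides,
    )


_CONDITION_INDEX = {"A": 0, "B": 1}


def _condition_index(condition: str) -> int:
    try:
        return _CONDITION_INDEX[condition]
    except KeyError:
        raise ParameterError(f"condition must be 'A' or 'B', got {condition!r}")


def _run_peptide_state(
    truth: GroundTruth,
    config: SimConfig,
    condition: str,
    replicate: int,
) -> dict[str, tuple[float, float]]:
    """Per-run peptide state: ion_id -> (apex intensity, retention time).

    Missing peptide-run observations are omitted. The lognormal multiplier
    has unit mean so the expected intensity equals the planted one; the
    draw order (sorted ion ids; one missingness, one intensity, and one
    jitter draw per ion) is fixed for determinism.
    """
    cond = _condition_index(condition)
    rng = np.random.default_rng([truth.seed, 101, cond, replicate])
    sigma = math.sqrt(math.log(1 + config.replicate_cv**2))
    margin = 3 * config.peak_fwhm
    span = max(config.gradient_length - 2 * margin, 0.0)
    state: dict[str, tuple[float, float]] = {}
    for ion_id in sorted(truth.base_abundance):
        u_miss = rng.uniform()
        factor = rng.lognormal(-sigma**2 / 2, sigma) if sigma > 0 else 1.0
        jitter = rng.normal(0, config.rt_jitter_sd) if config.rt_jitter_sd > 0 else 0.0
        if u_miss < config.missing_rate:
            continue
        log2fc = truth.ion_log2fc(ion_id) if condition == "B" else 0.0
        apex = truth.base_abundance[ion_id] * 2.0**log2fc * factor
        rt = margin + truth.peptides[ion_id].rt_fraction * span + jitter
        state[ion_id] = (apex, rt)
    return state


def peptide_intensity_table(
    truth: GroundTruth,
    config: SimConfig,
    conditions: Sequence[str] = ("A", "B"),
) -> pd.DataFrame:
    """Peptide-ion x sample apex-intensity table (0 = missing).

    This is the intensity layer of the spectral simulator: the same
    per-run lognormal/missingness model that sets apex intensities in
    :func:`simulate_dia_run`, without spectral rendering.
    """
    columns = [
        (cond, rep)
        for cond in conditions
        for rep in range(config.n_replicates_per_condition)
    ]
    ion_ids = sorted(truth.base_abundance)
    data = np.zeros((len(ion_ids), len(columns)))
    for j, (cond, rep) in enumerate(columns):
        state = _run_peptide_state(truth, config, cond, rep)
        for i, ion_id in enumerate(ion_ids):
            if ion_id in state:
                data[i, j] = state[ion_id][0]
    return pd.DataFrame(
        data, index=ion_ids,
        columns=pd.MultiIndex.from_tuples(columns, names=["condition", "replicate"]),
    )


def _gaussian_amp(t: float, rt: float, sigma: float) -> float:
    return math.exp(-((t - rt) ** 2) / (2 * sigma**2))


def simulate_dia_run(
    truth: GroundTruth,
    config: SimConfig,
    condition: str,
    replicate: int,
) -> list[SpectrumScan]:
    """Simulate one DIA run as a time-ordered list of centroided scans.

    Each cycle holds one MS1 survey scan plus one MS2 scan per isolation
    window. A peptide ion elutes as a Gaussian of the configured FWHM
    centred on its (jittered) reference RT; its fragments appear in every
    MS2 scan whose isolation window contains the precursor m/z. Peptides
    whose precursor lies outside all windows are silently absent (logged).
    """
    scheme = config.scheme()
    state = _run_peptide_state(truth, config, condition, replicate)
    sigma = config.peak_fwhm / 2.35482
    n_cycles = max(int(round(config.gradient_length / config.cycle_time)), 0)
    dt = config.cycle_time / (scheme.n_windows + 1)

    ms2_contrib: dict[tuple[int, int], list[tuple[np.ndarray, np.ndarray]]] = {}
    ms1_contrib: dict[int, list[tuple[float, float]]] = {}
    n_outside = 0
    for ion_id in sorted(state):
        pep = truth.peptides[ion_id]
        windows = scheme.windows_containing(pep.ion.precursor_mz)
        if not windows:
            n_outside += 1
            continue
        apex, rt = state[ion_id]
        frag_mz, frag_rel = _fragment_pattern(pep.ion, config.ms2_range)
        if frag_mz.size == 0:
            continue
        c_lo = max(0, int((rt - 4 * sigma) / config.cycle_time) - 1)
        c_hi = min(n_cycles - 1, int((rt + 4 * sigma) / config.cycle_time) + 1)
        for cycle in range(c_lo, c_hi + 1):
            t0 = cycle * config.cycle_time
            if config.ms1_range[0] <= pep.ion.precursor_mz <= config.ms1_range[1]:
                amp1 = apex * _gaussian_amp(t0, rt, sigma)
                if amp1 > 1e-6 * apex:
                    ms1_contrib.setdefault(cycle, []).append(
                        (pep.ion.precursor_mz, amp1))
            for w in windows:
                t = t0 + (w + 1) * dt
                amp = apex * _gaussian_amp(t, rt, sigma)
                if amp <= 1e-6 * apex:
                    continue
                ms2_contrib.setdefault((cycle, w), []).append(
                    (frag_mz, frag_rel * amp))
    if n_outside:
        logger.info("%d peptide ions outside all isolation windows", n_outside)

    noise_rng = np.random.default_rng(
        [truth.seed, 202, _condition_index(condition), replicate])
    scans: list[SpectrumScan] = []
    for cycle in range(n_cycles):
        t0 = cycle * config.cycle_time
        peaks = ms1_contrib.get(cycle, [])
        scans.append(SpectrumScan(
            ms_level=1, rt=t0,
            mz=np.array([p[0] for p in peaks]),
            intensity=np.array([p[1] for p in peaks]),
            window=None, cycle_index=cycle))
        for w in range(scheme.n_windows):
            parts = ms2_contrib.get((cycle, w), [])
            mz = [a for a, _ in parts]
            inten = [b for _, b in parts]
            if config.noise_peaks_per_scan > 0:
                n = config.noise_peaks_per_scan
                mz.append(noise_rng.uniform(*config.ms2_range, size=n))
                inten.append(noise_rng.lognormal(
                    math.log(config.noise_intensity), 0.5, size=n))
            mz_arr = np.concatenate(mz) if mz else np.empty(0)
            int_arr = np.concatenate(inten) if inten else np.empty(0)
            scans.append(SpectrumScan(
                ms_level=2, rt=t0 + (w + 1) * dt,
                mz=mz_arr, intensity=int_arr,
                window=(scheme.centers[w], scheme.isolation_width),
                cycle_index=cycle))
    return scans


def simulate_prm_run(
    truth: GroundTruth,
    inclusion_list: Sequence,
    config: SimConfig,
    condition: str,
    replicate: int,
    isolation_width: float = 1.6,
    run_tag: int = 0,
) -> list[SpectrumScan]:
    """Simulate a PRM run cycling over an inclusion list (no RT scheduling).

    ``inclusion_list`` entries are target precursor m/z values (floats) or
    objects with a ``precursor_mz`` attribute, at most 30 per acquisition.
    Every target is sampled once per duty cycle for the whole gradient; a
    target absent from the truth yields noise-only scans.
    """
    targets = [
        float(getattr(e, "precursor_mz", e)) for e in inclusion_list
    ]
    if not 1 <= len(targets) <= 30:
        raise ParameterError("inclusion list must have 1-30 entries")
    state = _run_peptide_state(truth, config, condition, replicate)
    sigma = config.peak_fwhm / 2.35482
    cycle_time = config.prm_cycle_time
    n_cycles = max(int(round(config.gradient_length / cycle_time)), 0)
    dt = cycle_time / len(targets)

    # Precompute eluting ions per target window.
    per_target: list[list[tuple[float, float, np.ndarray, np.ndarray]]] = []
    for target in targets:
        ions = []
        for ion_id in sorted(state):
            pep = truth.peptides[ion_id]
            if abs(pep.ion.precursor_mz - target) <= isolation_width / 2:
                apex, rt = state[ion_id]
                frag_mz, frag_rel = _fragment_pattern(pep.ion, config.ms2_range)
                ions.append((apex, rt, frag_mz, frag_rel))
        per_target.append(ions)

    noise_rng = np.random.default_rng(
        [truth.seed, 303, _condition_index(condition), replicate, run_tag])
    scans: list[SpectrumScan] = []
    for cycle in range(n_cycles):
        for k, target in enumerate(targets):
            t = cycle * cycle_time + k * dt
            mz, inten = [], []
            for apex, rt, frag_mz, frag_rel in per_target[k]:
                amp = apex * _gaussian_amp(t, rt, sigma)
                if amp > 1e-6 * apex:
                    mz.append(frag_mz)
                    inten.append(frag_rel * amp)
            if config.noise_peaks_per_scan > 0:
                n = config.noise_peaks_per_scan
                mz.append(noise_rng.uniform(*config.ms2_range, size=n))
                inten.append(noise_rng.lognormal(
                    math.log(config.noise_intensity), 0.5, size=n))
            scans.append(SpectrumScan(
                ms_level=2, rt=t,
                mz=np.concatenate(mz) if mz else np.empty(0),
                intensity=np.concatenate(inten) if inten else np.empty(0),
                window=(target, isolation_width),
                cycle_index=cycle))
    return scans


def write_fasta(truth: GroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        for p in truth.proteins:
            fh.write(f">{p.accession} GN={p.gene}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    """Planted per-protein truth as TSV (accession, gene, log2fc, pathways)."""
    gene_of = truth.gene_of
    rows = []
    for p in truth.proteins:
        pw = sorted(pid for pid, genes in truth.pathway_membership.items()
                    if p.gene in genes)
        rows.append((p.accession, p.gene,
                     truth.condition_log2fc.get(p.accession, 0.0),
                     ",".join(pw)))
    pd.DataFrame(rows, columns=["accession", "gene", "log2fc", "pathways"]).to_csv(
        path, sep="\t", index=False)
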