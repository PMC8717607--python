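"""Peptide chemistry primitives.

Monoisotopic residue masses, tryptic digestion, and theoretical b/y fragment
ions for peptide-centric DIA/PRM analysis. All masses are monoisotopic, in
daltons, from the standard IUPAC/Unimod tables; m/z values use the proton
mass 1.007276 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AA_MONO",
    "WATER",
    "PROTON",
    "MOD_DELTAS",
    "Fragment",
    "PeptideIon",
    "digest",
    "peptide_mass",
    "precursor_mz",
    "theoretical_ions",
]

# Monoisotopic residue masses for the 20 canonical amino acids (Da).
AA_MONO: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276

# Supported modification mass deltas (Da). Carbamidomethyl-C is fixed in the
# search settings; the rest are variable.
MOD_DELTAS: dict[str, float] = {
    "carbamidomethyl": 57.021464,
    "oxidation": 15.994915,
    "acetyl": 42.010565,
    "pyro-glu-Q": -17.026549,
    "pyro-glu-E": -18.010565,
}

# Fragment series index bounds used throughout: b2-b15 and y2-y15.
FRAGMENT_INDEX_MIN = 2
FRAGMENT_INDEX_MAX = 15


class InputError(ValueError):
    """Raised for malformed sequences or unsupported modifications."""


@dataclass(frozen=True)
class Fragment:
    series: str  # "b" or "y"
    index: int
    charge: int
    mz: float


@dataclass(frozen=True)
class PeptideIon:
    """A modified peptide at a fixed precursor charge with its fragment ions.

    ``modifications`` is a tuple of ``(position, name)`` pairs with 0-based
    residue positions; N-terminal modifications sit at position 0.
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...]
    charge: int
    precursor_mz: float
    fragments: tuple[Fragment, ...]
    parent_accessions: frozenset[str] = field(default_factory=frozenset)
    is_decoy: bool = False

    @property
    def ion_id(self) -> str:
        mods = ";".join(f"{pos}:{name}" for pos, name in self.modifications
                        if name != "carbamidomethyl")
        return f"{self.sequence}[{mods}]/{self.charge}"

    def fragment_mz_array(self, min_mz: float = 0.0,
                          max_mz: float = np.inf) -> np.ndarray:
        mz = np.array([f.mz for f in self.fragments])
        return mz[(mz >= min_mz) & (mz <= max_mz)]


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise InputError("empty peptide/protein sequence")
    bad = set(sequence) - set(AA_MONO)
    if bad:
        raise InputError(f"non-canonical residues in sequence: {sorted(bad)}")


def digest(
    sequence: str,
    max_missed_cleavages: int = 1,
    min_length: int | None = None,
    max_length: int | None = None,
) -> list[tuple[str, int, int]]:
    """Tryptic digest of ``sequence`` (cleave C-terminal to K/R, not before P).

    Returns ``(peptide, start, end)`` tuples with 1-based inclusive positions,
    covering 0..``max_missed_cleavages`` internal missed cleavages. Optional
    length bounds restrict the returned peptides (used when constructing a
    finite search space).
    """
    _check_sequence(sequence)
    if max_missed_cleavages < 0:
        raise InputError("max_missed_cleavages must be >= 0")

    # Cleavage sites: index i such that the bond after residue i is cut.
    sites = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(sequence)]  # exclusive

    peptides: list[tuple[str, int, int]] = []
    for i, start in enumerate(starts):
        for missed in range(max_missed_cleavages + 1):
            j = i + missed
            if j >= len(ends):
                break
            end = ends[j]
            pep = sequence[start:end]
            if min_length is not None and len(pep) < min_length:
                continue
            if max_length is not None and len(pep) > max_length:
                continue
            peptides.append((pep, start + 1, end))
    return peptides


def _residue_masses(
    sequence: str,
    modifications: Sequence[tuple[int, str]],
    fixed_carbamidomethyl: bool = True,
) -> np.ndarray:
    _check_sequence(sequence)
    masses = np.array([AA_MONO[a] for a in sequence])
    if fixed_carbamidomethyl:
        for i, a in enumerate(sequence):
            if a == "C":
                masses[i] += MOD_DELTAS["carbamidomethyl"]
    for pos, name in modifications:
        if name == "carbamidomethyl":
            continue  # already applied as fixed
        if name not in MOD_DELTAS:
            raise InputError(f"unsupported modification: {name!r}")
        if not 0 <= pos < len(sequence):
            raise InputError(f"modification site {pos} outside peptide")
        masses[pos] += MOD_DELTAS[name]
    return masses


def peptide_mass(
    sequence: str,
    modifications: Sequence[tuple[int, str]] = (),
    fixed_carbamidomethyl: bool = True,
) -> float:
    """Neutral monoisotopic mass of a (modified) peptide."""
    return float(_residue_masses(sequence, modifications,
                                 fixed_carbamidomethyl).sum() + WATER)


def precursor_mz(neutral_mass: float, charge: int) -> float:
    return (neutral_mass + charge * PROTON) / charge


def theoretical_ions(
    peptide: str,
    modifications: Sequence[tuple[int, str]] = (),
    precursor_charges: Iterable[int] = (2, 3),
    fragment_charges: Iterable[int] = (1, 2),
    parent_accessions: Iterable[str] = (),
    is_decoy: bool = False,
    fixed_carbamidomethyl: bool = True,
) -> list[PeptideIon]:
    """Build :class:`PeptideIon` objects for each precursor charge state.

    Fragments cover the b2-b15 and y2-y15 series (bounded by peptide length)
    at the requested fragment charges. Modification deltas are applied at
    their stated sites; the N-terminal delta (acetyl, pyro-glu) therefore
    shifts every b ion and the full-length y ion only.
    """
    if len(peptide) < 2:
        raise InputError("peptide must have length >= 2")
    masses = _residue_masses(peptide, modifications, fixed_carbamidomethyl)
    n = len(peptide)
    prefix = np.cumsum(masses)            # b_i neutral = prefix[i-1]
    suffix = np.cumsum(masses[::-1])      # y_i neutral = suffix[i-1] + WATER
    neutral = float(prefix[-1] + WATER)

    # b ions run to b_{n-1}; y ions to y_n (a 2-mer still has its y2).
    b_idx = range(FRAGMENT_INDEX_MIN, min(FRAGMENT_INDEX_MAX, n - 1) + 1)
    y_idx = range(FRAGMENT_INDEX_MIN, min(FRAGMENT_INDEX_MAX, n) + 1)
    fragments: list[Fragment] = []
    for z in fragment_charges:
        for i in b_idx:
            fragments.append(
                Fragment("b", i, z, (prefix[i - 1] + z * PROTON) / z))
        for i in y_idx:
            fragments.append(
                Fragment("y", i, z, (suffix[i - 1] + WATER + z * PROTON) / z))
    fragments.sort(key=lambda f: f.mz)

    parents = frozenset(parent_accessions)
    return [
        PeptideIon(
            sequence=peptide,
            modifications=tuple(modifications),
            charge=z,
            precursor_mz=precursor_mz(neutral, z),
            fragments=tuple(fragments),
            parent_accessions=parents,
            is_decoy=is_decoy,
        )
        for z in precursor_charges
    ]
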