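"""Peptide quantification matrix, protein roll-up, and differential tests.

Normalized peptide intensities are placed on a relative fold-change scale
where the smallest quantifiable amount across the compared samples is 1
and missing observations are 0. Proteins with more than one peptide are
quantified from peptides observed in *all* samples ("universal" peptides);
the per-sample protein value is the mean of its peptides' relative values,
log2-transformed (0 mapped to a log2 floor of -1) before an unpaired
t-test. A protein is called differential at |fold change| >= 1.3 and
p <= 0.05; proteins detected in only one condition are excluded from
volcano-style displays but reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "QuantMatrix",
    "RollupResult",
    "build_quant_matrix",
    "rollup_proteins",
    "test_differential",
    "signed_fold_change",
]

LOG2_FLOOR = -1.0
FC_THRESHOLD = 1.3
P_THRESHOLD = 0.05


@dataclass
class QuantMatrix:
    """Peptide-ion x sample relative abundances (row min over nonzero = 1)."""

    values: pd.DataFrame            # rows: ion ids; columns: sample labels
    provenance: pd.DataFrame | None = None  # same shape, "identified"/"transferred"
    n_dropped_rows: int = 0


@dataclass
class RollupResult:
    linear: pd.DataFrame            # protein x sample relative values
    log2: pd.DataFrame              # log2 with 0 -> LOG2_FLOOR
    n_peptides_used: pd.Series
    n_peptides_total: pd.Series


def build_quant_matrix(
    intensities: pd.DataFrame,
    provenance: pd.DataFrame | None = None,
) -> QuantMatrix:
    """Scale a peptide x sample intensity table to the relative scale.

    Every row is divided by its smallest nonzero entry; zeros (missing)
    stay zero. Rows with no nonzero entry are dropped (logged).
    """
    if intensities.shape[1] < 2:
        raise ParameterError("need at least two samples")
    if (intensities.values < 0).any():
        raise ParameterError("intensities must be non-negative")
    values = intensities.to_numpy(dtype=float)
    nonzero_min = np.where(values > 0, values, np.inf).min(axis=1)
    keep = np.isfinite(nonzero_min)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d all-zero peptide rows", n_dropped)
    scaled = values[keep] / nonzero_min[keep, None]
    out = pd.DataFrame(scaled, index=intensities.index[keep],
                       columns=intensities.columns)
    if provenance is not None:
        provenance = provenance.loc[out.index]
    return QuantMatrix(values=out, provenance=provenance,
                       n_dropped_rows=n_dropped)


def rollup_proteins(
    matrix: QuantMatrix,
    razor_map: Mapping[str, str],
) -> RollupResult:
    """Roll peptide relative values up to per-protein per-sample values.

    ``razor_map`` maps each peptide row id to its single razor accession.
    For proteins with more than one peptide, only peptides quantified in
    all samples are used; if none qualify (or only one peptide exists),
    all its peptides are used with zeros entering the mean. The protein
    value is the arithmetic mean of the used peptide rows.
    """
    missing = [i for i in matrix.values.index if i not in razor_map]
    if missing:
        raise ParameterError(
            f"razor map lacks {len(missing)} quantified peptides "
            f"(e.g. {missing[0]!r})")
    groups: dict[str, list] = {}
    for ion_id in matrix.values.index:
        groups.setdefault(razor_map[ion_id], []).append(ion_id)

    rows, used, total = {}, {}, {}
    for acc in sorted(groups):
        block = matrix.values.loc[groups[acc]]
        use = block
        if len(block) > 1:
            universal = block[(block > 0).all(axis=1)]
            if len(universal) >= 1:
                use = universal
        rows[acc] = use.mean(axis=0)
        used[acc] = len(use)
        total[acc] = len(block)
    linear = pd.DataFrame(rows).T
    linear.columns = matrix.values.columns
    log2 = pd.DataFrame(
        np.where(linear.values > 0, np.log2(np.where(linear.values > 0,
                                                     linear.values, 1.0)),
                 LOG2_FLOOR),
        index=linear.index, columns=linear.columns)
    return RollupResult(
        linear=linear, log2=log2,
        n_peptides_used=pd.Series(used), n_peptides_total=pd.Series(total))


def signed_fold_change(log2fc: float) -> float:
    """Report-style signed linear fold change (-1/fc for decreases)."""
    fc = 2.0 ** log2fc
    return fc if fc >= 1 else -1.0 / fc


def test_differential(
    rollup: RollupResult,
    design: Sequence[str],
    equal_var: bool = True,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Unpaired two-sided t-test of per-protein log2 values, B versus A.

    ``design`` gives the condition label ("A" or "B") per sample column.
    Returns one row per protein with the linear fold change (B/A, derived
    from the difference of group means on the log2 scale), the signed
    report-style fold change, the p-value, the differential call at
    ``|fc| >= fc_threshold`` and ``p <= p_threshold``, and volcano
    eligibility (False iff detected in only one condition). Groups with
    zero variance on both sides yield p = 1 for equal means, else p = 0
    with ``degenerate_variance`` set.
    """
    design = list(design)
    if len(design) != rollup.log2.shape[1]:
        raise ParameterError("design length must match sample count")
    a_cols = [i for i, d in enumerate(design) if d == "A"]
    b_cols = [i for i, d in enumerate(design) if d == "B"]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ParameterError("need >=2 samples per condition")

    records = []
    log2 = rollup.log2.to_numpy()
    linear = rollup.linear.to_numpy()
    for i, acc in enumerate(rollup.log2.index):
        a, b = log2[i, a_cols], log2[i, b_cols]
        lin_a, lin_b = linear[i, a_cols], linear[i, b_cols]
        mean_a, mean_b = float(a.mean()), float(b.mean())
        log2fc = mean_b - mean_a
        degenerate = False
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            degenerate = True
            p = 1.0 if mean_a == mean_b else 0.0
        else:
            p = float(stats.ttest_ind(b, a, equal_var=equal_var).pvalue)
        fc = 2.0 ** log2fc
        called = (fc >= fc_threshold or fc <= 1 / fc_threshold) and p <= p_threshold
        only_a = (lin_b == 0).all() and (lin_a > 0).any()
        only_b = (lin_a == 0).all() and (lin_b > 0).any()
        records.append({
            "accession": acc,
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "log2_fold_change": log2fc,
            "fold_change": fc,
            "fold_change_signed": signed_fold_change(log2fc),
            "p_value": p,
            "called": bool(called),
            "volcano_eligible": not (only_a or only_b),
            "only_in_condition": "A" if only_a else ("B" if only_b else ""),
            "degenerate_variance": degenerate,
            "n_peptides_used": int(rollup.n_peptides_used[acc]),
        })
    return pd.DataFrame.from_records(records).set_index("accession")
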