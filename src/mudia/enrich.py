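"""EASE-score pathway enrichment and cell-type annotation joins.

The EASE score is the conservative DAVID variant of the one-sided Fisher
exact test: the overlap count is reduced by one before taking the
hypergeometric upper tail, so single-gene overlaps are never significant.
The reference background is the set of quantified proteins, up- and
down-regulated lists are tested separately, and (matching the upstream
analysis convention) no multiple-testing correction is applied to the
reporting threshold of p < 0.01 -- a Benjamini-Hochberg column is emitted
for information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .acquisition import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "ease_pvalue",
    "enrich_pathways",
    "annotate_cell_types",
    "read_gmt",
]

REPORT_THRESHOLD = 0.01


@dataclass
class AnnotationTable:
    """Pathway membership restricted to a quantified-proteome background."""

    pathways: dict[str, set[str]]
    background: set[str]

    @classmethod
    def from_memberships(
        cls, pathways: Mapping[str, Iterable[str]], quantified: Iterable[str]
    ) -> "AnnotationTable":
        # Background = quantified proteome restricted to the annotation
        # universe (genes no pathway annotates cannot be drawn by the test).
        universe: set[str] = set().union(*map(set, pathways.values())) if pathways else set()
        background = set(quantified) & universe if universe else set(quantified)
        trimmed = {
            pid: set(genes) & background for pid, genes in pathways.items()
        }
        return cls(pathways={p: g for p, g in trimmed.items() if g},
                   background=background)


def ease_pvalue(k: int, n: int, K: int, N: int) -> float:
    """EASE score: hypergeometric upper tail with the overlap reduced by 1.

    ``p = P(X >= k - 1)`` for ``X ~ Hypergeometric(N, K, n)`` where ``k``
    of the ``n`` list genes fall in a pathway of size ``K`` within a
    background of size ``N``. ``k <= 1`` gives p = 1.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ParameterError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k <= 1:
        return 1.0
    return float(stats.hypergeom.sf(k - 2, N, K, n))


def enrich_pathways(
    gene_list: Iterable[str],
    annotation: AnnotationTable,
    report_threshold: float = REPORT_THRESHOLD,
) -> pd.DataFrame:
    """Test every pathway with overlap >= 1 against the background.

    Genes absent from the background are dropped from the list size
    (logged). Results are sorted by EASE p-value; ``reported`` flags
    p < ``report_threshold`` (no multiple-testing correction); the
    ``bh_q`` column is informational only.
    """
    genes = set(gene_list)
    in_bg = genes & annotation.background
    dropped = len(genes) - len(in_bg)
    if dropped:
        logger.info("%d list genes outside the quantified background dropped",
                    dropped)
    N = len(annotation.background)
    n = len(in_bg)
    records = []
    for pid, members in sorted(annotation.pathways.items()):
        overlap = in_bg & members
        k = len(overlap)
        if k < 1:
            continue
        K = len(members)
        p = ease_pvalue(k, n, K, N)
        records.append({
            "pathway": pid,
            "k": k, "n": n, "K": K, "N": N,
            "overlap_genes": ",".join(sorted(overlap)),
            "ease_p": p,
        })
    if not records:
        return pd.DataFrame(columns=["pathway", "k", "n", "K", "N",
                                     "overlap_genes", "ease_p", "bh_q",
                                     "reported"]).set_index("pathway")
    df = pd.DataFrame.from_records(records).set_index("pathway")
    df["bh_q"] = multipletests(df["ease_p"], method="fdr_bh")[1]
    df["reported"] = df["ease_p"] < report_threshold
    return df.sort_values("ease_p")


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT-style pathway file (name, description, genes...)."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = {g for g in parts[2:] if g}
    return pathways


def annotate_cell_types(
    results: pd.DataFrame,
    cell_types: Mapping[str, str] | pd.DataFrame | str,
    gene_column: str = "gene",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left-join differential results with gene -> cell-type labels.

    ``cell_types`` is a mapping, a two-column DataFrame, or a TSV path.
    Unmatched genes get ``"unassigned"``; duplicate gene rows keep the
    first occurrence (warning). Returns the annotated table plus
    per-cell-type counts of up/down called proteins.
    """
    if isinstance(cell_types, str):
        table = pd.read_csv(cell_types, sep="\t", header=0)
        mapping_items = list(zip(table.iloc[:, 0], table.iloc[:, 1]))
    elif isinstance(cell_types, pd.DataFrame):
        mapping_items = list(zip(cell_types.iloc[:, 0], cell_types.iloc[:, 1]))
    else:
        mapping_items = list(cell_types.items())
    mapping: dict[str, str] = {}
    for gene, label in mapping_items:
        if gene in mapping:
            if mapping[gene] != label:
                logger.warning("gene %s has conflicting cell types; keeping "
                               "first (%s)", gene, mapping[gene])
            continue
        mapping[gene] = label

    annotated = results.copy()
    annotated["cell_type"] = [
        mapping.get(g, "unassigned") for g in annotated[gene_column]
    ]
    called = annotated[annotated.get("called", pd.Series(True, index=annotated.index))]
    summary_rows = []
    for cell_type, grp in called.groupby("cell_type"):
        up = int((grp["log2_fold_change"] > 0).sum())
        summary_rows.append({"cell_type": cell_type, "n_up": up,
                             "n_down": len(grp) - up})
    summary = pd.DataFrame(summary_rows,
                           columns=["cell_type", "n_up", "n_down"])
    if len(summary):
        summary = summary.set_index("cell_type")
    return annotated, summary
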