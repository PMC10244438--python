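"""Differential-expression filtering and candidate-gene nomination.

The pipeline's final step intersects three gene sets — genes targeted by
condition-gain super-enhancers, genes significantly upregulated on
treatment, and genes differentially expressed in the disease cohort — to
nominate SE-driven identity genes (the intersection that singled out ZBTB16
in the motivating osteogenesis study).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import DEGRecord

__all__ = [
    "CandidateReport",
    "bh_adjust",
    "filter_degs",
    "intersect_candidates",
]

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the p-values sorted
    ascending, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(
    records: list[DEGRecord],
    min_abs_log2fc: float = 1.0,
    max_q: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Split DEG records into up- and down-regulated gene sets.

    ``up = {log2fc >= min_abs_log2fc and q <= max_q}``,
    ``down = {log2fc <= -min_abs_log2fc and q <= max_q}`` — boundary values
    are included on both thresholds.  Every record must carry a q-value;
    apply :func:`bh_adjust` to the p-values first if it does not.
    """
    missing = [r.gene_id for r in records if r.qvalue is None]
    if missing:
        raise ValueError(
            f"{len(missing)} record(s) lack q-values (first: {missing[0]!r}); "
            "run bh_adjust on the p-values first"
        )
    up = {
        r.gene_id
        for r in records
        if r.log2fc >= min_abs_log2fc and r.qvalue <= max_q
    }
    down = {
        r.gene_id
        for r in records
        if r.log2fc <= -min_abs_log2fc and r.qvalue <= max_q
    }
    return up, down


@dataclass
class CandidateReport:
    """Triple intersection of SE-target, upregulated and disease gene sets."""

    se_genes: set[str]
    up_genes: set[str]
    disease_genes: set[str]
    candidates: list[str]
    provenance: dict = field(default_factory=dict)


def intersect_candidates(
    se_genes, up_genes, disease_genes
) -> CandidateReport:
    """Nominate candidates as ``se_genes & up_genes & disease_genes``.

    Matching is exact and case-sensitive; identifiers that would match only
    after upper-casing are reported as a warning so namespace mismatches
    (e.g. mouse Zbtb16 vs human ZBTB16) surface instead of silently failing.
    Candidates are returned sorted lexicographically.
    """
    se_genes, up_genes, disease_genes = set(se_genes), set(up_genes), set(disease_genes)
    candidates = sorted(se_genes & up_genes & disease_genes)
    _warn_case_mismatches(se_genes, up_genes, disease_genes)
    return CandidateReport(
        se_genes=se_genes,
        up_genes=up_genes,
        disease_genes=disease_genes,
        candidates=candidates,
        provenance={
            "n_se_genes": len(se_genes),
            "n_up_genes": len(up_genes),
            "n_disease_genes": len(disease_genes),
            "n_candidates": len(candidates),
        },
    )


def _warn_case_mismatches(*sets: set[str]) -> None:
    exact = set().union(*sets)
    folded: dict[str, set[str]] = {}
    for g in exact:
        folded.setdefault(g.upper(), set()).add(g)
    clashes = {k: v for k, v in folded.items() if len(v) > 1}
    for variants in clashes.values():
        logger.warning(
            "gene ids differing only by case will not intersect: %s",
            sorted(variants),
        )
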