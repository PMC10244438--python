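"""Condition dynamics of super-enhancers and cross-dataset consensus.

Classification is strictly presence/absence: an SE present only after
treatment (osteogenic induction in the motivating study) is a *gain* SE,
one present only in the control condition is *lost*, and overlapping pairs
are *shared*.  The consensus operation intersects the gain sets of several
datasets, the Venn-style analysis that nominates loci gained in every
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval

__all__ = [
    "SEDynamics",
    "ConsensusResult",
    "GeneAssignment",
    "classify_dynamics",
    "consensus_regions",
    "annotate_nearest_tss",
]

logger = logging.getLogger(__name__)


def _required_overlap(a: GenomicInterval, b: GenomicInterval, frac: float) -> float:
    return max(1.0, frac * min(a.length, b.length))


def _build_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def _matches(
    query: GenomicInterval, targets: list[GenomicInterval], trees, frac: float
) -> list[int]:
    """Indices of *targets* overlapping *query* by >= max(1 bp, frac x shorter length)."""
    tree = trees.get(query.chrom)
    if tree is None:
        return []
    out = []
    for hit in tree.overlap(query.start, query.end):
        t = targets[hit.data]
        if query.overlap_len(t) >= _required_overlap(query, t, frac):
            out.append(hit.data)
    return sorted(out)


@dataclass
class SEDynamics:
    """Gain/lost/shared partition of two condition-specific SE sets.

    ``shared`` holds (control SE, treated SE) pairs; each treated SE appears
    in exactly one of ``gain`` / shared pairs, and each control SE in exactly
    one of ``lost`` / shared pairs.  Swapping the two input conditions swaps
    gain and lost and transposes the shared pairs.
    """

    gain: list[GenomicInterval]
    lost: list[GenomicInterval]
    shared: list[tuple[GenomicInterval, GenomicInterval]]
    min_overlap_frac: float = 0.0


def classify_dynamics(
    se_control: list[GenomicInterval],
    se_treated: list[GenomicInterval],
    min_overlap_frac: float = 0.0,
) -> SEDynamics:
    """Presence/absence classification of SEs between two conditions.

    A treated SE is *shared* if some control SE overlaps it by at least
    ``max(1 bp, min_overlap_frac x shorter region length)``, else it is a
    *gain* SE; control SEs with no such treated partner are *lost*.  A shared
    treated SE is paired with its largest-overlap control partner.
    """
    if not 0.0 <= min_overlap_frac <= 1.0:
        raise ValueError("min_overlap_frac must be in [0, 1]")
    se_control = sorted(se_control, key=GenomicInterval.sort_key)
    se_treated = sorted(se_treated, key=GenomicInterval.sort_key)
    ctrees = _build_trees(se_control)
    gain: list[GenomicInterval] = []
    shared: list[tuple[GenomicInterval, GenomicInterval]] = []
    matched_controls: set[int] = set()
    for t in se_treated:
        hits = _matches(t, se_control, ctrees, min_overlap_frac)
        if not hits:
            gain.append(t)
        else:
            best = max(hits, key=lambda i: (t.overlap_len(se_control[i]), -i))
            shared.append((se_control[best], t))
            matched_controls.update(hits)
    # a control SE is lost iff no treated SE anywhere meets the overlap rule
    ttrees = _build_trees(se_treated)
    lost = [
        c
        for i, c in enumerate(se_control)
        if not _matches(c, se_treated, ttrees, min_overlap_frac)
    ]
    return SEDynamics(
        gain=gain, lost=lost, shared=shared, min_overlap_frac=min_overlap_frac
    )


@dataclass
class ConsensusResult:
    """Regions whose gain status replicates across every dataset.

    ``common_regions`` are intersection spans of the overlapping
    representatives, one per consensus locus; ``representatives`` maps each
    consensus region to its per-dataset representative intervals, in dataset
    order.  ``common_genes`` is filled by nearest-TSS annotation downstream.
    """

    datasets: list[str]
    common_regions: list[GenomicInterval]
    per_dataset_counts: dict[str, int]
    representatives: list[list[GenomicInterval]] = field(default_factory=list)
    common_genes: list[str] | None = None


def consensus_regions(
    gain_sets: list[list[GenomicInterval]],
    min_overlap_frac: float = 0.0,
    labels: list[str] | None = None,
) -> ConsensusResult:
    """Intersect gain-SE sets across >= 2 datasets.

    A region of the first dataset enters the consensus iff every other
    dataset has a gain SE overlapping it under the same rule as
    :func:`classify_dynamics`; the reported interval is the intersection span
    of the best-overlapping representative from each dataset.
    """
    if len(gain_sets) < 2:
        raise ValueError(f"consensus needs >= 2 datasets, got {len(gain_sets)}")
    if labels is None:
        labels = [f"dataset{i + 1}" for i in range(len(gain_sets))]
    if len(labels) != len(gain_sets):
        raise ValueError("labels must match gain_sets")
    sets = [sorted(s, key=GenomicInterval.sort_key) for s in gain_sets]
    trees = [_build_trees(s) for s in sets]
    common: list[GenomicInterval] = []
    reps_all: list[list[GenomicInterval]] = []
    for seed in sets[0]:
        reps = [seed]
        ok = True
        for other, otree in zip(sets[1:], trees[1:]):
            hits = _matches(seed, other, otree, min_overlap_frac)
            if not hits:
                ok = False
                break
            best = max(hits, key=lambda i: (seed.overlap_len(other[i]), -i))
            reps.append(other[best])
        if not ok:
            continue
        start = max(r.start for r in reps)
        end = min(r.end for r in reps)
        if end <= start:  # pairwise overlaps need not share a common core
            continue
        common.append(GenomicInterval(seed.chrom, start, end))
        reps_all.append(reps)
    return ConsensusResult(
        datasets=list(labels),
        common_regions=common,
        per_dataset_counts={lab: len(s) for lab, s in zip(labels, sets)},
        representatives=reps_all,
    )


@dataclass(slots=True)
class GeneAssignment:
    """A region assigned to the gene with the nearest strand-aware TSS."""

    region: GenomicInterval
    gene_id: str
    distance: int


def annotate_nearest_tss(
    regions: list[GenomicInterval], genes: list[GeneModel]
) -> list[GeneAssignment]:
    """Assign each region to the gene with the TSS closest to its center.

    Only genes on the region's chromosome are considered; ties go to the
    smaller TSS coordinate, then to the lexicographically smaller gene id.
    Distance is 0 when the region center falls inside the assigned gene body.
    Regions on a chromosome with no annotated gene are skipped with a warning.
    """
    if not genes:
        raise ValueError("gene model is empty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneAssignment] = []
    for region in regions:
        cands = by_chrom.get(region.chrom)
        if not cands:
            logger.warning(
                "no genes on chromosome %r; region %s left unannotated",
                region.chrom,
                region,
            )
            continue
        c = region.center
        best = min(cands, key=lambda g: (abs(c - g.tss), g.tss, g.gene_id))
        inside = best.interval.start <= c < best.interval.end
        out.append(
            GeneAssignment(
                region=region,
                gene_id=best.gene_id,
                distance=0 if inside else abs(c - best.tss),
            )
        )
    return out
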