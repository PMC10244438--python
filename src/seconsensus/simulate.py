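"""Synthetic multi-dataset enhancer landscapes with planted ground truth.

The generator emulates the structure of a two-condition (control vs.
osteogenically induced) multi-dataset ChIP-seq/accessibility study: several
datasets (cell line x marker pairs) share one genome; super-enhancer loci are
planted as clusters of constituent peaks near a target gene's TSS, labelled
shared-gain (treated-only, in every dataset), private-gain (treated-only, one
dataset), lost (control-only, one dataset) or constitutive (both conditions);
isolated singleton background peaks act as typical enhancers.  Coverage is a
sum of boxcar bumps plus zero-truncated Gaussian noise, and the accompanying
differential-expression table upregulates the gain-SE target genes.

The geometry is slot-based: the genome is divided into fixed slots large
enough that features in different slots can never stitch together, and all
peak coordinates are aligned to the coverage bin width so noiseless region
signals have an exact closed form (amplitude x peak length).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEGRecord, GeneModel, GenomicInterval, PeakSet
from .tracks import RAW, SignalTrack

__all__ = [
    "SimulationParams",
    "PlantedLocus",
    "SyntheticTruth",
    "SyntheticStudy",
    "simulate_study",
    "write_study",
    "evaluate_recovery",
]

CONTROL = "control"
TREATED = "treated"
_MARKERS = ("H3K27ac", "BRD4", "MED1")


@dataclass
class SimulationParams:
    """Study-design knobs for :func:`simulate_study`.

    Defaults describe a desk-scale analogue of a five-dataset osteogenesis
    study: 2 chromosomes x 10 Mb, 200 genes, one shared gain SE plus private
    gain/lost/constitutive SEs per dataset, and 200 isolated background
    peaks per condition.
    """

    seed: int = 42
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 200
    n_datasets: int = 5
    n_shared_gain_se: int = 1
    n_private_gain_se: int = 3
    n_lost_se: int = 3
    n_constitutive_se: int = 5
    constituents_per_se: int = 4
    constituent_length: int = 1_000
    se_span: int = 30_000
    n_background_peaks: int = 200
    background_peak_length: int = 1_000
    amp_se: float = 10.0
    amp_te: float = 3.0
    noise_sd: float = 1.0
    bin_width: int = 50
    deg_effect_mean: float = 2.5
    deg_effect_sd: float = 0.5
    background_lfc_sd: float = 0.3
    n_disease_decoys: int = 30
    stitch_distance: int = 12_500
    gene_length: int = 10_000

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "chrom_length", "n_genes", "n_datasets",
            "n_shared_gain_se", "n_private_gain_se", "n_lost_se",
            "n_constitutive_se", "constituents_per_se", "n_background_peaks",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.amp_se > self.amp_te > 0:
            raise ValueError("amplitudes must satisfy amp_se > amp_te > 0")
        if self.constituents_per_se >= 2:
            gap = (
                self.se_span - self.constituents_per_se * self.constituent_length
            ) / (self.constituents_per_se - 1)
            if gap <= 0 or gap >= self.stitch_distance:
                raise ValueError(
                    "se_span incompatible with constituent count/length: "
                    f"inter-constituent gap {gap:.0f} bp must be in "
                    f"(0, {self.stitch_distance})"
                )

    @property
    def n_planted_loci(self) -> int:
        return self.n_shared_gain_se + self.n_datasets * (
            self.n_private_gain_se + self.n_lost_se + self.n_constitutive_se
        )

    @property
    def slot_size(self) -> int:
        # a slot holds one gene and (optionally) one SE zone; consecutive
        # zones must sit further apart than the stitch distance
        return self.se_span + self.stitch_distance + 2 * self.bin_width + 2_500


@dataclass(slots=True)
class PlantedLocus:
    """One planted SE: its span, label, target gene and owning dataset."""

    label: str  # shared-gain | private-gain | lost | constitutive
    interval: GenomicInterval
    gene_id: str
    dataset: str | None  # None for shared-gain (present in all datasets)
    constituents: list[GenomicInterval]

    def present_in(self, dataset: str, condition: str) -> bool:
        if self.label == "shared-gain":
            return condition == TREATED
        if self.dataset != dataset:
            return False
        if self.label == "private-gain":
            return condition == TREATED
        if self.label == "lost":
            return condition == CONTROL
        return True  # constitutive


@dataclass
class SyntheticTruth:
    """Planted ground truth for scoring recovery."""

    loci: list[PlantedLocus]
    shared_gain_genes: list[str]
    up_genes: list[str]
    down_genes: list[str]

    def loci_for(self, dataset: str, condition: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.present_in(dataset, condition)]

    def gain_loci_for(self, dataset: str) -> list[PlantedLocus]:
        return [
            l
            for l in self.loci
            if l.present_in(dataset, TREATED) and not l.present_in(dataset, CONTROL)
        ]


@dataclass
class SyntheticStudy:
    """In-memory synthetic study: inputs plus planted truth."""

    params: SimulationParams
    genes: list[GeneModel]
    dataset_names: list[str]
    markers: dict[str, str]
    peaks: dict[tuple[str, str], PeakSet]
    tracks: dict[tuple[str, str], SignalTrack]
    deg_records: list[DEGRecord]
    disease_genes: list[str]
    truth: SyntheticTruth


def _boxcar_add(bins: dict[str, np.ndarray], iv: GenomicInterval, amp: float, w: int):
    arr = bins[iv.chrom]
    # peak coordinates are bin-aligned by construction, so this is exact
    arr[iv.start // w : -(-iv.end // w)] += amp


def simulate_study(params: SimulationParams | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study from *params* (deterministic in seed).

    Raises ``ValueError`` with the required minimum genome size if the
    requested features do not fit.
    """
    p = params or SimulationParams()
    rng = np.random.default_rng(p.seed)
    w = p.bin_width

    slots_per_chrom = p.chrom_length // p.slot_size
    n_slots = p.n_chroms * slots_per_chrom
    n_needed = max(p.n_genes, p.n_planted_loci) + p.n_background_peaks
    if p.n_planted_loci > p.n_genes:
        raise ValueError(
            f"{p.n_planted_loci} planted loci need distinct target genes but "
            f"only {p.n_genes} genes requested"
        )
    if n_needed > n_slots:
        need_len = -(-n_needed * p.slot_size // p.n_chroms)
        raise ValueError(
            f"genome too small: {n_needed} feature slots of {p.slot_size} bp "
            f"needed but only {n_slots} available; increase chrom_length to "
            f">= {need_len} bp"
        )

    chrom_names = [f"chr{i + 1}" for i in range(p.n_chroms)]
    all_slots = [
        (chrom_names[c], s * p.slot_size)
        for c in range(p.n_chroms)
        for s in range(slots_per_chrom)
    ]
    order = rng.permutation(len(all_slots))
    gene_slots = [all_slots[i] for i in order[: p.n_genes]]
    bg_slots = [all_slots[i] for i in order[p.n_genes : p.n_genes + p.n_background_peaks]]

    def snap(x: int) -> int:
        return (x // w) * w

    # genes: one per gene slot, body starting at the slot's feature zone
    genes: list[GeneModel] = []
    zone_off = snap(1_000)
    for i, (chrom, slot) in enumerate(gene_slots):
        strand = "+" if rng.random() < 0.5 else "-"
        start = slot + zone_off
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:04d}",
                interval=GenomicInterval(chrom, start, start + p.gene_length, strand),
            )
        )

    dataset_names = [f"ds{i + 1}" for i in range(p.n_datasets)]
    markers = {d: _MARKERS[i % len(_MARKERS)] for i, d in enumerate(dataset_names)}

    # assign planted loci to distinct target genes
    target_idx = rng.choice(p.n_genes, size=p.n_planted_loci, replace=False)
    labels: list[tuple[str, str | None]] = [("shared-gain", None)] * p.n_shared_gain_se
    for d in dataset_names:
        labels += [("private-gain", d)] * p.n_private_gain_se
        labels += [("lost", d)] * p.n_lost_se
        labels += [("constitutive", d)] * p.n_constitutive_se

    loci: list[PlantedLocus] = []
    c = p.constituents_per_se
    for (label, dataset), gi in zip(labels, target_idx):
        g = genes[gi]
        chrom, slot = gene_slots[gi]
        zone_start = slot + zone_off
        constituents = []
        if c == 1:
            base_starts = [zone_start + (p.se_span - p.constituent_length) // 2]
        else:
            step = (p.se_span - p.constituent_length) / (c - 1)
            base_starts = [zone_start + round(k * step) for k in range(c)]
        jitter_max = max(w, int(min(500, (step if c > 1 else p.se_span) / 8))) if c > 1 else w
        for b in base_starts:
            j = int(rng.integers(-jitter_max, jitter_max + 1))
            s = snap(max(zone_start, b + j))
            constituents.append(
                GenomicInterval(chrom, s, s + p.constituent_length)
            )
        constituents.sort(key=GenomicInterval.sort_key)
        loci.append(
            PlantedLocus(
                label=label,
                interval=GenomicInterval(
                    chrom, constituents[0].start, constituents[-1].end
                ),
                gene_id=g.gene_id,
                dataset=dataset,
                constituents=constituents,
            )
        )

    background = []
    for chrom, slot in bg_slots:
        s = snap(slot + zone_off + int(rng.integers(0, p.se_span // w)) * w)
        background.append(
            GenomicInterval(chrom, s, s + p.background_peak_length)
        )

    # peaks and coverage per (dataset, condition)
    n_bins = {ch: -(-p.chrom_length // w) for ch in chrom_names}
    peaks: dict[tuple[str, str], PeakSet] = {}
    tracks: dict[tuple[str, str], SignalTrack] = {}
    for d in dataset_names:
        for cond in (CONTROL, TREATED):
            ivs = list(background)
            bins = {ch: np.zeros(nb) for ch, nb in n_bins.items()}
            for iv in background:
                _boxcar_add(bins, iv, p.amp_te, w)
            for locus in loci:
                if locus.present_in(d, cond):
                    ivs.extend(locus.constituents)
                    for iv in locus.constituents:
                        _boxcar_add(bins, iv, p.amp_se, w)
            if p.noise_sd > 0:
                for ch in chrom_names:
                    bins[ch] += rng.normal(0.0, p.noise_sd, bins[ch].size)
                    np.maximum(bins[ch], 0.0, out=bins[ch])
            peaks[(d, cond)] = PeakSet(
                intervals=list(ivs), source=d, marker=markers[d]
            )
            tracks[(d, cond)] = SignalTrack(
                bins=bins, bin_width=w, normalized=RAW
            )

    # differential expression: gain targets up, lost targets down, rest null
    up_genes = sorted(
        {l.gene_id for l in loci if l.label in ("shared-gain", "private-gain")}
    )
    down_genes = sorted({l.gene_id for l in loci if l.label == "lost"})
    shared_genes = sorted({l.gene_id for l in loci if l.label == "shared-gain"})
    deg_records: list[DEGRecord] = []
    for g in genes:
        if g.gene_id in up_genes:
            lfc = rng.normal(p.deg_effect_mean, p.deg_effect_sd)
            pval = 10.0 ** rng.uniform(-12, -8)
        elif g.gene_id in down_genes:
            lfc = -rng.normal(p.deg_effect_mean, p.deg_effect_sd)
            pval = 10.0 ** rng.uniform(-12, -8)
        else:
            lfc = rng.normal(0.0, p.background_lfc_sd)
            pval = rng.uniform(0.0, 1.0)
        deg_records.append(DEGRecord(gene_id=g.gene_id, log2fc=float(lfc), pvalue=float(pval)))

    decoy_pool = [g.gene_id for g in genes if g.gene_id not in shared_genes]
    n_decoys = min(p.n_disease_decoys, len(decoy_pool))
    decoys = list(rng.choice(decoy_pool, size=n_decoys, replace=False))
    disease_genes = sorted(set(shared_genes) | set(decoys))

    truth = SyntheticTruth(
        loci=loci,
        shared_gain_genes=shared_genes,
        up_genes=up_genes,
        down_genes=down_genes,
    )
    return SyntheticStudy(
        params=p,
        genes=genes,
        dataset_names=dataset_names,
        markers=markers,
        peaks=peaks,
        tracks=tracks,
        deg_records=deg_records,
        disease_genes=disease_genes,
        truth=truth,
    )


def evaluate_recovery(
    called: list[GenomicInterval], truth_loci: list[GenomicInterval]
) -> tuple[float, float]:
    """Precision/recall of called regions against planted loci (>= 1 bp overlap)."""
    if not called:
        return (1.0 if not truth_loci else 0.0, 0.0 if truth_loci else 1.0)
    hit_called = sum(1 for c in called if any(c.overlaps(t) for t in truth_loci))
    hit_truth = sum(1 for t in truth_loci if any(t.overlaps(c) for c in called))
    precision = hit_called / len(called)
    recall = hit_truth / len(truth_loci) if truth_loci else 1.0
    return precision, recall


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_study(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write the study as pipeline-ready files; returns {relative path: sha256}.

    Emits per dataset/condition a peak BED and a bedGraph coverage file, the
    gene model TSV, the DEG table, the disease gene list, ``truth.json`` and
    a ready-to-run ``config.yaml``, plus ``manifest.json`` with checksums.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = study.params
    written: list[str] = []

    gene_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in study.genes],
            "chrom": [g.chrom for g in study.genes],
            "start": [g.interval.start for g in study.genes],
            "end": [g.interval.end for g in study.genes],
            "strand": [g.interval.strand for g in study.genes],
        }
    )
    gene_df.to_csv(out / "genes.tsv", sep="\t", index=False)
    written.append("genes.tsv")

    datasets_cfg = []
    for d in study.dataset_names:
        entry = {"name": d, "marker": study.markers[d]}
        for cond in (CONTROL, TREATED):
            bed = f"{d}_{cond}.peaks.bed"
            bg = f"{d}_{cond}.bedGraph"
            ps = study.peaks[(d, cond)]
            with open(out / bed, "w", encoding="utf-8", newline="\n") as fh:
                for iv in ps:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            track = study.tracks[(d, cond)]
            with open(out / bg, "w", encoding="utf-8", newline="\n") as fh:
                w = track.bin_width
                for chrom in sorted(track.bins):
                    arr = track.bins[chrom]
                    nz = np.flatnonzero(arr)
                    starts = nz * w
                    for i, s in zip(nz, starts):
                        fh.write(f"{chrom}\t{s}\t{s + w}\t{arr[i]:.8g}\n")
            entry[cond] = {"peaks": bed, "signal": bg}
            written += [bed, bg]
        datasets_cfg.append(entry)

    deg_df = pd.DataFrame(
        {
            "gene": [r.gene_id for r in study.deg_records],
            "log2fc": [r.log2fc for r in study.deg_records],
            "pvalue": [r.pvalue for r in study.deg_records],
        }
    )
    deg_df.to_csv(out / "deg.tsv", sep="\t", index=False, float_format="%.8g")
    written.append("deg.tsv")

    with open(out / "disease_genes.txt", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# disease cohort differentially expressed genes\n")
        for g in study.disease_genes:
            fh.write(g + "\n")
    written.append("disease_genes.txt")

    truth = {
        "shared_gain_genes": study.truth.shared_gain_genes,
        "up_genes": study.truth.up_genes,
        "down_genes": study.truth.down_genes,
        "loci": [
            {
                "label": l.label,
                "chrom": l.interval.chrom,
                "start": l.interval.start,
                "end": l.interval.end,
                "gene_id": l.gene_id,
                "dataset": l.dataset,
                "constituents": [
                    [iv.chrom, iv.start, iv.end] for iv in l.constituents
                ],
            }
            for l in study.truth.loci
        ],
        "params": asdict(p),
    }
    with open(out / "truth.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append("truth.json")

    config = {
        "datasets": datasets_cfg,
        "stitch_distance": p.stitch_distance,
        "bin_width": p.bin_width,
        "min_overlap_frac": 0.0,
        "tss_exclusion": {"enabled": False, "window": 2500},
        "gene_model": "genes.tsv",
        "deg": {"table": "deg.tsv", "lfc_min": 1.0, "q_max": 0.05},
        "disease_genes": "disease_genes.txt",
        "venn_mode": "interval",
        "output_dir": "results",
    }
    with open(out / "config.yaml", "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    written.append("config.yaml")

    manifest = {name: _sha256(out / name) for name in written}
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
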