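"""Config-driven end-to-end runner: SE calling -> dynamics -> consensus -> candidates.

The pipeline reproduces the integrative analysis graph: per dataset and
condition, peaks are stitched and scored and SEs are called; SEs are
classified as gain/lost/shared between the two conditions; gain sets are
intersected across datasets; consensus regions are annotated to nearest-TSS
genes; the DEG table is thresholded; and the SE-target, upregulated and
disease gene sets are intersected into the final candidate list.  Every
artifact is written under ``output_dir`` together with ``report.json`` and
``run.log``, and the report's counts are audited against the emitted files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .core import GenomicInterval
from .dynamics import annotate_nearest_tss, classify_dynamics, consensus_regions
from .integrate import bh_adjust, filter_degs, intersect_candidates
from .readwrite import (
    read_deg_table,
    read_gene_list,
    read_gene_models,
    read_intervals,
    read_signal_track,
    write_intervals,
)
from .rose import call_superenhancers

__all__ = [
    "PipelineConfig",
    "DatasetConfig",
    "PipelineError",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the report carries a FAILED marker."""


@dataclass
class ConditionInputs:
    peaks: Path
    signal: Path
    control_signal: Path | None = None
    library_size: float | None = None


@dataclass
class DatasetConfig:
    name: str
    marker: str = ""
    control: ConditionInputs | None = None
    treated: ConditionInputs | None = None


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; see ``load_config`` for the YAML layout."""

    datasets: list[DatasetConfig]
    gene_model: Path
    deg_table: Path | None = None
    disease_genes: Path | None = None
    output_dir: Path = Path("seconsensus_out")
    stitch_distance: int = 12_500
    bin_width: int = 50
    min_overlap_frac: float = 0.0
    tss_exclusion_enabled: bool = False
    tss_exclusion_window: int = 2_500
    lfc_min: float = 1.0
    q_max: float = 0.05
    venn_mode: str = "interval"
    make_plots: bool = True

    def validate(self) -> None:
        if not self.datasets:
            raise PipelineError("config must list at least one dataset")
        if self.stitch_distance < 0 or self.bin_width < 1:
            raise PipelineError("stitch_distance and bin_width must be positive")
        if self.venn_mode not in ("interval", "gene"):
            raise PipelineError(f"venn_mode must be interval or gene, got {self.venn_mode!r}")
        for ds in self.datasets:
            for cond_name in ("control", "treated"):
                cond = getattr(ds, cond_name)
                if cond is None:
                    raise PipelineError(
                        f"dataset {ds.name!r}: missing {cond_name} inputs"
                    )
                for label, path in (
                    ("peaks", cond.peaks),
                    ("signal", cond.signal),
                ):
                    if not Path(path).exists():
                        raise PipelineError(
                            f"dataset {ds.name!r}: {cond_name} {label} file "
                            f"not found: {path}"
                        )
        for label, path in (
            ("gene_model", self.gene_model),
            ("deg table", self.deg_table),
            ("disease gene list", self.disease_genes),
        ):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"{label} file not found: {path}")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; paths resolve against its directory."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def _p(x):
        return None if x is None else (base / x)

    datasets = []
    for entry in raw.get("datasets", []):
        conds = {}
        for cond_name in ("control", "treated"):
            c = entry.get(cond_name)
            if c is not None:
                conds[cond_name] = ConditionInputs(
                    peaks=_p(c.get("peaks")),
                    signal=_p(c.get("signal")),
                    control_signal=_p(c.get("control_signal")),
                    library_size=c.get("library_size"),
                )
        datasets.append(
            DatasetConfig(
                name=str(entry.get("name", f"dataset{len(datasets) + 1}")),
                marker=str(entry.get("marker", "")),
                **conds,
            )
        )
    deg = raw.get("deg", {}) or {}
    tss = raw.get("tss_exclusion", {}) or {}
    cfg = PipelineConfig(
        datasets=datasets,
        gene_model=_p(raw.get("gene_model")),
        deg_table=_p(deg.get("table")),
        disease_genes=_p(raw.get("disease_genes")),
        output_dir=base / raw.get("output_dir", "seconsensus_out"),
        stitch_distance=int(raw.get("stitch_distance", 12_500)),
        bin_width=int(raw.get("bin_width", 50)),
        min_overlap_frac=float(raw.get("min_overlap_frac", 0.0)),
        tss_exclusion_enabled=bool(tss.get("enabled", False)),
        tss_exclusion_window=int(tss.get("window", 2_500)),
        lfc_min=float(deg.get("lfc_min", 1.0)),
        q_max=float(deg.get("q_max", 0.05)),
        venn_mode=str(raw.get("venn_mode", "interval")),
        make_plots=bool(raw.get("make_plots", True)),
    )
    if cfg.gene_model is None:
        raise PipelineError("config must set gene_model")
    cfg.validate()
    return cfg


def _count_bed_lines(path: Path) -> int:
    with open(path, encoding="utf-8") as fh:
        return sum(1 for line in fh if line.strip() and not line.startswith("#"))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dedup_union(intervals: list[GenomicInterval]) -> int:
    """Number of connected overlap components among intervals (>=1 bp rule)."""
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    n = 0
    cur_chrom, cur_end = None, -1
    for iv in ivs:
        if iv.chrom != cur_chrom or iv.start >= cur_end:
            n += 1
            cur_chrom, cur_end = iv.chrom, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    return n


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the machine-readable report.

    On a stage failure a report carrying ``status: FAILED`` and the error is
    still written before :class:`PipelineError` is raised, so partial outputs
    remain inspectable.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("seconsensus")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    report: dict = {
        "status": "RUNNING",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            "stitch_distance": config.stitch_distance,
            "bin_width": config.bin_width,
            "min_overlap_frac": config.min_overlap_frac,
            "tss_exclusion": {
                "enabled": config.tss_exclusion_enabled,
                "window": config.tss_exclusion_window,
            },
            "lfc_min": config.lfc_min,
            "q_max": config.q_max,
            "venn_mode": config.venn_mode,
        },
    }
    try:
        report.update(_run(config, out))
        report["status"] = "OK"
    except Exception as exc:
        report["status"] = "FAILED"
        report["error"] = str(exc)
        _write_report(report, out)
        logger.exception("pipeline failed")
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(str(exc)) from exc
    _write_report(report, out)
    root.removeHandler(handler)
    handler.close()
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _run(config: PipelineConfig, out: Path) -> dict:
    config.validate()
    genes = read_gene_models(config.gene_model)
    logger.info("gene model: %d genes from %s", len(genes), config.gene_model)
    tss_excl = (
        (genes, config.tss_exclusion_window) if config.tss_exclusion_enabled else None
    )

    per_dataset: dict[str, dict] = {}
    gain_sets: list[list[GenomicInterval]] = []
    all_gain: list[GenomicInterval] = []
    all_lost: list[GenomicInterval] = []
    input_checksums: dict[str, str] = {}
    emitted_counts: dict[str, int] = {}

    for ds in config.datasets:
        ds_out = out / ds.name
        ds_out.mkdir(exist_ok=True)
        calls = {}
        for cond_name in ("control", "treated"):
            cond: ConditionInputs = getattr(ds, cond_name)
            input_checksums[str(cond.peaks)] = _sha256(cond.peaks)
            input_checksums[str(cond.signal)] = _sha256(cond.signal)
            peaks = read_intervals(cond.peaks, source=ds.name, marker=ds.marker)
            track = read_signal_track(
                cond.signal, config.bin_width, library_size=cond.library_size
            )
            control_track = (
                read_signal_track(cond.control_signal, config.bin_width)
                if cond.control_signal
                else None
            )
            result = call_superenhancers(
                peaks,
                track,
                stitch_distance=config.stitch_distance,
                control=control_track,
                tss_exclusion=tss_excl,
            )
            calls[cond_name] = result
            stem = f"{ds.name}_{cond_name}"
            result.to_dataframe().to_csv(
                ds_out / f"{stem}_stitched.tsv", sep="\t", index=False
            )
            ses = result.superenhancers
            tes = result.typical_enhancers
            write_intervals(
                [r.interval for r in ses], ds_out / f"{stem}_SE.bed",
                scores=[r.signal for r in ses],
            )
            write_intervals(
                [r.interval for r in tes], ds_out / f"{stem}_TE.bed",
                scores=[r.signal for r in tes],
            )
            emitted_counts[f"{ds.name}/{stem}_SE.bed"] = len(ses)
            emitted_counts[f"{ds.name}/{stem}_TE.bed"] = len(tes)
            if config.make_plots:
                result.plot_hockey_stick(
                    ds_out / f"{stem}_hockey.png", title=f"{ds.name} {cond_name}"
                )
            logger.info(
                "%s/%s: %d peaks -> %d stitched, %d SE / %d TE (cutoff %.1f)",
                ds.name, cond_name, len(peaks), len(result.regions),
                len(ses), len(tes), result.cutoff_value,
            )

        dyn = classify_dynamics(
            [r.interval for r in calls["control"].superenhancers],
            [r.interval for r in calls["treated"].superenhancers],
            min_overlap_frac=config.min_overlap_frac,
        )
        write_intervals(dyn.gain, ds_out / "gain.bed")
        write_intervals(dyn.lost, ds_out / "lost.bed")
        write_intervals([t for _, t in dyn.shared], ds_out / "shared.bed")
        emitted_counts[f"{ds.name}/gain.bed"] = len(dyn.gain)
        emitted_counts[f"{ds.name}/lost.bed"] = len(dyn.lost)
        emitted_counts[f"{ds.name}/shared.bed"] = len(dyn.shared)
        logger.info(
            "%s dynamics: %d gain, %d lost, %d shared",
            ds.name, len(dyn.gain), len(dyn.lost), len(dyn.shared),
        )
        gain_sets.append(dyn.gain)
        all_gain.extend(dyn.gain)
        all_lost.extend(dyn.lost)
        per_dataset[ds.name] = {
            "marker": ds.marker,
            "n_stitched_control": len(calls["control"].regions),
            "n_stitched_treated": len(calls["treated"].regions),
            "n_se_control": len(calls["control"].superenhancers),
            "n_se_treated": len(calls["treated"].superenhancers),
            "n_gain": len(dyn.gain),
            "n_lost": len(dyn.lost),
            "n_shared": len(dyn.shared),
        }

    labels = [ds.name for ds in config.datasets]
    if len(gain_sets) >= 2:
        cons = consensus_regions(
            gain_sets, min_overlap_frac=config.min_overlap_frac, labels=labels
        )
        consensus_ivs = cons.common_regions
    else:
        cons = None
        consensus_ivs = list(gain_sets[0])

    assignments = annotate_nearest_tss(consensus_ivs, genes) if consensus_ivs else []
    consensus_genes = sorted({a.gene_id for a in assignments})

    if config.venn_mode == "gene":
        # gene-level Venn: intersect nearest-TSS gene sets of the gain sets
        gene_sets = [
            {a.gene_id for a in annotate_nearest_tss(gs, genes)} for gs in gain_sets
        ]
        se_gene_set = set.intersection(*gene_sets) if gene_sets else set()
        logger.info("gene-mode Venn: %d common genes", len(se_gene_set))
    else:
        se_gene_set = set(consensus_genes)

    rows = []
    for iv, a in zip(consensus_ivs, assignments):
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "gene": a.gene_id,
                "tss_distance": a.distance,
            }
        )
    import pandas as pd

    pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "tss_distance"]).to_csv(
        out / "consensus.tsv", sep="\t", index=False
    )
    emitted_counts["consensus.tsv"] = len(rows)
    logger.info(
        "consensus: %d region(s), genes: %s", len(consensus_ivs), consensus_genes
    )

    deg_section: dict = {}
    candidates_section: dict = {}
    if config.deg_table is not None:
        input_checksums[str(config.deg_table)] = _sha256(config.deg_table)
        records = read_deg_table(config.deg_table)
        if any(r.qvalue is None for r in records):
            if any(r.pvalue is None for r in records):
                raise PipelineError(
                    "DEG table mixes missing p- and q-values; cannot adjust"
                )
            qvals = bh_adjust([r.pvalue for r in records])
            records = [
                dataclasses.replace(r, qvalue=float(q))
                for r, q in zip(records, qvals)
            ]
            logger.info("q-values filled by Benjamini-Hochberg adjustment")
        up, down = filter_degs(records, config.lfc_min, config.q_max)
        deg_section = {
            "n_records": len(records),
            "n_up": len(up),
            "n_down": len(down),
        }
        logger.info(
            "DEGs: %d records, %d up, %d down (|log2fc| >= %g, q <= %g)",
            len(records), len(up), len(down), config.lfc_min, config.q_max,
        )
        if config.disease_genes is not None:
            input_checksums[str(config.disease_genes)] = _sha256(config.disease_genes)
            disease = read_gene_list(config.disease_genes)
            rep = intersect_candidates(se_gene_set, up, disease)
            by_gene = {r.gene_id: r for r in records}
            cand_rows = [
                {
                    "gene": g,
                    "log2fc": by_gene[g].log2fc if g in by_gene else float("nan"),
                    "qvalue": by_gene[g].qvalue if g in by_gene else float("nan"),
                }
                for g in rep.candidates
            ]
            pd.DataFrame(cand_rows, columns=["gene", "log2fc", "qvalue"]).to_csv(
                out / "candidates.tsv", sep="\t", index=False
            )
            emitted_counts["candidates.tsv"] = len(cand_rows)
            candidates_section = {
                "genes": rep.candidates,
                "n": len(rep.candidates),
                "set_sizes": rep.provenance,
            }
            logger.info("candidate genes: %s", rep.candidates)

    audit = _audit(out, emitted_counts)
    return {
        "datasets": per_dataset,
        "gain_totals": {
            "per_dataset": {k: v["n_gain"] for k, v in per_dataset.items()},
            "union_raw": len(all_gain),
            "union_deduplicated": _dedup_union(all_gain),
        },
        "lost_totals": {
            "per_dataset": {k: v["n_lost"] for k, v in per_dataset.items()},
            "union_raw": len(all_lost),
            "union_deduplicated": _dedup_union(all_lost),
        },
        "consensus": {
            "mode": config.venn_mode,
            "n_regions": len(consensus_ivs),
            "regions": [
                [iv.chrom, iv.start, iv.end] for iv in consensus_ivs
            ],
            "genes": consensus_genes,
            "per_dataset_counts": cons.per_dataset_counts if cons else {},
        },
        "deg": deg_section,
        "candidates": candidates_section,
        "inputs": input_checksums,
        "audit": audit,
    }


def _audit(out: Path, expected: dict[str, int]) -> dict:
    """Recount emitted files and compare with the report's counts."""
    checks = {}
    ok = True
    for rel, n in expected.items():
        path = out / rel
        actual = _count_bed_lines(path)
        if rel.endswith(".tsv"):
            actual -= 1  # header
        match = actual == n
        ok = ok and match
        checks[rel] = {"expected": n, "actual": actual, "match": match}
    return {"self_consistent": ok, "checks": checks}
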