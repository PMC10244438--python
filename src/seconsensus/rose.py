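"""Super-enhancer identification: stitch, score, hockey-stick cutoff, partition.

The procedure follows the classic rank-signal approach: enhancer peaks whose
gaps are at most a stitching distance (12.5 kb by default) are merged into
stitched regions; regions are ranked by integrated signal; on the unit-scaled
rank-signal curve the cutoff sits where the curve's tangent has slope 1, and
regions with signal strictly above the cutoff are super-enhancers (SEs), the
rest typical enhancers (TEs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GeneModel, GenomicInterval, PeakSet
from .tracks import SignalTrack, region_signal

__all__ = [
    "StitchedRegion",
    "SECallResult",
    "stitch_peaks",
    "score_stitched",
    "find_se_cutoff",
    "call_superenhancers",
    "constituent_enhancers",
]

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_WINDOW = 2_500


@dataclass(slots=True)
class StitchedRegion:
    """A run of stitched peaks with its integrated signal score.

    ``constituent_ids`` index into the originating PeakSet (post TSS
    exclusion, in sorted order).  ``rank`` 1 is the highest-signal region.
    """

    interval: GenomicInterval
    constituent_ids: list[int]
    signal: float = 0.0
    rank: int | None = None

    @property
    def n_constituents(self) -> int:
        return len(self.constituent_ids)


def stitch_peaks(
    peaks: PeakSet,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: tuple[list[GeneModel], int] | None = None,
) -> list[StitchedRegion]:
    """Merge consecutive peaks whose gap is <= ``stitch_distance`` (inclusive).

    Peaks are processed per chromosome in sorted order; a peak joins the
    current region iff ``peak.start - region.end <= stitch_distance``.  With
    ``tss_exclusion=(genes, window)``, peaks lying entirely within any
    TSS +/- window are removed before stitching (promoter filtering, as in
    the original algorithm's optional mode).
    """
    if stitch_distance < 0:
        raise ValueError(f"stitch_distance must be >= 0, got {stitch_distance}")
    intervals = list(peaks)
    if tss_exclusion is not None:
        genes, window = tss_exclusion
        if window < 0:
            raise ValueError("tss exclusion window must be >= 0")
        zones: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            zones.setdefault(g.chrom, []).append(
                (g.tss - window, g.tss + window + 1)
            )
        intervals = [
            iv
            for iv in intervals
            if not any(
                iv.start >= z0 and iv.end <= z1 for z0, z1 in zones.get(iv.chrom, ())
            )
        ]
    regions: list[StitchedRegion] = []
    cur_ids: list[int] = []
    cur_chrom, cur_start, cur_end = None, 0, 0

    def flush():
        if cur_ids:
            regions.append(
                StitchedRegion(
                    interval=GenomicInterval(cur_chrom, cur_start, cur_end),
                    constituent_ids=list(cur_ids),
                )
            )

    for i, iv in enumerate(intervals):
        if iv.chrom == cur_chrom and iv.start - cur_end <= stitch_distance:
            cur_ids.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            cur_ids = [i]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    flush()
    return regions


def score_stitched(
    regions: list[StitchedRegion],
    track: SignalTrack,
    control: SignalTrack | None = None,
) -> list[StitchedRegion]:
    """Score each region by integrated signal and sort ascending.

    Ties are broken by (chrom, start) so the ranking is deterministic.
    Rank 1 is the highest-signal region.
    """
    scored = [
        StitchedRegion(
            interval=r.interval,
            constituent_ids=list(r.constituent_ids),
            signal=region_signal(track, r.interval, control),
        )
        for r in regions
    ]
    scored.sort(key=lambda r: (r.signal, r.interval.chrom, r.interval.start))
    n = len(scored)
    for pos, r in enumerate(scored):
        r.rank = n - pos
    return scored


def find_se_cutoff(signals) -> tuple[float, int]:
    """Locate the slope-1 tangent point on the scaled rank-signal curve.

    With ascending signals ``s`` of length ``n``, scale ``x_i = i/(n-1)`` and
    ``y_i = s_i / max(s)``; the cutoff index is ``argmin_i (y_i - x_i)`` (the
    point where the unit-slope line supports the curve from below), ties going
    to the largest index so flat or exactly-linear curves yield no SEs.
    Negative entries are clamped to zero; an all-zero curve is degenerate
    (cutoff 0 at the last index, no SEs).  Returns (cutoff_value, cutoff_index).
    """
    s = np.maximum(np.asarray(signals, dtype=float), 0.0)
    n = s.size
    if n < 2:
        raise ValueError(f"need at least 2 signals to place a cutoff, got {n}")
    if np.any(np.diff(s) < 0):
        raise ValueError("signals must be sorted ascending")
    smax = s[-1]
    if smax == 0.0:
        return 0.0, n - 1
    x = np.arange(n) / (n - 1)
    y = s / smax
    d = y - x
    # argmin with ties resolved to the LARGEST index
    idx = int(n - 1 - np.argmin(d[::-1]))
    return float(s[idx]), idx


@dataclass
class SECallResult:
    """Ranked stitched regions with the SE/TE partition.

    ``regions`` are sorted ascending by signal; ``is_super[i]`` is True iff
    ``regions[i].signal > cutoff_value``, so the SE set is a suffix of the
    ranking (the top-k by signal).
    """

    regions: list[StitchedRegion]
    cutoff_value: float
    cutoff_index: int
    is_super: np.ndarray
    scaled_x: np.ndarray
    scaled_y: np.ndarray

    @property
    def superenhancers(self) -> list[StitchedRegion]:
        return [r for r, s in zip(self.regions, self.is_super) if s]

    @property
    def typical_enhancers(self) -> list[StitchedRegion]:
        return [r for r, s in zip(self.regions, self.is_super) if not s]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [r.interval.chrom for r in self.regions],
                "start": [r.interval.start for r in self.regions],
                "end": [r.interval.end for r in self.regions],
                "n_constituents": [r.n_constituents for r in self.regions],
                "signal": [r.signal for r in self.regions],
                "rank": [r.rank for r in self.regions],
                "is_super": list(map(bool, self.is_super)),
            }
        )

    def plot_hockey_stick(self, path, title: str = "") -> None:
        """Rank-signal curve with the slope-1 cutoff marked (PNG)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        signals = np.array([r.signal for r in self.regions])
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(np.arange(signals.size), signals, lw=1.2, color="tab:red")
        ax.axhline(self.cutoff_value, ls="--", lw=0.8, color="grey")
        ax.axvline(self.cutoff_index, ls="--", lw=0.8, color="grey")
        n_se = int(self.is_super.sum())
        ax.set_xlabel("stitched enhancers ranked by signal")
        ax.set_ylabel("signal (value × bp)")
        ax.set_title(title or f"{n_se} SEs / {signals.size} stitched regions")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def call_superenhancers(
    peaks: PeakSet,
    track: SignalTrack,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    control: SignalTrack | None = None,
    tss_exclusion: tuple[list[GeneModel], int] | None = None,
) -> SECallResult:
    """Full SE call: stitch -> score -> slope-1 cutoff -> SE/TE partition.

    The comparison against the cutoff is strict (``signal > cutoff_value``),
    so the tangent-point region itself is a TE.  Membership is invariant to
    positive rescaling of the track since the cutoff works on the unit-scaled
    curve.
    """
    stitched = stitch_peaks(peaks, stitch_distance, tss_exclusion)
    scored = score_stitched(stitched, track, control)
    signals = np.array([r.signal for r in scored], dtype=float)
    if signals.size == 0:
        return SECallResult(
            regions=[],
            cutoff_value=0.0,
            cutoff_index=0,
            is_super=np.zeros(0, dtype=bool),
            scaled_x=np.zeros(0),
            scaled_y=np.zeros(0),
        )
    if signals.size == 1:
        # a single region cannot define a curve; conservatively a TE
        return SECallResult(
            regions=scored,
            cutoff_value=float(signals[0]),
            cutoff_index=0,
            is_super=np.zeros(1, dtype=bool),
            scaled_x=np.zeros(1),
            scaled_y=np.ones(1),
        )
    cutoff_value, cutoff_index = find_se_cutoff(signals)
    n = signals.size
    smax = signals.max()
    scaled_x = np.arange(n) / (n - 1)
    scaled_y = signals / smax if smax > 0 else np.zeros(n)
    return SECallResult(
        regions=scored,
        cutoff_value=cutoff_value,
        cutoff_index=cutoff_index,
        is_super=signals > cutoff_value,
        scaled_x=scaled_x,
        scaled_y=scaled_y,
    )


def constituent_enhancers(se: StitchedRegion, peaks: PeakSet) -> list[GenomicInterval]:
    """Peaks overlapping the SE interval by >= 1 bp, sorted by start.

    Used to decompose an SE into candidate component enhancers, e.g. from
    chromatin-accessibility peaks over the same locus.
    """
    hits = [iv for iv in peaks if iv.overlaps(se.interval)]
    hits.sort(key=GenomicInterval.sort_key)
    return hits
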