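"""Binned coverage tracks: RPKM normalization, region signal, profile matrices.

A :class:`SignalTrack` stores fixed-width binned coverage per chromosome.
Bin ``i`` of chromosome ``c`` covers ``[i*w, (i+1)*w)`` bp.  Positions past
the end of a chromosome's array, and whole chromosomes absent from the track,
read as zero signal (with a warning for absent chromosomes, since mixed
marker/assembly inputs make a hard failure impractical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval, PeakSet

__all__ = [
    "SignalTrack",
    "ProfileMatrix",
    "rpkm_normalize",
    "region_signal",
    "profile_matrix",
]

logger = logging.getLogger(__name__)

RAW = "raw"
RPKM = "RPKM"


@dataclass
class SignalTrack:
    """Fixed-width binned coverage, one float array per chromosome."""

    bins: dict[str, np.ndarray]
    bin_width: int
    library_size: float | None = None
    normalized: str = RAW
    _warned: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError(f"bin_width must be >= 1, got {self.bin_width}")
        if self.normalized not in (RAW, RPKM):
            raise ValueError(f"normalized must be {RAW!r} or {RPKM!r}")
        if self.normalized == RPKM and self.library_size is None:
            raise ValueError("an RPKM track must record its library_size")
        for chrom, arr in self.bins.items():
            arr = np.asarray(arr, dtype=float)
            if self.normalized == RAW and arr.size and arr.min() < 0:
                raise ValueError(f"negative bin value on {chrom} in a raw track")
            self.bins[chrom] = arr

    def chrom_array(self, chrom: str) -> np.ndarray | None:
        arr = self.bins.get(chrom)
        if arr is None and chrom not in self._warned:
            self._warned.add(chrom)
            logger.warning(
                "chromosome %r absent from track; treating as all-zero signal", chrom
            )
        return arr

    def total_mass(self) -> float:
        """Integrated signal, sum of (bin value x bin width) over all bins."""
        return float(sum(a.sum() for a in self.bins.values()) * self.bin_width)


def rpkm_normalize(track: SignalTrack, library_size: float) -> SignalTrack:
    """Convert per-bin read counts to RPKM.

    Each bin count ``c`` becomes ``c * 1e9 / (bin_width * library_size)`` —
    reads per kilobase of bin per million mapped reads.
    """
    if track.normalized != RAW:
        raise ValueError("track is already normalized; refusing to normalize twice")
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    factor = 1e9 / (track.bin_width * library_size)
    bins = {c: a * factor for c, a in track.bins.items()}
    return SignalTrack(
        bins=bins,
        bin_width=track.bin_width,
        library_size=library_size,
        normalized=RPKM,
    )


def _interval_mass(arr: np.ndarray, w: int, start: float, end: float) -> float:
    """Integral of the piecewise-constant track over ``[start, end)`` in value*bp.

    Fractional bounds are allowed (profile sampling needs them); out-of-array
    positions contribute zero.
    """
    start = max(float(start), 0.0)
    end = min(float(end), float(len(arr)) * w)
    if end <= start:
        return 0.0
    i0 = int(start // w)
    i1 = int(np.ceil(end / w)) - 1
    if i0 == i1:
        return float(arr[i0]) * (end - start)
    mass = float(arr[i0]) * ((i0 + 1) * w - start) + float(arr[i1]) * (end - i1 * w)
    if i1 > i0 + 1:
        mass += float(arr[i0 + 1 : i1].sum()) * w
    return mass


def region_signal(
    track: SignalTrack,
    region: GenomicInterval,
    control: SignalTrack | None = None,
) -> float:
    """Signal area (value x bp) of *track* over *region*, optionally control-subtracted.

    The integral is the sum over bins overlapping the region of
    bin value times overlapped width.  With a control track, the control's
    area over the same region is subtracted and the result is clamped at 0.
    """
    if control is not None and control.bin_width != track.bin_width:
        raise ValueError(
            f"control bin_width {control.bin_width} != track bin_width {track.bin_width}"
        )
    arr = track.chrom_array(region.chrom)
    area = 0.0 if arr is None else _interval_mass(arr, track.bin_width, region.start, region.end)
    if control is not None:
        carr = control.chrom_array(region.chrom)
        carea = 0.0 if carr is None else _interval_mass(
            carr, control.bin_width, region.start, region.end
        )
        area = max(0.0, area - carea)
    return area


def _sample_window(
    arr: np.ndarray | None, w: int, start: float, end: float, n: int
) -> np.ndarray:
    """Mean signal in *n* equal sub-windows of ``[start, end)``; off-track reads 0."""
    out = np.zeros(n)
    if arr is None or end <= start:
        return out
    step = (end - start) / n
    for k in range(n):
        out[k] = _interval_mass(arr, w, start + k * step, start + (k + 1) * step) / step
    return out


REFERENCE_POINT = "reference-point"
SCALE_REGIONS = "scale-regions"


@dataclass
class ProfileMatrix:
    """Signal profiles around/over a set of regions, one row per region.

    ``offsets`` labels the columns: bp relative to the region center in
    reference-point mode; in scale-regions mode flank columns carry bp
    offsets from the region edges and body columns fractional positions.
    """

    values: np.ndarray
    mode: str
    flank: int
    n_body_bins: int
    offsets: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=self.offsets or None).to_csv(
            path, sep="\t", index=False
        )

    def plot_heatmap(self, path, cmap: str = "Reds") -> None:
        """Render rows (ordered by descending mean) as a heatmap PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = np.argsort(-self.values.mean(axis=1), kind="stable")
        fig, ax = plt.subplots(figsize=(4, 6))
        ax.imshow(self.values[order], aspect="auto", cmap=cmap, interpolation="nearest")
        ax.set_xlabel("position bin")
        ax.set_ylabel("region (by descending mean)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def profile_matrix(
    track: SignalTrack,
    regions: PeakSet | list[GenomicInterval],
    mode: str = REFERENCE_POINT,
    flank: int = 5000,
    n_bins: int = 50,
    n_flank_bins: int | None = None,
) -> ProfileMatrix:
    """Build a computeMatrix-style profile matrix.

    reference-point: each row samples ``[center - flank, center + flank)``
    into ``n_bins`` equal windows, center = ``floor((start+end)/2)``.
    scale-regions: the region body is rescaled into ``n_bins`` windows with
    ``n_flank_bins`` (default ``n_bins // 2``) windows per flank on each side.
    Rows of minus-strand regions are reversed; out-of-bounds positions read 0.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if mode not in (REFERENCE_POINT, SCALE_REGIONS):
        raise ValueError(f"unknown mode {mode!r}")
    ivs = list(regions)
    if n_flank_bins is None:
        n_flank_bins = n_bins // 2 if flank > 0 else 0
    if flank == 0:
        n_flank_bins = 0

    if mode == REFERENCE_POINT:
        ncol = n_bins
        offsets = [
            str(int(-flank + (k + 0.5) * (2 * flank) / n_bins)) for k in range(n_bins)
        ]
    else:
        ncol = n_bins + 2 * n_flank_bins
        offsets = (
            [f"u{-flank + k * flank // max(n_flank_bins,1)}" for k in range(n_flank_bins)]
            + [f"b{k}" for k in range(n_bins)]
            + [f"d{k * flank // max(n_flank_bins,1)}" for k in range(n_flank_bins)]
        )
    values = np.zeros((len(ivs), ncol))
    w = track.bin_width
    for r, iv in enumerate(ivs):
        arr = track.chrom_array(iv.chrom)
        if mode == REFERENCE_POINT:
            c = iv.center
            row = _sample_window(arr, w, c - flank, c + flank, n_bins)
        else:
            parts = [
                _sample_window(arr, w, iv.start - flank, iv.start, n_flank_bins)
                if n_flank_bins
                else np.empty(0),
                _sample_window(arr, w, iv.start, iv.end, n_bins),
                _sample_window(arr, w, iv.end, iv.end + flank, n_flank_bins)
                if n_flank_bins
                else np.empty(0),
            ]
            row = np.concatenate(parts)
        if iv.strand == "-":
            row = row[::-1]
        values[r] = row
    return ProfileMatrix(
        values=values, mode=mode, flank=flank, n_body_bins=n_bins, offsets=offsets
    )
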