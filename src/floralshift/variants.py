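"""Genome-wide variant-density profiling.

Called variants (one VCF per within-species comparison) are binned into
fixed-width windows tiling each chromosome, and the per-window counts are
smoothed with a centred second-order (quadratic) local least-squares fit
over a symmetric neighbourhood — the Savitzky-Golay convention, with the
neighbourhood shrunk symmetrically at chromosome ends. Two species' smoothed
tracks on the same windowing grid can then be overlaid and compared
per chromosome.

Variant input positions are 1-based (the variant-format standard); windows
are stored 0-based half-open. Every record at a site counts once — a
site-count, not an allele-count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("floralshift.variants")


@dataclass(frozen=True)
class VariantWindowTrack:
    """Per-window variant counts along one chromosome.

    Windows tile [0, chromosome_length) without gaps or overlap; the last
    window may be short. ``counts[i]`` covers
    [i*window_size, min((i+1)*window_size, length)).
    """

    chromosome: str
    chromosome_length: int
    window_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if np.any(counts < 0):
            raise ValueError("window counts must be >= 0")
        expected = n_windows(self.chromosome_length, self.window_size)
        if counts.size != expected:
            raise ValueError(
                f"{counts.size} windows given, {expected} needed to tile "
                f"{self.chromosome} of length {self.chromosome_length}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.counts.size, dtype=int) * self.window_size

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window_size, self.chromosome_length)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "start": self.starts,
                "end": self.ends,
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class SmoothConfig:
    """Neighbourhood for local quadratic smoothing.

    ``neighbors`` windows on EACH side (so 2*neighbors + 1 points in the
    full interior window)."""

    neighbors: int = 50
    polynomial_order: int = 2

    def __post_init__(self) -> None:
        if 2 * self.neighbors + 1 <= self.polynomial_order:
            raise ValueError("window length 2*neighbors+1 must exceed polynomial_order")


def n_windows(length: int, window_size: int) -> int:
    if length <= 0 or window_size <= 0:
        raise ValueError("length and window_size must be > 0")
    return -(-length // window_size)  # ceil division


def window_counts(
    positions: Sequence[int], chromosome: str, chromosome_length: int, window_size: int
) -> VariantWindowTrack:
    """Bin 1-based variant positions into fixed windows.

    A variant at 1-based position p falls in the window containing 0-based
    coordinate p-1. Total count is conserved.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size:
        bad = (pos < 1) | (pos > chromosome_length)
        if np.any(bad):
            raise ValueError(
                f"positions outside [1, {chromosome_length}] on {chromosome}: "
                f"{pos[bad][:5].tolist()}"
            )
    nw = n_windows(chromosome_length, window_size)
    counts = np.bincount((pos - 1) // window_size, minlength=nw) if pos.size else np.zeros(nw, int)
    return VariantWindowTrack(
        chromosome=chromosome,
        chromosome_length=chromosome_length,
        window_size=window_size,
        counts=counts,
    )


def smooth_values(values: Sequence[float], config: SmoothConfig = SmoothConfig()) -> np.ndarray:
    """Centred local least-squares polynomial smoothing with symmetric edge
    shrinkage.

    At interior index i the value is the order-``polynomial_order`` fit over
    the 2*neighbors+1 surrounding points evaluated at i (Savitzky-Golay).
    Near the ends the half-window shrinks to min(neighbors, i, n-1-i) so the
    fit stays centred; with fewer points than the order allows, the order
    drops to fit. Polynomials of degree <= polynomial_order are reproduced
    exactly in the interior.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n == 1:
        warnings.warn("single-window track: returned unchanged", stacklevel=2)
        return y.copy()
    half = config.neighbors
    if n < 2 * half + 1:
        half = (n - 1) // 2
        logger.info("track shorter than smoothing window; neighbors shrunk to %d", half)
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        if h == 0:
            out[i] = y[i]
            continue
        window = y[i - h : i + h + 1]
        deg = min(config.polynomial_order, 2 * h)
        x = np.arange(-h, h + 1, dtype=float)
        coeffs = np.polynomial.polynomial.polyfit(x, window, deg)
        out[i] = coeffs[0]  # value of the fit at the centre, x = 0
    return out


def smooth_track(track: VariantWindowTrack, config: SmoothConfig = SmoothConfig()) -> np.ndarray:
    """Smoothed per-window values of a variant track."""
    return smooth_values(track.counts, config)


def overlay_summary(
    track_a: VariantWindowTrack,
    track_b: VariantWindowTrack,
    config: SmoothConfig = SmoothConfig(),
) -> dict:
    """Compare two species' tracks on the same windowing grid.

    Returns per-window differences of the smoothed tracks and their
    Spearman rank correlation for the chromosome.
    """
    if (
        track_a.window_size != track_b.window_size
        or track_a.chromosome_length != track_b.chromosome_length
        or track_a.counts.size != track_b.counts.size
    ):
        raise ValueError("tracks are on mismatched windowing grids")
    sa = smooth_track(track_a, config)
    sb = smooth_track(track_b, config)
    if np.allclose(sa, sa[0]) or np.allclose(sb, sb[0]):
        rho = 1.0 if np.allclose(sa - sa[0], sb - sb[0]) else float("nan")
    else:
        rho = float(stats.spearmanr(sa, sb).statistic)
    return {
        "chromosome": track_a.chromosome,
        "difference": sa - sb,
        "rank_correlation": rho,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fai(path) -> dict[str, int]:
    """Chromosome lengths from a FASTA index (.fai) table."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_vcf_positions(path) -> dict[str, np.ndarray]:
    """1-based variant site positions per chromosome from a VCF
    (optionally gzip-compressed). Each record counts once."""
    from cyvcf2 import VCF

    positions: dict[str, list[int]] = {}
    for rec in VCF(str(path)):
        positions.setdefault(rec.CHROM, []).append(rec.POS)
    return {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}


def genome_tracks(
    vcf_path, fai_path, window_size: int
) -> dict[str, VariantWindowTrack]:
    """Windowed variant counts for every chromosome in the length table."""
    lengths = read_fai(fai_path)
    positions = read_vcf_positions(vcf_path)
    unknown = set(positions) - set(lengths)
    if unknown:
        raise ValueError(f"VCF chromosomes missing from length table: {sorted(unknown)}")
    return {
        chrom: window_counts(positions.get(chrom, []), chrom, length, window_size)
        for chrom, length in lengths.items()
    }
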