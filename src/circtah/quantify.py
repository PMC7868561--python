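"""Expression and promoter-activity scores for circRNAs and their host genes.

Three scores drive the whole analysis:

* back-splice RPM: junction-spanning reads per million raw reads — the only
  reads unambiguously attributable to the circle;
* back-splice RPKM: RPM / 112 × 1000, where 112 bp is the effective
  junction-detection length of a 75 bp read with 20 bp anchors on either
  side (a fixed normalisation constant, exposed as a parameter);
* RPKM_body = 10^9·m/(n·L): conventional read-density RPKM over a linear
  region of length L with m reads out of n total;
* RPKM_ss = 10^9·C/(2000·N): promoter activity, the H3K27ac read count C
  falling in ±1 kb of a TSS normalised by the 2 kb window and library size N.

C is derived from coverage as (coverage sum over the window) / read length,
so every score is computable from a bedGraph plus its library size.  When a
TSS sits near a chromosome edge the window is clipped but the denominator
stays 2000 (the constant in the score's definition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenomicInterval, SignalTrack

#: effective junction-detection length (bp) used to convert RPM to RPKM
BACKSPLICE_EFFECTIVE_LENGTH = 112.0

#: promoter-activity window half-width (bp) around the TSS
SS_HALF_WIDTH = 1000

#: default simulated/assumed read length (bp) for coverage-to-reads conversion
DEFAULT_READ_LENGTH = 75


@dataclass
class ExpressionRecord:
    """Per-feature expression summary."""

    feature_id: str
    junction_read_count: float = 0.0
    rpm: float = 0.0
    rpkm: float = 0.0
    rpkm_body: float = 0.0


def rpm_backsplice(junction_reads: float, total_reads: float) -> float:
    """Back-splice junction reads per million raw reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if junction_reads < 0:
        raise ValueError("junction_reads must be >= 0")
    return junction_reads / total_reads * 1e6


def rpkm_backsplice(
    rpm: float, effective_length: float = BACKSPLICE_EFFECTIVE_LENGTH
) -> float:
    """Convert back-splice RPM to RPKM via the effective junction length."""
    if rpm < 0:
        raise ValueError("rpm must be >= 0")
    if effective_length <= 0:
        raise ValueError("effective_length must be > 0")
    return rpm / effective_length * 1000.0


def rpkm_body(body_reads: float, total_reads: float, length: float) -> float:
    """Read-density RPKM: 10^9 * m / (n * L)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if length <= 0:
        raise ValueError("length must be > 0")
    if body_reads < 0:
        raise ValueError("body_reads must be >= 0")
    return 1e9 * body_reads / (total_reads * length)


def rpkm_ss(
    track: SignalTrack,
    chrom: str,
    tss: int,
    read_length: float = DEFAULT_READ_LENGTH,
    half_width: int = SS_HALF_WIDTH,
) -> float:
    """Promoter activity: 10^9 * C / (2*half_width * N).

    C = (coverage sum over [tss-half_width, tss+half_width)) / read_length.
    The window is clipped at position 0 but the denominator keeps the full
    window length.
    """
    start = max(0, tss - half_width)
    end = tss + half_width
    c = track.interval_sum(chrom, start, end) / read_length
    return 1e9 * c / (2.0 * half_width * track.total_reads)


def interval_mean_signal(track: SignalTrack, interval: GenomicInterval) -> float:
    """Arithmetic mean of a per-base score over an interval (unscored bp = 0).

    Generic summary used for conservation and DNase accessibility tracks.
    """
    length = interval.end - interval.start
    if length <= 0:
        raise ValueError("zero-length interval")
    return track.interval_sum(interval.chrom, interval.start, interval.end) / length


def metagene_profile(
    track: SignalTrack,
    tss_list: list[tuple[str, int, str]],
    half_width: int = 2000,
    bin_size: int = 50,
) -> np.ndarray:
    """Strand-oriented mean coverage profile around a list of TSSs.

    Each TSS contributes its per-bp coverage over ±``half_width``, binned at
    ``bin_size`` bp and oriented so upstream is on the left regardless of
    strand.  The mean across TSSs is normalised per million total reads.
    Returns an array of ``2*half_width/bin_size`` bin means.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    if half_width % bin_size != 0:
        raise ValueError("half_width must be a multiple of bin_size")
    nbins = 2 * half_width // bin_size
    acc = np.zeros(nbins, dtype=float)
    for chrom, tss, strand in tss_list:
        start = tss - half_width
        vals = np.zeros(2 * half_width, dtype=float)
        lo = max(0, start)
        seg = track.interval_values(chrom, lo, tss + half_width)
        vals[lo - start :] = seg
        if strand == "-":
            vals = vals[::-1]
        acc += vals.reshape(nbins, bin_size).mean(axis=1)
    return acc / len(tss_list) / (track.total_reads / 1e6)
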