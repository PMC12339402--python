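"""Spike-in scale factors and (normalized) RPKM binned coverage.

CUT&RUN releases target-bound fragments; a fixed exogenous spike-in lets
samples be compared quantitatively. The scale factor is an arbitrary
per-antibody constant divided by the properly-paired spike-in read count,
and is applied multiplicatively to RPKM binned coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import Config
from .core import BinnedSignalTrack, Genome, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaleFactor:
    """s = C / n_spikein for one sample of one antibody."""

    mark: str
    constant: float
    n_spikein: int

    def __post_init__(self) -> None:
        if self.n_spikein <= 0:
            raise ValueError("n_spikein must be > 0")
        if self.constant <= 0:
            raise ValueError("constant must be > 0")

    @property
    def value(self) -> float:
        return self.constant / self.n_spikein


@dataclass
class FragmentSet:
    """Target-genome fragments plus the sample's spike-in read count.

    total_mapped (M) is the RPKM "per million" denominator; it always equals
    the number of fragments.
    """

    fragments: List[GenomicInterval]
    n_spikein: int

    def __post_init__(self) -> None:
        if self.n_spikein < 0:
            raise ValueError("n_spikein must be >= 0")

    @property
    def total_mapped(self) -> int:
        return len(self.fragments)


def compute_scale_factor(mark: str, n_spikein: int, config: Config) -> ScaleFactor:
    """Scale factor = antibody constant / spike-in read count.

    A zero spike-in count is an explicit error: no pseudo-count is applied.
    """
    if mark not in config.antibody_constants:
        known = ", ".join(sorted(config.antibody_constants))
        raise KeyError(f"unknown mark {mark!r}; known marks: {known}")
    if n_spikein == 0:
        raise ValueError(f"{mark}: spike-in read count is zero; cannot scale")
    return ScaleFactor(mark, config.antibody_constants[mark], n_spikein)


def bin_counts(
    fragments: Sequence[GenomicInterval],
    genome: Genome,
    bin_size: int,
) -> Dict[str, np.ndarray]:
    """Count fragments per bin, each assigned once by its midpoint."""
    counts = {c: np.zeros(genome.n_bins(c, bin_size), dtype=np.int64) for c in genome}
    for frag in fragments:
        if frag.chrom not in genome:
            raise ValueError(f"fragment on unknown chromosome {frag.chrom!r}")
        if frag.end > genome[frag.chrom]:
            raise ValueError(
                f"fragment {frag.chrom}:{frag.start}-{frag.end} beyond "
                f"chromosome length {genome[frag.chrom]}"
            )
        mid = (frag.start + frag.end) // 2
        counts[frag.chrom][mid // bin_size] += 1
    return counts


def blacklist_mask(
    genome: Genome, bin_size: int, blacklist: Optional[Sequence[GenomicInterval]]
) -> Dict[str, np.ndarray]:
    """Valid-bin mask: any overlap with a blacklist interval masks the bin."""
    mask = {c: np.ones(genome.n_bins(c, bin_size), dtype=bool) for c in genome}
    for iv in blacklist or ():
        if iv.chrom not in genome:
            continue
        first = iv.start // bin_size
        last = (min(iv.end, genome[iv.chrom]) - 1) // bin_size
        mask[iv.chrom][first : last + 1] = False
    return mask


def rpkm_from_counts(
    counts: Dict[str, np.ndarray],
    genome: Genome,
    bin_size: int,
    total_mapped: int,
    mask: Optional[Dict[str, np.ndarray]] = None,
) -> BinnedSignalTrack:
    """RPKM_bin = c_bin / ((L_bin/1000) * (M/1e6)); L_bin is the actual bin
    length, so final partial bins are normalized by their true length."""
    if total_mapped <= 0:
        raise ValueError("total mapped fragment count M must be > 0")
    values = {}
    for chrom in genome:
        L_kb = genome.bin_lengths(chrom, bin_size) / 1000.0
        values[chrom] = counts[chrom] / (L_kb * (total_mapped / 1e6))
    return BinnedSignalTrack(genome, bin_size, values, mask)


def bin_rpkm(
    fragments: FragmentSet,
    genome: Genome,
    bin_size: int,
    blacklist: Optional[Sequence[GenomicInterval]] = None,
) -> BinnedSignalTrack:
    """Midpoint-binned RPKM coverage with blacklist bins masked invalid.

    Each fragment lands in exactly one bin, so valid-bin counts plus
    masked-bin counts conserve the total fragment number exactly.
    """
    counts = bin_counts(fragments.fragments, genome, bin_size)
    mask = blacklist_mask(genome, bin_size, blacklist)
    track = rpkm_from_counts(counts, genome, bin_size, fragments.total_mapped, mask)
    n_masked = sum(int((~mask[c]).sum()) for c in genome)
    logger.info(
        "bin_rpkm: %d fragments, %d bp bins, %d bins masked by blacklist",
        fragments.total_mapped, bin_size, n_masked,
    )
    return track


def normalize_track(track: BinnedSignalTrack, s: ScaleFactor | float) -> BinnedSignalTrack:
    """Multiply every valid bin by the scale factor; the mask is preserved."""
    factor = s.value if isinstance(s, ScaleFactor) else float(s)
    values = {c: track.values[c] * factor for c in track.genome}
    return BinnedSignalTrack(track.genome, track.bin_size, values, track.mask)


def average_tracks(tracks: Sequence[BinnedSignalTrack]) -> BinnedSignalTrack:
    """Per-bin arithmetic mean; a bin invalid in any input is invalid out."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t):
            raise ValueError("tracks are on different genomes or bin grids")
    values, mask = {}, {}
    for chrom in first.genome:
        m = np.logical_and.reduce([t.mask[chrom] for t in tracks])
        stacked = np.vstack([t.values[chrom] for t in tracks])
        v = np.full(m.shape, np.nan)
        v[m] = stacked[:, m].mean(axis=0)
        values[chrom], mask[chrom] = v, m
    return BinnedSignalTrack(first.genome, first.bin_size, values, mask)


def yield_ratio(total_mapped: int, n_spikein: int) -> float:
    """Target-fragment : spike-in read ratio, a proxy for the quantitative
    yield of released DNA relative to the fixed spike-in input."""
    if n_spikein == 0:
        raise ValueError("spike-in read count is zero")
    return total_mapped / n_spikein
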