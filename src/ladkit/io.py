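"""Readers and writers for the standard text formats the pipeline touches.

BED3/BED4 for domains, genes and blacklists; bedGraph for binned signal
tracks; two-column TSV for chromosome sizes. Every writer emits files its
paired reader parses back to an equal value.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .core import BinnedSignalTrack, DomainSet, Genome, GenomicInterval

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


def read_genome(path: str | Path) -> Genome:
    """Read a chrom-sizes TSV (name<TAB>length)."""
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected name<TAB>length")
        try:
            pairs.append((fields[0], int(fields[1])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return Genome(pairs)


def write_genome(genome: Genome, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{length}\n" for c, length in genome.items())
    )


def read_intervals(path: str | Path, format: str = "BED") -> List[GenomicInterval]:
    """Read intervals from BED (0-based half-open) or GTF-lite TSV.

    GTF-lite TSV has columns chrom, start, end[, name] with 1-based inclusive
    coordinates, converted to 0-based half-open at this boundary. File order
    is preserved.
    """
    if format not in ("BED", "GTF-lite-TSV"):
        raise ValueError(f"unknown interval format {format!r}")
    one_based = format == "GTF-lite-TSV"
    out: List[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if one_based:
            start -= 1
        label = fields[3] if len(fields) > 3 and fields[3] != "" else None
        try:
            out.append(GenomicInterval(chrom, start, end, label))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3/BED4 in the given order."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def write_domains(domains: DomainSet, path: str | Path) -> None:
    """Write a DomainSet as BED, sorted by (chrom, start).

    DomainSet construction already sorts; re-sorting here keeps the output
    deterministic even for hand-built inputs.
    """
    ivs = sorted(domains.intervals, key=lambda iv: (iv.chrom, iv.start))
    if ivs != domains.intervals:
        logger.info("write_domains: input not sorted; sorted on output")
    write_intervals(ivs, path)


def read_domains(
    path: str | Path, mark: str = "", sample: str = ""
) -> DomainSet:
    return DomainSet(mark=mark, sample=sample, intervals=read_intervals(path))


def read_binned_track(
    path: str | Path, genome: Genome, bin_size: int
) -> BinnedSignalTrack:
    """Read a bedGraph whose records are aligned to the bin grid.

    Unlisted bins are invalid (masked). Records must start on a bin boundary
    and end on the next boundary (or at the chromosome end for the final
    partial bin).
    """
    track = BinnedSignalTrack.empty(genome, bin_size)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected chrom/start/end/value")
        chrom = fields[0]
        if chrom not in genome:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        L = genome[chrom]
        if end > L:
            raise ValueError(
                f"{path}:{lineno}: record end {end} beyond {chrom} length {L}"
            )
        if start % bin_size != 0:
            raise ParseError(
                f"{path}:{lineno}: start {start} not aligned to {bin_size} bp grid"
            )
        idx = start // bin_size
        expected_end = min(start + bin_size, L)
        if end != expected_end:
            raise ParseError(
                f"{path}:{lineno}: record [{start},{end}) does not span one bin "
                f"(expected end {expected_end})"
            )
        track.values[chrom][idx] = value
        track.mask[chrom][idx] = True
    for chrom in genome:
        vals = track.values[chrom]
        if np.any(vals[track.mask[chrom]] < 0):
            raise ValueError(f"{path}: negative signal on {chrom}")
    return track


def write_binned_track(track: BinnedSignalTrack, path: str | Path) -> None:
    """Write valid bins as bedGraph records (one record per bin)."""
    with open(path, "w") as fh:
        for chrom in track.genome:
            L = track.genome[chrom]
            b = track.bin_size
            for i in np.flatnonzero(track.mask[chrom]):
                start = int(i) * b
                end = min(start + b, L)
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{float(track.values[chrom][i])!r}\n"
                )
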