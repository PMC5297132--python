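"""Readers and writers for mapped-read and track files.

Input formats are BED3/BED6 (tab-separated, 0-based half-open) and the legacy
bowtie default text output. Occupancy tracks are written as bedGraph and DNR
calls as a BED6+3 table. All coordinates are 0-based half-open internally and
in every file this package writes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger("dimnp")

__all__ = [
    "AlignedRead",
    "FragmentSet",
    "read_bed",
    "read_bowtie",
    "pair_mates",
    "write_occupancy",
    "read_occupancy",
    "write_dnrs",
]


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read (or mate-joined fragment).

    Coordinates are 0-based half-open; ``strand`` is ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid read span [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentSet:
    """Chromosome-indexed collection of reads for one sample.

    ``chrom_lengths`` defaults to the maximum observed end per chromosome; a
    chrom-sizes mapping may be supplied to fix the coordinate frame, in which
    case reads on unknown chromosomes are dropped (with a logged count) and a
    read extending past the stated length is an error.
    """

    reads: dict[str, list[AlignedRead]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    sample_id: str = ""

    def add(self, read: AlignedRead) -> None:
        self.reads.setdefault(read.chrom, []).append(read)
        if read.end > self.chrom_lengths.get(read.chrom, 0):
            self.chrom_lengths[read.chrom] = read.end

    def __len__(self) -> int:
        return sum(len(v) for v in self.reads.values())

    def __iter__(self) -> Iterator[AlignedRead]:
        for chrom in sorted(self.reads):
            yield from self.reads[chrom]

    def restrict(self, chrom_sizes: dict[str, int]) -> "FragmentSet":
        """Return a copy on the coordinate frame given by ``chrom_sizes``."""
        out = FragmentSet(chrom_lengths=dict(chrom_sizes), sample_id=self.sample_id)
        dropped = 0
        for chrom, reads in self.reads.items():
            if chrom not in chrom_sizes:
                dropped += len(reads)
                continue
            length = chrom_sizes[chrom]
            for r in reads:
                if r.end > length:
                    raise ValueError(
                        f"read ends at {r.end} past stated length {length} of {chrom}"
                    )
            out.reads[chrom] = list(reads)
        if dropped:
            logger.warning("dropped %d reads on chromosomes absent from chrom sizes", dropped)
        return out


def _from_reads(reads: Iterable[AlignedRead], sample_id: str = "") -> FragmentSet:
    fs = FragmentSet(sample_id=sample_id)
    for r in reads:
        fs.add(r)
    return fs


def read_bed(path: str | os.PathLike, sample_id: str | None = None) -> FragmentSet:
    """Parse a BED3/BED6 file of mapped reads.

    Columns beyond the first three are optional; a missing strand column
    defaults to ``+`` (warned once). Malformed coordinates raise with the
    offending line number; an empty file is an error.
    """
    fs = FragmentSet(sample_id=sample_id or os.path.basename(os.fspath(path)))
    missing_strand = 0
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: fewer than 3 columns at line {lineno}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer coordinates at line {lineno}"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}: start >= end at line {lineno}")
            if start < 0:
                raise ValueError(f"{path}: negative start at line {lineno}")
            if len(cols) >= 6 and cols[5] in ("+", "-"):
                strand = cols[5]
            else:
                strand = "+"
                missing_strand += 1
            name = cols[3] if len(cols) >= 4 else None
            fs.add(AlignedRead(cols[0], start, end, strand, name))
            n += 1
    if n == 0:
        raise ValueError(f"{path}: no reads found")
    if missing_strand:
        logger.warning(
            "%s: %d lines lacked a strand column; defaulted to '+'", path, missing_strand
        )
    return fs


def read_bowtie(path: str | os.PathLike, sample_id: str | None = None) -> FragmentSet:
    """Parse legacy bowtie default text output.

    Columns: read name, strand, reference, 0-based offset, sequence,
    qualities, ... ; the read span is [offset, offset + len(sequence)).
    """
    fs = FragmentSet(sample_id=sample_id or os.path.basename(os.fspath(path)))
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}: fewer than 5 columns at line {lineno}")
            name, strand, chrom, offset, seq = cols[0], cols[1], cols[2], cols[3], cols[4]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: invalid strand {strand!r} at line {lineno}")
            try:
                start = int(offset)
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer offset at line {lineno}") from exc
            if not seq:
                raise ValueError(f"{path}: empty sequence at line {lineno}")
            fs.add(AlignedRead(chrom, start, start + len(seq), strand, name))
            n += 1
    if n == 0:
        raise ValueError(f"{path}: no reads found")
    return fs


def pair_mates(fragments: FragmentSet) -> FragmentSet:
    """Join mate pairs (identical name field) into single fragments.

    Each pair becomes one fragment spanning leftmost start to rightmost end;
    unpaired reads are dropped with a logged count. If no pair can be formed
    at all this raises, suggesting single-end mode.
    """
    out = FragmentSet(sample_id=fragments.sample_id)
    unpaired = 0
    paired = 0
    for chrom in sorted(fragments.reads):
        by_name: dict[str, list[AlignedRead]] = {}
        for r in fragments.reads[chrom]:
            by_name.setdefault(r.name or "", []).append(r)
        for name, group in by_name.items():
            if name and len(group) == 2:
                start = min(r.start for r in group)
                end = max(r.end for r in group)
                out.add(AlignedRead(chrom, start, end, "+", name))
                paired += 1
            else:
                unpaired += len(group)
    if paired == 0:
        raise ValueError(
            "no mate pairs could be formed; if the data are single-end, "
            "run in single-end mode (-p 0)"
        )
    if unpaired:
        logger.warning("dropped %d unpaired reads", unpaired)
    return out


def write_occupancy(profile, path: str | os.PathLike) -> None:
    """Write an occupancy profile as bedGraph with equal-value runs collapsed.

    A header comment records the sample, normalization mode and raw mean so
    that downstream calling can recover the count scale.
    """
    values = np.asarray(profile.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("profile contains non-finite values")
    if np.any(values < 0):
        raise ValueError("profile contains negative values")
    # run-length boundaries
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    with open(path, "w") as fh:
        fh.write(
            f"# dimnp occupancy sample={profile.sample_id} chrom={profile.chrom} "
            f"normalization={profile.normalization} raw_mean={profile.raw_mean:.10g} "
            f"window_bp={profile.window_bp or 0}\n"
        )
        for s, e in zip(starts, ends):
            fh.write(f"{profile.chrom}\t{s}\t{e}\t{values[s]:.6f}\n")


def read_occupancy(path: str | os.PathLike):
    """Read a bedGraph written by :func:`write_occupancy` back into a profile."""
    from .occupancy import OccupancyProfile

    meta: dict[str, str] = {}
    chrom = None
    rows: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            if not line:
                continue
            c, s, e, v = line.split("\t")
            chrom = c
            rows.append((int(s), int(e), float(v)))
    if not rows:
        raise ValueError(f"{path}: empty occupancy file")
    length = rows[-1][1]
    values = np.zeros(length, dtype=float)
    for s, e, v in rows:
        values[s:e] = v
    window = int(meta.get("window_bp", "0")) or None
    return OccupancyProfile(
        chrom=chrom,
        values=values,
        sample_id=meta.get("sample", ""),
        normalization=meta.get("normalization", "global"),
        window_bp=window,
        raw_mean=float(meta.get("raw_mean", "nan")),
    )


DNR_HEADER = "#chrom\tstart\tend\tid\tneg_log10_p\tstrand\tcenter\tp_value\tfdr"


def write_dnrs(dnrs, path: str | os.PathLike) -> None:
    """Write called DNRs as a BED6+3 table (sorted input required)."""
    keys = [(d.chrom, d.start) for d in dnrs]
    if keys != sorted(keys):
        raise ValueError("DNRs must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        fh.write(DNR_HEADER + "\n")
        for d in dnrs:
            neg_log_p = -np.log10(max(d.p_value, 1e-300))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.id}\t{neg_log_p:.4f}\t.\t"
                f"{d.center}\t{d.p_value:.6g}\t{d.fdr:.6g}\n"
            )
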