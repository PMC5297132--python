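"""Synthetic MNase-seq read generator with planted differential regions.

Emulates a chromosome carrying a regular nucleosome array: dyads every
``nucleosome_spacing`` bp, each protected by a ``fragment_length`` bp
fragment. Per sample and per nucleosome the read count is Poisson with mean
reads_per_nucleosome x depth_factor, multiplied by the fold change f when the
dyad lies inside a planted region affecting that sample. Each simulated
fragment is centered on the dyad plus Gaussian jitter and is reported as a
single-end 50 bp read from one fragment end (strand matching), so the 75/37
extension-and-shift step reconstructs the fragment body. Output is
deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dnr import DNR
from .io_reads import AlignedRead, FragmentSet

__all__ = [
    "PlantedRegion",
    "SyntheticConfig",
    "TruthSet",
    "simulate_samples",
    "write_sample_beds",
    "truth_overlap_report",
]


@dataclass(frozen=True)
class PlantedRegion:
    start: int
    end: int
    samples: tuple[int, ...]  # indices of affected samples
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0 or self.fold == 1.0:
            raise ValueError("fold change must be positive and != 1")


@dataclass
class SyntheticConfig:
    chrom_length: int
    n_samples: int = 2
    chrom: str = "chrS"
    nucleosome_spacing: int = 165
    fragment_length: int = 147
    read_length: int = 50
    reads_per_nucleosome: float = 30.0
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    positional_jitter_sd: float = 20.0
    depth_factors: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples")
        if self.depth_factors is None:
            self.depth_factors = [1.0] * self.n_samples
        if len(self.depth_factors) != self.n_samples:
            raise ValueError("one depth factor per sample required")
        regs = sorted(self.planted_regions, key=lambda r: r.start)
        prev_end = 0
        for r in regs:
            if r.start < prev_end:
                raise ValueError("planted regions overlap")
            if r.start < 0 or r.end > self.chrom_length:
                raise ValueError("planted region out of chromosome bounds")
            prev_end = r.end
        self.planted_regions = regs


@dataclass
class TruthSet:
    """Planted intervals with the affected samples and fold changes."""

    intervals: list[tuple[int, int]]
    regions: list[PlantedRegion]


def simulate_samples(config: SyntheticConfig) -> tuple[list[FragmentSet], TruthSet]:
    """Generate per-sample single-end reads and the planted truth."""
    rng = np.random.default_rng(config.seed)
    half = config.fragment_length // 2
    dyads = np.arange(
        config.nucleosome_spacing // 2, config.chrom_length, config.nucleosome_spacing
    )
    samples: list[FragmentSet] = []
    for i in range(config.n_samples):
        fs = FragmentSet(sample_id=f"sample_{i}")
        depth = config.depth_factors[i]
        for dyad in dyads:
            fold = 1.0
            for reg in config.planted_regions:
                if reg.start <= dyad < reg.end and i in reg.samples:
                    fold = reg.fold
                    break
            mean = config.reads_per_nucleosome * depth * fold
            k = rng.poisson(mean)
            if k == 0:
                continue
            centers = dyad + rng.normal(0.0, config.positional_jitter_sd, size=k)
            frag_starts = np.rint(centers).astype(int) - half
            frag_ends = frag_starts + config.fragment_length
            from_plus = rng.random(k) < 0.5
            for fs_, fe_, plus in zip(frag_starts, frag_ends, from_plus):
                if plus:
                    s, e, strand = fs_, fs_ + config.read_length, "+"
                else:
                    s, e, strand = fe_ - config.read_length, fe_, "-"
                s = max(s, 0)
                e = min(e, config.chrom_length)
                if e - s >= 1:
                    fs.add(AlignedRead(config.chrom, int(s), int(e), strand))
        # lock the coordinate frame so all samples share it
        fs.chrom_lengths[config.chrom] = config.chrom_length
        samples.append(fs)
    truth = TruthSet(
        intervals=[(r.start, r.end) for r in config.planted_regions],
        regions=list(config.planted_regions),
    )
    return samples, truth


def write_sample_beds(
    samples: Sequence[FragmentSet],
    truth: TruthSet,
    out_dir: str | os.PathLike,
    seed: int | None = None,
) -> list[str]:
    """Write one BED6 per sample plus the truth intervals as BED3.

    Reads are written in deterministic (chrom, start, end, strand) order;
    the seed is recorded in each header. Returns the sample file paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for fs in samples:
        path = os.path.join(out_dir, f"{fs.sample_id}.bed")
        reads = sorted(
            (r for r in fs), key=lambda r: (r.chrom, r.start, r.end, r.strand)
        )
        with open(path, "w") as fh:
            fh.write(f"# dimnp synthetic sample={fs.sample_id} seed={seed}\n")
            for j, r in enumerate(reads):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{j}\t0\t{r.strand}\n")
        paths.append(path)
    chrom = next(iter(samples[0].reads), "chrS") if samples else "chrS"
    with open(os.path.join(out_dir, "truth.bed"), "w") as fh:
        fh.write(f"# dimnp synthetic truth seed={seed}\n")
        for (s, e), reg in zip(truth.intervals, truth.regions):
            fh.write(f"{chrom}\t{s}\t{e}\tfold={reg.fold};samples={','.join(map(str, reg.samples))}\n")
    return paths


def _overlaps(a: tuple[int, int], b: tuple[int, int], slack: int) -> bool:
    return a[0] - slack < b[1] and b[0] < a[1] + slack


def truth_overlap_report(
    dnrs: Sequence[DNR],
    truth: TruthSet,
    slack_bp: int = 0,
) -> tuple[float, float]:
    """(sensitivity, precision) of called DNRs against the planted truth.

    Sensitivity: fraction of truth intervals overlapped (within slack) by at
    least one DNR. Precision: fraction of DNRs overlapping at least one truth
    interval. An empty DNR list reports (0, 0).
    """
    if not truth.intervals:
        raise ValueError("truth set is empty")
    if not len(dnrs):
        import logging

        logging.getLogger("dimnp").warning("no DNRs called; precision undefined, reported as 0")
        return 0.0, 0.0
    dnr_iv = [(d.start, d.end) for d in dnrs]
    hit_truth = sum(
        1 for t in truth.intervals if any(_overlaps(t, d, slack_bp) for d in dnr_iv)
    )
    hit_dnr = sum(
        1 for d in dnr_iv if any(_overlaps(t, d, slack_bp) for t in truth.intervals)
    )
    return hit_truth / len(truth.intervals), hit_dnr / len(dnr_iv)
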