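"""Detect sex-specific (hemizygous) regions from grouped read depth and
SNP-call density, plus the X-contig selection rule."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    FEMALE,
    MALE,
    GenomicInterval,
    InputError,
    SampleSheet,
    VariantTable,
)


@dataclass
class DepthTrack:
    """Per-window mean depth for each sample.

    ``depth`` has shape ``(n_windows, n_samples)``. Windows must be sorted and
    non-overlapping. ``mq_floor`` records the mapping-quality floor applied
    when the track was produced upstream.
    """

    windows: list[GenomicInterval]
    samples: list[str]
    depth: np.ndarray
    mq_floor: int = 30

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.windows), len(self.samples)):
            raise ValueError("depth shape does not match windows x samples")
        if (self.depth < 0).any():
            raise ValueError("negative depths")
        prev_end: dict[str, int] = {}
        for w in self.windows:
            if w.start < prev_end.get(w.chrom, 0):
                raise ValueError("windows overlap or are unsorted")
            prev_end[w.chrom] = w.end


def read_depth_track(path: str | Path, mq_floor: int = 30) -> DepthTrack:
    """Wide TSV: ``chrom  start  end  <sample1> ... <sampleN>`` with header."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    header = lines[0].lstrip("#").split("\t")
    samples = header[3:]
    windows = []
    rows = []
    for line in lines[1:]:
        parts = line.split("\t")
        windows.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
        rows.append([float(x) for x in parts[3:]])
    return DepthTrack(windows, samples, np.array(rows), mq_floor=mq_floor)


def write_depth_track(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\t" + "\t".join(track.samples) + "\n")
        for w, row in zip(track.windows, track.depth):
            vals = "\t".join(f"{v:g}" for v in row)
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{vals}\n")


@dataclass
class HemizygousInterval:
    interval: GenomicInterval
    male_mean: float
    female_mean: float


def _merge_flagged(
    windows: list[GenomicInterval], flagged: np.ndarray
) -> list[list[int]]:
    """Group indices of flagged windows that are adjacent on the same chrom."""
    groups: list[list[int]] = []
    cur: list[int] = []
    for i, w in enumerate(windows):
        if not flagged[i]:
            if cur:
                groups.append(cur)
                cur = []
            continue
        if cur:
            prev = windows[cur[-1]]
            if prev.chrom != w.chrom or prev.end != w.start:
                groups.append(cur)
                cur = []
        cur.append(i)
    if cur:
        groups.append(cur)
    return groups


def depth_scan(
    track: DepthTrack,
    sexes: SampleSheet,
    f_low: float = 0.2,
    m_min: float = 0.35,
) -> list[HemizygousInterval]:
    """Flag windows with near-zero female depth but appreciable male depth.

    Each sample's depths are first normalized by that sample's genome-wide
    median, so the scan is invariant to library size. A window is flagged iff
    mean normalized female depth < ``f_low`` and mean normalized male depth
    >= ``m_min``; adjacent flagged windows are merged.
    """
    male = sexes.mask(track.samples, MALE)
    female = sexes.mask(track.samples, FEMALE)
    if not male.any() or not female.any():
        raise InputError("depth_scan needs samples of both sexes")
    med = np.median(track.depth, axis=0)
    med[med == 0] = 1.0
    norm = track.depth / med[None, :]
    m_mean = norm[:, male].mean(axis=1)
    f_mean = norm[:, female].mean(axis=1)
    flagged = (f_mean < f_low) & (m_mean >= m_min)
    out = []
    for grp in _merge_flagged(track.windows, flagged):
        first, last = track.windows[grp[0]], track.windows[grp[-1]]
        out.append(
            HemizygousInterval(
                GenomicInterval(first.chrom, first.start, last.end, "hemizygous"),
                male_mean=float(m_mean[grp].mean()),
                female_mean=float(f_mean[grp].mean()),
            )
        )
    return out


@dataclass
class SnpPresenceResult:
    windows: list[GenomicInterval]
    male_counts: np.ndarray
    female_counts: np.ndarray
    depleted: list[GenomicInterval] = field(default_factory=list)


def snp_presence_scan(
    table: VariantTable,
    sexes: SampleSheet,
    window: int = 5_000,
    depletion: float = 0.1,
    min_male_sites: int = 5,
) -> SnpPresenceResult:
    """Count per-window sites with >= 1 called genotype per sex; flag windows
    where the female count is <= ``depletion`` x the male count.

    Windows with fewer than ``min_male_sites`` male-called sites are never
    flagged (a ratio over a handful of sites is meaningless).
    """
    male = sexes.mask(table.samples, MALE)
    female = sexes.mask(table.samples, FEMALE)
    per_chrom: dict[str, dict[int, list[int]]] = {}
    for rec in table.records:
        idx = (rec.pos - 1) // window
        called = rec.called
        m = int((called & male).any())
        f = int((called & female).any())
        per_chrom.setdefault(rec.chrom, {}).setdefault(idx, [0, 0])
        per_chrom[rec.chrom][idx][0] += m
        per_chrom[rec.chrom][idx][1] += f
    windows: list[GenomicInterval] = []
    m_counts: list[int] = []
    f_counts: list[int] = []
    for chrom in sorted(per_chrom):
        for idx in sorted(per_chrom[chrom]):
            m, f = per_chrom[chrom][idx]
            windows.append(GenomicInterval(chrom, idx * window, (idx + 1) * window))
            m_counts.append(m)
            f_counts.append(f)
    m_arr = np.array(m_counts)
    f_arr = np.array(f_counts)
    flagged = (m_arr >= min_male_sites) & (f_arr <= depletion * m_arr)
    depleted = []
    for grp in _merge_flagged(windows, flagged):
        first, last = windows[grp[0]], windows[grp[-1]]
        depleted.append(
            GenomicInterval(first.chrom, first.start, last.end, "female_depleted")
        )
    return SnpPresenceResult(windows, m_arr, f_arr, depleted)


@dataclass
class ContigAnnotation:
    contig: str
    length: int
    gene_count: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("contig length must be > 0")
        if self.gene_count < 0:
            raise ValueError("gene count must be >= 0")


def select_x_contigs(
    annotations: list[ContigAnnotation],
    min_len: int = 300_000,
    min_density: float = 1e-4,
) -> list[str]:
    """Keep contigs longer than ``min_len`` whose gene density (genes/bp)
    exceeds ``min_density``. The length rule is applied per contig."""
    return [
        a.contig
        for a in annotations
        if a.length > min_len and a.gene_count / a.length > min_density
    ]
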