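"""Place phased X/Y alleles onto other haplotypes via their flanking
sequence and count allele identity.

Placement replaces BLASTN with an in-house seed-and-extend placer: exact
k-mer seeds from the flanks locate candidate diagonals on both strands, and
an ungapped comparison over the whole query scores each candidate. A unique
best hit above the identity threshold is accepted; ties or sub-threshold
candidates leave the locus unplaced.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    GenomicInterval,
    HaplotypeSequence,
    InputError,
    VariantTable,
    revcomp,
    seq_to_array,
)
from .phase_halfsib import PhasedSdrAllele

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class FlankedLocus:
    chrom: str
    pos: int  # 1-based source position
    y_allele: str
    x_allele: str
    left: str  # up to `flank` bases, focal base excluded
    right: str
    truncated: bool = False

    @property
    def query(self) -> str:
        """Flanks joined around the focal slot (source base placeholder)."""
        return self.left + "N" + self.right

    @property
    def focal_index(self) -> int:
        return len(self.left)


def extract_flanks(
    reference: HaplotypeSequence,
    phased: list[PhasedSdrAllele],
    flank: int = 150,
) -> list[FlankedLocus]:
    """Extract up to ``flank`` bases each side of every phased site,
    truncated at sequence ends (truncation recorded)."""
    out = []
    seq = reference.seq
    for p in phased:
        if not (1 <= p.pos <= len(seq)):
            raise InputError(
                f"position {p.chrom}:{p.pos} outside reference ({len(seq)} bp)"
            )
        i = p.pos - 1
        left = seq[max(0, i - flank) : i]
        right = seq[i + 1 : i + 1 + flank]
        out.append(
            FlankedLocus(
                chrom=p.chrom,
                pos=p.pos,
                y_allele=p.y_allele,
                x_allele=p.x_allele,
                left=left,
                right=right,
                truncated=len(left) < flank or len(right) < flank,
            )
        )
    return out


@dataclass
class Placement:
    target: str
    pos: int  # 1-based position of the focal slot on the target
    strand: str
    identity: float
    target_allele: str


class SeedPlacer:
    """K-mer index over one target sequence for repeated flank placement."""

    def __init__(self, target: HaplotypeSequence, seed_len: int = 31):
        if seed_len > 31:
            raise ValueError("seed_len must be <= 31")
        self.target = target
        self.seed_len = seed_len
        self._arr = seq_to_array(target.seq.replace("N", "A"))
        self._codes, self._order = self._index(self._arr, seed_len)

    @staticmethod
    def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
        n = arr.shape[0]
        if n < k:
            return np.empty(0, dtype=np.uint64)
        codes = np.zeros(n - k + 1, dtype=np.uint64)
        for i in range(k):
            codes = (codes << np.uint64(2)) | arr[i : n - k + 1 + i].astype(np.uint64)
        return codes

    def _index(self, arr: np.ndarray, k: int):
        codes = self._kmer_codes(arr, k)
        order = np.argsort(codes, kind="stable")
        return codes[order], order

    def _seed_offsets(self, qarr: np.ndarray) -> np.ndarray:
        """Candidate alignment offsets (target start of the query)."""
        k = self.seed_len
        qcodes = self._kmer_codes(qarr, k)
        lo = np.searchsorted(self._codes, qcodes, side="left")
        hi = np.searchsorted(self._codes, qcodes, side="right")
        offs = []
        for qoff in np.flatnonzero(hi > lo):
            tpos = self._order[lo[qoff] : hi[qoff]]
            offs.append(tpos.astype(np.int64) - qoff)
        if not offs:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(offs))

    def place(
        self,
        query: str,
        focal_index: int | None = None,
        min_identity: float = 0.9,
    ) -> Placement | None:
        """Locate ``query`` on the target (both strands); return the unique
        best ungapped placement above ``min_identity``, else None.

        ``focal_index`` marks a placeholder column excluded from identity and
        read back from the target (complemented on the minus strand).
        """
        n = len(query)
        tlen = len(self.target.seq)
        best: tuple[float, int, str] | None = None
        tie = False
        for strand in ("+", "-"):
            q = query if strand == "+" else revcomp(query)
            f_idx = (
                None
                if focal_index is None
                else (focal_index if strand == "+" else n - 1 - focal_index)
            )
            qarr = seq_to_array(q.replace("N", "A"))
            compare = np.ones(n, dtype=bool)
            if f_idx is not None:
                compare[f_idx] = False
            for off in self._seed_offsets(qarr):
                off = int(off)
                if off < 0 or off + n > tlen:
                    continue
                window = self._arr[off : off + n]
                matches = int(((window == qarr) & compare).sum())
                ident = matches / compare.sum()
                if best is None or ident > best[0] + 1e-12:
                    best = (ident, off, strand)
                    tie = False
                elif abs(ident - best[0]) <= 1e-12 and (off, strand) != best[1:]:
                    tie = True
        if best is None or tie or best[0] < min_identity:
            return None
        ident, off, strand = best
        if focal_index is None:
            t_idx = off
        else:
            q_focal = focal_index if strand == "+" else n - 1 - focal_index
            t_idx = off + q_focal
        allele = self.target.seq[t_idx]
        if strand == "-":
            allele = _COMPLEMENT[allele]
        return Placement(
            target=self.target.name,
            pos=t_idx + 1,
            strand=strand,
            identity=float(ident),
            target_allele=allele,
        )

    def fetch(self, off: int, length: int, strand: str) -> str:
        """Target subsequence for an accepted placement, query-oriented."""
        sub = self.target.seq[off : off + length]
        return sub if strand == "+" else revcomp(sub)


def place_locus(
    locus: FlankedLocus,
    target: HaplotypeSequence | SeedPlacer,
    min_identity: float = 0.9,
    seed_len: int = 31,
) -> Placement | None:
    placer = (
        target if isinstance(target, SeedPlacer) else SeedPlacer(target, seed_len)
    )
    return placer.place(locus.query, locus.focal_index, min_identity)


@dataclass
class LocusTrace:
    locus: FlankedLocus
    placement: Placement | None
    match: str  # Y | X | neither | unplaced


@dataclass
class TraceResult:
    target: str
    traces: list[LocusTrace]
    n_y_match: int = 0
    n_x_match: int = 0
    n_neither: int = 0
    n_unplaced: int = 0
    links: list[tuple[int, int]] = field(default_factory=list)


def count_matches(
    loci: list[FlankedLocus],
    target: HaplotypeSequence,
    min_identity: float = 0.9,
    seed_len: int = 31,
) -> TraceResult:
    """Place every locus on one target and score allele identity."""
    placer = SeedPlacer(target, seed_len)
    traces = []
    tally: Counter = Counter()
    links = []
    for locus in loci:
        pl = placer.place(locus.query, locus.focal_index, min_identity)
        if pl is None:
            match = "unplaced"
        elif pl.target_allele == locus.y_allele:
            match = "Y"
        elif pl.target_allele == locus.x_allele:
            match = "X"
        else:
            match = "neither"
        if pl is not None:
            links.append((locus.pos, pl.pos))
        tally[match] += 1
        traces.append(LocusTrace(locus, pl, match))
    return TraceResult(
        target=target.name,
        traces=traces,
        n_y_match=tally["Y"],
        n_x_match=tally["X"],
        n_neither=tally["neither"],
        n_unplaced=tally["unplaced"],
        links=links,
    )


def trace_loci(
    loci: list[FlankedLocus],
    targets: dict[str, HaplotypeSequence],
    min_identity: float = 0.9,
    seed_len: int = 31,
) -> dict[str, TraceResult]:
    return {
        name: count_matches(loci, seq, min_identity, seed_len)
        for name, seq in targets.items()
    }


_TRACE_COLS = (
    "target source_chrom source_pos y_allele x_allele target_pos strand "
    "identity target_allele match"
).split()


def write_traces(traces: dict[str, TraceResult], path) -> None:
    from .core_io import write_tsv

    rows = []
    for name in sorted(traces):
        for t in traces[name].traces:
            pl = t.placement
            rows.append(
                (name, t.locus.chrom, t.locus.pos, t.locus.y_allele,
                 t.locus.x_allele,
                 pl.pos if pl else ".", pl.strand if pl else ".",
                 f"{pl.identity:.4f}" if pl else ".",
                 pl.target_allele if pl else ".", t.match)
            )
    write_tsv(rows, path, header=_TRACE_COLS)


def read_traces(path) -> dict[str, TraceResult]:
    """Rebuild per-target TraceResults from a trace TSV (flank sequences are
    not round-tripped; loci carry empty flanks)."""
    from pathlib import Path

    by_target: dict[str, TraceResult] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        f = line.split("\t")
        target = f[0]
        res = by_target.setdefault(target, TraceResult(target, []))
        locus = FlankedLocus(f[1], int(f[2]), f[3], f[4], "", "")
        pl = None
        if f[5] != ".":
            pl = Placement(target, int(f[5]), f[6], float(f[7]), f[8])
            res.links.append((locus.pos, pl.pos))
        match = f[9]
        res.traces.append(LocusTrace(locus, pl, match))
        if match == "Y":
            res.n_y_match += 1
        elif match == "X":
            res.n_x_match += 1
        elif match == "neither":
            res.n_neither += 1
        else:
            res.n_unplaced += 1
    return by_target


def count_crossings(links: list[tuple[int, int]]) -> int:
    """Number of crossing pairs in a source-to-target link table; zero for an
    unrearranged copy, positive after inversions/translocations."""
    n = 0
    for i in range(len(links)):
        for j in range(i + 1, len(links)):
            if (links[i][0] - links[j][0]) * (links[i][1] - links[j][1]) < 0:
                n += 1
    return n


def harvest_window_alignment(
    reference: HaplotypeSequence,
    positions: list[int],
    targets: dict[str, HaplotypeSequence],
    half: int = 300,
    min_identity: float = 0.7,
    seed_len: int = 21,
) -> tuple[dict[str, str], list[int]]:
    """Build an ungapped multi-target alignment from windows around loci.

    For each 1-based source position, the +-``half`` window is extracted
    from the reference and placed on every target; windows placeable on all
    targets contribute aligned columns. Returns per-target concatenated
    sequences plus the positions used.
    """
    placers = {n: SeedPlacer(s, seed_len) for n, s in targets.items()}
    parts: dict[str, list[str]] = {n: [] for n in targets}
    used: list[int] = []
    for pos in positions:
        i = pos - 1
        if i - half < 0 or i + half + 1 > len(reference.seq):
            continue
        window = reference.seq[i - half : i + half + 1]
        row: dict[str, str] = {}
        ok = True
        for name, placer in placers.items():
            pl = placer.place(window, None, min_identity)
            if pl is None:
                ok = False
                break
            off = pl.pos - 1  # focal_index None: pos is the window start
            row[name] = placer.fetch(off, len(window), pl.strand)
        if ok:
            used.append(pos)
            for name in targets:
                parts[name].append(row[name])
    return {n: "".join(v) for n, v in parts.items()}, used


def major_allele_consensus(
    table: VariantTable, sample_ids: list[str]
) -> dict[tuple[str, int], str]:
    """Per-site strict-majority allele among the given samples' called
    genotypes; ties yield 'N'. Used to derive a Z haplotype from ZZ males."""
    idx = [table.samples.index(s) for s in sample_ids]
    out = {}
    for rec in table.records:
        gt = rec.genotypes[idx]
        called = (gt >= 0).all(axis=1)
        alleles = gt[called].ravel()
        if alleles.size == 0:
            out[(rec.chrom, rec.pos)] = "N"
            continue
        n_alt = int((alleles == 1).sum())
        n_ref = alleles.size - n_alt
        if n_ref > n_alt:
            out[(rec.chrom, rec.pos)] = rec.ref
        elif n_alt > n_ref:
            out[(rec.chrom, rec.pos)] = rec.alt
        else:
            out[(rec.chrom, rec.pos)] = "N"
    return out
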