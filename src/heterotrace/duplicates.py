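"""Find partial duplicates of a query gene on chromosome sequences and pair
homologous duplicates across chromosomes.

The scanner is a BLASTN-like seed-and-extend local aligner: exact word
matches (default word size 8) seed ungapped X-drop extensions on both
strands; extensions on the same diagonal within a small gap are merged into
maximal hits. Scoring is +1/-2 with gapless extension — an approximation of
BLASTN HSP behaviour, not a bit-exact replica.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import HaplotypeSequence, InputError, revcomp, seq_to_array

MATCH = 1
MISMATCH = -2
XDROP = 12


@dataclass
class DuplicateHit:
    target: str
    start: int  # 0-based half-open target interval
    end: int
    strand: str
    query_start: int  # on the forward query
    query_end: int
    identity: float  # percent
    sequence: str  # target subsequence, oriented to the forward query
    intact: bool = False
    palindrome: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be within [0, 100]")


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    n = arr.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        codes = (codes << 2) | arr[i : n - k + 1 + i].astype(np.int64)
    return codes


def _extend(qarr, tarr, qpos, tpos, word):
    """Ungapped X-drop extension of one seed; returns (qs, qe, matches)."""
    # right of the seed
    qn, tn = qarr.shape[0], tarr.shape[0]
    span = min(qn - (qpos + word), tn - (tpos + word))
    if span > 0:
        m = qarr[qpos + word : qpos + word + span] == tarr[tpos + word : tpos + word + span]
        step = np.where(m, MATCH, MISMATCH)
        score = np.cumsum(step)
        run_max = np.maximum.accumulate(score)
        stopped = np.flatnonzero(run_max - score > XDROP)
        limit = stopped[0] if stopped.size else span
        best_r = int(np.argmax(score[:limit])) + 1 if limit > 0 else 0
        if limit > 0 and score[best_r - 1] <= 0:
            best_r = 0
    else:
        best_r = 0
    # left of the seed
    span = min(qpos, tpos)
    if span > 0:
        m = (qarr[qpos - span : qpos] == tarr[tpos - span : tpos])[::-1]
        step = np.where(m, MATCH, MISMATCH)
        score = np.cumsum(step)
        run_max = np.maximum.accumulate(score)
        stopped = np.flatnonzero(run_max - score > XDROP)
        limit = stopped[0] if stopped.size else span
        best_l = int(np.argmax(score[:limit])) + 1 if limit > 0 else 0
        if limit > 0 and score[best_l - 1] <= 0:
            best_l = 0
    else:
        best_l = 0
    qs, qe = qpos - best_l, qpos + word + best_r
    matches = int((qarr[qs:qe] == tarr[qs - qpos + tpos : qe - qpos + tpos]).sum())
    return qs, qe, matches


def _scan_strand(qarr, tarr, word, merge_gap):
    """Return raw HSPs [(diag, qs, qe, matches)] for one query orientation."""
    qcodes = _kmer_codes(qarr, word)
    order = np.argsort(qcodes, kind="stable")
    sorted_codes = qcodes[order]
    tcodes = _kmer_codes(tarr, word)
    lo = np.searchsorted(sorted_codes, tcodes, side="left")
    hi = np.searchsorted(sorted_codes, tcodes, side="right")
    hit_t = np.flatnonzero(hi > lo)
    seeds = []
    for tpos in hit_t:
        for qpos in order[lo[tpos] : hi[tpos]]:
            seeds.append((int(tpos) - int(qpos), int(qpos)))
    seeds.sort()
    hsps = []
    covered_diag, covered_end = None, -1
    for diag, qpos in seeds:
        if diag == covered_diag and qpos + word <= covered_end:
            continue
        qs, qe, matches = _extend(qarr, tarr, qpos, qpos + diag, word)
        covered_diag, covered_end = diag, qe
        hsps.append((diag, qs, qe, matches))
    # merge same-diagonal HSPs within merge_gap
    hsps.sort()
    merged = []
    for diag, qs, qe, matches in hsps:
        if merged and merged[-1][0] == diag and qs <= merged[-1][2] + merge_gap:
            pdiag, pqs, pqe, _ = merged[-1]
            nqs, nqe = min(pqs, qs), max(pqe, qe)
            nmatches = int(
                (qarr[nqs:nqe] == tarr[nqs + diag : nqe + diag]).sum()
            )
            merged[-1] = (diag, nqs, nqe, nmatches)
        else:
            merged.append((diag, qs, qe, matches))
    return merged


def scan_duplicates(
    query: HaplotypeSequence,
    target: HaplotypeSequence,
    word: int = 8,
    min_len: int = 30,
    min_identity: float = 70.0,
    merge_gap: int = 10,
    intact_coverage: float = 0.9,
) -> list[DuplicateHit]:
    """Seed-and-extend scan of ``target`` for copies of ``query`` on both
    strands; hits covering >= ``intact_coverage`` of the query are labelled
    intact copies, the rest partial duplicates."""
    if len(query.seq) < word:
        raise InputError("query shorter than the seed word size")
    tarr = seq_to_array(target.seq.replace("N", "A"))
    qlen = len(query.seq)
    hits: list[DuplicateHit] = []
    for strand in ("+", "-"):
        qseq = query.seq if strand == "+" else revcomp(query.seq)
        qarr = seq_to_array(qseq.replace("N", "A"))
        for diag, qs, qe, matches in _scan_strand(qarr, tarr, word, merge_gap):
            length = qe - qs
            identity = 100.0 * matches / length
            if length < min_len or identity < min_identity:
                continue
            ts, te = qs + diag, qe + diag
            if strand == "+":
                q0, q1 = qs, qe
                seq = target.seq[ts:te]
            else:
                q0, q1 = qlen - qe, qlen - qs
                seq = revcomp(target.seq[ts:te])
            hits.append(
                DuplicateHit(
                    target=target.name,
                    start=ts,
                    end=te,
                    strand=strand,
                    query_start=q0,
                    query_end=q1,
                    identity=round(identity, 2),
                    sequence=seq,
                    intact=length >= intact_coverage * qlen,
                )
            )
    hits.sort(key=lambda h: h.start)
    return _drop_shadowed(hits)


def _drop_shadowed(hits: list[DuplicateHit]) -> list[DuplicateHit]:
    """Remove hits wholly contained in a longer hit on the other strand or
    diagonal (seeding both strands of a palindromic query reports twice)."""
    kept = []
    for h in hits:
        shadowed = any(
            o is not h
            and o.start <= h.start
            and h.end <= o.end
            and o.length > h.length
            for o in hits
        )
        if not shadowed:
            kept.append(h)
    return kept


def annotate_palindromes(
    hits: list[DuplicateHit], max_spacing: int = 5_000
) -> list[DuplicateHit]:
    """Flag pairs of intact copies in inverted orientation within
    ``max_spacing`` of each other as palindromic."""
    intact = [h for h in hits if h.intact]
    for i, a in enumerate(intact):
        for b in intact[i + 1 :]:
            gap = max(a.start, b.start) - min(a.end, b.end)
            if a.strand != b.strand and gap < max_spacing:
                a.palindrome = b.palindrome = True
    return hits


def _pair_identity(a: str, b: str) -> float:
    """Percent identity of the best local alignment of two hit sequences,
    over the length of the longer one (boundary slop tolerated)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    matches = sum(
        1
        for (sa, ea), (sb, _eb) in zip(*aln.aligned)
        for i in range(ea - sa)
        if a[sa + i] == b[sb + i]
    )
    return 100.0 * matches / max(len(a), len(b))


@dataclass
class DuplicatePairing:
    pairs: list[tuple[DuplicateHit, DuplicateHit]]
    identities: list[float]
    same_length: list[bool]
    order_preserved: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def pair_duplicates(
    hits_a: list[DuplicateHit],
    hits_b: list[DuplicateHit],
    min_identity: float = 70.0,
) -> DuplicatePairing:
    """Greedy 1-1 pairing of hits across two chromosomes by best inter-hit
    identity; each hit used at most once."""
    hits_a = sorted(hits_a, key=lambda h: h.start)
    hits_b = sorted(hits_b, key=lambda h: h.start)
    candidates = []
    for i, a in enumerate(hits_a):
        for j, b in enumerate(hits_b):
            ident = _pair_identity(a.sequence, b.sequence)
            if ident >= min_identity:
                candidates.append((ident, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    chosen = []
    for ident, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        chosen.append((i, j, ident))
    chosen.sort()
    pairs = [(hits_a[i], hits_b[j]) for i, j, _ in chosen]
    idents = [ident for _, _, ident in chosen]
    same_len = [(a.length == b.length) for a, b in pairs]
    b_starts = [b.start for _, b in pairs]
    monotone = all(x < y for x, y in zip(b_starts, b_starts[1:]))
    strands_match = all(a.strand == b.strand for a, b in pairs)
    return DuplicatePairing(
        pairs=pairs,
        identities=idents,
        same_length=same_len,
        order_preserved=bool(pairs) and monotone and strands_match,
    )


_HIT_COLUMNS = (
    "target start end strand query_start query_end identity intact "
    "palindrome sequence"
).split()


def write_hits(hits: list[DuplicateHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.target, h.start, h.end, h.strand, h.query_start,
                        h.query_end, h.identity, int(h.intact),
                        int(h.palindrome), h.sequence,
                    )
                )
                + "\n"
            )


def read_hits(path: str | Path) -> list[DuplicateHit]:
    lines = Path(path).read_text().splitlines()
    hits = []
    for line in lines[1:]:
        f = line.split("\t")
        hits.append(
            DuplicateHit(
                target=f[0], start=int(f[1]), end=int(f[2]), strand=f[3],
                query_start=int(f[4]), query_end=int(f[5]),
                identity=float(f[6]), sequence=f[9],
                intact=bool(int(f[7])), palindrome=bool(int(f[8])),
            )
        )
    return hits
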