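"""Forward simulator of a homologous XY -> ZW sex-system transition.

A single ancestral chromosome gives rise to X and Y alleles of the
sex-determination region (SDR) in species 1 (male heterogametic), and the Y
(or, in the mirrored scenario, the X) then seeds both the Z and W of
species 2 (female heterogametic). The simulator emits every input the
analysis pipeline consumes — population VCFs for both species, a half-sib
family VCF with pedigree, a windowed depth track, haplotype FASTAs, planted
partial duplicates of a query gene — plus a ground-truth record, so every
downstream stage can be scored exactly.

All X/Y divergence is confined to the SDR (the pseudo-autosomal remainder is
treated as a freely recombining shared pool), and mutation is
independent-site substitution: no indels arise outside explicitly planted
insertions/deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_io import (
    FEMALE,
    MALE,
    GenomicInterval,
    HaplotypeSequence,
    Pedigree,
    SampleSheet,
    VariantRecord,
    VariantTable,
    write_bed,
    write_fasta,
    write_json,
    write_pedigree,
    write_tsv,
    write_vcf,
)
from .hemizygosity import DepthTrack, write_depth_track

from .core_io import array_to_seq, seq_to_array

W_FROM_Y = "W_from_Y"
W_FROM_X = "W_from_X"

CHROM = "chr15"

_BASES = "ACGT"


class ConfigError(ValueError):
    """Invalid scenario configuration."""


@dataclass
class TransitionScenario:
    """Parameters of one simulated XY -> ZW transition."""

    scenario: str = W_FROM_Y
    length: int = 200_000
    sdr: tuple[int, int] = (60_000, 190_000)
    y_specific: tuple[int, int] = (60_000, 130_000)
    # per-site substitution probabilities along each branch
    x_rate: float = 0.05
    y_rate: float = 0.05
    split_rate: float = 0.03
    z_rate: float = 0.05
    w_rate: float = 0.05
    outgroup_rate: float = 0.12
    n_tracer_loci: int = 30
    tracer_window: int = 75  # half-width of the conserved exon window
    n_duplicates: int = 5
    dup_len_range: tuple[int, int] = (80, 300)
    # divergence of each planted fragment from the intact gene at plant time
    # (pre-split derived mutations shared by the Y and Z copies)
    dup_divergence: float = 0.05
    gene_length: int = 1200
    error_rate: float = 0.0  # epsilon: genotype corruption probability
    missing_rate: float = 0.0  # m: genotype masking probability
    n_males: int = 24
    n_females: int = 24
    n_progeny: int = 48
    n_fathers: int = 1
    mean_depth: float = 30.0
    depth_window: int = 5_000
    n_background_snps: int = 500
    y_poly_density: float = 0.004
    qc_fail_fraction: float = 0.02
    # caps on emitted VCF sites (sequence divergence is unaffected; tracer
    # loci are always retained) — keeps desk-scale runs fast
    max_sdr_sites: int = 3000
    max_species2_sites: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (W_FROM_Y, W_FROM_X):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        s0, s1 = self.sdr
        y0, y1 = self.y_specific
        if not (0 <= s0 < s1 <= self.length):
            raise ConfigError(f"sdr {self.sdr} outside [0, {self.length})")
        if not (s0 <= y0 < y1 <= s1):
            raise ConfigError(
                f"y_specific {self.y_specific} not nested in sdr {self.sdr}"
            )
        for name in ("x_rate", "y_rate", "split_rate", "z_rate", "w_rate",
                     "outgroup_rate", "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1)")
        if self.error_rate + self.missing_rate >= 1.0:
            raise ConfigError("error_rate + missing_rate must be < 1")
        if self.n_males < 1 or self.n_females < 1 or self.n_progeny < 2:
            raise ConfigError("need both sexes and >= 2 progeny")

    @property
    def sdr_interval(self) -> GenomicInterval:
        return GenomicInterval(CHROM, *self.sdr, "sdr")

    @property
    def y_specific_interval(self) -> GenomicInterval:
        return GenomicInterval(CHROM, *self.y_specific, "y_specific")


@dataclass
class PlantedDuplicate:
    start: int  # frame coordinates on the Y/Z
    end: int
    strand: str
    query_start: int
    query_end: int
    on_w: bool


@dataclass
class TransitionTruth:
    """Ground truth emitted alongside the simulated files."""

    scenario: str
    sdr: GenomicInterval
    y_specific: GenomicInterval
    sequences: dict[str, str]  # final X, Y, Z, W, OUT sequences
    tracer_loci: list[dict]  # pos (1-based), x/y/z/w alleles, exon window
    divergent_sites: list[dict]  # every X!=Y SDR site: pos, y_allele, x_allele
    duplicates: list[PlantedDuplicate]
    w_insert_intervals: list[tuple[int, int]]  # intact-gene blocks, final W coords
    exon_windows: list[GenomicInterval]
    sex_system: dict[str, str]  # species1 -> XY, species2 -> ZW

    def to_json(self) -> dict:
        d = {
            "scenario": self.scenario,
            "sdr": [self.sdr.start, self.sdr.end],
            "y_specific": [self.y_specific.start, self.y_specific.end],
            "tracer_loci": self.tracer_loci,
            "divergent_sites": self.divergent_sites,
            "duplicates": [asdict(x) for x in self.duplicates],
            "w_insert_intervals": [list(x) for x in self.w_insert_intervals],
            "exon_windows": [[iv.start, iv.end] for iv in self.exon_windows],
            "sex_system": self.sex_system,
        }
        return d


@dataclass
class SimulationResult:
    scenario: TransitionScenario
    truth: TransitionTruth
    reference: HaplotypeSequence  # species-1 male assembly (Y frame)
    haplotypes: dict[str, HaplotypeSequence]  # X, Y, Z, W, OUT (final)
    query_gene: HaplotypeSequence
    species1: VariantTable
    sheet1: SampleSheet
    species2: VariantTable
    sheet2: SampleSheet
    family: VariantTable
    pedigree: Pedigree
    depth: DepthTrack
    exon_windows: list[GenomicInterval]


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------


def mutate_array(
    arr: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Substitute each site independently with probability ``rate``.

    A substituted site receives one of the three other bases uniformly
    (Jukes-Cantor style). Sites where ``mask`` is True are protected.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"rate {rate} outside [0, 1)")
    out = arr.copy()
    if rate == 0.0:
        return out
    hit = rng.random(arr.shape[0]) < rate
    if mask is not None:
        hit &= ~mask
    idx = np.flatnonzero(hit)
    out[idx] = (out[idx] + rng.integers(1, 4, idx.shape[0])) % 4
    return out


def mutate_branch(seq: HaplotypeSequence, rate: float, seed: int) -> HaplotypeSequence:
    """Jukes-Cantor-style branch mutation of a haplotype sequence."""
    rng = np.random.default_rng(seed)
    arr = seq_to_array(seq.seq)
    return HaplotypeSequence(seq.name, array_to_seq(mutate_array(arr, rate, rng)))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    key = int.from_bytes(label.encode(), "big") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _apply_edits(arr: np.ndarray, edits: list[tuple[int, int, np.ndarray | None]]):
    """Apply non-overlapping deletions/replacements; return (seq, final spans).

    Each edit is ``(start, end, replacement)`` in frame coordinates;
    ``replacement=None`` deletes the span. Returns the edited array and the
    final-coordinate span of each edit's replacement (``None`` for deletions).
    """
    parts = []
    spans: list[tuple[int, int] | None] = []
    cur = 0
    out_len = 0
    for start, end, rep in sorted(edits, key=lambda e: e[0]):
        if start < cur:
            raise ValueError("overlapping edits")
        parts.append(arr[cur:start])
        out_len += start - cur
        if rep is None:
            spans.append(None)
        else:
            spans.append((out_len, out_len + rep.shape[0]))
            parts.append(rep)
            out_len += rep.shape[0]
        cur = end
    parts.append(arr[cur:])
    return np.concatenate(parts), spans


def _other_base(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (base + rng.integers(1, 4, base.shape[0])) % 4


def _dosage_to_pairs(dos: np.ndarray) -> np.ndarray:
    """Map dosage codes {-1, 0, 1, 2} to unordered allele pairs."""
    pairs = np.empty(dos.shape + (2,), dtype=np.int8)
    pairs[..., 0] = np.where(dos == 2, 1, 0)
    pairs[..., 1] = np.where(dos >= 1, 1, 0)
    pairs[dos < 0] = -1
    return pairs


def _corrupt(dos: np.ndarray, eps: float, miss: float, rng: np.random.Generator) -> np.ndarray:
    """Corrupt called dosages at rate eps, then mask at rate miss."""
    out = dos.copy()
    called = out >= 0
    if eps > 0:
        flip = called & (rng.random(out.shape) < eps)
        shift = rng.integers(1, 3, out.shape)
        out[flip] = (out[flip] + shift[flip]) % 3
    if miss > 0:
        out[called & (rng.random(out.shape) < miss)] = -1
    return out


_QC_PASS = {
    "MQ": (40.0, 60.0),
    "SOR": (0.5, 3.0),
    "QD": (20.5, 35.0),
    "FS": (0.0, 30.0),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-1.8, 1.8),
    "DP": (20.0, 80.0),
}
_QC_FAIL = {
    "MQ": (2.0, 14.9),
    "SOR": (4.1, 9.0),
    "QD": (2.0, 19.5),
    "FS": (61.0, 200.0),
    "MQRankSum": (-25.0, -10.1),
    "ReadPosRankSum": (2.1, 6.0),  # sign flipped at random
    "DP": (101.0, 300.0),  # or low side, chosen at random
}


def _qc_annotations(
    n: int,
    rng: np.random.Generator,
    fail_fraction: float,
    force_pass: np.ndarray | None = None,
) -> list[dict[str, float]]:
    """Two-component per-key QC draws: pass range or fail range."""
    cols: dict[str, np.ndarray] = {}
    for key in _QC_PASS:
        lo, hi = _QC_PASS[key]
        vals = rng.uniform(lo, hi, n)
        fail = rng.random(n) < fail_fraction
        if force_pass is not None:
            fail &= ~force_pass
        flo, fhi = _QC_FAIL[key]
        fvals = rng.uniform(flo, fhi, n)
        if key == "ReadPosRankSum":
            sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            fvals = fvals * sign
        if key == "DP":
            low_side = rng.random(n) < 0.5
            fvals = np.where(low_side, rng.uniform(1.0, 5.0, n), fvals)
        vals = np.where(fail, fvals, vals)
        if key == "DP":
            vals = np.round(vals)
        cols[key] = vals
    keys = list(cols)
    rows = zip(*(cols[k].tolist() for k in keys))
    return [dict(zip(keys, row)) for row in rows]


def _make_table(
    chrom: str,
    positions: np.ndarray,  # 1-based, sorted
    ref_bases: np.ndarray,
    alt_bases: np.ndarray,
    dosages: np.ndarray,  # (n_sites, n_samples)
    samples: list[str],
    qc: list[dict[str, float]],
) -> VariantTable:
    pairs = _dosage_to_pairs(dosages)
    records = [
        VariantRecord(
            chrom,
            int(positions[i]),
            _BASES[ref_bases[i]],
            _BASES[alt_bases[i]],
            pairs[i],
            qc[i],
        )
        for i in range(positions.shape[0])
    ]
    return VariantTable(list(samples), records)


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------


def simulate_transition(
    scenario: TransitionScenario, out_dir: str | Path | None = None
) -> SimulationResult:
    """Run the forward simulation; optionally write all pipeline inputs."""
    sc = scenario
    L = sc.length
    s0, s1 = sc.sdr
    y0, y1 = sc.y_specific

    rng_seq = _substream(sc.seed, "sequences")
    rng_plant = _substream(sc.seed, "planting")
    rng_pop = _substream(sc.seed, "population")
    rng_fam = _substream(sc.seed, "family")
    rng_sp2 = _substream(sc.seed, "species2")
    rng_depth = _substream(sc.seed, "depth")
    rng_qc = _substream(sc.seed, "qc")
    rng_err = _substream(sc.seed, "noise")

    anc = rng_seq.integers(0, 4, L).astype(np.uint8)
    gene = rng_seq.integers(0, 4, sc.gene_length).astype(np.uint8)

    # --- tracer loci: conserved "exon" windows in the X/Y-homologous SDR ---
    segs = []
    if s0 < y0:
        segs.append((s0, y0))
    if y1 < s1:
        segs.append((y1, s1))
    hom_start, hom_end = max(segs, key=lambda t: t[1] - t[0])
    margin = sc.tracer_window + 425  # clearance for harvest windows and flanks
    usable = (hom_end - margin) - (hom_start + margin)
    if usable < sc.n_tracer_loci * (2 * sc.tracer_window + 50):
        raise ConfigError("homologous SDR segment too small for tracer loci")
    tracer_pos0 = (
        hom_start
        + margin
        + ((np.arange(sc.n_tracer_loci) + 0.5) * usable / sc.n_tracer_loci)
    ).astype(np.int64)
    win_mask = np.zeros(L, dtype=bool)
    for p in tracer_pos0:
        win_mask[p - sc.tracer_window : p + sc.tracer_window + 1] = True

    # --- SDR alleles at the species split ---
    sdr_slice = slice(s0, s1)
    xa = anc.copy()
    xa[sdr_slice] = mutate_array(
        anc[sdr_slice], sc.x_rate, rng_seq, mask=win_mask[sdr_slice]
    )
    ya = anc.copy()
    ya[sdr_slice] = mutate_array(
        anc[sdr_slice], sc.y_rate, rng_seq, mask=win_mask[sdr_slice]
    )
    # planted fixed X/Y difference at each tracer locus
    xa[tracer_pos0] = _other_base(ya[tracer_pos0], rng_plant)

    # --- partial duplicates of the query gene, planted on the ancestral Y ---
    duplicates: list[PlantedDuplicate] = []
    n_dup = sc.n_duplicates
    if n_dup:
        dup_margin = 500
        step = (y1 - y0 - 2 * dup_margin) // max(n_dup, 1)
        for i in range(n_dup):
            dlen = int(rng_plant.integers(sc.dup_len_range[0], sc.dup_len_range[1] + 1))
            qstart = int(rng_plant.integers(0, sc.gene_length - dlen + 1))
            strand = "+" if rng_plant.random() < 0.5 else "-"
            start = y0 + dup_margin + i * step
            frag = mutate_array(
                gene[qstart : qstart + dlen], sc.dup_divergence, rng_plant
            )
            if strand == "-":
                frag = 3 - frag[::-1]
            ya[start : start + dlen] = frag
            duplicates.append(
                # duplicates end up on Y and Z only: deleted from a Y-derived
                # W, and never present on an X-derived W
                PlantedDuplicate(
                    start, start + dlen, strand, qstart, qstart + dlen, on_w=False
                )
            )

    # --- descendant haplotypes ---
    y_final = ya.copy()
    y_final[sdr_slice] = mutate_array(
        ya[sdr_slice], sc.split_rate, rng_seq, mask=win_mask[sdr_slice]
    )
    z = mutate_array(ya, sc.z_rate, rng_seq)
    w_src = ya if sc.scenario == W_FROM_Y else xa
    w_frame = mutate_array(w_src, sc.w_rate, rng_seq)
    outg = mutate_array(anc, sc.outgroup_rate, rng_seq)

    # --- structural edits on final X and W ---
    x_seq_arr, _ = _apply_edits(xa, [(y0, y1, None)])

    spacer = rng_plant.integers(0, 4, 30).astype(np.uint8)
    block = np.concatenate([gene, spacer, 3 - gene[::-1]])  # inverted pair
    ins_pts = []
    for frac in (1.0 / 3.0, 2.0 / 3.0):
        k = int(frac * sc.n_tracer_loci)
        if 0 < k < sc.n_tracer_loci:
            mid = int((tracer_pos0[k - 1] + tracer_pos0[k]) // 2)
        else:
            mid = (hom_start + hom_end) // 2
        ins_pts.append(mid)
    w_edits: list[tuple[int, int, np.ndarray | None]] = [
        (p, p, block) for p in ins_pts
    ]
    if sc.scenario == W_FROM_Y:
        # partial duplicates were deleted from the W
        w_edits += [(d.start, d.end, None) for d in duplicates]
    else:
        # W derives from the X, which never carried the Y-specific region
        w_edits.append((y0, y1, None))
    w_edits_sorted = sorted(w_edits, key=lambda e: e[0])
    w_seq_arr, w_spans = _apply_edits(w_frame, w_edits_sorted)
    # spans run parallel to the sorted edit list; insertions have start == end
    w_inserts = [
        sp
        for (s, e, _rep), sp in zip(w_edits_sorted, w_spans)
        if s == e and sp is not None
    ]

    reference = HaplotypeSequence(CHROM, array_to_seq(y_final))
    haplotypes = {
        "X": HaplotypeSequence("X", array_to_seq(x_seq_arr)),
        "Y": HaplotypeSequence("Y", array_to_seq(y_final)),
        "Z": HaplotypeSequence("Z", array_to_seq(z)),
        "W": HaplotypeSequence("W", array_to_seq(w_seq_arr)),
        "OUT": HaplotypeSequence("OUT", array_to_seq(outg)),
    }
    query_gene = HaplotypeSequence("query_gene", array_to_seq(gene))

    # --- site classes ---
    hom_mask = np.zeros(L, dtype=bool)
    for a, b in segs:
        hom_mask[a:b] = True
    div_pos0 = np.flatnonzero((xa != y_final) & hom_mask)
    if 0 < sc.max_sdr_sites < div_pos0.shape[0]:
        keep = rng_pop.choice(
            div_pos0.shape[0], size=sc.max_sdr_sites, replace=False
        )
        keep_mask = np.zeros(div_pos0.shape[0], dtype=bool)
        keep_mask[keep] = True
        keep_mask |= np.isin(div_pos0, tracer_pos0)
        div_pos0 = div_pos0[keep_mask]

    ysp_len = y1 - y0
    n_ypoly = int(round(ysp_len * sc.y_poly_density))
    ypoly_pos0 = np.sort(
        rng_pop.choice(np.arange(y0, y1), size=min(n_ypoly, ysp_len), replace=False)
    )

    outside = np.concatenate([np.arange(0, s0), np.arange(s1, L)])
    bg_pos0 = np.sort(
        rng_pop.choice(outside, size=min(sc.n_background_snps, outside.shape[0]),
                       replace=False)
    )

    # --- species 1 population table (males X/Y, females X/X) ---
    n1 = sc.n_males + sc.n_females
    samples1 = [f"M{i+1:02d}" for i in range(sc.n_males)] + [
        f"F{i+1:02d}" for i in range(sc.n_females)
    ]
    sheet1 = SampleSheet(
        {s: (MALE if s.startswith("M") else FEMALE) for s in samples1}
    )
    male1 = np.arange(sc.n_males)

    pos_all = np.concatenate([div_pos0, ypoly_pos0, bg_pos0])
    order = np.argsort(pos_all, kind="stable")
    n_div, n_yp, n_bg = len(div_pos0), len(ypoly_pos0), len(bg_pos0)

    dos = np.zeros((len(pos_all), n1), dtype=np.int8)
    ref_b = np.empty(len(pos_all), dtype=np.uint8)
    alt_b = np.empty(len(pos_all), dtype=np.uint8)
    is_tracer = np.zeros(len(pos_all), dtype=bool)

    # divergent SDR sites: REF is the (Y-frame) reference base
    ref_b[:n_div] = y_final[div_pos0]
    alt_b[:n_div] = xa[div_pos0]
    dos[:n_div, male1] = 1  # het X/Y
    dos[:n_div, sc.n_males :] = 2  # hom X/X (alt)
    tracer_set = set(int(p) for p in tracer_pos0)
    is_tracer[:n_div] = np.array([int(p) in tracer_set for p in div_pos0])

    # Y-specific male-only polymorphism: females have no call
    sl = slice(n_div, n_div + n_yp)
    ref_b[sl] = y_final[ypoly_pos0]
    alt_b[sl] = _other_base(y_final[ypoly_pos0], rng_pop)
    freq = rng_pop.uniform(0.05, 0.5, n_yp)
    carrier = rng_pop.random((n_yp, sc.n_males)) < freq[:, None]
    dos[sl, : sc.n_males] = np.where(carrier, 2, 0)
    dos[sl, sc.n_males :] = -1

    # background SNPs: HWE in both sexes
    sl = slice(n_div + n_yp, None)
    ref_b[sl] = y_final[bg_pos0]
    alt_b[sl] = _other_base(y_final[bg_pos0], rng_pop)
    q = rng_pop.uniform(0.1, 0.5, n_bg)
    dos[sl] = (
        (rng_pop.random((n_bg, n1)) < q[:, None]).astype(np.int8)
        + (rng_pop.random((n_bg, n1)) < q[:, None]).astype(np.int8)
    )

    dos = _corrupt(dos, sc.error_rate, sc.missing_rate, rng_err)
    qc1 = _qc_annotations(len(pos_all), rng_qc, sc.qc_fail_fraction, is_tracer)
    species1 = _make_table(
        CHROM,
        (pos_all + 1)[order],
        ref_b[order],
        alt_b[order],
        dos[order],
        samples1,
        [qc1[i] for i in order],
    )

    # --- half-sib family (mother X/X; sons X/Y, daughters X/X) ---
    prog_is_male = rng_fam.random(sc.n_progeny) < 0.5
    if not prog_is_male.any():
        prog_is_male[0] = True
    if prog_is_male.all():
        prog_is_male[0] = False
    prog_names = [f"P{i+1:02d}" for i in range(sc.n_progeny)]
    pedigree = Pedigree(
        "MOTHER",
        {p: (MALE if m else FEMALE) for p, m in zip(prog_names, prog_is_male)},
    )
    fam_samples = ["MOTHER"] + prog_names
    nf = len(fam_samples)

    fam_pos = np.concatenate([div_pos0, bg_pos0])
    fdos = np.zeros((len(fam_pos), nf), dtype=np.int8)
    # SDR divergent sites: REF = Y allele, ALT = X allele
    fdos[:n_div, 0] = 2
    fdos[:n_div, 1:] = np.where(prog_is_male, 1, 2)
    # background: progeny draw one maternal allele plus a population allele
    mat = (
        (rng_fam.random((n_bg, 2)) < q[:, None]).astype(np.int8)
    )  # mother's two allele copies
    fdos[n_div:, 0] = mat.sum(axis=1)
    pick = rng_fam.integers(0, 2, (n_bg, sc.n_progeny))
    maternal = np.take_along_axis(
        np.repeat(mat[:, None, :], sc.n_progeny, axis=1),
        pick[:, :, None],
        axis=2,
    )[:, :, 0]
    paternal = (rng_fam.random((n_bg, sc.n_progeny)) < q[:, None]).astype(np.int8)
    fdos[n_div:, 1:] = maternal + paternal

    forder = np.argsort(fam_pos, kind="stable")
    fref = np.concatenate([y_final[div_pos0], ref_b[n_div + n_yp :]])
    falt = np.concatenate([xa[div_pos0], alt_b[n_div + n_yp :]])
    f_tracer = np.concatenate([is_tracer[:n_div], np.zeros(n_bg, dtype=bool)])
    fdos = _corrupt(fdos, sc.error_rate, sc.missing_rate, rng_err)
    qcf = _qc_annotations(len(fam_pos), rng_qc, sc.qc_fail_fraction, f_tracer)
    family = _make_table(
        CHROM,
        (fam_pos + 1)[forder],
        fref[forder],
        falt[forder],
        fdos[forder],
        fam_samples,
        [qcf[i] for i in forder],
    )

    # --- species 2 population (males Z/Z, females Z/W) ---
    samples2 = [f"ZM{i+1:02d}" for i in range(sc.n_males)] + [
        f"ZF{i+1:02d}" for i in range(sc.n_females)
    ]
    sheet2 = SampleSheet(
        {s: (MALE if s.startswith("ZM") else FEMALE) for s in samples2}
    )
    # Z/W fixed differences exist only where they cannot recombine: the SDR
    absent_w = np.zeros(L, dtype=bool)
    absent_w[:s0] = True
    absent_w[s1:] = True
    if sc.scenario == W_FROM_Y:
        for d in duplicates:
            absent_w[d.start : d.end] = True
    else:
        absent_w[y0:y1] = True
    zw_pos0 = np.flatnonzero((z != w_frame) & ~absent_w)
    if 0 < sc.max_species2_sites < zw_pos0.shape[0]:
        zw_pos0 = np.sort(
            rng_sp2.choice(zw_pos0, size=sc.max_species2_sites, replace=False)
        )
    bg2_pos0 = np.sort(
        rng_sp2.choice(outside, size=min(sc.n_background_snps, outside.shape[0]),
                       replace=False)
    )
    pos2 = np.concatenate([zw_pos0, bg2_pos0])
    n_zw = len(zw_pos0)
    dos2 = np.zeros((len(pos2), n1), dtype=np.int8)
    ref2 = np.empty(len(pos2), dtype=np.uint8)
    alt2 = np.empty(len(pos2), dtype=np.uint8)
    ref2[:n_zw] = z[zw_pos0]
    alt2[:n_zw] = w_frame[zw_pos0]
    dos2[:n_zw, sc.n_males :] = 1  # females Z/W het
    ref2[n_zw:] = z[bg2_pos0]
    alt2[n_zw:] = _other_base(z[bg2_pos0], rng_sp2)
    q2 = rng_sp2.uniform(0.1, 0.5, len(bg2_pos0))
    dos2[n_zw:] = (
        (rng_sp2.random((len(bg2_pos0), n1)) < q2[:, None]).astype(np.int8)
        + (rng_sp2.random((len(bg2_pos0), n1)) < q2[:, None]).astype(np.int8)
    )
    order2 = np.argsort(pos2, kind="stable")
    dos2 = _corrupt(dos2, sc.error_rate, sc.missing_rate, rng_err)
    qc2 = _qc_annotations(len(pos2), rng_qc, sc.qc_fail_fraction)
    species2 = _make_table(
        "chr15Z",
        (pos2 + 1)[order2],
        ref2[order2],
        alt2[order2],
        dos2[order2],
        samples2,
        [qc2[i] for i in order2],
    )

    # --- depth track for species 1 ---
    depth = simulate_depth_track(sc, rng_depth, sheet1, samples1)

    # --- truth ---
    exon_windows = [
        GenomicInterval(
            CHROM, int(p - sc.tracer_window), int(p + sc.tracer_window + 1), f"exon{i+1}"
        )
        for i, p in enumerate(tracer_pos0)
    ]
    w_origin_hap = ya if sc.scenario == W_FROM_Y else xa
    tracer_loci = [
        {
            "pos": int(p + 1),
            "x_allele": _BASES[xa[p]],
            "y_allele": _BASES[y_final[p]],
            "z_allele": _BASES[z[p]],
            "w_allele": _BASES[w_frame[p]],
            "w_ancestral_allele": _BASES[w_origin_hap[p]],
        }
        for p in tracer_pos0
    ]
    divergent_sites = [
        {"pos": int(p + 1), "y_allele": _BASES[y_final[p]], "x_allele": _BASES[xa[p]]}
        for p in div_pos0
    ]
    truth = TransitionTruth(
        scenario=sc.scenario,
        sdr=sc.sdr_interval,
        y_specific=sc.y_specific_interval,
        sequences={k: v.seq for k, v in haplotypes.items()},
        tracer_loci=tracer_loci,
        divergent_sites=divergent_sites,
        duplicates=duplicates,
        w_insert_intervals=[tuple(sp) for sp in w_inserts],
        exon_windows=exon_windows,
        sex_system={"species1": "XY", "species2": "ZW"},
    )

    result = SimulationResult(
        scenario=sc,
        truth=truth,
        reference=reference,
        haplotypes=haplotypes,
        query_gene=query_gene,
        species1=species1,
        sheet1=sheet1,
        species2=species2,
        sheet2=sheet2,
        family=family,
        pedigree=pedigree,
        depth=depth,
        exon_windows=exon_windows,
    )
    if out_dir is not None:
        write_simulation(result, out_dir)
    return result


def simulate_null_snps(
    n_snps: int,
    n_males: int = 24,
    n_females: int = 24,
    seed: int = 0,
    chrom: str = "chrNull",
) -> tuple[VariantTable, SampleSheet]:
    """Sex-independent HWE genotypes: a null panel for association error
    calibration. Complete calls, no QC annotations."""
    rng = _substream(seed, "null")
    n = n_males + n_females
    samples = [f"M{i+1:02d}" for i in range(n_males)] + [
        f"F{i+1:02d}" for i in range(n_females)
    ]
    sheet = SampleSheet({s: (MALE if s.startswith("M") else FEMALE) for s in samples})
    q = rng.uniform(0.1, 0.5, n_snps)
    dos = (
        (rng.random((n_snps, n)) < q[:, None]).astype(np.int8)
        + (rng.random((n_snps, n)) < q[:, None]).astype(np.int8)
    )
    ref = rng.integers(0, 4, n_snps).astype(np.uint8)
    alt = _other_base(ref, rng)
    qc = [{} for _ in range(n_snps)]
    return (
        _make_table(chrom, np.arange(1, n_snps + 1), ref, alt, dos, samples, qc),
        sheet,
    )


def simulate_depth_track(
    sc: TransitionScenario,
    rng: np.random.Generator | None = None,
    sheet: SampleSheet | None = None,
    samples: list[str] | None = None,
) -> DepthTrack:
    """Windowed per-sample mean depth: Poisson(lambda * copy_number / 2).

    Per-sample library-size factors are drawn from U(0.6, 1.6) so that
    median normalization downstream is actually exercised.
    """
    if rng is None:
        rng = _substream(sc.seed, "depth")
    if samples is None:
        samples = [f"M{i+1:02d}" for i in range(sc.n_males)] + [
            f"F{i+1:02d}" for i in range(sc.n_females)
        ]
        sheet = SampleSheet(
            {s: (MALE if s.startswith("M") else FEMALE) for s in samples}
        )
    assert sheet is not None
    n = len(samples)
    starts = np.arange(0, sc.length, sc.depth_window)
    ends = np.minimum(starts + sc.depth_window, sc.length)
    windows = [GenomicInterval(CHROM, int(a), int(b)) for a, b in zip(starts, ends)]
    y0, y1 = sc.y_specific
    overlap = np.maximum(
        0, np.minimum(ends, y1) - np.maximum(starts, y0)
    ) / (ends - starts)
    is_male = sheet.mask(samples, MALE)
    cn = np.empty((len(windows), n))
    cn[:, is_male] = (2.0 * (1 - overlap) + 1.0 * overlap)[:, None]
    cn[:, ~is_male] = (2.0 * (1 - overlap))[:, None]
    scale = rng.uniform(0.6, 1.6, n)
    lam = sc.mean_depth * scale[None, :] * cn / 2.0
    depth = rng.poisson(lam).astype(float)
    return DepthTrack(windows=windows, samples=list(samples), depth=depth, mq_floor=30)


def write_simulation(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus truth.json; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fa",
        "haplotypes": out / "haplotypes.fa",
        "query_gene": out / "query_gene.fa",
        "species1_vcf": out / "species1.vcf",
        "species1_samples": out / "species1_samples.tsv",
        "species2_vcf": out / "species2.vcf",
        "species2_samples": out / "species2_samples.tsv",
        "family_vcf": out / "family.vcf",
        "pedigree": out / "pedigree.tsv",
        "depth": out / "depth.tsv",
        "exons": out / "exons.bed",
        "truth": out / "truth.json",
    }
    write_fasta([result.reference], paths["reference"])
    write_fasta(result.haplotypes.values(), paths["haplotypes"])
    write_fasta([result.query_gene], paths["query_gene"])
    contigs = {CHROM: result.scenario.length}
    write_vcf(result.species1, paths["species1_vcf"], contigs)
    write_vcf(result.species2, paths["species2_vcf"], {"chr15Z": result.scenario.length})
    write_vcf(result.family, paths["family_vcf"], contigs)
    write_tsv(
        sorted(result.sheet1.sex.items()), paths["species1_samples"],
        header=("sample", "sex"),
    )
    write_tsv(
        sorted(result.sheet2.sex.items()), paths["species2_samples"],
        header=("sample", "sex"),
    )
    write_pedigree(result.pedigree, paths["pedigree"])
    write_depth_track(result.depth, paths["depth"])
    write_bed(result.exon_windows, paths["exons"])
    write_json(result.truth.to_json(), paths["truth"])
    return paths
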