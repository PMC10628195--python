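"""Readers/writers for the standard formats plus shared domain types.

Coordinate conventions are uniform across the package: VCF positions are
1-based, intervals (BED and :class:`GenomicInterval`) are 0-based half-open,
so a VCF position ``p`` maps to the interval ``[p - 1, p)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

QC_KEYS = ("MQ", "SOR", "QD", "FS", "MQRankSum", "ReadPosRankSum", "DP")

MALE = "male"
FEMALE = "female"

_DNA = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


class InputError(ValueError):
    """Structurally valid input that violates a precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """A biallelic SNP with per-sample genotypes and site QC annotations.

    ``genotypes`` is an ``(n_samples, 2)`` int8 array of allele indices
    (0 = ref, 1 = alt); a genotype with any allele < 0 is missing.
    ``qc`` holds numeric values for any of :data:`QC_KEYS` that were present;
    absent keys mean the annotation could not be evaluated.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: np.ndarray
    qc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise ValueError("genotypes must have shape (n_samples, 2)")

    @property
    def called(self) -> np.ndarray:
        """Boolean mask over samples: genotype fully called."""
        return (self.genotypes >= 0).all(axis=1)

    @property
    def call_rate(self) -> float:
        n = self.genotypes.shape[0]
        return float(self.called.sum()) / n if n else 0.0

    def interval(self) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.pos - 1, self.pos)


@dataclass
class VariantTable:
    """Sample order plus a list of :class:`VariantRecord`."""

    samples: list[str]
    records: list[VariantRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def genotype_matrix(self) -> np.ndarray:
        """Stack genotypes into an ``(n_records, n_samples, 2)`` array."""
        if not self.records:
            return np.empty((0, len(self.samples), 2), dtype=np.int8)
        return np.stack([r.genotypes for r in self.records])


@dataclass
class SampleSheet:
    """Mapping of sample id to sex label (``male``/``female``)."""

    sex: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.sex.values()} - {MALE, FEMALE}
        if bad:
            raise InputError(f"unknown sex labels: {sorted(bad)}")

    @property
    def males(self) -> list[str]:
        return [s for s, x in self.sex.items() if x == MALE]

    @property
    def females(self) -> list[str]:
        return [s for s, x in self.sex.items() if x == FEMALE]

    def mask(self, samples: Sequence[str], label: str) -> np.ndarray:
        return np.array([self.sex.get(s) == label for s in samples], dtype=bool)

    def swapped(self) -> "SampleSheet":
        flip = {MALE: FEMALE, FEMALE: MALE}
        return SampleSheet({s: flip[x] for s, x in self.sex.items()})


@dataclass
class Pedigree:
    """One mother plus sexed half-sib progeny."""

    mother: str
    progeny_sex: dict[str, str]

    def __post_init__(self) -> None:
        if self.mother in self.progeny_sex:
            raise InputError("mother listed among progeny")
        bad = set(self.progeny_sex.values()) - {MALE, FEMALE}
        if bad:
            raise InputError(f"unknown sex labels: {sorted(bad)}")

    @property
    def sons(self) -> list[str]:
        return [p for p, x in self.progeny_sex.items() if x == MALE]

    @property
    def daughters(self) -> list[str]:
        return [p for p, x in self.progeny_sex.items() if x == FEMALE]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end

    def jaccard(self, other: "GenomicInterval") -> float:
        if self.chrom != other.chrom:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return 0.0
        union = len(self) + len(other) - inter
        return inter / union


@dataclass
class HaplotypeSequence:
    """A named DNA sequence, canonically uppercase over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"empty sequence {self.name!r}")
        if set(self.seq) - _DNA:
            raise FormatError(
                f"sequence {self.name!r} has non-DNA characters: "
                f"{sorted(set(self.seq) - _DNA)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> VariantTable:
    """Read biallelic SNPs from a VCF 4.x file.

    Multiallelic and indel records are dropped (count logged). INFO keys from
    :data:`QC_KEYS` are surfaced when present; absent keys stay absent.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"VCF {path} has zero samples")
    records: list[VariantRecord] = []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int8)
        gts[(gts < 0).any(axis=1)] = -1
        qc = {}
        for key in QC_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                qc[key] = float(val)
        records.append(
            VariantRecord(v.CHROM, v.POS, v.REF, v.ALT[0], gts, qc)
        )
    vcf.close()
    if n_dropped:
        log.info("read_vcf(%s): dropped %d multiallelic/indel records", path, n_dropped)
    return VariantTable(samples, records)


_GT_STR = {-1: ".", 0: "0", 1: "1"}


def write_vcf(table: VariantTable, path: str | Path, contigs: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 file (GT format, QC values in INFO)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    for key in QC_KEYS:
        num_type = "Integer" if key == "DP" else "Float"
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={num_type},Description="{key}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
    )
    for r in table.records:
        if r.qc:
            info = ";".join(
                f"{k}={int(v) if k == 'DP' else round(float(v), 4)}"
                for k, v in r.qc.items()
            )
        else:
            info = "."
        gts = "\t".join(
            f"{_GT_STR[int(a)]}/{_GT_STR[int(b)]}" for a, b in r.genotypes
        )
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[HaplotypeSequence]:
    from Bio import SeqIO

    seqs = [
        HaplotypeSequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise FormatError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: Iterable[HaplotypeSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: expected >= 3 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
        label = parts[3] if len(parts) > 3 else ""
        intervals.append(GenomicInterval(parts[0], start, end, label))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")


def write_tsv(rows: Iterable[Sequence], path: str | Path, header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Two-column TSV: sample id, sex label."""
    sex: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{ln}: expected 2 columns")
        if ln == 1 and parts[1].strip().lower() == "sex":
            continue  # header row
        if parts[0] in sex:
            raise FormatError(f"{path}:{ln}: duplicate sample id {parts[0]!r}")
        sex[parts[0]] = parts[1].strip().lower()
    return SampleSheet(sex)


def read_pedigree(path: str | Path) -> Pedigree:
    """TSV with rows ``id<TAB>role<TAB>sex`` where role is mother/progeny."""
    mother = None
    progeny: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: expected 3 columns")
        sid, role, sex = parts[0], parts[1].lower(), parts[2].lower()
        if ln == 1 and role == "role":
            continue  # header row
        if role == "mother":
            if mother is not None:
                raise FormatError(f"{path}:{ln}: second mother row")
            mother = sid
        elif role == "progeny":
            progeny[sid] = sex
        else:
            raise FormatError(f"{path}:{ln}: unknown role {role!r}")
    if mother is None:
        raise InputError(f"{path}: no mother row")
    return Pedigree(mother, progeny)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    rows = [(ped.mother, "mother", FEMALE)]
    rows += [(p, "progeny", x) for p, x in ped.progeny_sex.items()]
    write_tsv(rows, path, header=("sample", "role", "sex"))


# ---------------------------------------------------------------------------
# Newick / JSON
# ---------------------------------------------------------------------------


def read_newick(path: str | Path):
    """Parse a Newick tree (branch lengths, internal support labels)."""
    import dendropy

    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick {path}: {exc}") from exc


def write_newick(tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, GenomicInterval):
        return {"chrom": o.chrom, "start": o.start, "end": o.end, "label": o.label}
    raise TypeError(f"not JSON serializable: {type(o)}")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")

# 2-bit base codec shared by the simulator and the alignment-free placers
_BASES = "ACGT"
_ENC_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC_TABLE[ord(_b)] = _i
_DEC_TABLE = np.frombuffer(_BASES.encode(), dtype=np.uint8)


def seq_to_array(seq: str) -> np.ndarray:
    """Encode ACGT to uint8 codes 0..3 (raises on other characters)."""
    arr = _ENC_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def array_to_seq(arr: np.ndarray) -> str:
    return _DEC_TABLE[arr].tobytes().decode()
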