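"""Infer Y-specific and X-specific alleles in the SDR from a mother and her
sexed half-sib progeny.

At a biallelic SDR site an allele is called the Y allele iff it is carried
heterozygously by all non-missing male progeny (up to ``tol`` exceptions),
is absent from the mother's genotype, and absent from all non-missing female
progeny (up to ``tol`` exceptions). The X allele is the site's other allele
as carried by the female progeny; missing genotypes are excluded from both
the "present" and "absent" tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    GenomicInterval,
    InputError,
    Pedigree,
    VariantTable,
)
from .sex_assoc import AssociationRecord


@dataclass
class PhasedSdrAllele:
    chrom: str
    pos: int
    y_allele: str
    x_allele: str
    n_male_support: int
    n_female_support: int
    female_minority_allele: str | None = None
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.y_allele == self.x_allele:
            raise ValueError("y_allele must differ from x_allele")


def phase_sdr(
    table: VariantTable,
    pedigree: Pedigree,
    sdr: list[GenomicInterval],
    tol: int = 0,
) -> list[PhasedSdrAllele]:
    """Phase X/Y alleles at biallelic SDR sites from the half-sib family."""
    if not pedigree.sons or not pedigree.daughters:
        raise InputError("pedigree needs progeny of both sexes")
    index = {s: i for i, s in enumerate(table.samples)}
    try:
        i_mother = index[pedigree.mother]
        i_sons = np.array([index[p] for p in pedigree.sons])
        i_daughters = np.array([index[p] for p in pedigree.daughters])
    except KeyError as exc:
        raise InputError(f"pedigree sample {exc} not in VCF") from exc

    phased: list[PhasedSdrAllele] = []
    for rec in table.records:
        if not any(iv.contains(rec.chrom, rec.pos - 1) for iv in sdr):
            continue
        gt = rec.genotypes
        called = rec.called
        alleles = (rec.ref, rec.alt)
        mother_called = bool(called[i_mother])
        if not mother_called:
            continue  # cannot apply the maternal-exclusion clause
        mother = set(gt[i_mother])
        call = None
        for a in (0, 1):
            if a in mother:
                continue  # maternal origin possible: exclusion clause
            sons_called = called[i_sons]
            if sons_called.sum() == 0:
                continue
            son_gt = gt[i_sons][sons_called]
            carries_het = (son_gt == a).any(axis=1) & (
                son_gt[:, 0] != son_gt[:, 1]
            )
            if (~carries_het).sum() > tol:
                continue
            dau_called = called[i_daughters]
            dau_gt = gt[i_daughters][dau_called]
            dau_carries = (dau_gt == a).any(axis=1)
            if dau_carries.sum() > tol:
                continue
            if dau_called.sum() == 0:
                continue
            # X allele: the other allele, as carried by the female progeny
            other = 1 - a
            dau_alleles = dau_gt.ravel()
            n_other = int((dau_alleles == other).sum())
            n_a = int((dau_alleles == a).sum())
            if n_other == 0:
                continue
            minority = alleles[a] if n_a else None
            call = PhasedSdrAllele(
                chrom=rec.chrom,
                pos=rec.pos,
                y_allele=alleles[a],
                x_allele=alleles[other],
                n_male_support=int(carries_het.sum()),
                n_female_support=int((~dau_carries).sum()),
                female_minority_allele=minority,
            )
            break
        if call is not None:
            phased.append(call)
    return phased


_PHASED_COLS = (
    "chrom pos y_allele x_allele n_male_support n_female_support "
    "female_minority_allele confirmed"
).split()


def write_phased(phased: list[PhasedSdrAllele], path) -> None:
    from .core_io import write_tsv

    rows = [
        (p.chrom, p.pos, p.y_allele, p.x_allele, p.n_male_support,
         p.n_female_support, p.female_minority_allele or ".", int(p.confirmed))
        for p in phased
    ]
    write_tsv(rows, path, header=_PHASED_COLS)


def read_phased(path) -> list[PhasedSdrAllele]:
    from pathlib import Path

    out = []
    for line in Path(path).read_text().splitlines()[1:]:
        f = line.split("\t")
        out.append(
            PhasedSdrAllele(
                chrom=f[0], pos=int(f[1]), y_allele=f[2], x_allele=f[3],
                n_male_support=int(f[4]), n_female_support=int(f[5]),
                female_minority_allele=None if f[6] == "." else f[6],
                confirmed=bool(int(f[7])),
            )
        )
    return out


def confirm_sex_linkage(
    phased: list[PhasedSdrAllele],
    assoc: list[AssociationRecord],
    radius: int = 0,
) -> list[PhasedSdrAllele]:
    """Flag each phased site that is (or is within ``radius`` of) a
    Bonferroni-significant SNP in an independent association scan. Sites
    without a match are retained with ``confirmed=False``."""
    sig_by_chrom: dict[str, np.ndarray] = {}
    for r in assoc:
        if r.significant:
            sig_by_chrom.setdefault(r.chrom, []).append(r.pos)  # type: ignore[attr-defined]
    sig_sorted = {c: np.sort(np.array(v)) for c, v in sig_by_chrom.items()}
    for p in phased:
        positions = sig_sorted.get(p.chrom)
        if positions is None or positions.size == 0:
            p.confirmed = False
            continue
        i = np.searchsorted(positions, p.pos)
        near = []
        if i < positions.size:
            near.append(abs(int(positions[i]) - p.pos))
        if i > 0:
            near.append(abs(int(positions[i - 1]) - p.pos))
        p.confirmed = bool(near and min(near) <= radius)
    return phased
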