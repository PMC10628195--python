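"""Per-SNP sex association with Bonferroni control, SDR interval
summarization, and heterogamety classification.

The default test is Fisher's exact test on the 2x2 sex-by-allele count
table, computed by explicit hypergeometric enumeration (vectorized across
sites); the 1-df allelic chi-square is available for PLINK comparability.
Monomorphic sites are excluded from testing and from the Bonferroni
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import (
    FEMALE,
    MALE,
    GenomicInterval,
    InputError,
    SampleSheet,
    VariantTable,
)


@dataclass
class AssociationRecord:
    chrom: str
    pos: int
    # genotype counts per sex: rows (male, female), cols (hom-ref, het, hom-alt)
    genotype_counts: np.ndarray
    p_value: float
    significant: bool
    tested: bool = True


@dataclass
class SexGwasResult:
    records: list[AssociationRecord]
    n_tested: int
    alpha: float
    threshold: float  # alpha / n_tested

    @property
    def significant(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.significant]


def _fisher_two_sided(k, n1, n2, K) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for 2x2 tables.

    ``k``: alt alleles in group 1 (observed), ``n1``/``n2``: allele totals per
    group, ``K``: total alt alleles. Enumerates the full hypergeometric
    support and sums probabilities <= P(observed), the classical definition.
    """
    k = np.asarray(k)
    M = n1 + n2
    jmax = int(np.minimum(n1, K).max(initial=0))
    j = np.arange(jmax + 1)
    pmf = stats.hypergeom.pmf(j[None, :], M[:, None], K[:, None], n1[:, None])
    pmf = np.nan_to_num(pmf, nan=0.0)
    obs = pmf[np.arange(k.shape[0]), k]
    mask = pmf <= obs[:, None] * (1 + 1e-7)
    return np.minimum((pmf * mask).sum(axis=1), 1.0)


def _chi2_allelic(k, n1, n2, K) -> np.ndarray:
    """1-df Pearson chi-square on the 2x2 allele-count table."""
    M = n1 + n2
    a, b = k, n1 - k
    c, d = K - k, n2 - (K - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = M * (a * d - b * c) ** 2 / (K * (M - K) * n1 * n2)
    return stats.chi2.sf(chi2, df=1)


def sex_gwas(
    table: VariantTable,
    sexes: SampleSheet,
    alpha: float = 0.05,
    method: str = "fisher",
) -> SexGwasResult:
    """Test each SNP for sex association on allele counts; flag records
    significant at the Bonferroni-adjusted ``alpha``."""
    male = sexes.mask(table.samples, MALE)
    female = sexes.mask(table.samples, FEMALE)
    if not male.any() or not female.any():
        raise InputError("sex_gwas needs samples of both sexes")
    if method not in ("fisher", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    if not table.records:
        return SexGwasResult([], 0, alpha, np.nan)

    gt = table.genotype_matrix()  # (R, S, 2)
    called = (gt >= 0).all(axis=2)
    dose = np.where(called, gt.sum(axis=2), 0).astype(np.int64)

    def sex_counts(mask):
        n_called = (called & mask[None, :]).sum(axis=1)
        alt = (dose * (called & mask[None, :])).sum(axis=1)
        counts = np.stack(
            [
                ((dose == g) & called & mask[None, :]).sum(axis=1)
                for g in (0, 1, 2)
            ],
            axis=1,
        )
        return 2 * n_called, alt, counts

    n1, k1, male_counts = sex_counts(male)
    n2, k2, female_counts = sex_counts(female)
    K = k1 + k2
    total = n1 + n2
    polymorphic = (K > 0) & (K < total) & (n1 > 0) & (n2 > 0)

    p = np.full(len(table.records), np.nan)
    if polymorphic.any():
        idx = np.flatnonzero(polymorphic)
        if method == "fisher":
            p[idx] = _fisher_two_sided(k1[idx], n1[idx], n2[idx], K[idx])
        else:
            p[idx] = _chi2_allelic(k1[idx], n1[idx], n2[idx], K[idx])

    n_tested = int(polymorphic.sum())
    threshold = alpha / n_tested if n_tested else np.nan
    records = []
    for i, rec in enumerate(table.records):
        records.append(
            AssociationRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                genotype_counts=np.stack([male_counts[i], female_counts[i]]),
                p_value=float(p[i]),
                significant=bool(polymorphic[i] and p[i] <= threshold),
                tested=bool(polymorphic[i]),
            )
        )
    return SexGwasResult(records, n_tested, alpha, threshold)


def permutation_fwer(
    table: VariantTable,
    sexes: SampleSheet,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise false-positive rate of the Bonferroni-corrected Fisher
    scan under random sex-label permutations.

    Requires complete genotypes (fixed table margins), which lets the
    per-site p-value be precomputed as a lookup over the male alt-allele
    count. Returns the fraction of permutations with >= 1 significant SNP.
    """
    gt = table.genotype_matrix()
    if (gt < 0).any():
        raise InputError("permutation_fwer requires complete genotypes")
    male = sexes.mask(table.samples, MALE)
    n_males = int(male.sum())
    n_samples = len(table.samples)
    if n_males == 0 or n_males == n_samples:
        raise InputError("need samples of both sexes")
    dose = gt.sum(axis=2).astype(np.int64)  # (R, S)
    K = dose.sum(axis=1)
    total = 2 * n_samples
    poly = (K > 0) & (K < total)
    dose = dose[poly]
    K = K[poly]
    R = dose.shape[0]
    if R == 0:
        return 0.0
    threshold = alpha / R
    n1 = 2 * n_males
    jmax = int(np.minimum(n1, K).max())
    j = np.arange(jmax + 1)
    pmf = stats.hypergeom.pmf(
        j[None, :], np.full(R, total)[:, None], K[:, None], n1
    )
    pmf = np.nan_to_num(pmf, nan=0.0)
    # p(k) = sum of pmf no larger than pmf(k): (R, jmax+1) lookup
    plook = np.empty_like(pmf)
    for k in range(jmax + 1):
        mask = pmf <= pmf[:, k][:, None] * (1 + 1e-7)
        plook[:, k] = (pmf * mask).sum(axis=1)
    plook = np.minimum(plook, 1.0)

    rng = np.random.default_rng(seed)
    indicator = np.zeros((n_samples, n_perm), dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(n_samples)[:n_males]
        indicator[perm, b] = 1
    kmat = dose @ indicator  # (R, n_perm) male alt counts
    pmin = plook[np.arange(R)[:, None], kmat].min(axis=0)
    return float((pmin <= threshold).mean())


def sdr_interval(
    significant: list[AssociationRecord], gap: int = 500_000
) -> list[GenomicInterval]:
    """Cluster significant SNP positions per chromosome, merging neighbors
    <= ``gap`` apart; each cluster becomes its min-max span (>= 1 bp)."""
    import logging

    if not significant:
        logging.getLogger(__name__).warning("sdr_interval: no significant SNPs")
        return []
    by_chrom: dict[str, list[int]] = {}
    for r in significant:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    out = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        start = prev = positions[0]
        for pos in positions[1:]:
            if pos - prev > gap:
                out.append(GenomicInterval(chrom, start - 1, prev, "sdr"))
                start = pos
            prev = pos
        out.append(GenomicInterval(chrom, start - 1, prev, "sdr"))
    return out


_ASSOC_COLS = (
    "chrom pos p_value significant tested "
    "male_homref male_het male_homalt female_homref female_het female_homalt"
).split()


def write_assoc(result: SexGwasResult, path) -> None:
    from .core_io import write_tsv

    rows = []
    for r in result.records:
        m, f = r.genotype_counts
        rows.append(
            (r.chrom, r.pos, f"{r.p_value:.6g}", int(r.significant),
             int(r.tested), *m.tolist(), *f.tolist())
        )
    write_tsv(rows, path, header=_ASSOC_COLS)


def read_assoc(path) -> list[AssociationRecord]:
    from pathlib import Path

    records = []
    for line in Path(path).read_text().splitlines()[1:]:
        f = line.split("\t")
        records.append(
            AssociationRecord(
                chrom=f[0],
                pos=int(f[1]),
                genotype_counts=np.array(
                    [[int(x) for x in f[5:8]], [int(x) for x in f[8:11]]]
                ),
                p_value=float(f[2]),
                significant=bool(int(f[3])),
                tested=bool(int(f[4])),
            )
        )
    return records


@dataclass
class HeterogametyCall:
    male_het: float
    male_hom: float
    female_het: float
    female_hom: float
    system: str  # XY | ZW | ambiguous
    n_snps: int = 0


def classify_heterogamety(
    table: VariantTable,
    significant: list[AssociationRecord],
    sexes: SampleSheet,
    t: float = 0.8,
) -> HeterogametyCall:
    """Average per-sex heterozygosity/homozygosity fractions over the
    significant SNPs (per SNP over called genotypes, then over SNPs):
    XY iff male het >= t and female hom >= t; ZW for the mirror; else
    ambiguous."""
    male = sexes.mask(table.samples, MALE)
    female = sexes.mask(table.samples, FEMALE)
    m_het, f_het = [], []
    by_pos = {(r.chrom, r.pos): r for r in table.records}
    seen = set()
    for s in significant:
        key = (s.chrom, s.pos)
        rec = by_pos.get(key)
        if rec is None or key in seen:
            continue
        seen.add(key)
        called = rec.called
        het = rec.genotypes[:, 0] != rec.genotypes[:, 1]
        for mask, acc in ((male, m_het), (female, f_het)):
            n = (called & mask).sum()
            if n:
                acc.append((het & called & mask).sum() / n)
    if not m_het or not f_het:
        return HeterogametyCall(np.nan, np.nan, np.nan, np.nan, "ambiguous", 0)
    male_het = float(np.mean(m_het))
    female_het = float(np.mean(f_het))
    male_hom = 1.0 - male_het
    female_hom = 1.0 - female_het
    if male_het >= t and female_hom >= t:
        system = "XY"
    elif female_het >= t and male_hom >= t:
        system = "ZW"
    else:
        system = "ambiguous"
    return HeterogametyCall(
        male_het, male_hom, female_het, female_hom, system, len(m_het)
    )
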