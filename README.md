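# heterotrace

Trace sex-determination regions (SDRs) through a homologous XY → ZW
sex-chromosome turnover. Given population VCFs, sex labels, a half-sib
pedigree, haplotype FASTAs and a windowed depth track, `heterotrace`:

1. hard-filters variants and enforces the genotype call-rate rule
   (`variant_qc`),
2. runs a per-SNP sex GWAS with Bonferroni control, summarizes the SDR span
   and classifies heterogamety (XY vs ZW) from sex-specific
   het/homozygosity (`sex_assoc`),
3. detects hemizygous (Y-specific) sequence from male/female depth and
   SNP-call density, and applies the X-contig selection rule
   (`hemizygosity`),
4. phases X- and Y-specific alleles from a mother plus sexed half-sib
   progeny by maternal exclusion (`phase_halfsib`),
5. places each phased allele onto other haplotypes (e.g. a second species'
   Z and W) via 150-bp flanks with a seed-and-extend placer, and counts
   allele identity (`trace_origin`),
6. scans chromosomes for (partial) duplicates of a query gene with a
   BLAST-like word-8 local aligner, pairs homologous duplicates across
   chromosomes and flags palindromes (`duplicates`),
7. builds a Jukes–Cantor + neighbor-joining tree with column bootstrap over
   the concatenated exon windows, tests monophyly, and combines both
   evidence lines into a W-origin verdict: `W_from_Y`, `W_from_X`, or
   `undetermined` (`phylo_verdict`).

A forward simulator of the whole transition (`simulate`) emits every input
the pipeline consumes — two species' population VCFs, a half-sib family
VCF + pedigree, depth track, haplotype/reference/query FASTAs, exon
windows — plus a `truth.json` ground-truth record, so every stage is
testable end to end without external data.

## CLI

Everything is exposed through one `heterotrace` entry point.
The quickest tour is a full simulated run:

```sh
heterotrace all --seed 7 --out run/        # simulate + every stage
cat run/verdict.json
```

Stage by stage (all file formats are plain text — VCF 4.2, FASTA, BED,
TSV, Newick, JSON):

```sh
heterotrace simulate --config cfg.yaml --out sim/     # cfg keys = TransitionScenario fields
heterotrace filter   --vcf sim/species1.vcf --out f.vcf --report tally.tsv
heterotrace assoc    --vcf f.vcf --sexes sim/species1_samples.tsv \
                     --out assoc.tsv --sdr-bed sdr.bed
heterotrace classify --assoc assoc.tsv --vcf f.vcf --sexes sim/species1_samples.tsv
heterotrace hemiscan --depth sim/depth.tsv --sexes sim/species1_samples.tsv --out ys.bed
heterotrace snpscan  --vcf sim/species1.vcf --sexes sim/species1_samples.tsv --out depleted.bed
heterotrace xcontigs --annot contigs.tsv              # contig / length / gene-count TSV
heterotrace phase    --vcf sim/family.vcf --pedigree sim/pedigree.tsv \
                     --sdr sdr.bed --assoc assoc.tsv --out phased.tsv
heterotrace trace    --phased phased.tsv --source sim/reference.fa \
                     --targets sim/haplotypes.fa --out trace.tsv --links links.tsv
heterotrace dupscan  --query sim/query_gene.fa --target sim/reference.fa --out hits.tsv
heterotrace duppair  --a hitsY.tsv --b hitsZ.tsv --out pairs.tsv
heterotrace tree     --alignment concat.fa --bootstrap 100 --seed 7 --out tree.nwk
heterotrace verdict  --trace trace.tsv --tree tree.nwk --out verdict.json
```

## Simulator outputs (`heterotrace simulate --out dir/`)

| file | content |
| --- | --- |
| `reference.fa` | species-1 male assembly (Y frame, incl. Y-specific region) |
| `haplotypes.fa` | final X, Y, Z, W and outgroup (OUT) sequences |
| `species1.vcf` / `species1_samples.tsv` | XY-species population genotypes + sexes |
| `species2.vcf` / `species2_samples.tsv` | ZW-species population genotypes + sexes |
| `family.vcf` / `pedigree.tsv` | mother + sexed half-sib progeny |
| `depth.tsv` | per-5-kb per-sample mean depth (`chrom start end sample...`) |
| `exons.bed` | exon-anchored tracer windows (capture targets) |
| `query_gene.fa` | the intact query gene used for duplicate scanning |
| `truth.json` | scenario, SDR / Y-specific intervals, tracer alleles, planted duplicates, W insertions, sex systems |

`truth.json` keys: `scenario` (`W_from_Y`/`W_from_X`), `sdr` and
`y_specific` (0-based half-open), `tracer_loci` (1-based `pos` with
`x/y/z/w_allele` and `w_ancestral_allele`), `divergent_sites` (all X≠Y SDR
sites), `duplicates` (frame intervals, strand, query interval),
`w_insert_intervals` (final W coordinates of the intact-gene palindromic
blocks), `exon_windows`, `sex_system`.

The same scenario seed reproduces byte-identical outputs.

## Conventions

VCF positions are 1-based; BED and all in-memory intervals are 0-based
half-open (VCF pos *p* ↔ interval `[p−1, p)`). Sex labels live in a
two-column TSV sidecar (`sample<TAB>male|female`), never in the VCF.
Multiallelic and indel records are dropped on read. A missing QC
annotation passes its filter criterion unless `FilterPolicy(strict=True)`.
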