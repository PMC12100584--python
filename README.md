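# hybridpaint

Hybrid-zone genomics from low-coverage genotype data: detect
ancestry-informative markers (AIMs) between two parental panels, classify
hybrids (F1 / F2 / backcross) from hybrid index and interspecific
heterozygosity, estimate admixture proportions from genotype likelihoods, and
localise introgression along chromosomes with a windowed admixture-painting
method that controls for incomplete lineage sorting (ILS).

## The problem

When two recently diverged species meet and hybridise — the motivating case
is a pair of sister bird-of-paradise species meeting along an elevational
contact zone, sampled largely from low-coverage museum specimens — three
questions arise:

1. **Is a given individual a hybrid, and of what generation?**
2. **Which chromosomal regions carry introgressed ancestry?**
3. **Is an apparently introgressed region really introgression, or shared
   ancestral polymorphism (ILS)?**

`hybridpaint` answers these with hard-call genotypes where coverage allows
and genotype likelihoods where it does not, and ships a seeded simulator of
hybrid genomes with known ancestry truth (ZW sex chromosomes, Poisson
recombination, fixed differences plus shared ancestral polymorphism,
Poisson-depth read noise) so every method is testable end to end.

## Methods at a glance

* **AIMs** — sites fixed for different alleles between the two parental
  reference panels (per-site Weir–Cockerham θ̂ = 1).  For a hybrid genotyped
  at *n*<sub>AA</sub> + *n*<sub>Aa</sub> + *n*<sub>aa</sub> called AIMs:
  hybrid index *h* = (2·*n*<sub>AA</sub> + *n*<sub>Aa</sub>) / 2(*n*<sub>AA</sub> +
  *n*<sub>Aa</sub> + *n*<sub>aa</sub>) and interspecific heterozygosity
  *H* = *n*<sub>Aa</sub> / (*n*<sub>AA</sub> + *n*<sub>Aa</sub> + *n*<sub>aa</sub>).
  On the (*h*, *H*) triangle: F1 at (0.5, 1), F2 at (0.5, 0.5), first
  backcrosses at (0.25, 0.5) / (0.75, 0.5), *H* halving each further
  backcross generation.
* **Genotype-likelihood admixture** — the K-population binomial mixture
  model: individual *i*'s alt dose at site *j* has prior Binomial(2, a_ij)
  with a_ij = Σ_k Q_ik F_kj; the genotype is marginalised through the GL
  triple.  Fit by EM (monotone in log-likelihood) with multi-restart
  best-likelihood selection.
* **Windowed painting** — chromosomes are split into 9 / 7 / 5 equal windows
  (macro > 40 Mbp, intermediate 20–40 Mbp, micro < 20 Mbp); K=2 admixture is
  fit per window over both reference panels and all hybrids jointly and
  oriented so Q_A = 1 is pure parent A.  Windows where any reference
  individual itself appears admixed are flagged as putative ILS and excluded
  from summaries; the per-window median Q_A across hybrids is drawn as an
  ideogram and size-class boxplots.
* **Population-genetic support** — hard-call filters (genotype depth ≥ 2×,
  site MAF ≥ 0.03, call rate ≥ 90%, bounded site depth), LD thinning by
  keeping every 50th variant, windowed two-population Weir–Cockerham F_ST
  (ratio-of-sums over 50-kb windows), and frequency-weighted Patterson's D
  (ABBA–BABA) with a block-jackknife Z score.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a simulated
hybrid zone (5 + 5 parental references, an outgroup, one F2-like and five
backcross-like hybrids on a 30-chromosome avian-style genome) and write their
tables under `results/`:

```bash
python analysis/01_simulate_hybrid_zone.py
python analysis/02_filter_fst_dstat.py
python analysis/03_aims_triangle.py
python analysis/04_genomewide_admixture.py
python analysis/05_paint_chromosomes.py
```

`03_aims_triangle.py` prints, for the bundled seed:

```
2095 AIMs detected between the parental panels
  hyb21: h=0.575, H=0.433, homozygous AIMs 56.7% -> F2
  hyb22: h=0.246, H=0.487, homozygous AIMs 51.3% -> backcross_into_B
  hyb23: h=0.188, H=0.374, homozygous AIMs 62.6% -> later_generation
  hyb24: h=0.257, H=0.506, homozygous AIMs 49.4% -> backcross_into_B; female Z alleles: 4 A vs 126 B
  hyb25: h=0.214, H=0.422, homozygous AIMs 57.8% -> backcross_into_B
  hyb26: h=0.273, H=0.539, homozygous AIMs 46.1% -> backcross_into_B; female Z alleles: 5 A vs 125 B
```

The F2-like hybrid sits near the (0.5, 0.5) triangle vertex with roughly half
its AIMs homozygous; the backcrosses cluster near (0.25, 0.5); the two female
backcrosses carry an essentially pure parent-B Z chromosome (their single Z
is paternal).  One true backcross (hyb23) drifts into the `later_generation`
band — with a finite karyotype the (h, H) coordinates of a single individual
scatter around their pedigree expectation.  `05_paint_chromosomes.py` then
shows the same hybrids window by window, e.g. a Z chromosome painted Q_A ≈ 0
in every window while autosomal windows carrying retained donor tracts rise
towards 0.5.

The same functionality is exposed as CLI subcommands (`hybridpaint simulate |
filter | fst | dstat | aims | admix | paint`), each writing TSV (and
optionally PNG) outputs.

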