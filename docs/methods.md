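# Methods

This note documents the models implemented in `hybridpaint`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Ancestry-informative markers and hybrid classification

An AIM is a biallelic SNP at which every called genotype in the parent-A
reference panel is homozygous for one allele and every called genotype in the
parent-B panel homozygous for the other.  This is equivalent to a per-site
two-population Weir–Cockerham θ̂ of 1, and `detect_aims` is tested against
both an exhaustive per-site enumeration and the F_ST components.  A site is
only evaluable once each panel has a minimum number of non-missing calls
(default 2): the upstream call-rate filter keeps missingness low, but small
panels need an explicit floor so a single called genotype cannot declare a
site "fixed".

For a hybrid genotyped at the AIM set, with counts n_AA (homozygous parent-A
allele), n_Aa (heterozygous), n_aa (homozygous parent-B) over called AIMs:

    h = (2 n_AA + n_Aa) / (2 (n_AA + n_Aa + n_aa))
    H = n_Aa / (n_AA + n_Aa + n_aa)

Missing AIMs are excluded from every denominator.  Generation classes are
assigned from bands of half-width `tol` (default 0.1 on both axes) around the
pedigree expectations: parentals (0, 0) / (1, 0), F1 (0.5, 1), F2 (0.5, 0.5),
first backcrosses (0.25, 0.5) and (0.75, 0.5); profiles with H below the BC1
band but intermediate h are called `later_generation`, anything else
`unclassified`.  The underlying field convention draws no numeric boundaries,
so the bands are configurable and always reported alongside the call.  Note
that the spread of (h, H) around the pedigree expectation is governed by the
number of independently segregating chromosomes: single individuals on small
karyotypes legitimately wander out of their band, which is why cohort-level
tests (and users) should judge distributions, not single points.

Sex linkage: males are ZZ and females ZW, so a female's Z genotypes are
hemizygous.  Z-linked AIMs enter h and H only for males; a female's single-Z
allele counts (parent A vs parent B) are reported separately — they are the
direct read-out of her paternal Z ancestry.

## Genotype-likelihood admixture (EM)

The admixture model for low-coverage data: individual i draws each of its two
allele copies at site j from ancestral population k with probability Q_ik,
and the copy is the alternate allele with probability F_kj.  With
a_ij = Σ_k Q_ik F_kj the genotype prior is Binomial(2, a_ij), and the
observed-data log-likelihood marginalises the unknown genotype through the
normalised genotype-likelihood triple GL_ijg:

    loglik = Σ_ij log Σ_g GL_ijg · C(2,g) a_ij^g (1 − a_ij)^(2−g)

Fitting is plain EM on expected ancestry-labelled allele counts.  Plain EM
(rather than quasi-Newton acceleration) was chosen because its monotonicity
is a testable invariant and the window-sized problems the painter creates are
small; the test suite asserts a non-decreasing log-likelihood trace on every
fit it makes.  Details:

* **Restarts.** Initialisation draws Q rows from a symmetric Dirichlet(1) and
  F from the empirical per-site frequency plus uniform ±0.3 noise, from a
  generator seeded per fit; the default is 10 restarts and the repetition
  with the highest likelihood is returned, with all restart likelihoods kept
  in the result.  Identical seeds give bit-identical fits.
* **Convergence.** Δloglik < 1e-6 between iterations, max 2000 iterations; a
  fit that hits the cap is returned flagged `converged=False`.
* **Bounds.** F is clamped to [1e-6, 1 − 1e-6] to keep log terms finite.
* **Missing data.** An exactly uniform GL triple means "no reads"; such
  entries are excluded from the likelihood and the expected counts, so empty
  genotypes cannot pull Q toward the prior.  Each individual's Q denominator
  uses its own number of informative sites.
* **MAF floor.** Sites with estimated minor allele frequency below 0.03 are
  dropped before fitting (configurable), matching standard GL-pipeline
  practice; the frequency estimate is the mean posterior-mean dose under a
  flat prior.
* **Orientation.** For K=2 the components are relabelled so the component
  with the larger mean Q among parent-A reference individuals is "A"; Q_A = 1
  then always means pure parent A.  Reference panels that do not separate the
  components yield an `orientation_ambiguous` flag rather than a guess.

K is fixed by the caller (the pipeline uses K=2 throughout); model selection
across K is out of scope.

## Windowed admixture painting with ILS control

Chromosome size classes follow the avian convention: macro > 40 Mbp,
intermediate 20–40 Mbp, micro < 20 Mbp, with boundary lengths assigned to the
smaller class (the class definitions are strict inequalities; exact 20/40-Mbp
lengths are a measure-zero documentation case).  Macro chromosomes get 9
equal windows, intermediate 7, micro 5; widths are ⌊L/n⌋ with the remainder
absorbed by the final window so the windows tile [0, L) exactly.  All window
arithmetic is 0-based half-open; VCF and Beagle coordinates are 1-based and
converted once at I/O.

Per window, the K=2 EM fit runs on the window's sites over the two reference
panels and all hybrids jointly (a per-hybrid mode would refit per hybrid;
joint fitting shares the ancestral-frequency estimate and is the default).
Windows with fewer informative sites than a floor (default 50) are reported
undefined rather than fit — a two-parameter-per-site model on a handful of
sites is noise.  Each window derives its own seed deterministically from the
run seed, so paintings are reproducible.

ILS flagging: a window is marked when any parent-A reference has
Q_A < 1 − τ or any parent-B reference has Q_A > τ (default τ = 0.05; the
flagging rule is standard, the numeric cutoff is ours).  In such a window the
parental panels themselves are not cleanly separated, so hybrid admixture
there cannot be distinguished from shared ancestral polymorphism.  Raising τ
can only un-flag windows (tested).  Summaries report the median Q_A across
hybrids per window (medians resist single-hybrid outliers, and no single
hybrid genotype represents a hybrid zone); flagged and undefined windows are
excluded from the size-class boxplots, and per-hybrid paintings are emitted
alongside the median.

## Population-genetic statistics

* **Filters** (hard-call path): genotypes below 2× depth are set missing;
  sites are dropped at minor allele frequency < 0.03, call rate < 90%, or
  total site depth outside [10, 75].  MAF and call rate are computed across
  the individuals present in the matrix being filtered — after subsetting to
  an analysis panel this is the only reproducible choice.  The depth bounds
  are cohort-size-dependent; the analysis scripts scale them to their
  18-individual panel.  Filtering is idempotent.
* **Weir–Cockerham F_ST**: the two-population variance components a, b, c
  with the observed-heterozygosity term; missing genotypes reduce per-site
  sample sizes instead of dropping the site, matching the intent of the
  call-rate filter.  Windowed θ̂ is Σa / Σ(a+b+c) over non-overlapping 50-kb
  windows; windows with no informative site (or zero denominator) are NaN.
  Sites need ≥ 2 called genotypes per panel.
* **LD thinning**: every 50th variant in genome-wide sorted order, first
  variant always kept.  Counting genome-wide (not per chromosome) makes the
  kept set independent of chromosome boundaries.
* **Patterson's D**: frequency-weighted pattern sums ABBA = Σ(1−p1)p2p3(1−p4)
  and BABA = Σp1(1−p2)p3(1−p4) with P4 polarising the ancestral state;
  D = (ABBA − BABA)/(ABBA + BABA).  The standard error is a delete-one block
  jackknife over contiguous 1-Mbp blocks (equal block weights; block counts
  here are near-equal by construction) and is validated against the empirical
  scatter of D across independent simulations.  Fewer than two non-empty
  blocks leave the SE undefined.

## The synthetic-data generator

The generator produces the *structure* the methods assume, not a full
population-genetic history:

* **Sites** are unlinked conditional on the per-site class: `fixed_diff`
  (opposite fixation in the two parents — AIM-grade), `shared_poly` (one
  common Beta(0.8, 0.8) ancestral frequency segregating in both parents — the
  ILS stand-in), `private` (segregating in one parent).  Class fractions
  default to 0.30 / 0.20 and are illustrative, not estimates for any real
  species pair; they can be overridden per chromosome to concentrate shared
  polymorphism (for ILS-flagging experiments).
* **Pedigrees**: founders are drawn fresh from the population frequencies;
  gametes carry Poisson(recomb_rate) crossovers placed uniformly with no
  interference.  ZW transmission is enforced: a son receives his mother's Z
  intact and a recombinant paternal Z, a daughter only the recombinant
  paternal Z; the W carries no modelled sites, and female Z genotypes are
  stored hemizygously (dosage 0/2).  Canonical crosses route the hybrid
  lineage through the mother (BC1B = F1 female × parent-B male), which is
  what makes the all-B Z chromosome of backcrossed-into-B offspring a
  theorem rather than a tendency; explicit pedigrees can specify any other
  arrangement.  Ancestry truth is recorded as half-open donor tracts that
  must tile every chromosome (validated).
* **Read noise**: per genotype, reads ~ Poisson(depth_mean = 8, museum-grade)
  and alt reads ~ Binomial(reads, p_g) with p = (ε, ½, 1−ε), ε = 0.01;
  GL triples are the normalised binomial likelihoods, computed in log space,
  uniform at zero reads.  Hemizygous genotypes zero out the heterozygous
  likelihood.

Not emulated: linkage disequilibrium within parental panels, coalescent ILS
(the shared-frequency stand-in has no tree structure), selection, gene
conversion, mutation-rate heterogeneity, post-mortem DNA damage, mapping
bias.  Passing tests therefore demonstrate the *methods'* correctness under
the stated model, not robustness to every pathology of real museum data.

## Problem sizes and determinism

The test and demo problem sizes are desk-scale by design: hundreds to a few
thousand sites per genome, 5–10 individuals per panel, windows with tens of
sites, 3–10 EM restarts.  The analysis scripts use a 30-chromosome
avian-style karyotype because the (h, H) dispersion of single hybrids scales
with chromosome number, and an 8-chromosome toy genome visibly mis-sorts true
backcrosses.  Every stochastic component takes an explicit seed (simulator
config, GL generation, EM restarts, per-window seeds derived via
`SeedSequence`), and fixed seeds reproduce byte-identical outputs.

## Known limitations

* The EM is unaccelerated; genome-scale single fits with millions of sites
  would want SQUAREM-style acceleration.
* Window painting assumes windows are large enough to hold tens of
  informative sites; it does not smooth across windows (no HMM) and ignores
  recombination-map heterogeneity within a window.
* The triangle classifier is deliberately geometric; it does not model
  genotyping error at AIMs (noise is absorbed by the tolerance bands) and
  cannot separate, e.g., F3 from BC2 — both land in `later_generation`.
* Patterson's D uses equal jackknife block weights; strongly unequal block
  sizes would warrant the weighted jackknife.
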