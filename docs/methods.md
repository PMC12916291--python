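# Methods

This note documents the statistical model behind `ildscan`, the design
choices made where the method left room, the simulator that generates its
validation data, and the limits of what desk-scale validation can show.

## The statistic

In a recombining bacterial population, a beneficial allele can spread across
strain backgrounds by homologous recombination (HGT) of a short genomic
fragment — a *gene-specific* sweep — rather than by clonal expansion of one
genome. Such a sweep drags previously-rare variants in the fragment's
vicinity to intermediate frequency. Because the vast majority of
non-synonymous (N) mutations are deleterious and therefore rare, an
intermediate-frequency non-synonymous variant near a sweep is
disproportionately likely to be a hitchhiker sitting on the sweeping
haplotype, in strong linkage disequilibrium (LD) with other hitchhikers.
Synonymous (S) variants reach intermediate frequency by drift as well, on
many backgrounds, and so show lower mutual LD. Two signed areas measure this
per genomic window, among common variants (minor allele frequency
MAF >= 0.2):

- `r2_dNS = AUC(r2_N - r2_S)`: the area between the distance-binned LD decay
  curves of non-synonymous and synonymous variants (units: bp x r^2);
- `r2_dLG = AUC(r2_local - r2_genome-wide)`: the area between the window's
  own decay curve over all common variants and the genome-wide average curve
  over the same distance span.

Each component is standardized by its mean and standard deviation across all
windows of the genome, giving z-scores `z_dNS`, `z_dLG`, and the combined
score is

    iLDS = z_dNS^2 + z_dLG^2.

One window is placed around every common non-synonymous SNP. A window is
called significant when three conditions hold at once:

1. the N-vs-S area exceeds zero by a class-label permutation test
   (p <= 0.05, one-sided);
2. the local-vs-genome area exceeds zero by a site-level bootstrap
   (one-sided 95% bound above zero);
3. iLDS exceeds an empirical genome-wide quantile (99.9th percentile of the
   per-genome iLDS distribution by default).

Overlapping or near-adjacent (within one window size) significant windows on
one contig merge into a sweep call, annotated with every gene model the
merged interval intersects. Windows never span contig boundaries;
standardization pools windows across the contigs of one genome.

## LD machinery

r^2 is the squared correlation of allelic indicators, computed per pair over
the haplotypes called at both sites; pairs that are monomorphic among
jointly-called haplotypes are skipped, never imputed as zero (zero-filling
biases curves downward). Curves bin pairs by distance on log-spaced bins
(LD decays roughly geometrically, so log bins equalize per-bin pair counts):
18 bins from 100 bp to one third of the contig for the genome-wide curve
(>= 10 pairs per bin), 6 bins from 100 bp to the window size for
within-window curves (>= 2 pairs per bin — a 4-8 kb window holds only tens
of class-stratified pairs, and the genome-curve binning would mask nearly
everything), and 8 bins (>= 5 pairs) for genome-level class-stratified
comparisons, where the sparse non-synonymous pair set must still populate
enough shared bins. Areas use the trapezoid rule over populated bin midpoints;
when two curves are compared, bins masked in either are dropped from both so
the areas remain comparable.

Uncertainty is quantified at the *site* level, not the pair level, because
pairs sharing a site are strongly dependent:

- **Site bootstrap.** Sites of a curve are resampled with replacement
  (multinomial weights), each class independently; the curve is rebuilt per
  replicate and the area difference recomputed. The reported interval is the
  central 90% band; its lower edge is the one-sided 95% bound used for the
  significance call. A staged evaluation skips the bulk of replicates when a
  200-replicate pilot already places >= 20% of the mass at or below zero
  (the one-sided 5% bound can then never come out positive, so the call
  cannot change).
- **Class-label permutation.** For the N-vs-S component inside a window, the
  null of "no class difference" makes labels exchangeable given the observed
  genotypes: N/S labels are permuted among the window's common sites (class
  sizes preserved) and the area difference recomputed. This test is exact
  and retains power when one class holds only a handful of sites — the
  situation inside every window — where a site bootstrap of a 3-8-site curve
  is too noisy to ever reject.

The critical iLDS threshold is an empirical quantile rather than an analytic
chi-square(2) cutoff because the two z-scores are neither Gaussian nor
independent; an empirical outlier criterion is conservative by construction.

## Window sizing

Windows are sized to the distance at which genome-wide LD has decayed
halfway from its short-range peak (first populated bin, after a
rolling-median-of-three smoothing that damps single noisy bins) to its
long-range background (mean over the largest-distance quartile of populated
bins); the window is twice that distance. Two guards make this robust on a
single ~50 kb genome, where the decay curve is itself a noisy estimate:

- if the curve never decays below the midpoint, the largest binned distance
  is used (with a warning);
- a feasibility floor widens the window to 1.5x the span expected to hold
  the minimum per-class SNV content (5 non-synonymous, 3 synonymous common
  SNVs) at the genome's observed class densities, capped at half the maximum
  binned distance. Without the floor, a noisy decay estimate can yield
  windows that no SNV content can fill, degenerating the whole scan.

The synonymous minimum (3) is below the non-synonymous one (5) because
sweep regions are intrinsically synonymous-poor: hitchhikers inherit the
~3:1 N:S mutational target ratio of coding sequence, so demanding many
synonymous sites per window systematically skips exactly the windows the
scan exists to find.

## The simulator

A haploid Wright-Fisher population of N genomes with:

- a codon-structured genome: 50 tandem genes of 999 bp on alternating
  strands with 21 bp intergenic spacers (~51 kb total), random stop-free
  codons. The synonymous/non-synonymous status of every possible point
  mutation follows mechanistically from the genetic code, which lets the
  annotation module's classifier be validated against simulator truth;
- multiplicative selection: a fraction (default 0.5) of non-synonymous
  mutations is deleterious with coefficient `s_D`, the rest effectively
  neutral — a minimal two-class distribution of fitness effects. With every
  non-synonymous mutation deleterious at 2Ns ~ 20, a ~50 kb genome has
  essentially *no* intermediate-frequency non-synonymous variants outside
  sweeps, and the window scan has nowhere to anchor windows; real genomes
  escape this through DFE heterogeneity, which the neutral fraction stands
  in for;
- HGT as gene-conversion-like tract replacement: per generation each genome
  initiates, with probability `rho`, replacement of one tract (geometric
  length, mean `tract_mean`) by the homologous tract of a uniformly chosen
  donor from the parent generation;
- optional step demography and a beneficial allele (coefficient `s_B`)
  introduced at a chosen generation at the non-synonymous site nearest the
  genome midpoint, re-seeded on loss (conditioning on establishment, capped),
  with sampling triggered when the allele reaches a target frequency
  (default 0.5 — "mid-sweep").

Populations are initialized at neutral coalescent equilibrium with msprime
(haploid samples, gene conversion at the matching rate and tract length);
deleterious standing variants are thinned at initialization to the
mutation-selection-balance spectrum (keep probability `exp(-2 N s_D x)` for
a variant at frequency x) — without this, purging the neutral-equilibrium
deleterious load crashes genome-wide diversity within `1/s_D` generations.
The forward phase then needs only a short burn-in (default 1000 generations
full scale; 2000 for selected scenarios, a few times `1/s_D` once rescaled).

Desk-scale runs rescale by a factor `scale`: N and generation counts shrink
by `scale` while mutation, recombination and selection coefficients grow by
`1/scale`, keeping the diffusion products `Ne*s`, `Ne*mu*L` and `Ne*rho`
fixed.

### Default rates and why

Full-scale defaults: `Ne = 1e4`, `mu = 1.5e-7` per site per generation,
`rho = 2e-3` per genome per generation, `tract_mean = 3 kb`, sample size
100. These give sample diversity pi ~ 0.003 (a typical intra-species value
for prevalent gut commensals), r/m of order 2-3 (recombination-dominated
evolution, as in the species the method targets), genome-wide LD that decays
within ~1 kb to a low background, and windows of roughly 4-8 kb (usually set
by the content floor) holding ~10-25 common SNVs. They were calibrated once,
on neutral and selected exploratory runs, against those observable
properties.

Two desk-scale constraints shaped the recombination geometry, and are worth
recording because they bind *any* ~50 kb forward simulation of this method:

- the tract must be much shorter than the genome, or a sweep transfers the
  whole genome and is clonal, not gene-specific (tract/L here is 0.06);
- the far genome decouples from the sweeping fragment only if
  `rho * (2*tract/L) * T_sweep` is of order one (T_sweep the sweep
  duration), while hitchhikers inside the fragment survive only if the same
  quantity evaluated at core distances stays below one. Both scale with
  `rho * tract`, so the contrast between "fragment sweeps" and "background
  escapes" is set by the ratio of tract length to the fragment core — and a
  ~50 kb genome leaves little room between the two regimes.

### Scenario suite

Deterministic configuration lists, all derived from the same baseline:
`neutral`; `purifying_only` (s_D = 1e-3); `sweep_grid`
(s_B in {0, 1e-3, 1e-2, 1e-1} x s_D in {0, 1e-4, 1e-3, 1e-2}, sweep
introduced at burn-in end); `contraction` (10x population contraction, no
selection); `low_recombination` (rho/10, no selection). Seeds are derived
from a base seed and distinct per replicate; identical seeds reproduce
byte-identical outputs.

## What the validation does and does not show

The test suite and the acceptance script validate, at scale 0.1
(N = 1000, ~51 kb):

- the false-positive rate of the full pipeline under neutrality (pooled
  fraction of significant windows across >= 200 replicates) — the
  conservative three-way criterion keeps this far below 1%;
- robustness of that rate to a 10x demographic contraction and a 10x lower
  recombination rate, both of which raise LD overall but not the N-vs-S
  contrast;
- the sign structure of AUC(r2_N - r2_S): negative among rare variants under
  purifying selection (deleterious variants are young, scattered across
  backgrounds, and in mutual repulsion), near zero among common variants
  without positive selection;
- detection behaviour on mid-sweep genomes across the selection grid.

The generator emulates codon structure, purifying selection, HGT and
demography, but not: variation in recombination rate along the genome, gene
content differences between strains (synteny variability), multi-contig
assemblies with contig-specific depth, sequencing/phasing error, or a
continuous DFE. Passing these suites therefore demonstrates internal
consistency of statistic + simulator at desk scale, not performance on real
metagenomes. Two desk-scale limitations deserve emphasis:

- *Window content is marginal.* Real applications of window scans of this
  kind have hundreds of common SNVs per window; ~50 kb at pi ~ 0.004 gives
  tens. Component estimates per window are accordingly noisy, the
  cross-window standardization spread is wide, and single-genome empirical
  thresholds (99.9th percentile of ~50-200 windows) effectively demand that
  the sweep window be the genome-wide maximum.
- *Sweep power at desk scale is weak.* The number of hitchhikers a sweep can
  recruit is bounded by the founder haplotype's rare variants within the
  fragment (~ theta * tract-core * 0.2, i.e. single digits here), so the
  mid-sweep N/S contrast rides on a handful of sites. The package reports
  detection probabilities honestly rather than tuning the criterion to the
  simulation.

## Numerical and degenerate-input conventions

- Coordinates 0-based half-open internally; GFF3 1-based inclusive at the
  boundary; BED output 0-based half-open.
- Gaps and Ns are missing data, never alleles; MAF is computed over called
  haplotypes; columns below 90% calledness are dropped.
- Sites whose codon context is polymorphic (a second SNV in the same codon)
  are classified OTHER and excluded from N/S curves: the dichotomy presumes
  an unambiguous single-site amino-acid change.
- Multi-allelic columns are excluded. Recurrent mutation at an occupied site
  is ignored by the simulator (infinite-sites behaviour at segregating
  sites); fixed differences are dropped from state (invisible to LD and
  classification against the sample consensus).
- Curve comparison requires >= 2 bins populated in both curves; windows
  failing content or curve requirements are skipped and logged, never scored
  as zero. A scan with < 10 scorable windows raises a degenerate-scan error.
- All randomness flows from explicit integer seeds (one generator per scan /
  simulation); reruns are byte-identical.
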