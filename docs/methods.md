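# Methods

## Scope and data model

`radpop` operates on the *downstream* product of a reference-aligned RAD
pipeline: diploid genotype calls at SNP columns of fixed-length RAD loci
(150 bp by default), for named individuals grouped into sub-populations by
a population map. It does not align reads, assemble loci or call genotypes.
Missingness is modelled at the locus level (allele dropout): a restriction
site mutation removes the whole tag for an individual, so an individual
either has a locus (at least one SNP column called) or lacks all of its
columns. The reference allele at every site is authoritative from input
(the VCF REF field); it is never re-inferred from sample frequencies,
because private/common classification is defined relative to the reference
genome. Coordinates are 1-based for genome positions (`BP`, locus starts)
and 0-based for the SNP column offset within a locus (`Col`).

## Per-site statistics

Within one population at one site, with `N` genotyped individuals and
`n = 2N` called alleles of frequencies `p_i`:

- `H_exp = 1 − Σ p_i²` (general multi-allele form; multi-allelic sites are
  retained and flagged rather than dropped);
- `π = n/(n−1) · H_exp`, the unbiased estimator of mean pairwise allele
  difference — it equals the brute-force average over all `n(n−1)/2`
  allele pairs, which the test suite verifies exhaustively for all
  biallelic configurations with `N ≤ 5`;
- `H_obs` = fraction of genotyped individuals that are heterozygous;
- `F_IS = (π − H_obs)/π` when `π > 0`, else 0. Hence `F_IS = 1` exactly
  when a polymorphic site has no heterozygotes, and negative values
  (bounded below by −1, −0.5 for two balanced heterozygotes) indicate
  heterozygote excess, as expected in clonally propagated outbred material.

The reported `P` column is the frequency of the *P nucleotide*, which is
the reference allele whenever it is present in the population (it can be
the minor allele; contrast-scan rows with `P < 0.5` are normal). When the
reference allele is absent, `P = 0` and no P nucleotide is reported; `Q`
is the most frequent observed alternative, ties broken alphabetically. The
within-population major-allele frequency is exposed separately
(`p_major`), since the two notions differ precisely at the diagnostic
sites this package exists to find.

`N` is always the per-site count of genotyped individuals, not the nominal
population size; the two differ under allele dropout.

## Population summaries and the χ² statistic

Population summaries are means of the per-site statistics over the sites
polymorphic in the metapopulation (default). An all-sites mode dilutes the
means with a supplied count of invariant sites (`P = 1`, all other
statistics 0); the count must be supplied because invariant RAD columns
are typically not exported to a genotype matrix. The deviation of observed
from expected zygosity is summarized as

    χ² = N · [ (H̄_obs − H̄_exp)²/H̄_exp + (H̄om_obs − H̄om_exp)²/H̄om_exp ]

with 1 degree of freedom and `N` the nominal population size, computed on
the population-level means. This mean-level form is a reconstruction — the
statistic is conventional but its exact inputs are rarely stated in
published tables — and it reproduces published per-variety values from
their printed means within input-rounding tolerance (±0.005). p-values are
bucketed for reporting as `>0.9`, `>0.5`, or `<=0.5` (the numeric p is kept
alongside). A degenerate mean expected heterozygosity of exactly 0 or 1
leaves the statistic undefined; 0 is returned with a warning flag.

## Allele classification and diagnostic filters

Classification is by presence: a non-reference allele with ≥ 1 copy in
exactly one sub-population is private, in two or more common. Every
observed (site, alternative allele) pair yields exactly one call — the
partition property tested against brute-force enumeration on small
catalogs. Coarsening the population map is monotone *non-decreasing* on
the private set: merging two populations promotes exactly the alleles
previously shared by those two and destroys none.

The diagnostic filter evaluates uniformity over genotyped carrier-population
members only (individuals missing the locus are ignored): all homozygous
for the alternative → `fixed_homozygous`; all heterozygous carriers →
`all_heterozygous`; mixtures are dropped. The universal-locus filter keeps
alleles whose locus was genotyped in at least a configurable fraction
(default all) of the individuals.

The group-contrast scan requires exactly two populations. A hit is an
allele with ≥ 1 copy in one group, zero copies in the other, and a carrier
fraction at least the threshold (default 0.5, inclusive). The carrier
fraction is computed over the *genotyped* members of the group by default:
on the published resistant/susceptible rows this denominator reproduces
all five listed hits, whereas the nominal-group-size denominator would
exclude two of them. Both denominators are exposed; the per-copy
alternative-allele frequency is reported on every hit as well.

## F_ST

Weir–Cockerham's θ is the default estimator (per-allele variance
components summed over alleles and sites, θ = Σa / Σ(a+b+c)); Hudson's
estimator in the Bhatia ratio-of-averages form is the alternative. Sites
enter a pair's estimate only if both populations have ≥ 2 genotyped
individuals and the pair is jointly polymorphic; per-pair usable-site
counts are reported, and a pair with no usable site is NaN, never 0.
Small negative estimates are kept (clipping offered only at
serialization). The tests check the limiting cases (identical frequencies
→ ≈ 0 within 3 block-jackknife SE; fixed differences → 1), agreement of
the two estimators on balanced designs, monotonicity in simulated
divergence, and recovery of the island-model equilibrium value
`F_ST = 1/(1+4Nm)` from a frequency-level simulation oracle in which deme
frequencies are Beta-distributed around an ancestral frequency with
variance `F·p(1−p)`.

## Synthetic catalogs

The generator emulates the genotype matrices the analysis consumes, not
reads. Defaults mirror the hazelnut study shape: nine varietal
sub-populations at the published sizes (and an 8-vs-13 contrast
configuration), 150 bp loci, 0–10 SNP columns per locus
(min(Poisson(2), 10)). Per population and site, an alternative-allele
frequency `q` is drawn from Beta(0.5, 2) — chosen so the reference allele
is major at most sites, as expected for conspecific alignment — or fixed
(`fixed_q`) for parameter-recovery checks. Genotypes follow the inbreeding
mixture `{p²+Fpq, 2pq(1−F), q²+Fpq}` with negative `F` truncated to
`max(F, −p/q, −q/p)`. Planted private alleles occupy dedicated sites,
monomorphic-reference in every other population, with carrier profiles
`fixed_homozygous`, `all_heterozygous` or `mixed`. Dropout is Bernoulli
per (locus, individual), applied to all columns of the locus.

Randomness is keyed per locus from `(seed, locus_index)`, so the same seed
reproduces a catalog byte-for-byte and growing `n_loci` extends a catalog
without reshuffling earlier loci.

Recovery tests use a symmetric Beta(5, 5) prior for background sites, so
background polymorphism is shared by all populations by construction and
the planted alleles are the only private ones — recall = precision = 1 at
zero dropout is then a structural property, and recall degrades
monotonically as dropout removes whole carrier sets. F_IS recovery is
tested against the finite-sample expectation `F − F(1−F)/(2N−1)` (the
within-individual allele pairs among the `n(n−1)/2` enter π with
probability `2pq(1−F)` rather than `2pq`), within 3 SE at `N = 60` over
≥ 2000 loci.

What the generator does **not** emulate: linkage between loci and between
SNP columns of one locus (columns are drawn independently), sequencing or
genotype-calling error, depth-dependent missingness, paralog collapse, or
shared drift structure between populations (frequencies are drawn
independently per population, so inter-population covariance is absent
except where planted). Passing recovery tests therefore demonstrates
correctness of the bookkeeping and estimators under the stated model, not
robustness to these real-data artifacts.

## Catalog density

Per-chromosome tables count distinct locus IDs and SNP columns; density is
loci per Mb rounded to integer; unplaced ("NA") sites form a SNP-only
bucket, and totals are conserved. Both the mean of per-chromosome
densities and the overall density (total loci / total Mb) are exposed,
since published summaries use either convention. The assembly lengths
bundled for the hazelnut catalog are reconstructed from published counts
and densities (`n_loci/density`, rounded to bp) and are labelled synthetic
stand-ins, not true assembly lengths.

## Numerical and reporting choices

- Statistics are kept at full precision internally; rounding (4 decimals
  by default, 3 in summary tables) happens only at serialization.
- Unordered genotype pairs are normalised (sorted) on construction so
  matrix equality and round trips are well defined.
- TSV everywhere, UTF-8, population names preserved exactly (including
  Turkish characters); VCF 4.2 GT-only output with `LOCUS`/`COL`/`LSTART`
  INFO keys for lossless round trips; plain-VCF input without those keys
  groups sites into loci within a 150 bp window.
- Indels and symbolic alleles are skipped on read with a logged warning;
  non-diploid GT entries are a hard error naming the individual and site.

## Known limitations

- Genome-wide published counts (e.g. hundreds of thousands of loci, the
  101/57/44 private-allele tallies, per-variety mean tables) require the
  archived sequencing data and are documented rather than reproduced; the
  desk-scale checks rest on single-site configurations that published
  rows fully determine.
- The χ² reconstruction matches published statistics but one published
  p-value bucket (Susceptible, χ² = 0.025 → p ≈ 0.875) is inconsistent
  with its own printed statistic and cannot be reproduced by any 1-df rule.
- F_ST estimates between populations of 2–3 individuals are extremely
  noisy; the per-pair site counts should be consulted before interpreting
  them.
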