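# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `racecaps`.

## The biological setting and the effective locus

Female *Ostrinia nubilalis* produce a pheromone blend whose E:Z isomer ratio
is controlled by the codominant *pgfar* locus; *pgfar-e/pgfar-e* females
produce an E-dominant blend (~98% E), heterozygotes an intermediate blend
(~68% E) and *pgfar-z/pgfar-z* a Z-dominant blend (~3% E). Three SNPs in
*pgfar* (cDNA positions 857, 995, 1005) are fixed differentially between
races and sit inside restriction-site contexts (TaqI, NdeII, MseI), which is
what makes a PCR-RFLP assay possible. In field data the three markers give
identical genotype calls (complete linkage within the gene), so the
population-genetic layer treats them as **one effective biallelic locus**
with alleles *e* and *z*; a site sample is just the genotype-count triple
(n_zz, n_ez, n_ee). Observed heterozygosity H_O = n_ez/n doubles as the
per-site hybridization-frequency estimate, because every heterozygote is an
F1 (or later-generation) hybrid at this locus.

## Diversity statistics

* **p-distance / π** — mean pairwise proportion of differing sites, with
  *pairwise deletion*: a column enters a pair's comparison only when both
  sequences carry A/C/G/T there. This matches the default distance
  behaviour of standard alignment software and keeps the statistics
  well-defined on gapped panels. The reported standard error is
  sqrt(mean over pairs of p(1−p)/L), the analytical binomial variance of
  the per-pair p-distance.
* **Segregating sites S** — columns with ≥2 distinct unambiguous bases;
  gap/N-only variation never counts.
* **Tajima's D** — D = (k − S/a1) / sqrt(e1·S + e2·S(S−1)) with k the mean
  pairwise difference count and a1, e1, e2 the standard coefficients of the
  sample size. With S = 0 the denominator vanishes and D is reported as
  *undefined* (not 0) and excluded from window flagging.
* **Sliding windows** — width 100 columns, step 25, flag threshold D > 2.0.
  The threshold is a plain numeric cutoff, not a formal test. Windows start
  at 1, 1+step, …; the terminal window is truncated and marked. Flagged
  windows that overlap or touch are merged into "divergent regions". The
  unit suite verifies the implementation against a from-the-definition
  brute-force D on small random panels, and verifies near-zero mean D on
  neutral coalescent panels generated independently with msprime.
* **Fixed differences** — columns where every E sequence carries one base
  and every Z sequence a different single base, no gaps or Ns among
  labelled rows. Codon position and synonymy are annotated against a
  user-supplied reading frame on the ungapped consensus. Coordinates are
  1-based inclusive alignment columns; cDNA positions refer to the ungapped
  majority-rule consensus, with explicit column↔consensus mapping.

## CAPS marker model

A diagnostic candidate is a fixed SNP for which **exactly one** allele
completes an enzyme's recognition site at some placement covering the SNP,
with the rest of the footprint monomorphic across the whole panel. If both
alleles complete sites of the same enzyme — even at placements shifted by a
base — the SNP is rejected: the resulting fragment-length difference of
1–2 bp is unreadable on a gel.

In-silico PCR is exact-match under IUPAC degeneracy (the degenerate W in
the published mnr primer matches A or T), with zero mismatches and no
thermodynamics: the assay being modelled uses validated primers, so primer
*design* is out of scope. Zero or multiple products raise an error naming
the count. Digestion reports fragment lengths between successive top-strand
cut positions, ignoring 2-nt overhangs; palindromic enzymes are scanned on
the top strand only, non-palindromic enzymes on both. Cut offsets default
to TaqI T^CGA (1), NdeII ^GATC (0), MseI T^TAA (1); the enzyme table is
user-extensible via CSV.

Each marker stores two pattern sets: the **full** digestion truth (every
site in the amplicon) and the **nominal** diagnostic-site-only sizes, the
convention assay tables use. The two differ exactly when the amplicon
carries a constitutive same-enzyme site; notably the published TaqI forward
primer itself contains a TCGA, so the full TaqI patterns carry an extra
2-bp terminal fragment that no gel resolves. Markers with constitutive
sites are emitted but flagged.

### The synthetic assay-geometry panel

The original cDNA panel is a set of GenBank records not redistributed here.
`pgfar_standin_panel()` builds a **synthetic** stand-in that embeds every
published constraint a colinear template can satisfy: the two primer pairs,
the three diagnostic SNPs at consensus positions 857/995/1005 with the
published alleles and enzymes, a 150-bp TaqI amplicon and a 145-bp
NdeII/MseI amplicon, the TaqI diagnostic cut at 118+32 and the NdeII cut at
83+62. Two published numbers are geometrically unreachable on any colinear
template: the NdeII and MseI cuts sit 12 bp apart in cDNA coordinates
(GATC with its T at 995 cuts after 992; TTAA with its T at 1005 cuts after
1004) while the published sizes 83+62 and 93+52 put them 10 bp apart, so
MseI here digests to 95+50; and the primer-embedded TaqI site makes the
uncut "150" read 148 on a full digest. Both discrepancies are within the
5-bp gel-calling tolerance, and the genotype caller resolves the published
gel sizes correctly against this panel. Panel-level diversity quantities
(overall divergence, Tajima's D of the real gene) are properties of the
real sequences and are not asserted against the stand-in.

## Genotype calling

Observed fragment lists match an expected pattern when they pair one-to-one
within a size tolerance, default 5 bp — the resolution of sizing short
fragments against a 50-bp ladder; expected fragments under 20 bp are
dropped first (sub-resolution). Cut-only → homozygote for the cut-allele
race, uncut-only → the other homozygote, union of both → heterozygote,
anything else → missing. Consensus over markers is strict by default:
any disagreement is reported as *discordant* with the full per-marker
vector, never silently resolved, because marker discordance is itself a
finding (the study observed five females homozygous z at TaqI but
heterozygous at NdeII/MseI). An optional majority mode resolves 2-of-3.
Dosage counts *z* alleles/2 (EE=0, EZ=0.5, ZZ=1); an `e` orientation flag
flips it.

## Phenotype association

Classification: class 1.0 iff %E ≥ 90, class 3.0 iff %E ≤ 5, class 2.0
otherwise, U when the GC reading is unresolved; boundary values belong to
the outer classes. Two correlation codings are computed and both reported,
because the study describes a class coding in its methods yet its printed
pooled r matches the continuous coding: (a) continuous %E against
*e*-allele count 0/1/2 (the default), and (b) class code 1/2/3 against
z-dosage 0/0.5/1, which is affinely increasing on concordant data and hence
exactly 1 there. |r| is reported alongside signed r since the two codings
run in opposite directions. Per-family coefficients are combined as the
unweighted mean ± SD across families.

## Synthetic generators

* **Panels** — ancestral random sequence; diagnostic SNPs planted with
  their recognition contexts written into both race consensuses and the
  broken allele chosen so neither allele completes any other site
  (re-drawn on collision); plain fixed SNPs verified not to create sites
  under either allele; accidental sites scrubbed jointly from both
  consensuses so scrubbing cannot create spurious fixed differences;
  within-race diversity from singleton mutations at density d·L·n/2, which
  gives mean pairwise diversity d in expectation. Defaults mirror the
  study panel: 21 sequences, 1607 columns, within-race d = 0.002, 3
  diagnostic + 12 plain fixed SNPs.
* **Populations** — genotypes multinomial from (q²+Fpq, 2pq(1−F), p²+Fpq),
  or from a two-deme mixture whose pooled counts show the Wahlund
  heterozygote deficit without any within-deme inbreeding. A discordance
  rate flips the TaqI call of that fraction of individuals (heterozygotes
  recorded as z/z at TaqI, mirroring the study's discrepancy class).
* **Phenotypes** — class-conditional truncated normals on [0, 100] with
  the study's estimates as defaults (98.02 ± 4.24, 67.58 ± 8.92,
  2.74 ± 6.24 %E; n = 42/59/143). Truncation is *not* negligible for the
  z/z class, whose mean sits within half an SD of zero: the realised class
  mean is ≈ +3 %E above the nominal 2.74. Tests therefore compare
  recovered means against the truncated-normal mean, and the simulated
  pooled correlation (≈ 0.972) sits a few thousandths above the
  published 0.9699.

What the generators deliberately do not model: coalescent realism in the
panels (no recombination, no shared polymorphism), genotyping error other
than the discordance channel, GC measurement error, family structure in the
phenotype cohorts. Passing tests demonstrate the statistical machinery is
correct under the stated models, not that real data meet those models.

## Exact and Markov-chain HWE tests

The exact conditional test enumerates every heterozygote count compatible
with the observed allele counts (same parity, up to the minor allele
count), computes log-probabilities via log-Γ, and sums the probabilities of
configurations no more probable than the observed one, ties included
(relative slack 1e-12). Every call asserts the enumerated mass is 1 within
1e-9. The p-value is invariant under allele-label swap. Monomorphic
samples admit one configuration and return p = 1; they are reported
"monomorphic" in site summaries and excluded from testing, but retained in
AMOVA, where they still carry information.

The Markov-chain variant (a Metropolis walk with ±2-heterozygote proposals)
exists because the original analyses used chain-based software and because
enumeration stops being an option for multi-allelic extensions; it
converges to the enumerated p and is seeded and bitwise-reproducible.
Enumeration is always the default.

`reconstruct_counts` inverts a printed (n, H_O, H_E) row back to the unique
count triple: n_ez = round(H_O·n), homozygote split matched on unbiased H_E
within ±0.001 (one printed row's H_E is off by one in the third decimal
from the exact value, so strict 3-decimal rounding equality would fail),
canonicalised with z as the major allele, erroring on no or multiple
solutions. The test suite validates it by exhaustive search over all
triples for every field row.

## F-statistics and AMOVA

Pairwise differentiation uses the Weir–Cockerham (1984) θ for one biallelic
locus (the full a/b/c variance components, including the heterozygosity
correction). The hierarchical analysis is a four-level nested ANOVA on
allele indicator values — among groups, among populations within groups,
among individuals within populations, within individuals — with standard
unbalanced-design moment estimators; because every individual contributes
exactly two alleles, the intra-individual coefficients are exactly 2, and
the among-individual component is derived from observed heterozygosity.
F-ratios follow the usual partition: F_CT = a/T, F_SC = b/(b+c+d),
F_IS = c/(c+d), F_ST = (a+b)/T, T = a+b+c+d. When every group holds a
single population the among-populations level is absent and its component
is fixed at 0.

Permutation significance (default 1000 permutations, seeded, p =
(#{perm ≥ obs}+1)/(n_perm+1)): whole populations among groups for F_CT,
individuals among populations within groups for F_SC, alleles among
individuals within populations for F_IS. Two practical notes. First, the
F_CT test's resolution is the number of distinct group labelings — with one
population per group every permutation returns the same F_CT and p is
necessarily 1. Second, because the statistics are functions of discrete
genotype counts, permutation p-values are tied and therefore *conservative*
rather than exactly uniform under the null; the suite checks validity
(P(p ≤ α) ≤ α within binomial noise at several levels), which is the
guarantee a permutation test actually provides.

Field-data grouping follows the published regional split (Midwest sites
1–5 vs East Coast 7–16); the partially-sympatric site 6 is excluded from
the hierarchical analysis by default and included only by explicit choice.
On the reconstructed field counts the analysis shows positive, significant
among-region differentiation and positive within-population inbreeding
(heterozygote deficit), the direction the study reports; exact magnitudes
depend on estimator details of the original software and are not asserted.

Multiple testing across pairwise comparisons uses the Benjamini–Yekutieli
threshold α / Σ_{i=1}^m 1/i, which controls FDR under arbitrary dependence
(pairwise θs share populations). For α = 0.05 and m = 55 comparisons this
gives ≈ 0.0109.

## Problem sizes and tolerances

Printed-table comparisons are made after rounding to 3 decimals, the
table's precision. The acceptance script averages the pooled correlation
over 200 simulated cohorts of 244 females (Monte-Carlo SE ≈ 0.0002). The
chain-vs-enumeration agreement is checked at 60k steps (abs 0.03) on a
random spread of sample sizes up to n = 100 and at 200k steps (abs 0.01)
on the study's own configurations; enumeration propriety is verified
exhaustively for all n ≤ 100. Island-model recovery uses Balding–Nichols
deme frequencies at F = 0.10 with two demes of 100 diploids, 60–100
replicates. Neutral-panel checks use coalescent simulations (n = 10–20,
300–400 sites). These sizes keep the default suite under a minute of
statistical testing while leaving estimator standard errors several times
smaller than the asserted tolerances.

## Known limitations

* Single-locus theory throughout: no haplotypes, no LD decay, no
  multi-locus estimators; the three markers are assumed perfectly linked,
  as observed in the study data.
* The exact HWE enumerator is biallelic; the Markov chain is the intended
  route to a multi-allelic extension but currently shares the biallelic
  state space.
* In-silico PCR has no mismatch model, so primer-binding polymorphisms
  (e.g. null alleles) are invisible.
* The phenotype model draws independent females; family effects and the
  study's modifier-locus variation in heterozygote blends are not modelled
  beyond the heterozygote class SD.
* AMOVA variance components can be negative in near-boundary data, as with
  all moment estimators; they are reported as computed, not truncated.
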