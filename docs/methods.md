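# Methods

## The cross design being modelled

Two inbred parental lines, P1 (maternal; every hybrid inherits its
cytoplasm) and P2 (paternal), are crossed to produce F1s that are
heterozygous at every diagnostic marker. Two second-generation designs
are analysed:

- **F2 intercross** (F1 × F1), sampled twice: newly hatched larvae
  (nauplii) and adult males. Comparing the two snapshots separates
  distortion arising at or before hatching (meiotic drive, gametic
  selection, embryonic mortality) from viability selection between
  hatching and adulthood.
- **Non-recombinant backcross** (F1 female × P2 male). Because females
  of the modelled species are achiasmatic — female meiosis has no
  crossing-over — each maternal chromosome is transmitted intact, so
  every offspring chromosome is either uniformly heterozygous or
  uniformly P2-homozygous. The NR-BC is therefore a chromosome-level
  assay: 1:1 HET:HOM₂ per chromosome under Mendelian expectations.

Genotypes are codominant calls AA/AB/BB/NA (P1 homozygote /
heterozygote / P2 homozygote / missing), stored per individual with
cohort, family and sex metadata so one table can hold all cohorts.

## Statistical procedures

### Single-locus scans

Each marker's non-missing counts are tested against fixed Mendelian
ratios — 2:1:1 (HET:HOM₁:HOM₂) in the F2, 1:1 in the NR-BC — with the
plain Pearson χ² (no continuity correction). Expected ratios are fixed
rather than estimated: the F2 Hardy–Weinberg expectation at allele
frequency ½ is exactly 2:1:1. Each marker uses its own non-missing n
(pairwise/listwise completeness is per test), since genotyping success
differs between marker classes. Tiers follow the three-star
convention: p < 0.05, p < 0.01, and p < 0.05/m for m tests (0.05/53 ≈
0.00094 marker-wise; 0.05/12 ≈ 0.004 chromosome-wise). The pooled
allele-ratio test counts two alleles per non-missing call and compares
P1 vs P2 totals with a 1-df χ²; it deliberately ignores the
non-independence of alleles within individuals and across linked
markers, so its nominal p-value is anti-conservative — it is reported
as the field reports it, and the caveat stands.

### Two-point linkage

For markers A and B in a phase-known coupling-phase intercross, the
3×3 genotype table is a multinomial whose class probabilities follow
from gamete probabilities ((1−r)/2 parental, r/2 recombinant per
class). Under the `symmetric` model both parents recombine with the
same r; the EM treats the number of recombinant gametes as missing
data. All classes except the double heterozygote determine their
recombinant count (corners carry 2, single-het edges 1, diagonal ends
0); the double heterozygote is both-parental with probability
(1−r)²/((1−r)²+r²) and both-recombinant otherwise. The M-step is
r ← E[recombinant gametes]/2n, iterated from r = 0.25 until
|Δr| < 1e−8 (at most 100 iterations), clipped to [0, 0.5]. The
test-suite checks the EM against an independent brute-force grid
oracle (step 1e−4) to 1e−3, both on simulated and on arbitrary
(hypothesis-generated) tables.

Under the `female_achiasmatic` model only male gametes recombine; the
MLE is closed-form (recombinant classes / n). The corner classes
HOM₁/HOM₂ and HOM₂/HOM₁ are impossible under this model — they require
a recombinant female gamete — and observed corner counts (possible
only through genotyping error) are excluded from the fit rather than
crashing the likelihood.

Linkage significance is the likelihood-ratio test of r̂ against
r = 0.5, with p from the χ²(1) upper tail of 2·lnLR and
LOD = lnLR/ln10. Because r is on the boundary of its space under the
null, the exact null is the mixture ½χ²₀ + ½χ²₁; using plain χ²(1)
doubles the nominal p and is therefore conservative for linkage
detection. The grouping criterion is p < 0.001 (single-linkage
transitive closure), the ordering criterion is minimum sum of adjacent
r̂ (exhaustive to 8 markers, greedy + 2-opt beyond, orientation
canonicalized lexicographically), and adjacent distances use Kosambi's
d = 25·ln[(1+2r)/(1−2r)], inverse r = tanh(d/50)/2.

With ~1,300 between-chromosome pairs at α = 0.001, a chance join that
merges two true chromosomes occurs in a minority of datasets at
n ≈ 200 (the acceptance test therefore asserts the *modal* group count
over replicates, which is stably the true 12). SARF ordering recovers
the simulated order essentially always at 6.5 cM spacing and n = 205.

### Map length and coverage

Group length is the sum of adjacent Kosambi distances. The corrected
length adds 2 cM per group and scales by (m+1)/(m−1) (the standard
correction for chromosome ends falling outside the terminal markers);
singleton groups are excluded throughout, because the correction is
undefined at m = 1 and a singleton contributes no intervals. Mean
spacing is d = (uncorrected total length)/(number of adjacent
intervals) — this convention, with the corrected L in the exponent,
jointly reproduces the published triple (d = 6.5 cM from 266.7/41,
L = 484.8 cM, c = 75.2%). Coverage is c = 1 − e^(−2dn/L), increasing
in d and n and decreasing in L.

### Two-locus epistasis

For unlinked pairs (same-group pairs are excluded — linkage itself
produces association), expected class frequencies are products of the
observed single-locus marginals. The default `ordered9` mode keeps all
nine ordered combinations (df = 8); `pooled6` pools the reciprocal
mixed classes into the six unordered combinations (df = 5). The df is
the class count minus one, with no reduction for the estimated
marginals — the goodness-of-fit convention, which is also the df
implied by published χ²/p pairings for this test (e.g. χ² = 17.1 →
p ≈ 0.03 at 8 df). Signed class contributions sign(O−E)·(O−E)²/E sum
in absolute value to χ² by construction. Cells with expected count
below 5 set a `low_expected` flag; nothing is pooled silently. The
multiple-testing denominator across the scan is the number of ordered
pairs of distinct linkage groups, G(G−1) = 132 for G = 12 (the
published convention; the unordered count would be 66).

NR-BC inter-chromosome linkage disequilibrium reduces each chromosome
to one state per individual (majority over its markers; AA artifacts
vote with HET since only a true heterozygote can miscall to AA here;
ties and all-missing are unscorable) and applies the 2×2 Pearson
independence χ². A zero marginal flags the pair untestable instead of
raising.

## The simulator

Maternal meiosis returns one intact parental haplotype per chromosome
(probability ½). Male meiosis is a first-order Markov walk: a random
starting homolog, then an independent switch in each marker interval
with probability r_j = inverse-Kosambi of the configured adjacent
distance. The chiasma interference implied by the Kosambi function is
deliberately not modelled — standard gene-drop practice, and two-point
statistics are insensitive to it.

Viability selection: a regime maps loci to (w_HOM₁, w_HET, w_HOM₂) and
optionally locus pairs to 3×3 tables, all in [0, 1], tagged with a
stage (`pre_hatching` acts before the nauplii snapshot,
`hatching_to_adult` before the adult snapshot; adults pass both).
Survival is Bernoulli with probability equal to the product of
applicable viabilities divided by the product of the per-term maxima,
so the fittest genotype survives with probability 1. When epistatic
terms share loci with single-locus terms this normalizer is an upper
bound on the best achievable product, which only scales all survival
probabilities down uniformly. Cohorts are filled by rejection sampling
to the configured sizes; sex is Bernoulli(½) independent of genotype
(genotype-linked sex determination is out of scope); family labels
cycle over the configured number of F1 pairs — families are labels
only, since every F1 is genetically identical at the diagnostic
markers.

Genotyping artifacts are applied last: each true heterozygote is
rewritten to a random homozygote with probability
`het_undercall_rate`, then every call is lost with probability
`missing_rate`.

Default parameters (units; rationale):

| parameter | default | why |
|---|---|---|
| cohort sizes | 190 / 205 / 39 | the study's genotyped samples |
| F1 pairs | 4 / 25 / 7 | the study's family structure |
| panel | 53 markers, 12 chromosomes (one singleton) | 52 assigned markers over 41 intervals |
| marker spacing | 6.5 cM | the study's mean intermarker distance |
| `missing_rate` | 0.02 | a few percent failed calls, typical of SNP-assay panels |
| `het_undercall_rate` | 0.0 | undercalling was a marker-specific artifact, not a panel-wide one; raise it explicitly to study its effect |
| preset `chr10_sd_deficit` | w_HOM₁ = 0.05 on chromosome 10 | near-lethality of the P1 homozygote between hatching and adulthood |
| preset `het_excess_2_7` | w_HOM₂ = 0.5 on chromosomes 2 and 7 | P2-homozygote disadvantage producing adult heterozygote excess |

Because per-marker viabilities multiply along an achiasmatic
chromosome, a whole-chromosome homozygote under `chr10_sd_deficit`
survives with probability ∝ 0.05⁵ — the presets encode strong,
chromosome-scale selection, which is what they are for (power tests).

## What the simulator does and does not emulate

It reproduces: achiasmatic maternal transmission (hence strong
within-chromosome correlation and chromosome-level NR-BC states),
male-map recombination, stage-specific viability selection, males-only
adult sampling, missing data and heterozygote undercalling, and the
study's sample sizes. It does not model: genotype- or
environment-dependent sex determination (the real backcross was
female-biased for unknown reasons), segregation of family-level
genetic background (all F1s are identical here, so between-family
variance is purely sampling), mutation, de-novo marker error
correlated across a run, or multi-generation designs. Passing tests
therefore demonstrate the statistical machinery under the stated
generative model, not robustness to every artifact of real assays.

## Numerical choices and degenerate inputs

- EM tolerance 1e−8 on |Δr|, 100 iterations, start r = 0.25; r̂
  clipped to [0, 0.5]; p ≡ 1 when the LR statistic is 0.
- Log-likelihoods treat 0·log 0 as 0; a positive count in a
  zero-probability cell yields −inf, which correctly never wins.
- Adjacent r̂ of 0.5 inside a group (possible only through a chain of
  indirect links) is clipped just below 0.5 before the Kosambi
  transform to keep positions finite.
- Empty tables, empty cohorts, unknown markers, non-normalized
  marginals and out-of-range probabilities raise `ValueError` with the
  offending name; structural CSV problems raise dedicated format/parse
  errors naming the column or cell.
- A matrix with 0 individuals round-trips as a header-only CSV.
- All simulation randomness flows through one `numpy` Generator; a
  seed fixes every output byte.

## Known limitations

- Two-point mapping only; no multipoint likelihood, no QTL mapping.
- The p < 0.001 linkage criterion is taken at face value; with dozens
  of markers it implies an appreciable chance of one spurious
  between-chromosome join per dataset (quantified above). A
  boundary-mixture p-value would halve the nominal p and is exposed as
  a documented alternative interpretation, not the default.
- The pooled allele-ratio χ² overstates significance by construction
  (correlated alleles); interpret it comparatively, not absolutely.
- Epistasis power at n ≈ 200 is marginal for realistic two-locus
  effects; the simulator's power properties are demonstrated at larger
  n in the test-suite.
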