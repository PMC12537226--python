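# Methods

## Model

Maternal-plasma cfDNA at a biallelic SNP is modelled as a two-component
mixture: a fraction 1 − *ff* of maternal fragments and *ff* of fetal
fragments. The expected plasma reference-allele frequency is

p = (1 − ff) · g_m / 2 + ff · g_f / 2,

with g_m, g_f the maternal and fetal reference-allele counts. Reads are
binomial draws at p given the site's depth; depths across sites are treated
as independent. The quantity the caller works with is the per-site dosage
change on the reference-allele scale,

DC = (observed ref frequency) − g_m / 2,

i.e. the deviation from the fetus-independent baseline set by the maternal
genotype (0.5 at maternal-heterozygous sites, 0 or 1 at
maternal-homozygous sites). This is the minimal definition that reproduces
the expected dosage table: at an informative SNP whose marker allele is the
reference base, DC has expectation +ff/2 when the linked haplotype is
inherited; −ff/2 when the marker is the alternative base; 0 when the
haplotype is not inherited.

## Phasing

The four parental haplotypes are labelled HM1/HM2 (maternal
pathogenic/wild-type) and HF1/HF2 (paternal). The unaffected sibling is
asserted a noncarrier, i.e. received HM2 and HF2. At each site the sibling
genotype is decomposed into one maternal plus one paternal transmitted
allele consistent with the parental genotypes; when that decomposition is
unique, the transmitted alleles define HM2 and HF2 and the parents' other
alleles define HM1 and HF1. Sites with several decompositions (e.g. all
three individuals heterozygous) are marked ambiguous and dropped rather
than imputed — phasing stays strictly within the family; sites with none
are Mendelian errors; sites with any missing genotype are skipped. The
pathogenic variant itself (a structural allele in the motivating scenario)
is not treated as a phaseable SNP; carrier status enters only through
configuration assertions. A single meiotic block is assumed: recombination
between the sibling's and the fetus's meioses within the analysed window
is not modelled.

## Informative-SNP typing

A phased site is informative when exactly one parent is heterozygous.
Maternal-informative sites: the father's homozygous allele either matches
HM1 (Type 1, marker = HM1's allele) or HM2 (Type 2, marker = HM2's
allele). Paternal-informative sites: the mother's homozygous allele
matches HF2 (Type 3, marker = HF1's allele) or HF1 (Type 4, marker =
HF2's allele). In each case the marker allele is the one whose plasma
frequency rises by ff/2 when the type's haplotype is inherited; this
orientation is verified exhaustively against the mixture arithmetic in the
test suite. Each type is stratified into `typeN_ref` / `typeN_alt` by
whether the marker is the reference base. Sites with |DC| > 0.5 at depth ≥
100 are excluded as genotyping or mapping artifacts (both bounds
configurable).

## Bayes factors

For one type, the statistic is the difference of subgroup mean DCs,
D = mean(DC, ref subgroup) − mean(DC, alt subgroup). Its expectation is
+ff under H₁ ("this type's haplotype inherited") and 0 under H₂. For the
classic two-type route, DCs are first oriented to the marker-allele scale
and contrasted between partner types, with expectations ±ff/2. In both
routes the sampling density is Gaussian with variance propagated from
per-site binomial read noise:

var(D) = Σ_ref v_i / n_ref² + Σ_alt v_i / n_alt²,  v_i = p_i(1 − p_i)/depth_i.

The per-site binomial variance is evaluated at the midpoint of the site's
H₁ and H₂ expected frequencies, p_i = baseline ± ff/4. Evaluating at the
H₂ baseline alone would be degenerate: paternal-informative baselines are
0 or 1, giving v_i = 0 and an undefined BF. The midpoint is strictly
interior for every type, hypothesis-symmetric, and differs from the
baseline variance by O(ff²) at maternal sites. A summary-statistic density
(rather than a per-SNP likelihood product) was chosen for transparency: it
matches the stated mean structure exactly and admits an independent
numerical oracle.

The BF is the ratio of the two Gaussian densities at the observed D,
computed in log space; log₁₀ BF is clamped to ±300 (the double-precision
underflow boundary). Equal per-SNP weighting is used within subgroup means
— depth enters only through the variance — trading a little efficiency for
robustness to depth-correlated bias; a reimplementation may reasonably
revisit this with inverse-variance weights.

Per-type BFs keep H₁ = "the type's haplotype is inherited". The per-parent
combined log₁₀ BF is oriented pathogenic-vs-wild-type: log₁₀ BF of the
pathogenic-linked type (1 or 3) minus that of the wild-type-linked type (2
or 4), over whichever types are computable (≥ `min_subgroup_snps` per
subgroup). The three-way call applies |log₁₀ BF| ≥ threshold. Because
ref and alt subgroups share every multiplicative capture distortion of the
reference-allele frequency, a uniform shift cancels exactly in D; the
classic oriented contrast retains a term proportional to the difference in
ref/alt composition between the two types and is therefore bias-sensitive.

Optional blocking (`block_size`) cuts each type into consecutive
fixed-SNP-count blocks and sums per-block log₁₀ BFs; per-block
recombination inference is out of scope.

## Fetal fraction

At loci where the parents are opposite homozygotes, the fetus is an
obligate heterozygote and the paternal allele is fetus-specific in plasma:
ff_locus = 2a/(a + b) with a the paternal-specific and b the shared-allele
depth. The run estimate is the median over loci passing the depth filter —
the aggregator is a package choice (robust to isolated artifacts); no
outlier trimming or depth weighting is applied beyond the filter.
Father-heterozygous loci are excluded: the formula presumes a
fetus-specific paternal allele. Estimates outside (0.01, 0.5) are flagged
but returned.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_depth` | 50 | reads | below this, a single site's binomial noise (SD ≳ 0.07) swamps an ff/2 ≈ 0.05 signal |
| `min_ff_loci` | 20 | loci | median of fewer loci is fragile to single-locus artifacts |
| `min_subgroup_snps` | 10 | SNPs | smallest subgroup for which a mean-based Gaussian statistic is defensible |
| `log10_bf_threshold` | 2.0 | log₁₀ | "decisive" evidence on the conventional Bayes-factor scale |
| `outlier_dc_bound` / `outlier_min_depth` | 0.5 / 100 | — / reads | a half-unit frequency displacement at high depth is an artifact, not dosage |
| `flank_bp` | 1,000,000 | bp | SNPs within ±1 Mb of the pathogenic region (a 2-Mb window) are analysed |
| `block_size` | off | SNPs | single-block analysis by default |

## Simulator

The generator draws HM1, HM2 and HF2 site-wise from a population
reference-allele frequency (default 0.5, the regime of a common-SNP
capture panel); HF1 copies HM1 with probability `hm1_hf1_identity`
(default 0.9797, the near-identical-haplotype scenario) and is an
independent population draw otherwise. The sibling carries HM2 + HF2; the
fetal inheritance truth is configurable. Plasma depth is Poisson (default
mean 1000); reference read counts are binomial at the mixture frequency,
optionally distorted by a multiplicative reference-allele
capture-enrichment factor β, p′ = p(1 + β)/(1 + pβ). A dedicated
fetal-fraction panel of `n_ff_snps` (default 200) opposite-homozygote
parental loci is appended after the target SNPs, emulating the usable part
of the common-SNP FF panels such assays carry: under high HM1↔HF1
identity, opposite homozygotes are vanishingly rare among the linked
target SNPs themselves. Panel loci are flagged in the truth table and can
never be informative SNPs (both parents homozygous), so they do not
perturb type counts. Identical seeds give byte-identical outputs; seeds
feed independent deterministic streams for haplotype and read drawing.

What the simulator does **not** model — and what passing tests therefore
do not establish about real data: genotyping error in the parents or
sibling (genotypes are emitted error-free; robustness is probed separately
by injecting flips in tests), linkage disequilibrium beyond the HF1→HM1
copying mechanism, recombination within the window, sequencing error and
mapping artifacts, fragment-length structure, GC/coverage waves,
overdispersed depth (Poisson, not negative-binomial), site-specific or
fragment-level capture bias (β is a single genome-wide multiplier), and
maternal or placental mosaicism.

## Numerical choices and degenerate inputs

Log-space BF computation with a ±300 log₁₀ clamp; ties in the sibling
decomposition are never broken heuristically (ambiguous sites are
dropped); an empty subtype yields a "not computable" result, never a BF;
zero phaseable sites, inestimable fetal fraction, and allele-identity
mismatches between the genotype and plasma tables are hard errors; plasma
rows with zero depth are kept on input and removed by the depth filter
with a logged count. At sites whose non-inheritance mixture frequency is
exactly 0 or 1, observed DC is exactly 0 with zero variance — handled
naturally by the midpoint-variance evaluation.

## Problem sizes

Statistical tests and the acceptance script use 500–6,000 SNPs per
simulated pedigree, depth 1000, 15–100 replicates per condition, and all
four inheritance truth states — sizes at which every Monte-Carlo check has
comfortable margin (3 standard errors) while the full suite runs in well
under a minute of simulation time.

## Known limitations

Single-block inference (a recombination event inside the window biases the
statistic toward no-call or, if early in the block, a wrong-direction
signal — real deployments should inspect per-block BFs); uniparental
disomy and maternal mosaicism are not detected; sex chromosomes are out of
scope; the Gaussian summary-statistic likelihood understates tail mass at
very small subgroup sizes, which the `min_subgroup_snps` floor guards.
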