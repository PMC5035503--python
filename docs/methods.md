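# Methods

This note records the models behind `flockimpute`, the assumptions of the
synthetic-data generator, the numerically delicate choices, and what the
shipped tests do and do not demonstrate about real data.

## Genotype model and coding

Genotypes are additive B-allele dosages 0/1/2 with a single internal
missing code. VCF maps REF→A and ALT→B; PLINK text has no allele metadata,
so the reader takes the first allele listed per SNP as A unless a marker
map with allele labels is supplied — without one, dosage polarity at a SNP
whose first-listed animal is BB flips, which is inherent to the format,
not to the reader. Positions are 1-based bp; the canonical marker order is
(chromosome, position) with numeric-aware chromosome sorting.

## Quality control

Per-SNP filters run in a fixed order — undefined position, MAF < 5·10⁻⁴
(strict), call rate < 0.95, Hardy–Weinberg p < 10⁻⁵ — and each dropped SNP
records only its first failing rule. HWE uses the 1-df χ² test on genotype
counts by default (appropriate at chip-QC sample sizes); an exact test is
available via `QCThresholds(hwe_method="exact")`. The animal call-rate
filter (< 0.95) runs last, and SNP statistics are *not* recomputed after
animal removal: QC is a single pass, as chip pipelines usually run it. A
consequence worth knowing: when dropped animals move a borderline SNP
across a threshold, a second pass can drop more — single-pass QC is only
idempotent away from threshold boundaries.

## Genomic relationships and Mendelian inconsistency

`G = XX′ / (2 Σ pᵢ(1−pᵢ))` with X the 2p-centered dosage matrix (VanRaden
method 1). Missing dosages contribute 0 after centering (mean imputation),
which keeps G defined under missingness and biases relationships of
poorly-called animals toward 0. Within a scenario, frequencies come from
the union of reference and target animals — the only set guaranteed
available before imputation. Two caveats the tests make explicit:

* G matches pedigree expectations (parent–offspring ≈ 0.5) only against
  *base-population* frequencies from unrelated founders. Frequencies
  estimated from a structured sample shrink off-diagonal values by roughly
  the mean sample relationship, and founders that share ancestral
  haplotypes (see the generator below) add a background relatedness of
  order 1/K that compresses G further.
* MDS coordinates come from classical principal-coordinates analysis
  (scikit-bio's `pcoa`, eigendecomposition method) on
  d = √(gᵢᵢ+gⱼⱼ−2gᵢⱼ); negative eigenvalues are truncated and flagged in
  `attrs`. Axis signs are fixed deterministically (largest-magnitude
  coordinate positive).

Mendelian inconsistency between two animals is the count of opposing
homozygotes over SNPs called in both. AVTOP10 is the mean MI between a
target and its k = 10 *lowest-MI* reference animals (ties broken by animal
id); the top-10-by-G variant is also reported by `top_k_relationships` so
the two notions of "top 10 related" can be compared — they need not agree,
and the lowest-MI form is the default for prediction.

## Imputers

**Major-allele baseline** ("imputation by chance"): every missing entry
becomes the major-allele homozygote (heterozygote at p = 0.5 exactly).
Under Hardy–Weinberg its expected concordance is the mean major-homozygote
genotype frequency — a closed form the acceptance suite checks to 3σ with
exact binomial error propagation on independent founders.

**Window-haplotype imputer**: deterministic nearest-reference copying.
Windows of `window` SNPs (default 40, step = window − overlap) slide over
the high-density SNP order; in each window the reference animal minimising
the mean absolute dosage difference on co-observed low-density SNPs is
selected (ties → lowest animal id; no co-observed SNPs → lowest id) and
its dosages fill the target's missing entries. Cells covered by several
windows are resolved by majority vote, remaining ties by the later window.
Determinism was chosen over optimality throughout. This is a stand-in that
makes the *assessment* machinery testable; it shares only the
sliding-window vocabulary with real population imputers and none of their
haplotype modelling — absolute accuracies from it underestimate what
production software achieves, while the *orderings* across reference
designs reproduce the expected directions.

Window size should be matched to the informativeness scale of the data: we
default workflow runs to ~100–140 SNPs (the generator's ancestral-segment
scale, ~20 cM), because a window must contain enough low-density SNPs
(~10+) to discriminate a genuinely haplotype-sharing reference from the
minimum over thousands of unrelated ones. Two-step runs impute low→mid
against a (typically large) mid-density reference, then mid→high.

**External tools**: `export_external`/`import_external` write and read the
file dialects of the two commonly used population imputers (single
genotype file with chip indices and '5' as missing; per-set unphased
allele-pair files with '?' as missing) so results from an actual external
run can be mapped back onto the internal frame.

## Accuracy evaluation

CR and allelic r² are computed per animal (over evaluated SNPs) and per
SNP (over target animals), comparing only entries called on both sides.
The default evaluated set is the *masked* entries (target-panel SNPs
absent from the source panel): including pass-through observed genotypes
inflates accuracy; `evaluated="all"` provides the inclusive variant. r²
with zero dosage variance on either side is defined as 0 — a no-variation
SNP carries no recoverable signal, and the convention keeps the rarest
MAF-bin means defined; fewer than two comparable entries is NaN and
excluded from means. MAF bins are left-open/right-closed over
(0, 10⁻⁴], (10⁻⁴, 10⁻³], (10⁻³, 10⁻²], (10⁻², 0.05]; per-SNP r² for the
rare-allele table is only meaningful with a large imputed set, so the
default rare workflow uses ≥ 1000 target animals. Chromosome-end profiles
average per-SNP r² over the first and last n = 100 SNPs per chromosome in
map order; chromosomes shorter than 2n split at the midpoint without
double counting and are flagged truncated.

## Synthetic-data generator

The generator produces the population structure the assessment is designed
for, without claiming sequence realism:

* **Breed divergence** is Balding–Nichols: breed-b frequency
  pᵦ ~ Beta(p(1−c)/c, (1−p)(1−c)/c) around a base frequency p drawn from
  Beta(0.2, 0.2) (clipped to [5·10⁻⁵, 1−5·10⁻⁵]), a U-shaped spectrum with
  real mass below MAF 0.001. Divergence c per breed defaults to 0.05–0.06
  for the related maternal breeds and 0.3 for the terminal group, giving
  MDS-separable clusters and near-zero cross-breed relationships.
* **Pedigree**: founders (half male, half female) plus rule-driven
  generations; each mating rule draws dams from all earlier-born females
  of a dominant breed and sires from a small pool (~1 per 10 offspring),
  producing the half-sib-dominated top relationships typical of sheep;
  offspring breed composition is the parental mean and birth year is the
  generation index, so oldest-as-reference selection is well defined.
* **Founder haplotypes** default to an ancestral-mosaic LD model: each
  breed owns 20 ancestral haplotypes drawn from its frequencies, and each
  founder haplotype is a mosaic of them with Poisson segment switches
  (5 per Morgan, ~20 cM segments). SNPs with within-breed MAF < 0.01
  bypass the pool and are drawn independently per founder haplotype —
  rare variants behave like recent mutations that travel only through
  families, while common variants carry block LD that population
  imputation can exploit. `ld=None` gives independent Hardy–Weinberg
  draws. The mosaic is deliberately not coalescent-accurate: LD decay,
  allele-frequency/LD coupling and recombination hotspots are not
  modelled, so absolute simulated accuracies should not be read as
  field-realistic — the suite relies on within-simulation *comparisons*.
* **Gene drop**: Haldane recombination (no interference), crossover count
  per meiosis ~ Poisson(genetic length), positions uniform on the genetic
  map, genetic position linear in bp. Output is exactly
  Mendelian-consistent, so MI between error-free parent–offspring pairs
  is 0 by construction.
* **Panels**: nested subsets of the map. `informative_panels` draws lower
  densities evenly from SNPs with sample MAF ≥ 0.1, mirroring
  MAF-optimised commercial low-density chips; `evenly_spaced_panels` is
  the MAF-blind variant.
* **Noise**: genotyping error flips a called dosage to one of the other
  two states uniformly; missingness is independent Bernoulli. Defaults are
  0 because most workflows need error-free truth; QC tests switch them on.

All stages are seeded; `simulate_population` derives sub-seeds from one
seed and is bit-identical across runs.

## What passing tests show — and what they do not

The acceptance suite demonstrates, on these seeded conditions: exact
agreement of G/CR/r²/MI with brute-force oracles; the baseline's
closed-form CR; parent–offspring G ≈ 0.5 and MI = 0; cross-breed top-10
relationships near zero versus within-family values; monotone CR gains
from enlarging a nested reference; CR loss from excluding reference
animals with G > 0.45 to a target; two-step ≥ one-step with a large
mid-density reference; AVTOP10 rank-predicting per-animal CR (ρ < −0.3);
and non-decreasing MAF-bin r² with the union-singleton bin at exactly 0.
They do not certify absolute accuracy levels on real genotypes, the
portability of the 400/3000 AVTOP10 thresholds beyond the population they
were derived in (calibration is the recommended path), or the behaviour of
external imputation software.

## Problem sizes

Shipped tests and the acceptance script use 3 chromosomes × 500–700 SNPs,
multi-breed populations of ~1,150 animals, a rare-allele workflow of 5,500
animals × 2,100 SNPs (1,000 imputed), and a 10,000-SNP pedigree-recovery
population — sizes at which every directional effect is already stable
while a full run stays in the tens of seconds.
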