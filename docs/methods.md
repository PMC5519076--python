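# Methods

## Model and procedure

`corecollect` treats core-collection selection as a weighted greedy set
cover over *genotype classes*. The universe is the set of (marker, class)
pairs observed in the entire collection; a sample covers the pairs it
carries at its non-missing markers. The greedy criterion is not plain
count-based set cover: candidates are ranked by the coverage score `C_j`,
the mean entire-collection frequency of the classes the sample would newly
contribute, so common variation is secured first and rare variants enter
late. This ordering is what makes the coverage-versus-size curve rise as
fast as possible in the early steps.

Per iteration:

1. **Candidate pool.** Remaining samples that would still add coverage
   (`C_j > 0`), restricted to the stratum with the fewest missing calls.
   Preferring complete samples keeps low-quality genotypes out of the core;
   the stratum widens to the next missingness level only when the preferred
   one adds nothing, which guarantees the cover can always complete. A
   strict "least-missing only" pool can stall below full coverage when
   every complete sample is already redundant.
2. **Pick.** Argmax `C_j`; ties (equality after rounding to 12 decimals, a
   guard against floating-point noise) are resolved by minimum diversity
   score `D_j`; residual ties go to the first tied sample in input order.
   A seeded uniform draw is available (`tie_break="random"`), but the
   deterministic default is deliberate: residual ties occur precisely
   between interchangeable samples (typically duplicate accessions), and
   resolving them by a stable rule is what makes repeated runs return the
   identical core — the property that distinguishes this method from
   random-start optimisers.
3. **Masking.** Class frequencies `f` are computed once on the full
   collection and held fixed; covered (marker, class) contributions are
   zeroed in later rounds. The denominator `n(N_j)` is not reduced by
   masking — it depends only on missingness — so scores stay comparable
   across iterations and every accepted pick strictly increases CV. (The
   alternative of recomputing `f` over the shrinking remainder changes the
   meaning of the score mid-run and can break monotonicity.) `D_j` uses the
   same masked terms as the `C_j` it tie-breaks, for internal consistency.
4. **Duplicate removal.** The pick and every remaining sample with a
   byte-identical call vector (missing positions included) are removed.
   Exact identity is the only rule that never discards still-uncovered
   classes; near-duplicate collapsing is out of scope.
5. **Stopping**, checked in order after each step: cumulative CV ≥ target
   (default 99%); step gain < delta (default 0.01 percentage points);
   optional size cap. Before any step: no remaining candidate with
   `C_j > 0` (a state plain greedy theory ignores but missing data makes
   reachable), or pool exhausted.

## Statistics

* **CV** (percent): mean over informative markers of `GC_i / GE_i`,
  subset classes over entire-collection classes. Markers with every call
  missing are excluded from the denominator everywhere.
* **SH**: `−Σ_i p_i ln p_i` with `p_i` the subset's reference-allele
  frequency at marker `i`, exactly as conventionally printed for this
  statistic (one term per marker, not a per-marker entropy over both
  alleles). `p_i = 0` terms contribute 0.
* **MR**: `sqrt( (1/2m'') Σ (p_xij − p_yij)² )` with per-sample allele
  frequencies in {0, ½, 1} for diploids, over pairwise-complete markers
  only (`m''`), keeping MR in [0, 1] under any missingness pattern. The
  square root is part of the definition (it is what bounds the distance by
  1 for opposite homozygotes).
* **Reference allele**: VCF REF when the matrix came from VCF (allele
  index 0); otherwise the entire-collection major allele per marker, ties
  broken lexicographically.
* **Spectrum preservation**: per-marker `p_i` histograms (default bin
  width 0.05) for core and collection, compared by the maximum absolute
  difference of the normalised spectra.

## Genotype-call canonicalisation

Calls are normalised once at input: separator genotypes (`0/1`, `1|0`)
become sorted `/`-joined classes, two-character nucleotide calls are sorted
characterwise (`GA` → `AG`), half-calls and anything in the missing-code
set (`NA`, `--`, `NN`, `./.`, empty) become the missing sentinel, and any
other token (including dosage codes `0`/`1`/`2`) is kept verbatim as its
own class. For allele-based statistics a single-token call is read as a
homozygote for that token; dosage-coded matrices therefore get faithful
class-level statistics (CV, selection) but allele-level ones (SH, MR) only
under that reading — recode to nucleotide or `a/b` calls when SH/MR matter.

## Synthetic collections

The generator emulates a genebank panel: `n_founders` distinct prototype
lines, each present `dups_per_founder` times. Founder genotypes are drawn
per marker under Hardy–Weinberg proportions with reference-allele frequency
sampled from Beta(0.8, 0.8) by default — a U-shaped spectrum resembling SNP
array site-frequency distributions. Copies are perturbed by i.i.d. per-call
genotyping error (`mutation_rate`, resampling the call from the marker's
genotype distribution) and i.i.d. per-call dropout (`missing_rate`); an
option adds triallelic markers to exercise class logic beyond biallelic.
Everything is deterministic under the spec's seed.

Not emulated: linkage disequilibrium, pedigree relatedness among founders,
batch- or sample-level missingness structure. Tests passing on these data
therefore demonstrate the combinatorial and statistical behaviour of the
selector, not robustness to assay artefacts correlated across markers.

A consequence of realistic per-call dropout worth knowing: with, say, 2%
missing calls, one representative per founder is *not* always a complete
cover — the representative is missing at ~1–2% of markers, so classes
unique to its founder at those markers stay uncovered, and a run to 100%
coverage adds a second representative for a few founders (e.g. 28 picks
for 25 founders at 2000 markers). Exact one-per-founder recovery holds when
duplicates are exact (`missing_rate = 0`, `mutation_rate = 0`).

## Numerical and degenerate-input choices

* Score-tie tolerance: rounding to 12 decimals before comparison.
* A sample with no non-missing call scores 0 with a warning (never fatal).
* Empty matrices and all-uninformative matrices are hard errors for
  selection; all-missing markers alone are merely flagged.
* MR between samples sharing no complete marker raises rather than
  returning a silent sentinel.
* CV from the selection trace and CV recomputed on the final core agree to
  1e-9 by construction (same coverage bookkeeping).

## Problem sizes used in the shipped checks

Oracle-agreement checks run hundreds of small random matrices (≤ 10
samples × 12 markers) against unvectorised loop reimplementations at 1e-12.
End-to-end checks use a 500-sample / 2000-marker duplicated-founder panel
(selection, reproducibility over 100 seeds) and a 400-sample / 5000-marker
broad panel (spectrum preservation), sizes at which a full run takes
seconds on one CPU while exercising the same code paths as chip-scale data.
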