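# Methods

This note documents the statistical procedures implemented in `pangpred`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Call statistics and filtering

For a SNP over an accession subset of size n, the call rate (CR) is the
fraction of non-missing calls; the alternative-allele frequency is
(2·#hom-alt + #het) / (2·#non-missing); MAF = min(f, 1−f); heterozygosity is
#het / #non-missing. Using non-missing calls as the heterozygosity
denominator treats heterozygosity as a property of observed genotypes, not
of missingness. SNPs with no observed call have CR 0 and undefined (NaN)
MAF/heterozygosity.

Threshold filters are strict as printed (CR > 0.8, MAF > 0.05,
heterozygosity < 0.05 for the baseline; MAF > 0.05, CR > 0.05,
heterozygosity < 0.05 for the per-reference intermediate sets — the
permissive CR floor deliberately keeps SNPs inside rare dispensable
segments). When partitioning vertex SNPs into high- and low-CR sets for
encoding, a CR exactly at the 0.8 boundary goes to the high-CR (core) side;
the boundary mass is negligible in practice, but the filter and the
partition are deliberately consistent about where equality falls.

Mean imputation replaces a missing entry by its column mean over observed
entries, which preserves column means exactly. Imputation of a column never
depends on other columns, so the baseline pipeline imputes before windowed
LD pruning: the resulting matrix is identical to pruning first and imputing
the survivors, and the pruning precondition (no missing values) is met
without a special code path.

## Vertex selection and SNP assignment

Vertices are BED-convention intervals (0-based, half-open) on a source
reference; SNP positions are VCF 1-based, so a SNP at position p lies in
[start, end) iff start < p ≤ end. Selection keeps vertices strictly larger
than 5,000 bp from references other than the backbone. A SNP covered by
several overlapping vertices is attributed to the lowest graph-build rank,
then the left-most, then the lexicographically first vertex — mirroring the
attribution of shared vertices to the first reference that introduced them.
Vertices from different references are never merged; redundant signal from
the same physical variant called against two references is left to LD
pruning, which is the mechanism the whole pipeline relies on for
de-duplication.

## Encodings

Additive: hom-ref 0, het 1, hom-alt 2, missing NaN (imputed downstream).
PAV: any observed call 0 (a heterozygous call still implies the sequence is
present), missing 2. Modified one-hot: allele counts of (absence,
reference, alternative) — (2 0 0) missing, (0 2 0) hom-ref, (0 1 1) het,
(0 0 2) hom-alt; each triple sums to 2 (diploid allele conservation) and the
absence column equals the PAV marker by construction, so gains from PAV and
from residual nucleotide variation are separable. The classical four-column
one-hot encoder exists for comparison only: in a selfing crop the
heterozygote indicator column is a rare-state indicator prone to spurious
effects, and the pipeline never feeds it to prediction.

## LD pruning

LD between marker columns is the squared Pearson correlation of their
numeric values — dosages for additive markers, raw 0/2 or 0/1/2 columns for
PAV/OHE. One measure is used everywhere; thresholds are on r².

*Windowed* (baseline): greedy left-to-right scan, window of 50 marker
positions, threshold r² = 0.8. Each candidate is compared with the trailing
retained markers in its window; in an exceeding pair the lower-MAF member
is dropped (ties drop the later one), so a common variant can evict a rarer
retained one. Because evictions shorten distances in the retained sequence,
a final sweep re-checks all retained pairs within a window and resolves any
residual violation the same way; the exhaustive window-local post-condition
therefore holds for the output. Only the window size and threshold are
fixed by the procedure being mirrored; step size 1 and the drop-lower-MAF
rule follow common practice and are configurable.

*Joint, within-vertex* (appended markers): columns are first filtered by
column-MAF (min(mean/2, 1 − mean/2)) > 0.05, then pruned greedily with no
window inside each vertex at r² ≤ 0.6 — vertices contain few markers, so
every pair is checked. Whether the original tooling thresholded |r| or r²,
and which member of a pair it dropped, is not recoverable; both are exposed
as parameters and the defaults are r² with drop-the-later-column.
Zero-variance columns are removed up front with a warning in both modes
(r² is undefined for them and they carry no information).

## rrBLUP and REML

The model is y = 1μ + Zu + ε with u ~ N(0, Iσ²ᵤ), ε ~ N(0, Iσ²ₑ). Markers
enter exactly as encoded — no standardization — so the ridge penalty
λ = σ²ₑ/σ²ᵤ acts on the 0–2 scale of the encodings. The printed ridge
solution u = (Z′Z + Iλ)⁻¹Z′y omits the intercept; here μ and u are solved
jointly from the mixed-model equations (equivalently μ by GLS under
V = ZZ′ + λI and u = Z′V⁻¹(y − 1μ)), matching the behaviour of standard
mixed-model solvers. Both the m×m ("primal") and n×n ("kernel") forms are
implemented and agree to numerical precision; the smaller system is chosen
automatically.

REML profiles μ and the overall scale analytically: with Q₂ an orthonormal
basis of the complement of the intercept, the eigendecomposition of
Q₂′ZZ′Q₂ reduces the restricted likelihood to a smooth 1-D function of
log λ, maximized by bounded scalar optimization over λ ∈ [1e−9, 1e9] at
tolerance 1e−6. σ²ᵤ is recovered from the profiled scale (REML degrees of
freedom n−1) and σ²ₑ = λσ²ᵤ. A constant phenotype returns the boundary fit
(σ²ᵤ = 0, u = 0, μ = the constant) rather than raising.

## Cross-validation and GPA

Accuracy uses replicated k-fold cross-validation (default 10 × 5-fold) with
fold plans built once per trait and reused across all matrices, so matrix
comparisons share partitions exactly (plans carry a fingerprint, and ΔGPA
refuses to compare results from different plans). GPA per replication is
the Pearson correlation of observed and predicted values **pooled over the
k test folds** — the natural reading of correlating "over the folds";
per-fold averaging would be a different estimator and can be computed from
the exported tables if wanted. Folds are simple random (unstratified)
partitions; accessions missing the evaluated trait are dropped before the
plan is built. Subpopulation-restricted accuracies restrict the pooled test
set to the accessions of one subpopulation; a group with fewer than three
test members or degenerate variance gets an undefined (NaN) GPA for that
replication rather than a fabricated number.

## Synthetic panel generator

The generator produces the statistical structure the analysis assumes, not
a biological sequence simulation:

- **Population**: K subpopulations under the Balding–Nichols model —
  ancestral frequencies ~ U(0.05, 0.95), subpopulation frequencies ~ Beta
  with mean p and variance p(1−p)·Fst (default Fst 0.3). Accessions are
  near-fully inbred (hom-alt with probability f, else hom-ref), with a
  small fraction of calls (default 2%) flipped to heterozygous to emulate
  residual heterozygosity in purified gene bank material.
- **Vertices**: each vertex has a source reference (one per subpopulation
  by default, ranked in creation order) and a home subpopulation; per
  accession its segment is present with probability p_home (default 0.9)
  or p_away (default 0.2). SNPs nested in an absent segment are missing by
  construction; uniform technical missingness (default 5%) is layered on
  all calls, making technical and biological missingness indistinguishable
  in the observed data — exactly the confound the encodings address.
  Vertex sizes are drawn from a range straddling the 5 kb selection cut so
  the size filter is actually exercised.
- **Phenotype**: additive breeding values from three effect classes (core
  SNP dosages, vertex presence indicators, within-vertex SNP dosages for
  present accessions), effects ~ Normal with per-class scales, plus
  Gaussian noise scaled so Var(g)/(Var(g)+σ²ₑ) equals the target
  heritability. Breeding values use the true pre-missingness genotypes;
  the analysis only ever sees the observed calls. Causal vertices are
  drawn among vertices above the 5 kb cut, since those segments are the
  analysis target.

What it does **not** emulate: LD decay along chromosomes (core SNPs are
mutually independent given the subpopulation), haplotype-level presence
(presence is per accession, matching the binary present/missing treatment),
realistic allele-frequency spectra, or genotype-calling error beyond
uniform missingness. Consequently a passing recovery experiment shows the
pipeline's machinery extracts presence information when it is there and
adds none when it is not — it does not certify effect sizes on real panels,
where LD both helps (dimension reduction) and hurts (redundancy).

## The recovery experiments

Two simulation experiments anchor the test suite.

*Call-rate structure*: with the default enrichment (p_home 0.9, p_away 0.2,
5% technical missingness; 3 × 200 accessions), mean vertex-SNP call rate in
the home subpopulation is p_home·0.95 ≈ 0.855 versus p_away·0.95 ≈ 0.19
away — the home-vs-away gap exceeding 0.3 for every reference group, with
observed rates within ±0.03 of these Bernoulli-product expectations.

*Prediction recovery*: 600 accessions (3 × 200), 3,000 core SNPs, 150
vertices with 1–3 SNPs each, h² = 0.5, 5 replications of 5-fold CV under
one shared fold plan, mixed-panel evaluation. In the signal arm, 40 causal
vertex-presence effects contribute ≥ 50% of genetic variance under mild
enrichment (p_home 0.55, p_away 0.35), chosen so subpopulation structure —
an upper bound for any core-SNP predictor — explains < 20% of the variance
of every causal presence vector: PAV/OHE gains must then come from the
presence information itself, and both PanG-PAV and PanG-OHE beat BASELINE
by > 0.05 mean ΔGPA. In the null arm (all-core causal architecture) every
PanG matrix stays within ±0.03 of BASELINE. The appended marker set is kept
modest relative to n (1–3 SNPs per vertex, a few hundred appended columns
against ~2,700 baseline markers) because at desk-scale n the pure
dilution cost of appending many uninformative independent columns to a
ridge model is itself of order several hundredths of GPA — a small-sample
artifact, not a property of the encodings, and the null comparison is
meant to isolate the latter. These problem sizes keep the full suite to
well under a minute per experiment arm.

## Numerical and degenerate-input conventions

- Encoded matrices never contain missing values; assembly removes
  zero-variance columns, so downstream correlation and REML computations
  are well defined.
- r² on a zero-variance column raises in the public pairwise function;
  pruners drop such columns first with a warning and record them in the
  prune report.
- Marker matrices serialize to a self-describing two-block TSV (provenance
  metadata, then values written with the shortest round-tripping float
  representation), so write → read is bit-exact and every column remains
  classifiable as baseline- or vertex-origin.
- All generators and fold plans are seeded; pipeline reruns with the same
  config and seed reproduce every output file byte for byte.

## Known limitations

- The appended-column order (reference rank, vertex, position, allele
  role) pins down deterministic builds but is one of several defensible
  orders; greedy pruning outcomes depend on it.
- Genomic heritability is not estimated on the observed scale; σ²ᵤ is a
  per-marker prior variance and should not be read as a trait h².
- The CLI's `report` command recomputes the vertex pool from the input
  files rather than caching it; for very large panels, call the library
  functions directly and keep the pool in memory.
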