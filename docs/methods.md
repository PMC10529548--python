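# Methods

This note documents the models and procedures implemented in `museomics`,
the parameter choices that matter, and what the synthetic-data generators do
and do not emulate.

## Problem setting

Museum wet-collection specimens yield heavily degraded DNA: short fragments,
very low endogenous content against an overwhelming contaminant background,
and (absent UDG treatment) cytosine-deamination damage at fragment termini.
The package implements the informatic arc that turns such material into a
species-level inference: quality control of short single-end reads,
assessment of endogenous content by stringency-swept mapping, reconstruction
of a mitochondrial consensus by iterative reference refinement, calibrated
relaxed-clock dating of the resulting lineage on a fixed topology, and
univariate plus multivariate morphometrics of meristic characters for the
corresponding specimens.

## Read QC

Adapter trimming removes, in one pass, either a full internal adapter
occurrence (plus everything 3' of it) or the longest read suffix equal to an
adapter prefix, requiring as little as a single base of overlap
(`min_overlap=1`). Matching is exact by default; an optional
`max_error_rate` enables mismatch-tolerant matching but the shipped analyses
use 0. Single-base overlap trimming necessarily costs an occasional genuine
terminal base; with degraded short-insert libraries, read-through into the
adapter is common enough that the trade is standard practice. Reads shorter
than 30 bp after trimming are discarded. Trimming applied with
`min_overlap = len(adapter)` removes whole occurrences only and is
idempotent; with shorter overlaps a second pass can remove further bases, a
property shared by any single-pass trimmer honouring 1-base overlaps.

## Mapping

At mitogenome scale an exact k-mer positional index (default k = 13)
replaces an FM-index. Reads are placed ungapped on either strand at the
candidate offsets implied by exact seed hits; the placement minimising
Hamming distance wins, subject to a mismatch budget
`floor(frac × read_length)`. The stringency fractions mirror the
conventional aligner settings (0.04, 0.01, 0.001) but the budget rule is a
deliberate simplification of the expected-error integral used by `bwa aln`;
stringency is used comparatively, so only the ordering matters. N bases
never match anything. Seed completeness: a placement with `b` mismatches is
guaranteed discoverable when `(b+1)·k ≤ L` (pigeonhole), which holds
throughout the shipped analyses (75 bp reads, budget ≤ 7, k = 13 requires
only one clean 13-mer among 63).

Mapping quality is a declared deterministic function: 60 for a unique best
placement within budget, 0 for a tied best, otherwise
`min(60, 60·gap/(budget+1))` where `gap` is the best/second-best mismatch
difference. The MAPQ ≥ 30 filter therefore retains confidently unique
placements, preserving the intent of the conventional `-Q 30` filter without
reproducing any particular aligner's estimator. Duplicate removal collapses
alignments sharing (start, end, strand) to the highest-MAPQ representative
(ties to the lexicographically smallest read id), then sorts by start.

Circular references are supported by a `read_length−1` wrap-around
extension of the index with re-projection modulo the true length; the
shipped analyses treat the reference as linear.

## Consensus reconstruction

Majority-rule calling per column: below `min_depth` the call is N, except
that a depth-0 column is filled from the reference when reference fill is
enabled; otherwise the modal base is called iff
`count/depth ≥ threshold` (boundary included: a site at exactly the
threshold is called), with ties among modal bases yielding N rather than
IUPAC ambiguity codes (downstream alignment treats ambiguity as missing
anyway). "Regions lacking mapped reads" is interpreted as depth == 0
exactly; columns with `0 < depth < min_depth` are N, never reference-filled.

Iterative refinement maps all reads at a permissive budget (fraction 0.10,
the role played by a local-alignment-style mapper), calls a 50% majority /
depth ≥ 1 consensus with reference fill, and repeats with the new consensus
as reference, stopping when the mapped read-ID set is identical to the
previous round's or after 10 rounds. The consensus returned is the 90%
majority / depth ≥ 3 / no-fill call on the final alignment. A final
stringent stage re-maps everything at fraction 0.04 and calls 85% majority /
depth ≥ 10 / no-fill. Because the mapper is ungapped, insertions relative to
the reference are unrepresentable and deletions appear as coverage gaps;
the refined consensus always has the length of the starting reference.

Regions of depth ≥ `min_depth` (default 3) are extracted as maximal runs and
reported as 0-based half-open intervals with mean depth; these delimit the
trustworthy portion of a sparse reconstruction.

## Synthetic data

The read simulator emulates a museum shotgun library: lognormal fragment
lengths (real-space mean 60 bp, SD 20 bp, truncated to [20, 2×read length] —
the distribution itself is a conventional choice, not an estimate), 75 bp
single-end reads truncated from fragments, uniform fragment placement on
either strand, per-base miscall probability 0.001, and a contaminant genome
supplying `1−f` of reads for endogenous fraction `f`. Deamination damage is
modelled as C→T at the 5' terminus and G→A at the 3' terminus with
probability `delta·decay^offset` and is disabled by default, matching a
UDG-treated library; enabling it lets the pipeline's robustness be probed.
A truth table (source, coordinates, strand per read) accompanies every
library. Not emulated: cycle-dependent quality profiles, paired-end reads,
index hopping, chimeras. Amplicon simulation produces error-free,
undamaged reads uniformly tiling given intervals at a target depth.

Sequence evolution on a dated tree is the GTR+Γ(+I) CTMC: per-site rate
categories (including the invariant class) are drawn once and shared across
the tree; branch lengths in substitutions/site are
`duration × branch rate × clock rate`. The rate matrix is normalised to one
expected substitution per unit length at stationarity, so Jukes–Cantor
distances obey the usual closed form — the basis of several oracle tests.

Morphology simulation draws rounded, range-truncated normals per
population × sex group. Default group parameters are the published
scale-count summaries for the two rinkhals populations (e.g. Zimbabwe
female ventrals 128 ± 1.6, range 126–130); snout-vent and tail length are
generated with a sex-specific tail ratio so the ANCOVA has a real covariate
structure. The generator produces no missing data by default; tests inject
missingness explicitly where complete-case behaviour is under test.

## Divergence dating

The dating model is deliberately the standard one: partitioned GTR+Γ+I
likelihood by Felsenstein pruning (gamma discretised into four
equal-probability category means; the invariant class mixed in with weight
`p_inv`; missing data as all-ones partial likelihoods; per-node rescaling),
an uncorrelated lognormal relaxed clock (iid branch-rate multipliers with
real-space mean 1 and spread `clock_sd`, times a global clock rate in
subs/site/Myr), a Yule pure-birth prior over node ages, and normal
calibration priors on clade MRCA ages with the study convention sd = 0.01
Myr, which effectively fixes a calibrated date. Base frequencies are fixed
at their empirical (per-partition) values; exchangeabilities, gamma shape
and `p_inv` are sampled. The topology is fixed throughout: all inference
concerns node ages on an agreed topology, and calibrated clades must be
monophyletic in it.

Declared prior normalisations, where the literature offers choices: the
Yule term is `Σ_internal (log λ − λ·age)` (for two tips, the exponential
root-age density); hyperpriors are λ ~ LogNormal(0, 2), clock_sd ~
Exponential(1), clock rate ~ LogNormal(−3, 3), exchangeabilities iid
LogNormal(0, 1.5), gamma shape ~ Exponential(1), `p_inv` uniform. These are
broad and dominate nothing in the shipped analyses.

The sampler is single-move-per-generation Metropolis–Hastings: uniform and
local node-age slides within the (child, parent) interval, a root-age scale
move, branch-rate/clock/hyperparameter multipliers, and model-parameter
moves. Prior-only moves skip likelihood evaluation. Site patterns are
compressed once per partition. Initial ages pin calibrated nodes at their
prior means and push uncalibrated ancestors above their children; a
calibrated node forced below a descendant is reported as a conflict. The
clock rate is initialised from mean pairwise p-distance over twice the root
age — an initialisation, not a prior.

Trace summaries report the posterior mean, the shortest interval containing
95% of post-burn-in samples (HPD), and ESS `n/(1+2Σρ_k)` with
autocorrelations truncated at the first non-positive value (a constant
trace has ESS n by convention). Default burn-in is the first 10% of
generations.

Problem sizes: the package default is 500k generations sampled every 100;
the shipped analyses and tests use 30k–120k generations on 8–10-taxon,
1–2.3 kb data, sizes at which the calibrated-coverage experiment (20
replicates, one fixed root calibration, strict-clock data) puts true free
node ages inside the 95% HPD in ≈93% of checks. Per-replicate chains this
short leave some ESS in the tens; the coverage experiment measures exactly
what such a scaled-down analysis delivers.

## Morphometrics

Chi-squared (2×2, optional Yates correction, exposed because published
tables rarely state it) and Fisher's exact test (two-sided as the sum of
hypergeometric probabilities no larger than the observed table's; an r×c
variant enumerates all tables with the observed margins) operate on
dichotomised count classes at the published boundaries (midbody 17–18 vs
19; nape 16–18 vs 19). ANOVA and ANCOVA use sequential (Type I) sums of
squares in the order covariate (ANCOVA only), population, sex,
population×sex, computed by nested OLS fits — single-formula ANOVA tables
were rejected because design-matrix builders reorder terms, silently
changing the sequential decomposition on unbalanced data. The SS type is a
declared choice (the data are unbalanced, so types differ); effects with
essentially zero sequential SS (< 1e-9 of total) are reported as F = 0
rather than 0/0 round-off noise. With an empty cell the interaction is
omitted with a warning; a constant second factor degrades to one-way ANOVA.

PCA standardises each character to zero mean and unit sample SD (n−1) over
complete cases, then eigen-decomposes via SVD of the standardised data — the
covariance analysed is therefore the correlation matrix and eigenvalues sum
to the number of characters, a tested invariant. Each eigenvector's
largest-magnitude loading is made positive so loadings are sign-stable
across platforms.

## Known limitations

- The mapper is ungapped; indels in reads are tolerated only as mismatch
  load and indels between reference and sample appear as coverage artefacts.
- MAPQ is a declared function of placement ambiguity, not an error-model
  estimate; absolute values are not comparable with other aligners.
- The dating sampler has no topology moves by design; it cannot average
  over topological uncertainty.
- Control-region duplications (common in snake mitogenomes) are not
  resolved; a repeated region maps at MAPQ 0 and drops out of the filtered
  pileup.
- Synthetic reads lack quality-by-cycle structure, so the pipeline's
  indifference to base qualities is untested against realistic quality
  decay; qualities are carried through I/O but unused by the mapper.
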