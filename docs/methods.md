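# Methods

This note documents the models and procedures serpeak implements, the
parameters that matter, and the design choices made where the problem was
genuinely open. Coordinates are 0-based half-open throughout.

## Signal-enriched-region (SER) calling

**Model.** The genome is tiled with non-overlapping 200 bp windows; reads are
counted into every window they overlap by at least one base (so a
200 bp read straddling a window boundary increments both windows — this
any-overlap convention also makes adjacent window counts positively
correlated, which matters below). Window counts are transformed to
`log2(count + 1)` and modelled by a 4-state hidden Markov model with
univariate Gaussian emissions, learned by Baum–Welch on all chromosomes as
independent chains sharing one parameter set. After training, states are
relabelled by ascending emission mean; windows Viterbi-decoded into the two
top states are "enriched". The whole procedure is run twice, on the
original grid and on a grid shifted by 100 bp (half a window), each phase
learning its own model; only bases enriched in *both* phases survive. The
models learned from the ChIP sample are then applied — without refitting —
to the matched input sample, and any base that is input-enriched in either
phase is subtracted. Regions touching a blacklist interval by one or more
bases are dropped, and the remainder is merged with gap 0 into SERs.

**Why Viterbi and a Gaussian on log2 counts.** The enrichment HMM is a
segmentation device: Viterbi produces contiguous state runs suited to
window merging, and the log2 transform stabilizes the variance of counts so
the four states are interpretable as background / low / medium / high
signal. Posterior-argmax decoding and alternative emission scales are
available through the `GaussianHMM` API but are not the defaults.

**Regularization (important at shallow coverage).** Two floors keep the
maximum-likelihood fit from degenerating when coverage is low:

* *Emission sd floor* (`sd_floor`, default **0.4** on the log2 scale).
  Low counts are discrete — log2(count+1) takes the values 0, 1, 1.58, 2 … —
  and an unconstrained Gaussian state will collapse (sd → 0) onto a single
  count value, turning "state 3 or 4" into "any window with a read". The
  floor is about half the unit spacing between adjacent low-count levels,
  which is the smallest scale at which separating neighbouring count values
  still costs likelihood.
* *Self-transition floor* (`min_self_transition`, default **0.999**). The
  transition M-step is solved under the constraint `A[i,i] >= floor` (clamp
  the diagonal, rescale the off-diagonal row mass — the exact constrained
  maximizer, so EM monotonicity is preserved). This encodes that both
  background stretches and enriched regions are long relative to one
  window; without it, fragment-length reads smearing single background
  events across adjacent windows cause the trained chain to fragment and
  the top states to absorb scattered background runs.

With both floors at their defaults, planted-region simulations at fold 8
over a 0.5 reads/window background (2 Mb genome, 50 regions) give region
recall ≥ 0.94 and base-level precision mostly ≥ 0.9 across seeds, with at
most 2 false SERs on a background-only genome. Part of the residual
imprecision is structural: reads are `frag_len` long, so coverage —
and hence enrichment — extends up to one fragment length beyond a planted
region's boundary.

**Initialization.** Deterministic and rank-ordered: emission means at the
20th/50th/80th/99th percentiles of the transformed counts, sds equal to the
global standard deviation (floored), self-transitions 0.9, uniform initial
distribution. An infinite convergence tolerance returns this initial model
untouched; otherwise EM stops when the relative log-likelihood improvement
drops below `tol` (default 1e-6) or after `max_iter` (default 200)
iterations.

## Subpeak decomposition and scoring

Within each SER the per-base read pileup is smoothed by a centered moving
average (window 51 bp, truncated at the edges). Local maxima of the
smoothed profile are candidate summits; two adjacent candidates become
separate subpeaks when the minimum between them falls below
`valley_frac = 0.5` times the lower of the two smoothed maxima. The rule is
a ratio, so splitting is invariant to uniform scaling of the profile. The
boundary sits at the leftmost base of the minimal run; subpeaks narrower
than 50 bp are merged into their taller neighbour; the summit is the
leftmost base of maximal *unsmoothed* depth inside each subpeak (ties
leftmost, for determinism). The original splitting tool's exact rule and
defaults are not published, so this is a documented, configurable stand-in
with the same qualitative behaviour. On planted triangular summits
separated by deep valleys the splitter returns exactly the planted number
of subpeaks with summit error bounded by half the smoothing window.

Each subpeak is scored by its **normalized height**: raw read depth at the
summit rescaled to a 10-million-read library (`depth * 1e7 /
total_mapped`). Subpeaks with normalized height below 2 are discarded.

## Differential occupancy classification

For a subpeak called in dataset A, the normalized height `h_B` of dataset
B's pileup is measured at A's summit coordinate, and the uniqueness score is
`(h_A − h_B) / max(h_B, 1)`; the denominator floor of 1 damps fold changes
computed on near-zero background. The label rules, applied with strict
inequalities exactly as printed:

* **unique to A** — score > 2 *and* no B subpeak summit within 100 bp of
  A's summit (distance measured summit-to-summit; exactly 100 bp counts as
  within);
* **shared** — a B subpeak summit within 100 bp and the two matched summit
  heights differ by less than 1;
* **ambiguous** — anything else; excluded from set comparisons.

For whole-dataset comparisons, shared-labelled subpeaks are paired 1:1
greedily by summit distance (ties toward the leftmost summit). Presence of
a subpeak in any additional cell type uses the same normalized height at
the summit with the threshold 2.

Note a scale effect when libraries are small: the shared clause compares
heights on the absolute per-10M scale, and with a library of N reads one
read at a summit contributes 1e7/N height units. At the synthetic demo
scale (N ≈ 7·10³) that quantum is ≈ 1.4·10³, so matched heights essentially
never agree within 1 and the demo comparison yields unique + ambiguous
labels only. The rule's branches are therefore verified on constructed
fixtures with realistic library sizes, and the demo output should be read
with this in mind.

## Chromatin-state segmentation

Histone-mark counts per 200 bp bin are binarized against a Poisson
background: a bin is "marked" when `P(X >= count | X ~ Poisson(λ_bg))`
falls below 1e-4 — the convention of the widely used binarization-based
segmentation framework; the threshold and bin size are configurable. One
multivariate (product-)Bernoulli HMM with 6 states is learned jointly from
the binarized tracks of *all* cell types, concatenated as independent
chains, with the best of `n_restarts` seeded random initializations kept by
final log-likelihood. States are relabelled by descending total emission
probability, so the mark-richest state is state 1 and the quiescent state
lands last. Each cell type is then segmented by per-bin posterior-argmax
decoding — marginal posteriors, unlike the Viterbi choice above, because
the segmentation feeds fraction-of-overlap statistics for which per-bin
marginals are the appropriate quantity.

Two summaries operate on segmentations from any source (including external
segmentation BED files): the **peak–state distribution** counts a peak for
a state when some maximal same-state segment covers at least 30% of the
peak's length (a peak straddling a boundary can count for two states, so
the counts need not sum to the peak count), and the **state fate** matrix
assigns each fixed region its dominant state (largest covered fraction,
ties toward the lower state index) in each of two cell types and counts
the transitions; its row sums equal the number of regions.

On data simulated from a known 6-state model (100 000 bins, 3 marks, 5
pseudo-cell-types) the emission matrix is recovered to within 0.05 per
entry after optimal state matching — typically within 0.01.

## Supporting statistics

* **Genome-binned correlation** — non-overlapping 1 kb tiles, dropping any
  tile that overlaps a blacklist interval or a mappability ≤ 0.2 stretch by
  one or more bases; raw per-tile read counts (any-overlap counting) are
  compared by Pearson correlation; sample trees use average-linkage
  clustering on distance 1 − r (the linkage choice is a convention — the
  source figures do not name one).
* **Cohen's d** — pooled-sd standardized mean difference, with verbal
  categories on |d| closed left-inclusively to make them total:
  [0, 0.2) none, [0.2, 0.3) small, [0.3, 0.8) medium, [0.8, ∞) large.
  The printed category boundaries are open intervals; boundary cases are
  measure-zero and the left-closed convention is ours.
* **Boxplot summaries** — quartiles by linear interpolation (the common
  plotting default; no method is stated in the source figures), whiskers at
  the most extreme data points within 1.5·IQR of the box.
* **Overlap conventions** — peak-set comparisons use reciprocal 30%
  (the shared span must cover ≥ 30% of *each* peak); peak-to-segment
  assignment uses one-sided 30% of the peak; peak-to-gene assignment
  requires the promoter window (−1 kb … +0.5 kb of the TSS, strand-aware)
  to cover ≥ 30% of the peak.
* **Summit annotation** — five classes with strand-aware windows
  (promoter −1 kb…+0.5 kb of TSS; putative enhancer −20 kb…−1 kb of TSS;
  TTS −0.5 kb…+1 kb; gene body TSS+0.5 kb…TTS−0.5 kb; else distal
  intergenic). Where windows of several genes overlap the more
  proximal/definitive class wins: promoter > TTS > gene body > enhancer.
  The precedence and the genomic mirroring of minus-strand windows are our
  choices; the underlying offsets are the published ones.
* **Enrichment score** — `n_overlap / (n_A · n_B) · 10 000`, symmetric in
  the two sets.

## Synthetic data: what it emulates, and what it does not

The generator produces, as pure functions of `(config, seed)`: a genome
with planted enriched regions (default 50 regions of 2 kb at fold 8, 1–3
triangular summits each, over a homogeneous Poisson background of 0.5
reads per 200 bp window), input-only and ChIP+input artefact regions
(5 + 5 by default, the latter exercising input subtraction), blacklist
(1% of the genome) and low-mappability (2%, score 0.1) stretches placed
off the planted regions, uniformly placed gene models, mark tracks drawn
from a known Bernoulli chromatin model, and log-normal expression tied to
binding categories. Triangular bumps are scaled so the *average* intensity
multiplier over a bump equals the configured fold, putting the mode exactly
on the truth summit (closed-form mode location for summit-error checks).
Read totals may be left implicit (Poisson, from the rates) or fixed
exactly.

Deliberately not modelled: sequence content, sequencing error, GC bias,
duplicates, fragment-size variability, overdispersion beyond Poisson
(a gamma multiplier hook exists in the design space but is off), and
diploid/copy-number structure. Passing tests on this generator show the
*computational* pipeline is correct under its stated model; they do not
show robustness to the biases of real libraries.

## Problem sizes and numerical conventions

The shipped simulations use a 2 Mb single-chromosome genome for SER calling
(10⁴ windows per phase), 100 000 bins for chromatin-state recovery, and a
reduced 0.8 Mb genome for the end-to-end determinism check — sizes chosen
so the whole suite and the acceptance script each complete in well under a
minute on one core while keeping sampling error far from the tested
margins. Degenerate inputs are handled explicitly: constant count tracks
fit with the sd floor (single decoded state), flat-zero SERs yield one
subpeak with height 0 and a warning, empty gene lists classify all summits
distal with a warning, zero-variance samples produce missing correlations,
and a zero pooled sd makes Cohen's d raise. All randomness flows from a
single root seed through hashed per-stage derived seeds; reruns are
byte-identical.
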