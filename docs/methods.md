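# Methods

## The selection program

The design universe is a tripartite graph: region nodes (candidate
regulatory sequences assayed as 171-bp oligos), motif nodes (PWMs whose
predicted occurrences in those regions are the perturbable units), and
property nodes (shared temporal/epigenomic behaviors that the final
library must represent). An instance edge (t, r) means motif t occurs
in region r; a subset of edges is flagged low-confidence. Motifs are
partitioned into TF groups — several PWMs can describe one factor — and
some groups can be hand-picked for mandatory inclusion.

Selecting instances is an ILP over binary θ_r (region chosen), θ_t
(motif chosen) and e_{t,r} (instance chosen). The objective
Σθ_r + 3·Σe counts oligos to synthesize: one wild-type construct per
region plus three perturbation designs per instance. The constraint
families bound, in order: per-property motif coverage (≥ 12),
per-property region coverage (≥ min(17, degree)), per-region motif
coverage among selected nodes (≥ min(3, degree)), per-motif region
coverage (≥ min(20, degree)), edge/endpoint consistency, a cap of two
motifs per TF group, hand-picked coverage, a 40% floor on the region
count, a cap relating total to low-confidence selected edges
(Σe ≥ 5·Σ_lowconf e), and a bias toward broadly occurring motifs
(broad ≥ 1.5 × sparse selected, broad meaning graph degree ≥ 5).

Numerical/structural choices:

* The canonical program only lower-bounds e by θ_t + θ_r − 1 and relies
  on the objective to keep e minimal; the model here adds e ≤ θ_t and
  e ≤ θ_r so that e is exactly the selected-pair indicator and
  feasibility can be verified without solver state.
* Degree caps (min(·)) are applied exactly as stated so low-degree
  nodes never make the program infeasible.
* Families whose supporting set is empty are omitted and logged: the
  property families on an empty property layer, the hand-picked family
  with no hand-picked groups, the low-confidence family when no edge is
  flagged, and the broad-bias family when no motif reaches degree 5
  (otherwise that family would forbid selecting any motif at all, which
  also matters for tiny test graphs).
* Backend: HiGHS through `scipy.optimize.milp`; the branch-and-bound is
  deterministic for a fixed model. `check_constraints` recomputes every
  family from raw edge lists and reports worst-case margins, and the
  test suite additionally compares the solver against exhaustive
  enumeration on small random graphs.
* Infeasibility is diagnosed by cumulative relaxation probing: families
  are dropped in canonical order until the program becomes feasible,
  and the first family whose removal restores feasibility is named.

## Library construction

Per region the library holds one WT oligo, one SCRAM control
(full-sequence mononucleotide shuffle, re-drawn if it reproduces the
original) and three RAND controls (one random 12-bp window — the median
motif size — perturbed once by each method, same window for all three).
Per selected instance it holds three PERT constructs.

The two non-motif replacement sequences are derived by generating
dinucleotide-frequency-matched candidates of maximal motif length,
screening each through the PWM scanner in two embeddings (prefix
between 3-bp WT flanks, and substituted into the full region), ranking
candidates by hit count within each embedding, and keeping the two with
the lowest median rank (lowest candidate index on ties). The final
oligos embed the replacement by direct in-context substitution; the
flank embedding is retained for screening only, since the synthesized
oligo is the full region.

Strand handling: for minus-strand hits the reverse complement of the
replacement prefix is substituted on the forward strand, so the
disrupted unit is always the motif-bearing strand. Method 3 re-shuffles
the window's own nucleotides, re-drawing (up to 100 times) if the
shuffle equals the original; after that it keeps the draw of maximal
Hamming distance (relevant only for near-homopolymeric windows).

Hit multiplicity follows the assay's bookkeeping: a single occurrence
is perturbed as such (hit1); an exact +/− duplicate at one site is
perturbed once on the plus strand (hit2); two distinct occurrences are
perturbed separately and jointly (hit2diff), the joint construct
representing the instance in downstream single-site analyses; three or
more occurrences discard the instance with a log entry. Double
perturbations apply both windows left-to-right; window overlap is
recorded and later excludes the pair from interaction analysis.

## The PWM scanner

A deliberately minimal stand-in for a full motif-scanning suite, used
for screening and for verifying planted hits: log-odds scoring of both
strands against a 0-order background with exact p-values from the
dynamic-programming distribution of integer-discretized scores (4096
bins). Any callable with the same signature can be plugged in. Planted
consensus hits of length ≥ 7 score below the 1e-4 threshold used
throughout (a length-6 word cannot: its best attainable tail is
0.25^6 ≈ 2.4e-4), which is why the generator's minimum motif length is
7.

## Quantification model

Size factors are upper-quartile (of nonzero counts) per library,
normalized to geometric mean one within each modality, computed once on
the full dataset and reused in every analysis.

DNA stage: gamma GLM with log link and design
`~ timepoint + replicate + barcode`, fitted per sequence (the barcode
factor is sequence-specific). With a log link and factor design the
coordinate-wise MLE for each level multiplier given the others is a
plain mean of ratios, so the fit is a short coordinate-ascent loop
rather than a generic IRLS — exact at convergence and much faster. A
pseudocount of 1 replaces zero DNA counts to keep the gamma support.

RNA stage: negative binomial GLM with log link, the DNA fits plus size
factors entering as exposure offsets. The quantification design is
`~ timepoint + replicate`; alpha per (timepoint, replicate) is the
exponentiated linear predictor. Dispersion (variance mu + φ·mu²) is
estimated per dataset by maximum likelihood given the Poisson-fit
means, initialized by method of moments and floored at 1e-8; the
coefficient fit is then redone at the estimated φ (statsmodels).
Non-converged fits fall back to a flagged ratio estimator.

Comparative analyses are LRTs between nested NB designs sharing the
full-model dispersion, referenced to chi-square with df equal to the
column-rank difference: per-timepoint (`~ sequence` vs `~ 1`), temporal
(`~ time * sequence` vs `~ time`; the reported effect is the
time-averaged log fold change, i.e. the sequence main coefficient plus
the mean of its interaction terms — the main coefficient alone is the
effect at the reference timepoint and misorders late-acting sites), and
temporal-vs-null, where a joint NB model over all SCRAM controls
provides per-timepoint coefficients that enter the RNA model as
offsets (they are transcription-side quantities, hence RNA-model
offsets). The closed-form RNA/DNA ratio uses pseudocount 1 in numerator
and denominator, per-sample median normalization, then cross-replicate
averaging. The MAD z-test normalizes by 1.4826·MAD for normal
consistency and uses the one-sided upper normal tail by default
(two-sided and per-timepoint variants by flag); BH correction is
applied within each analysis, jointly across timepoints for the
per-timepoint comparison and within timepoint for the MAD tests.

## FRS calling

Filters, per instance and method, at FDR 0.05: (1) per-timepoint
PERT-vs-WT significant at ≥ 1 timepoint; (2) temporal PERT-vs-WT
significant; (3) WT above SCRAM at *every* timepoint or PERT above
SCRAM at ≥ 1 timepoint (MAD z); (4) temporal PERT-vs-SCRAM or temporal
WT-vs-SCRAM significant. Consensus: method 3 passes all four, method 1
or 2 passes, and the sign of the temporal log fold change agrees among
passing methods (a per-timepoint majority mode is available; the single
temporal sign is the default because it is well-defined for instances
significant at different timepoints). Instances with significant
effects in both directions are labeled mixed and excluded from
sub-categorization. Duplicates — identical perturbed coordinates under
different PWMs — keep the record with the lowest temporal FDR.

Sub-categories evaluate "indistinguishable from baseline" clauses:
activating instances are *essential* when temporal PERT-vs-SCRAM is
non-significant OR the MAD PERT-vs-SCRAM test is non-significant at
every timepoint (the disjunctive reading; a conjunctive mode is a
config switch since the intended connective is not decidable from the
stated rule), else *contributing*; dampening instances are *silencing*
when the analogous WT clauses hold, else *inhibiting*. Baseline clauses
must hold for all supporting methods.

Activation dynamics: for activators active at all timepoints, OLS of
delta = WT − PERT on WT across timepoints gives (a, b, R²); the implied
fold-change curve is FC = (1 − b) − a/WT, saturating at 1 − b for
strong WT activity. (The constants are reported as fitted; re-derive
any re-parameterization from them.)

## Interaction analysis

For a {WT, P1, P2, P12} quartet the RNA model gains binary Pert1/Pert2
covariates; the full design adds their product and the LRT has one df.
γ is the product coefficient on the model's native natural-log scale.
Classification applies, in order: overlap exclusion, functionality
(≥ 1 single perturbation passes all four filters, any method),
consistency (same significant/non-significant label in method 3 and in
1-or-2, on the binary label as defined; sign consistency is a strict
mode), then additive vs interacting via |γ| > 0.5 and BH p < 0.05
(BH across pairs within a method).

## The synthetic generator

`simulate` produces every input with planted truth. The graph generator
guarantees ILP feasibility by construction (an all-selected certificate:
TF groups of ≤ 2 motifs, per-property coverage ≥ 12 motifs and
min(17, degree) regions, low-confidence edges capped at a fifth of
instance edges, ≥ 60% broad motifs); violated preconditions raise
errors naming the bound. Default densities reproduce, at a reference assay scale of 1547 regions / 4393 motifs /
68 properties, a total edge count within a few percent of ~99k.

Counts: each barcode draws a latent construct abundance once from
Gamma(shape 4, scale 25) (mean 100 reads); observed DNA per library is
a rounded gamma measurement of it with shape 100 (10% CV, the
deep-coverage regime); RNA is NB with mean α·latent·size factor and
dispersion 0.1. Tying RNA to the latent abundance rather than to the
observed DNA draw matches both the physics (transcription depends on
copy number, not on DNA read sampling) and the nested-GLM structure,
and is what makes the LRTs calibrate at their nominal level (the
observed-DNA alternative drives the tests far conservative because
offset smoothing pushes measurement noise into the dispersion).

Planted truth: wild-type activity profiles are drawn from a small
temporal basis (flat, early-peak, late-peak, transient) on a log scale
between the scrambled baseline (α = 0.5) and a peak in [2, 8]. Active
regions draw from the dynamic shapes — the assay's inclusion criterion
is temporal activity, and an exactly flat elevation is invisible to the
temporal-vs-null test by construction; the flat element is the wild
type of silenced regions. Effects per category: essential sites drop
PERT to the baseline at every timepoint; contributing sites shrink
PERT toward (never below) the baseline by a factor e^-u, u ~ U(0.7,
1.5), so the effect scales with WT activity; inhibiting sites raise
PERT by u ~ U(0.7, 1.5); silencing sites sit in baseline-pinned regions
whose PERT follows a dynamic activation profile (a flat de-repression
would, correctly, fail filter 4); null sites have identically zero
effects. Pair truth assigns half the double-perturbation pairs a
log-scale interaction γ of magnitude 0.8–1.5 with random sign.

Association reads: clean barcodes get ≥ 3 UMIs on their true construct;
a configurable ambiguous fraction gets a 50–75% majority split across
two constructs (never assignable at the 80% rule) and a shallow
fraction gets 1–2 UMIs. Every stage draws from its own RNG stream
derived from the master seed, so stages re-run independently and the
whole pipeline is byte-reproducible.

What the generator does **not** emulate: chromatin context and
integration-site effects, read-level sequencing error (association is
simulated at the UMI-table level, not FASTQ), barcode sequencing errors
(counting is exact-match by design), PCR jackpotting, and correlations
between motif content and activity. Passing tests therefore validate
the statistical machinery and bookkeeping under the stated noise model,
not performance on real libraries.

## Problem sizes and tolerances in the test suite

The suite validates calibration with 300 null simulations per LRT
(bands 3–7% around the nominal 5%), recovery on a 30-instance
planted-truth study at 50 barcodes/construct (≥ 90% direction and
sub-category agreement), pair classification on a 150-pair bank with a
50/50 additive/interacting split (≥ 85% accuracy), dynamics-fit
coverage at the nominal t(5) level, and exhaustive ILP enumeration on
graphs with ≤ 4 regions and ≤ 3 motifs. These sizes are the package's
chosen desk-scale study conditions; all are re-generated at run time
from seeds.

## Known limitations

* Dispersion is a single per-dataset value shared between nested fits;
  MPRA frameworks that shrink dispersion across sequences will differ
  in small-barcode regimes (a caveat applies when < 10 barcodes).
* The chi-square reference for the LRT is asymptotic; at very low
  barcode counts the per-timepoint test runs slightly liberal.
* The scanner is 0-order-background log-odds only — no higher-order
  backgrounds, no q-values — and is meant for screening synthetic
  constructs, not for motif discovery on genomic sequence.
* Only pairwise interactions are modeled; constructs perturbing ≥ 3
  sites are built but not tested.
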