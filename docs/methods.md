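# Methods

`fconn` implements a graph-theoretic analysis of resting-state
functional connectomes for a three-group design (healthy controls and
two psychometrically defined patient subtypes of functional
constipation, FCNAD and FCAD), together with a synthetic cohort
generator that carries the statistical structure the analysis assumes.
This note documents the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic data can and cannot
establish.

## Synthetic cohort model

Each subject's ROI signals are draws from a zero-mean multivariate
Gaussian, colored by the Cholesky factor of a group-specific target
correlation matrix, then given a constant baseline (1000 a.u.), shared
white-matter/CSF-like nuisance components, a random linear drift, and
co-occurring signal/motion spikes at 0-3 random frames per subject.
There is no temporal autocorrelation model: the downstream Pearson
correlation estimator does not require one, and white noise keeps the
sampling distribution of correlations analytically transparent. The
defaults mirror the emulated study design: 43/42/41 subjects
(HC/FCNAD/FCAD), 246 nodes in seven modules of 50/50/48/21/22/27/28
nodes, 195 usable frames at TR = 2 s.

The target matrix is block-structured: within-module correlation 0.40,
between-module 0.05. These baselines were chosen so that, at 195
frames (correlation sampling SD ~ 0.07), the within/between separation
is large enough that group occurrence graphs recover the planted
seven-module parcellation essentially deterministically, while
subject-level networks still carry realistic estimation noise.

Planted patient effects (both patient groups):

* **within-module dropout** (fraction 0.12): a seeded 12% of
  within-module pairs is reduced to the between-module baseline.
  Because proportional thresholding renormalizes any uniform shift of
  the correlation distribution, uniformly raising or lowering blocks
  cannot change binarized topology; converting within-module pairs to
  between-level is the minimal perturbation that deterministically
  removes clustered structure, lowering Cp and hence gamma and sigma.
  At the default magnitude the patient deficit in gamma/sigma AUC is
  roughly two within-group SDs — large enough for the omnibus pipeline
  to flag reliably at n ~ 40/group, small enough that the networks stay
  small-world.
* **SN-SMN block shift** (+0.10 on the salience-to-sensorimotor
  inter-module block), emulating inter-network hyperconnectivity.
* **node down-weighting** (factor 0.8 on two rACC-like and two
  thalamus-like nodes), lowering those nodes' degree/efficiency.

Planted perturbations can make the target matrix indefinite; it is
then repaired by eigenvalue clipping at 1e-6 and renormalization to
unit diagonal, with a logged warning. The repair slightly attenuates
the planted magnitudes but preserves their sign and ordering, which is
what the recovery tests rely on.

Psychometrics are drawn per group from Normal(mean, SE * sqrt(n)) with
the emulated study's per-group means and standard errors (SDS, SAS,
SAI, TAI; plus four 0-100 constipation-symptom ratings for patients),
truncated to each scale's valid range. Standard errors are converted
to SDs with the default group sizes. Gender is assigned to match the
reported per-group male/female counts exactly rather than binomially,
so the chi-square worked example is reproducible from generated data.

What the generator does **not** emulate: spatial (voxel) structure,
physiological noise spectra, scanner drift beyond a linear trend,
temporal autocorrelation, and any heterogeneity of effect across
patients. Passing tests therefore demonstrate that the pipeline
recovers what it assumes — not that the assumed structure is what real
cohorts contain.

## Temporal cleaning

Order: (1) per-node OLS against intercept, linear trend, the
Friston-24 motion expansion (6 parameters, squares, one-frame lags,
lagged squares) and WM/CSF signals; collinear columns are dropped by
pivoted QR with a warning; (2) scrub flagging at FD > 0.5 mm AND
DVARS > 0.5% (the conjunction as literally specified; an `or` rule is
available since toolboxes differ), flagging — not silently passing —
subjects losing > 5% of frames; (3) band-pass 0.01-0.08 Hz by a hard
spectral mask, with censored frames linearly interpolated before the
FFT and re-censored after. The hard mask was preferred to an IIR
filter for determinism and exact band edges; neighbor frames are not
scrubbed. FD follows the Power convention with rotations projected on
a 50 mm sphere; DVARS is the RMS frame-difference across nodes as % of
the grand mean signal.

## Networks and topology

Pearson correlations over valid frames are Fisher z-transformed (|r|
clipped at 1 - 1e-7). Proportional thresholding keeps the E =
round(s * N(N-1)/2) largest signed z values (half-away-from-zero
rounding; negative correlations compete on signed value, the common
connectome-toolbox default), with ties broken by ascending (i, j) index so
edge sets are nested across the 10-30% (step 1%) grid. Group networks
are occurrence graphs: an edge must appear in at least ceil(tau * n)
subject networks, tau in 0.50-0.70 (step 0.01); subject networks enter
at a reference sparsity of 0.20 (grid midpoint — the emulated protocol
leaves this parameter unstated).

Global measures: Cp (mean local clustering, 0 for degree < 2), Lp
(mean shortest path over pairs of the largest connected component —
the convention that keeps Lp finite on fragmented graphs), Eglob (mean
inverse distance, 1/inf = 0), Eloc (mean over nodes of the neighbor
subgraph's Eglob). Normalization uses degree-preserving double-edge
swap nulls (default 100 per graph, 10 accepted swaps per edge;
configurable — the emulated protocol does not state the null family or
count, and this assumption is recorded in output metadata): gamma =
Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda. Distances are
computed by level-synchronous BFS as dense boolean matrix products;
the swap kernel is numba-compiled. Metric curves over the grid are
summarized by the trapezoidal AUC on the literal grid values (not
rescaled by grid width).

## Modular architecture

Community detection is agglomerative greedy Q-maximization from
singleton communities (merge the connected pair with the largest
dQ = e_st - 2 a_s a_t until none is positive), with a deterministic
smallest-pair tie-break; isolated nodes end as logged singletons. The
healthy-control reference partition is computed on occurrence graphs
over the tau grid, and the reporting partition is the tau with maximal
Q. All subjects are then evaluated under the HC-derived partitions.
Within-module degree/efficiency are normalized as ratio-to-module-mean
(the named-toolbox convention); a Guimera-Amaral z-score variant is
exposed because the definition is not standardized. Intra/inter-module
connectivity defaults to binary edge density with a weighted (mean
Fisher-z) option. Because the module count can differ across taus,
inter-module connectivity is AUC-integrated over taus by module *name*
(atlas-majority naming), for pairs present at every tau.

## Inference

Metrics are residualized on age and gender (0/1) before a classical
one-way ANOVA. The seven global measures use Bonferroni 0.05/7; nodal
and modular measures use Benjamini-Hochberg FDR; brain-behavior
partial correlations (Pearson on OLS residuals; t with n-2-q df) use
the fixed a-priori families 40 (regional), 8 (inter-module) and 64
(edgewise). Post hoc contrasts are pooled-variance two-sample t-tests.
All p-values are two-sided.

The network-based statistic computes edgewise ANOVA F values (on
age/gender-residualized z by default, for consistency with the metric
pipeline), forms components above a primary threshold (default F = 12),
and assigns each component p = (b+1)/(m+1) against the permutation
distribution of the maximal component edge count under global label
shuffles (default 10,000 permutations). Component size is edge count.
One calibration caveat is worth stating: at very extreme primary
thresholds the suprathreshold graph is almost always empty under the
null, so the procedure's familywise error is far below nominal
(conservative, still valid); the calibration suite therefore evaluates
the 0.05 operating characteristic at the conventional edgewise
p < 0.01 threshold, where the max-component null is non-degenerate.

## Subtyping

Patients are clustered on z-scored SDS/SAS/SAI/TAI (min-max
normalization available; the emulated protocol says only
"normalized") by Ward linkage on Euclidean distances. k is selected
over 2-6 by majority vote of silhouette (max), Calinski-Harabasz
(max) and Davies-Bouldin (min), ties toward smaller k; dendrogram
inspection is replaced by a machine-readable linkage-height record. A
silhouette below 0.4 at the chosen k raises a weak-structure flag. The
cluster with the higher mean normalized score is named FCAD. The
partition is retested with PAM k-medoids and fuzzy C-means (fuzzifier
m = 2, defuzzified by maximal membership), both implemented in-package,
reporting adjusted Rand indices against the Ward labels.

## Problem sizes used by the test suite

The suites run the full 246-node cohort where the claim concerns the
default conditions (small-world regime: 20 cohorts, 50 nulls per
graph, full grid; planted gamma/sigma recovery: one full cohort with a
5-point integration grid and 10 nulls). Replicated calibration suites
use reduced designs chosen to keep each property estimable with
hundreds of replicates: NBS calibration on 60-node networks with
20/group and 1,000 permutations; false-positive-rate replicates on
40-node cohorts with 10/group, a 3-point grid and 6 nulls. Oracle
equivalence uses 50 random graphs of at most 30 nodes against naive
pure-Python BFS/triangle/definition oracles at 1e-12.

## Known limitations

* The generator's group effects are homogeneous within groups; no
  subject-level effect heterogeneity or site/scanner variance.
* The positive-definiteness repair attenuates planted magnitudes
  nonlinearly when effects are large.
* Greedy modularity has the usual resolution limit; it is adequate for
  the planted module scale but alternative algorithms (Louvain,
  spectral) are deliberately out of scope.
* Lp's largest-component convention makes lambda (and hence sigma)
  sensitive to fragmentation at very sparse thresholds.
* The CLI pipeline's default null/permutation counts are desk-scale;
  publication-scale analyses should raise `n_null` and `nbs_n_perm`.
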