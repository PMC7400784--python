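# Methods

`pseudomut` implements an expression-based procedure for asking whether a
breast tumor that is wild-type for *TP53* by sequencing nevertheless *behaves*
transcriptionally like a *TP53*-mutant tumor. Such tumors are called
**pseudomutants (PM)**: they are deliberate, interpreted false positives of a
classifier trained to separate sequence-verified wt from mut tumors. This
note records the model, its assumptions, the tunable parameters, and the
design choices made where the procedure was genuinely open.

## The classification model

Learning operates on a log2 expression matrix (probes × samples) and a
binary label derived from *TP53* sequencing: samples with no mutation or
synonymous-only mutations are **wt**; missense and null (nonsense,
frameshift, splice, …) mutations are both **mut**. Normal-tissue samples
carry no label and never enter learning; they serve only as the reference
for pathway scoring.

The pipeline is an iterated-split ensemble:

1. **Two-level splitting.** A 20% test set is drawn once (stratified by
   binary label within each sub-cohort) and used exactly once at the end.
   The remaining learning set is re-split 100 times into 80% training / 20%
   validation ("iterations"). Stratification by label is our choice — the
   procedure is only described as "random" in general terms — because at
   ~18% mut prevalence an unstratified 20% draw can produce degenerate
   nearly-single-class validation sets.
2. **Per-iteration probe ranking (GR).** Four rankers are provided:
   absolute Pearson correlation of probe expression with the 0/1 label;
   univariate least-squares |t| of the slope (order-equivalent to
   correlation at fixed n — retained as a distinct code path for fidelity
   and cross-checked by a test); a greedy forward-selection wrapper (FSW)
   that at each step adds the probe minimizing the refit learner's training
   error (ties: higher |r|, then lexical probe id); and orthogonal matching
   pursuit (OMP) on standardized probes against the centered label. Lists
   are capped at N = 300 probes. Zero-variance probes are dropped before
   ranking (their correlation is undefined).
3. **FDR validity gate.** Per-probe Benjamini–Hochberg FDR at q = 0.05 on
   the marginal (Pearson) p-values. A k-probe subclassifier is **valid**
   only if all k probes pass the gate on its iteration's training data. For
   the wrapper methods the gate does not restrict the candidate pool — FSW
   must be able to pick up jointly-informative, marginally-null probes —
   but every selected probe carries its flag, and classifiers using a
   non-passing probe are invalid.
4. **Learners (ML).** Linear discriminant analysis, linear SVM, and
   Gaussian-kernel SVM, each fit on features standardized by training-set
   statistics. SVM cost is fixed at 1 and the Gaussian kernel width at
   1/(k·Var) on standardized features; no per-iteration tuning is done.
   LDA falls back to a fixed shrinkage of 0.1 toward the diagonal when the
   pooled covariance is ill-conditioned. By default learning is
   **uncompensated** for the ~82% wt class imbalance: the resulting
   classifier is conservative, biased toward wt calls, which is exactly
   what makes its rare mut calls on wt samples trustworthy. Optional
   inverse-class-frequency weighting is exposed (`class_weighting`).
5. **Error curves and stopping.** For k = 1, 2, … probes (adding one at a
   time along each iteration's ranking), training and validation errors are
   averaged over the valid subclassifiers; growth stops at the last k with
   at least C_min = 70 (of 100) valid subclassifiers. SEM = sd/√n_valid;
   with a single iteration SEM is reported as 0 and flagged undefined.
6. **Model selection.** The (GL, GR, ML) combination with the lowest
   minimum mean validation error wins; k\* is the smallest k with full
   validity whose mean validation error is within one SEM of that minimum.
   This one-standard-error rule codifies the stated preference for shorter,
   more robust probe lists over marginal error improvements. Ranking
   stability is reported as the mean pairwise intersection of the top-k
   lists across iterations plus the total number of distinct probes used.
7. **Majority vote.** The master classifier is the set of valid
   subclassifiers at k\*. A sample is called mut iff mut votes strictly
   exceed half the cast votes; an exact tie is wt (conservative). On a new
   platform, subclassifiers missing any required probe abstain and are
   dropped from that sample's vote with a logged count.
8. **Pseudomutant calling.** Test-set route: wt-by-sequence test samples
   voted mut. Validation route: for each wt learning sample, over the
   iterations in which it sat in validation, it is PM iff it was called mut
   in a strict majority of those appearances (tie → not PM); a sample never
   seen in validation is reported uncallable rather than imputed (with 100
   iterations at 20% validation the expected uncallable count is ~0).
   The validation calls are taken from each iteration's k\*-probe
   subclassifier, matching the model actually selected.

Classification error is (FP+FN)/total with mut as the positive class. ROC
curves are averaged vertically over subclassifiers on a fixed 101-point FPR
grid; the reported AUC is the mean of per-subclassifier AUCs, each
subclassifier scored on its own iteration's training or validation samples.

## Pathway deregulation scores (PDS)

Each pathway is scored by a principal curve fit through all samples (tumors
and normals together) in the space of the pathway's probes, restricted to
the top 5000 most variable probes overall and standardized per probe. The
curve is fit by Hastie–Stuetzle alternation: initialize with the first
principal component, then alternate (a) projection of the points onto the
current polyline and (b) per-coordinate smoothing against the projection
order, until the mean squared projection distance changes by < 1e-4
(relative), with at most 50 iterations (non-convergence is flagged, the
last iterate returned). The smoother is a fixed-span (0.3) running
**local-linear** smoother: unlike a running mean it reproduces straight
lines exactly, so collinear data recover the PCA limit with zero residual —
a property we treat as non-negotiable for a principal-curve smoother.

A sample's PDS is its signed arc-length distance from the projection of the
normal-tissue centroid, with the curve oriented so normals sit at the low
end, negative excursions clipped to 0, and the maximum normalized to 1.
Requirements: ≥3 mapped probes per pathway (else skipped, logged) and ≥5
normal reference samples.

**Stability filter.** A pathway's score is trusted only if it survives
subsampling: PDS is recomputed on 20 random 80% subsets (normals always
retained) and the pathway is stable iff the median Spearman correlation
with the full-data PDS is ≥ `rho_min` (default 0.75, exposed in config —
the original stability threshold is not published, so this is a calibrated
package choice).

**Differential deregulation.** Per-pathway Welch two-sided t-tests between
groups with BH-FDR across pathways (q = 0.05 for PM vs wt; q = 0.1 for the
deliberately more permissive PM vs mut contrast). Member-gene follow-up
tests every probe of the significant pathways' genes the same way. Welch
(unequal-variance) tests are used throughout; the reference procedure says
only "two-sided t-tests". Heatmap display ordering uses average-linkage
hierarchical clustering with optimal leaf ordering — a replacement for the
original display-only sorting algorithm that preserves the testable
adjacency property (PM samples landing near the mut block).

## Survival and markers

Kaplan–Meier curves (product-limit, via lifelines) and two-group log-rank
tests compare overall survival of wt, mut, and PM tumors; PM overrides wt
in group assignment, and "hotspot" (recurrent-missense) membership is an
input annotation on a mut subset, since it is data, not computation.
Marker comparisons (e.g. MKI67) and mutant-p53 gain-of-function signature
fold changes are Welch t-tests on log2 expression with BH-FDR per contrast;
fold changes are reported as 2^(mean log2 difference) relative to the wt
group.

## The synthetic cohort generator

Real cohorts with matched expression + *TP53* sequencing are
access-controlled, so every stage is exercised on synthetic cohorts whose
defaults encode the study conditions of an ER+Her2− breast-cancer cohort:
1122 wt and 251 mut tumors (~82% wt), 44 planted pseudomutants among the
wt-labeled samples (~4%), 144 normals, missense:null ≈ 61:39 with a hotspot
flag on ~40% of missense. The expression model is Gaussian per probe
(means ~N(7,1), sd 1 in log2 units): mut samples are shifted by `delta`
(in probe-sd units, random sign per probe) on `n_informative` planted
probes, correlated in exchangeable blocks of 5 (ρ = 0.5) to mimic
co-regulated targets; planted PM samples are drawn from the **mut**
expression distribution but labeled wt (`pm_mix` < 1 interpolates toward
wt for sensitivity studies); normals are baseline with variance shrunk by
half. The probe→gene map gives a configurable fraction of genes two probes
(default 0.5625, reproducing a 425-probe/272-gene curated-list ratio).

Pathways are planted as probe blocks driven nonlinearly (linear /
quadratic / sigmoid mix, amplitudes 1.5–2.5) by a per-sample latent
deregulation parameter with group means 0 (normal) < 0.5 (wt) < 1.5 (mut)
≤ 2.0 (PM) and sd 0.3 — so the qualitative finding that PM tumors are the
most deregulated is a plantable, testable property. Noise pathways
(latent-free) are included to exercise the stability filter. Survival is
exponential per group (PM shares the mut hazard; default wt median 10
years, hazard ratio 2) with independent exponential censoring.

The generator does **not** emulate platform artifacts (bead-level effects,
RNA-seq counts), probe-specific variances, subtype structure beyond the
single analyzed subtype, or correlated censoring; passing tests therefore
demonstrate correctness of the machinery and its statistical behavior
under the assumed model, not performance on real cohorts. Cross-platform
application is modeled abstractly by deleting probes (voters abstain).

All randomness flows from one top-level seed through
`numpy.random.SeedSequence` spawning (seed → split plan → per-iteration
streams → generator sections), so models, calls and files are bit-identical
across reruns with the same config and seed.

## Problem sizes used in the test and acceptance runs

Simulation-based checks run at desk scale, chosen so each property is
measured with adequate replication while the whole suite stays quick:
cohorts of 150–375 tumors with 200–500 probes and 20–30 planted informative
probes; 10–25 iterations with C_min scaled proportionally (e.g. 18/25
mirrors 70/100); 10–25 replicate cohorts for stochastic bounds; 300–1000
replicates for test-calibration checks. The conservatism check uses ~82% wt
prevalence with delta = 1 (moderate signal, so both error types are
populated); pseudomutant recovery uses delta = 2 (the strong-signal regime
in which recall ≥ 0.8 / precision ≥ 0.5 is the expected behavior).

## Known limitations

* The forward-selection wrapper is myopic: it finds jointly-informative
  probe pairs (XOR-like structure) only after one member enters the
  selected set, so its advantage over marginal ranking is probabilistic,
  not guaranteed.
* The FSW inner objective is training error (validation data are reserved
  for model selection); a validation-scored wrapper would be less prone to
  overfitting but would leak selection information.
* The one-standard-error rule can select very small k\* when the planted
  signal is strong and concentrated; this is by design (shorter lists are
  more stable) but means error curves should be inspected when comparing
  configurations.
* PDS values are comparable within a pathway, not across pathways (each is
  normalized by its own maximum).
* With heavy class imbalance and weak signal the conservative ensemble can
  degenerate to the majority classifier; the validity gate then usually
  reports failure (too few valid subclassifiers) rather than returning a
  vacuous model, but at intermediate signal the FN rate should always be
  checked against the FP rate.
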