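# Methods

## Model

The classifier is Bayesian logistic regression whose coefficients carry a
multivariate Laplace prior expressed as a Gaussian scale mixture.  Each
coefficient $\beta_i$ (one per channel × time-sample feature) has a pair of
latent Gaussian scale variables $(u_i, v_i)$:

- $\beta_i \mid u_i, v_i \sim \mathcal N(0, u_i^2 + v_i^2)$;
- $u$ and $v$ are independent draws from $\mathcal N(0, J^{-1})$;
- the bias $b$ has a broad $\mathcal N(0, 100)$ prior (unpenalized in
  spirit; the prior SD of 10 far exceeds any plausible intercept on
  standardized features).

The precision matrix is built as $J_0 = \lambda I + c\,L$, with $L$ the
graph Laplacian of the declared neighbour pairs, then symmetrically scaled
to unit diagonal.  Consequences of this construction worth knowing:

- at $c = 0$, $J = I$ exactly, so $u_i^2 + v_i^2$ is Exp(mean 2) and each
  $\beta_i$ has an iid standard Laplace marginal — the classic sparse
  prior;
- for $c > 0$ the *marginal* prior variance of the auxiliaries is
  position-dependent (diag of $J^{-1}$ grows toward ~10 in chain
  interiors and ~17 near chain ends at $c=100$).  Raw auxiliary
  variances therefore carry a graph-position baseline; importance maps
  default to the ratio posterior/prior variance, which removes it.  The
  raw variances remain available (`PosteriorFit.aux_variance`).

Default hyperparameters: coupling $c = 100$ between consecutive time
samples within each channel, regularization $\lambda = 1$.  Channel
coupling (index-adjacent channels) and cross-dataset coupling (the same
feature across datasets, used by transfer learning) are expressible
through the same `CouplingSpec`.

## Inference

Posterior inference is parallel expectation propagation (EP) with damping
(default 0.5):

- each likelihood factor $\sigma(t_n a_n)$, $a_n = x_n^\top\beta + b$, is a
  Gaussian site on the scalar activation, moment-matched by 41-node
  Gauss–Hermite quadrature;
- each scale-mixture factor $\mathcal N(\beta_i; 0, u_i^2+v_i^2)$ is a
  Gaussian site on $\beta_i$ plus a zero-mean precision contribution on
  $(u_i, v_i)$.  Because the $u$ and $v$ branches are exchangeable and are
  updated identically, their cavities share one variance $A$, making
  $s^2 = u_i^2 + v_i^2$ exponentially distributed under the cavity; the
  tilted moments then reduce to 32-node Gauss–Laguerre integrals.  The
  tilted mean of $u_i^2$ is $\mathbb E[s^2]/2$ by angular symmetry.

Numerical choices (all chosen for robustness, none data-dependent):

- the posterior over $(\beta, b)$ is recovered each sweep through
  subtraction-free Woodbury identities
  ($X\Sigma X^\top = S(I + \Lambda S)^{-1}$, cost $O(n^2 p)$), because the
  naive difference form cancels catastrophically once sites are strong;
- cavity precisions are floored at $10^{-6}$, likelihood-site precisions
  at 0 (valid: the logistic is log-concave), scale-site precisions on the
  auxiliaries at 0 so $J + \Omega$ stays positive definite.  The floor on
  auxiliary sites caps each posterior auxiliary variance at its prior
  value; importance is a relative measure, so rankings are unaffected;
- auxiliary-variable variances, diag$((J+\Omega)^{-1})$, are computed
  densely per connected component of the coupling graph (temporal chains,
  or chains linked across datasets);
- convergence: largest undamped site-parameter residual < 1e-4, at most
  200 sweeps.  Null-like data and weak coupling converge in 20–70 sweeps.
  Strongly coupled fits ($c=100$) on high-SNR data can settle into a
  small residual plateau (~1e-2) — a known behaviour of parallel EP on
  strongly coupled graphs; the fit is then returned with
  `converged=False` and remains bit-for-bit deterministic, and the
  plateau does not measurably affect accuracies or importance rankings in
  the test conditions;
- prediction integrates the logistic over the Gaussian posterior of the
  activation by Gauss–Hermite quadrature; a degenerate zero-variance
  posterior at $\beta=0, b=0$ yields exactly 0.5, and ties at 0.5 predict
  class 0 (fixed, arbitrary).

EP accuracy was validated against MCMC: on toys with ≤ 5 features and
≤ 40 trials the posterior means agree with emcee sampling of (a) the
analytically marginalized Laplace prior at $c=0$ and (b) the full
$(\beta,u,v)$ hierarchy at $c>0$, within 0.05 absolute
(`tests/test_acceptance.py`).

## Preprocessing

- Band-pass: zero-phase (forward–backward) 4th-order Butterworth, default
  1–30 Hz.  Note that a 1 Hz high-pass edge has an impulse response
  comparable to a 1-s epoch, so *per-epoch* filtering is approximate near
  the epoch edges; the filter/epoch commutation test uses a 5 Hz edge and
  a 10% tolerance on the central half of the epoch, and the real-data path
  should filter continuous recordings before epoching.
- Epoching: half-open windows, sample timestamps at 0, 2, …, 698 ms for a
  (−300, 700) ms window at 500 Hz; events whose window leaves the
  recording are skipped with a warning.
- Artifact rejection: a trial is removed iff its within-epoch per-channel
  peak-to-peak range exceeds the threshold (default 150 µV) on any
  channel — the standard per-trial reading of "voltage variations".
- Standardization: per-feature z-scoring with statistics from training
  trials only, re-applied to held-out trials.  This leakage-safe contract
  is a deliberate choice; pooling statistics across all trials would be
  marginally more favourable to the classifier but risks optimistic bias.
- Features: channel-major, time-minor flattening of the analysis interval
  (default 0–700 ms → 60 × 350 = 21 000 features at full scale); the
  `FeatureIndex` bijection is the single source of truth for the layout.

## Analyses

- **Cross-validation**: stratified 5-fold (scikit-learn), folds fixed per
  dataset and seed (shared across sliding windows); reported accuracy is
  the mean over folds, the binomial test pools all tested trials.
- **Sliding window**: independent full CV per 40-ms window, 16 windows
  from 0 to 640 ms by default; per-window importance maps are averaged
  over folds.
- **Unseen exemplar**: train on all exemplars but one, test on the
  held-out exemplar's trials.  Holding one exemplar out leaves training
  asymmetric (3 vs 4 exemplars); with strong exemplar-specific structure
  this measurably *anti-predicts* the held-out category, because the
  held-out trials carry none of the learned signatures and the asymmetric
  margin geometry places them off-centre.  Training is therefore
  balanced by default: one randomly chosen exemplar of the
  over-represented category is dropped and trial counts equalized
  (deterministic given a seed).
- **Transfer learning**: one joint EP fit per fold over all datasets —
  block-diagonal design matrix (each dataset keeps its own coefficients),
  auxiliary variables of corresponding features coupled across datasets
  with the same strength $c$; folds are stratified per dataset with a
  shared seed and aligned by fold index.  Per-dataset accuracies come
  from the joint fit's predictions; the joint importance map averages the
  per-dataset relative auxiliary variances.
- **Significance**: exact one-sided binomial tail
  $P[\mathrm{Bin}(n, p_0) \ge k]$ with $p_0$ the majority-class fraction
  of the tested trials; Bonferroni division by the number of comparisons
  (subjects, in the original design; windows are not additionally
  corrected).

## Synthetic data

The generator emulates a repeated-exemplar two-category ERP session:
60 channels, 500 Hz, 1-s epochs from −300 ms, 2 categories × 4 exemplars
× 80 repetitions by default.  Each trial is the sum of

1. a class-independent ERP background — three half-sine components with
   P1/N1/late-wave latencies (70–150, 110–220, 280–550 ms) and smooth
   random per-dataset topographies, scaled by
   `erp_background_amplitude` (default 6 µV);
2. optional **category-general** effects: half-sine bumps on declared
   channels/windows added at ±amplitude/2 to the two categories, so the
   class-mean difference at the bump peak equals the stated amplitude and
   the ground-truth mask marks exactly these cells;
3. optional **exemplar-specific** effects: per-exemplar signatures over
   the (channel × 3-lobe) coefficient space of the window, drawn
   *mutually orthogonal* (QR of a Gaussian matrix) so exemplars are
   individually recognizable while carrying, by construction, no
   category-general structure;
4. noise: per-channel AR(1) (default coefficient 0.9, marginal SD 8 µV)
   with optional neighbour averaging across channel indices for spatial
   correlation;
5. optional transient artifacts: floor(rate × trials) random trials get a
   half-sine deflection (default 200 µV) on one random channel, flagged
   in metadata.

All randomness flows from one master seed; per-trial noise streams are
spawned from it, so subsetting trials is reproducible.  What the
generator does **not** emulate: volume-conducted dipolar topographies,
eyeblink/EMG morphology, line noise, inter-subject variability, and any
genuine overlap between category- and exemplar-level codes.  Passing
tests on this generator therefore demonstrates correctness of the
pipeline's statistics and bookkeeping, not performance claims about real
EEG.

Effect sizes are free parameters (the underlying study reports no
per-condition SNR).  Defaults used by the test conditions were fixed
once: "moderate" category effects of 2–5 µV against 8 µV noise give CV
accuracies of 0.6–0.9 on reduced grids; the parameter-recovery condition
calibrates amplitude (3.5 µV over 4 channels × 60 ms on a 10 × 50 grid)
so CV accuracy lands near 0.8.  Spatially uncorrelated noise is used in
localization conditions because spatially mixed noise lets the classifier
exploit off-effect channels, which genuinely (not spuriously) delocalizes
the discriminative pattern.

## Problem sizes

Tests and the acceptance script run on reduced grids — 3–10 channels,
25–350 time samples, 80–640 trials — chosen so the full suite completes
on a single CPU while preserving the study's design structure (balanced
2 × 4 exemplar layout, 5-fold stratification, 16 windows, three-session
transfer).  The generator and all analyses run unchanged at the full
60 × 500 scale.

## Known limitations

- Parallel EP at $c = 100$ on high-SNR data may not reach the 1e-4
  residual tolerance (see above); results are deterministic and flagged.
- The auxiliary-site positivity floor caps posterior auxiliary variances
  at their prior values, compressing (not reordering) the top of the
  importance scale.
- Per-epoch band-pass filtering with a 1 Hz edge is approximate; filter
  continuous data when available.
- BrainVision input covers the common dialect (multiplexed INT_16 /
  IEEE_FLOAT_32) via MNE; other layouts are rejected with an explicit
  error.
- The binomial test treats trials as independent; repeated exemplars
  violate this mildly, which is precisely why the unseen-exemplar
  analysis exists.
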