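# Methods

## The measurement model

Each probing site of a full dentition is treated as an ordinal item
responding to one latent trait θ, the subject's overall periodontal
severity. For CAL and PD the readings (integer mm; periodontal probes read
in whole-millimetre steps) are categorized `<4`, `4–5`, `>5` mm — the
default `CategorizationConfig(4, 5)`; a wider middle band `4–6`/`>6` is
available as `CategorizationConfig(4, 6)` because both conventions occur
in the literature for this protocol. BOP is dichotomous. The 0–3 plaque
and mobility scales are collapsed to three ordered levels (0, 1, ≥2) so
that every polytomous item carries exactly two extremity parameters.

The graded response model uses logistic boundary curves
`P*_jk(θ) = expit(a_j (θ − b_jk))` **without** the historical 1.7 scaling
constant. This choice is substantive, not cosmetic: with the raw logistic,
a dichotomous item's Fisher-information integral over the latent axis
equals its discrimination (`∫ a² P*(1−P*) dθ = a (P*(hi) − P*(lo)) ≈ a`),
which is the identity that makes per-item "information" values directly
comparable to discriminations in the reference parameter tables.

## Estimation

Marginal maximum likelihood with a fixed standard-normal latent prior
(this identifies the latent scale; nothing else pins down location/scale).
The marginal likelihood is evaluated on a fixed grid of 61 equally spaced
nodes on [−6, 6] with normalized normal-density weights. For smooth
Gaussian-like integrands an equally spaced trapezoid-type rule converges
spectrally, so 61 nodes are ample; EAP scores computed on this grid agree
with a 10⁴-node oracle to well below 1e−3.

EM alternates:

* **E-step** — each subject's posterior over the grid nodes; missing
  responses (absent teeth) simply drop out of the likelihood product
  (missing-at-random).
* **M-step** — one joint L-BFGS pass over all item parameters. The
  expected complete-data log-likelihood separates over items, so the
  gradient is assembled block-wise; thresholds are kept strictly ordered
  through the reparameterization `(log a, b₁, log(b₂−b₁), …)`. The pass is
  warm-started from the current parameters and capped (30 inner
  iterations), i.e. a *generalized* EM step: any increase of the expected
  log-likelihood increases the marginal likelihood, so the monotonicity
  guarantee survives while 168-item fits stay fast.

Start values: `a = 1`, thresholds at standard-normal quantiles of the
observed cumulative category frequencies. Convergence is declared when the
marginal log-likelihood improves by less than `tol` (default 1e−4);
hitting `max_iter` (default 200) flags `converged_ = False` without
raising. The EM is deterministic given data and start values;
`random_state` exists for API symmetry and cloning.

An item with an *empty* response category is inestimable (its threshold
diverges), so `fit` raises a category-collapse error; pipelines first call
`OrdinalResponseMatrix.collapse_sparse_categories()`, which renumbers each
item's observed categories contiguously (recording a monotone old→new map)
and drops items with fewer than two observed levels. The selection chain
logs both actions in its audit trail.

Information integrals use a separate dense grid: 2001-point trapezoid on
[−10, 10]. The wide range matters for steep items whose information mass
is concentrated; the printed reference values for very steep dichotomous
items (discriminations ≈ 7.7 and 17) are known to carry numerical error of
the original software and are not treated as checks of this integral.

## Site reduction

Four stages, each a fresh fit on the surviving sites (parameters are never
carried over):

1. **Model 1** — all 168 unilateral sites.
2. **Model 2** — per tooth type (jaw × position from midline; 14 types)
   keep the (surface, position) slot with the highest left+right
   information sum → 28 sites. Ties break toward higher summed
   discrimination, then lingual before buccal, then mesial < central <
   distal — an explicit deterministic rule because information sums can
   tie on symmetric data.
3. **Model 3** — rank tooth types by bilateral information sum in the
   28-site refit; keep the top k (default 6) → 12 sites. "Top-k by
   information" operationalizes a published procedure that states no
   numeric threshold; k is exposed.
4. **Model 4** — merge each mirrored pair by the worst-of rule
   (`merge_bilateral` = maximum category, missing side ignored) → 6
   variables.

Molar exclusion (`exclude_molars`) restricts the starting universe to FDI
positions 1–5; the default keeps all 28 teeth and lets information decide.

Ability is the EAP posterior mean. `score_table` enumerates every complete
response pattern of the final model (3⁶ = 729 for a six-variable graded
protocol) with its ability and aggregates by raw sum score — the printed
quick-reference an examiner can use in the field. Pattern abilities are
strictly monotone under single-category increases, verified exhaustively.

## Evaluation conventions

* **ROC** — curve over all distinct score thresholds; AUC by trapezoid
  (identical to the tie-corrected concordant-pair statistic). The
  operating point minimizes |sensitivity − specificity|, ties toward
  higher sensitivity.
* **GLM** — candidates Gaussian-identity, Gaussian-log, Gamma-log,
  Gamma-inverse; minimum AIC wins. Log/inverse links and the Gamma family
  require positive responses and are skipped otherwise.
* **CDC-AAP** — severe: ≥2 interproximal sites with CAL ≥ 6 mm on
  different teeth *and* ≥1 interproximal site with PD ≥ 5 mm; moderate:
  ≥2 interproximal sites with CAL ≥ 4 mm on different teeth *or* ≥2
  interproximal PD ≥ 5 mm on different teeth. Thresholds follow the
  surveillance case definitions these criteria cite.
* **CPI** — per-person maximum of site codes 4 (PD ≥ 6 mm), 3 (PD 4–5 mm),
  1 (BOP), 0, over the ten classic index teeth by default. No calculus is
  charted, so code 2 is unreachable; the comparator is labelled
  "CPI (PD+BOP)" and retains its ranking use.
* **Partial-exam metrics** — a case has ≥1 site with CAL > 4 mm (strict
  inequality; `"ge"` available). Relative biases are ratios of pooled
  cohort means (partial vs full), the convention under which tiny biases
  like −0.0035 are interpretable; a per-subject-mean variant sits behind
  `per_subject=True`. The extent threshold is CAL ≥ 4 mm.

## The synthetic cohort generator

No patient-level dataset is deposited for this protocol family, so the
generator emulates the study population: treated chronic-periodontitis
patients, ≥ 20 teeth each. One latent trait drives all five parameters —
the unidimensionality the measurement model assumes.

Per subject: θ ~ N(0,1); 0–8 teeth are removed (Binomial(8, 0.22), molars
weighted 3×), never violating the 20-teeth floor. Per site: the CAL
severity category is drawn from that site's graded model; integer-mm CAL
is emitted per category (cat 0 → {1,2,3} mm, cat 1 → {4,5} mm, cat 2 → 6 +
capped-geometric heavy tail); PD = CAL − recession with recession ~
Poisson(0.8) truncated to [0, CAL−1] — this guarantees PD ≤ CAL and the
observed mean ordering PD < CAL; BOP ~ Bernoulli(expit(0.8 θ − 2.22 + 0.8
· 1[PD ≥ 4])); plaque and mobility follow cumulative-logit models sharing
θ (mobility drawn at tooth level and replicated across the tooth's six
sites). All draws flow through one seeded generator in a fixed order, so
cohorts are bit-reproducible; measurements for teeth later marked missing
are drawn and discarded to keep the stream independent of the missingness
pattern.

The `"paper-2020"` preset plants the published final-model CAL parameters
at the twelve winner sites and gives every other site a low,
deterministically varying discrimination (0.9–1.6) with thresholds solved
(by root-finding on the prior-marginal boundary probability) so its
category mix matches the cohort calibration: P(cat ≥ 1) = 0.34,
P(cat ≥ 2) = 0.10. Together with the emission tables this centres the four
published descriptives — mean CAL 3.1 mm, mean PD 2.5 mm, BOP 15.0%, PlI
0.3 — at n = 254 (measured across seeds: mean CAL 3.09 ± 0.06, BOP
14.9 ± 1.0%). The BOP slope was set so that cohort-level BOP% sampling
spread at n = 254 stays within the preset's ±2-point design band; the
deep-pocket bonus couples bleeding to pocketing as seen clinically.
Profiles are mirror-symmetric by default; an `asymmetry` knob scales
left-side discriminations to stress the bilateral merge rule.

What the generator does **not** emulate: site-level spatial correlation
beyond the shared trait (neighbouring sites are conditionally
independent), examiner measurement error and calibration drift,
covariates (age, smoking), longitudinal change, and calculus. Passing
tests therefore demonstrate correctness of the machinery under the
model's own assumptions and the stated marginal calibration — not
robustness to violations of unidimensionality in real mouths.

## Problem sizes used in the test suite

Estimator checks run at n = 200–2000 subjects (parameter recovery bounds:
mean absolute error < 0.4 on discriminations and < 0.15 on thresholds at
n = 2000 for the six-item reference configuration). Selection-recall runs
20 replicate cohorts of n = 500 through the full 168 → 28 → 12 → 6 chain
and requires the planted twelve sites to be recovered exactly in ≥ 80% of
replicates. Pipeline-level structural tests use a 60-subject cohort with a
relaxed EM tolerance (1e−3), which leaves selection decisions unchanged.

## Known limitations

* The EM targets the grid-approximated marginal likelihood; extremely
  steep items (a ≳ 10) make the likelihood nearly flat in `a` above a
  point and estimates of such discriminations are unstable (the
  information *integrals* remain stable, which is what selection uses).
* At n ≈ 254 the sampling error of per-item information integrals is on
  the order of ±1, so items whose true informations differ by less than
  ~0.5 are not reliably ordered; selection of *sets* (best slot per tooth,
  top-k types) is much more stable than full rankings.
* The two-parameter-per-item structure requires three observed categories;
  heavily diseased or fully healthy cohorts degrade items to fewer
  categories, which the pipeline handles by collapsing but which reduces
  information.
* `InformationSiteSelector.transform` scores new charts with the category
  maps learned at fit time; a new cohort exhibiting categories unseen
  during fitting has them folded into the nearest seen level.
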