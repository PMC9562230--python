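# Methods

## Model

Perceived quality is modelled as a power law over dimensionless groups.
Each of five flavour modulators M₁…M₅ (fruity, herbal, floral, woody,
other) contributes one Pi-term πᵢ, a ratio of expressions over its three
member concentrations whose numerator and denominator carry the same total
degree. Because all members of a modulator share one unit (μg/L), degree
balance makes πᵢ dimensionless and therefore invariant under a common
rescaling of its inputs — the property the validator enforces and the
property tests exercise at scale factors 0.1–1000.

The quality proxy is

    QP = k · π₁^{n₁} π₂^{n₂} π₃^{n₃} π₄^{n₄} π₅^{n₅},   n_{i+1} = α·nᵢ,

so the exponent vector is (n, αn, α²n, α³n, α⁴n) and the model has three
free parameters (α, n, k). Candidates are scored by the Euclidean distance
between the per-wine proxy vector and the per-wine panel quality vector,
both on the 10-point rating scale. k is unity by default; an optional
calibrated mode replaces it per grid cell with the least-squares rescaling
k\* = ⟨QP, q⟩/⟨QP, QP⟩, which is the distance-minimising k for that cell.

The two-group physiochemical variant ties α = n, giving
QP = k·π₁ⁿ·π₂^{n²} over group 1 (total sulphur, total phenolics,
titratable acidity — acidity rescaled from g/L to mg/L so the group shares
one unit) and group 2 (sugar, ethanol, pH). Group 2's variables do not
share a unit; the group is formed on the raw values as a modelling
convention, not a dimensional argument, and is flagged as such here.

## Pi-form enumeration

Two families are enumerated over k variables: additive forms (xᵢ+xⱼ)/xₗ
and xₗ/(xᵢ+xⱼ) with the denominator/numerator outside the pair, and
monomial ratios with disjoint variable support and equal total degree up
to `max_degree` (default 2, which covers every prototype the model uses;
higher degrees are available but config-gated to bound the search space).
At three variables and degree ≤ 2 this yields 6 additive and 18 monomial
forms. The degree-2/1 monomial x₁x₃/x₂ is *not* admissible — its
canonical balanced counterpart is x₁x₃/x₂² — and the validator rejects it;
tests pin this. Mixed forms with sums on both sides are excluded: none are
needed and they add no expressive power at degree 1. Enumeration counts
are cross-checked in the tests against an independent brute-force index
enumeration.

## Modulator membership

Membership is data, not code: a mapping from modulator label to an ordered
member list. The default layout follows the published membership, in which
eugenol appears in both the woody and the other group. The published
"other" group lists only two compounds while the construction wants three
variables per group; the default configuration adds guaiacol as a
configurable third member, and a two-member group (contributing a
two-variable form) can be allowed explicitly instead.

Selection scores each compound at its maximum concentration across wines:
a compound is aroma-active when its OAV can exceed 1 somewhere in the
sample set. Scoring at the mean would mis-handle compounds, such as
linalool, whose log-uniform range straddles the threshold: their mean OAV
sits below 1 even though several wines are clearly above it. The OAV
threshold is strict (> 1); ties are excluded.

## Synthetic data

The generator emulates the statistical shape of an 18-wine study, not any
particular wine:

- **Chemistry.** Log-uniform concentrations within per-compound ranges.
  Published ranges are used verbatim where they exist (the three ethyl
  esters share their published group range 18.5–874 μg/L with the group
  ODT collapsed to its lower bound 2 μg/L — the most conservative
  detection assumption; β-damascenone 0.2–102 at ODT 0.05;
  2-phenylethan-1-ol 236–158,473 at ODT 10,000; linalool 0.83–170 at ODT
  25). Eugenol and guaiacol concentrations are reconstructed from their
  published OAV span (0.32–14.4) at ODT 5. The remaining compounds carry
  documented oenological defaults, flagged `source="default"` in
  `CompoundSpec`, chosen so the herbal alcohols typically clear OAV 1 and
  the three override compounds typically do not. Log-uniform sampling is a
  deliberate choice: several ranges span three orders of magnitude, and
  uniform sampling would make the low decades vanishingly rare.
- **Physiochemistry.** Uniform within documented default ranges (pH
  3.3–3.9, ethanol 12.5–14.5 % v/v, etc.); the ranges are configuration,
  not measured values.
- **Sensory.** rating = grand mean (5.5) + wine effect (sd 0.6) +
  panelist effect (sd 0.5) + noise (sd 1.0), clamped to [1, 10]; perceived
  quality is the per-wine mean over 22 panelists. The additive-Gaussian
  form is a stand-in — real panel data were only ever summarised by a
  mixed model — but its spread (per-wine means with sd ≈ 0.64) matches
  what 10-point professional panels produce.
- **Model-consistent studies.** Chemistry as above; quality = QP(α, n, k)
  evaluated on that chemistry, plus optional Gaussian noise. With zero
  noise the quality column *is* the proxy, exactly, which is what the
  recovery experiments require; consequently no [1, 10] clamp is applied
  in this mode (a clamp would destroy the identity).

What passing tests on these data do **not** show: that the proxy fits real
wines, that the default compound ranges match any particular vineyard, or
that the recovered (α, n) for real data would equal the synthetic truth.
They show the machinery is correct: the search finds a truth that is
there, and the networks can learn a quality signal that is actually a
function of the features.

### Calibrated truth for end-to-end runs

The end-to-end network experiments need a truth whose quality column looks
like panel data. `calibrated_truth()` fixes α = 0.8 (the leading published
combination) and chooses n and k once, from the generator's own
distribution: n is set so sd(log QP) ≈ target sd / target median (0.6/5.5
rating units — real 18-wine panels spread with sd ≈ 0.56), and k centres
the median at 5.5. With the default forms this gives n ≈ 0.041,
k ≈ 3.70. The calibration sample is internal and seeded, so the truth is
deterministic. Under a truth with n = 1 the proxy spans orders of
magnitude — valid for recovery experiments, where scale is irrelevant, but
not rating-like.

## Grid search

Default grids: α ∈ {0.50, 0.51, …, 1.20}, n ∈ {0.50, 0.52, …, 1.50}
(inclusive; 71 × 51 = 3621 cells), covering every published (α, n)
combination. Every cell is evaluated exhaustively; ties break
lexicographically by (α, n) so rankings are reproducible. Each cell's
weight vector and proxy are computed with exactly the arithmetic of
`exponent_schedule` and `quality_proxy` (per-cell vector products rather
than one large matrix product), so a cell that reproduces the generating
parameters of a noiseless model-consistent study scores a distance of
exactly zero rather than accumulated float noise — the recovery tests
assert ≤ 1e-9. Under quality noise of sd 0.1 the minimiser typically moves
to a cell adjacent to the truth (one grid step: Δα = 0.01, Δn = 0.02);
across 20 seeds all recoveries land within one step.

## Augmentation

The 18-wine table is split 12/6 by a seeded permutation. Each synthetic
row starts from a uniformly drawn source row x, picks one of its k = 5
nearest neighbours x_k (Euclidean distance in z-scored feature space, so
μg/L-scale compounds do not drown pH-scale features), draws one gap
g ~ U(0, 1), and applies x′ = x + g·|x − x_k| coordinate-wise — quality
included, with the same gap. One gap per row keeps synthetic points on the
ray through x. The default formula is the one-sided absolute-difference
variant, which can only move coordinates upward from the seed; the
canonical signed interpolation x′ = x + g·(x_k − x) is available as
`standard-signed` since the one-sided variant deviates from standard
SMOTE. The dummy-class construction (append 1000 all-zero rows as a
majority class, oversample the 12-row minority, then drop the class
column, the zero rows, and the originals) is implemented literally and is
element-wise identical to the direct route under shared draws; the output
is exactly the 1000 synthetic rows — original wines are never in the
training pool. Holdout rows touch neither the interpolation nor any
normalisation statistic.

## Networks

The three presets are taken as given (hidden stacks 64R/64E/32E/16E with
RMSprop; 64R/64R/64R/8R and 128R/128E/64E/64E with Adam; single linear
output; MAE loss; 2000-epoch cap). Implementation is plain numpy — dense
layers, reverse-mode gradients, Adam and RMSprop with conventional
defaults (lr 1e-3, β₁ 0.9, β₂ 0.999 / ρ 0.9, ε 1e-8), batch size 32 —
single-threaded and bit-reproducible from one seed (initialisation,
shuffling, validation split). Early stopping monitors MAE on a 10 %
validation split of the training rows, patience 50, restoring the
best-epoch weights; with no validation rows it monitors training MAE.
The MAE subgradient uses sign(pred − y); at exact zero residual the
subgradient is taken as 0. He-scaled normal initialisation suits the
rectifier-family hidden units. The printed architectures expect 14 input
features; the default synthetic chemistry has 13 unique compound columns
(one compound is shared between two modulators in the published
membership), so `preset_spec` accepts an `input_dim` override and the
end-to-end runs use 13.

Problem sizes for the end-to-end validation: 18 wines, 1000 synthetic
training rows, three seeds per preset. Typical runs stop after 100–500
epochs and reach test MAE ≈ 0.15–0.45 rating units over all 18 wines; the
6 wines never seen by the augmentation are harder (their features lie
outside the interpolation's support) and dominate the error.

## Numerical choices

- Products of powers are evaluated in the log domain and exponentiated
  (relative error ≤ 1e-12 against the direct product on well-scaled
  inputs, asserted by a test oracle).
- Pi evaluation rejects zero or negative inputs rather than smoothing;
  under the positive-concentration precondition division by zero cannot
  occur.
- Constant feature columns z-score to zero with a warning.
- CSV round-trips preserve values to 1e-12 (pandas full-precision float
  formatting).

## Limitations

- All empirical statements above are about synthetic data; the study's
  measured tables are available only on request from its authors, so no
  claim is made that the published proxy columns or test MAEs are
  reproduced here.
- The exponent schedule explores only geometric weight decay; modulator
  order therefore matters (π₁ always carries the largest weight).
- The grid search takes one Pi-form choice per modulator as an argument
  (`grid_search_over_forms` can sweep assignments); which form the
  original study used per modulator is unknown.
- Group 2 of the physiochemical case study is not dimensionless in a
  strict unit sense (see above).
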