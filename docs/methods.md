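# Model and methods

`stroopsom` simulates the Stroop color-naming task with a pair of
laterally connected self-organizing maps (SOMs) joined by Hebbian
associative connections. This note documents the model, its parameters,
the numerical choices made where the design was genuinely open, and what
the synthetic stimulus set does and does not capture.

## The laterally connected map

Each map is a `rows × cols` grid of units (default 20×20), unit *i*
carrying a feature vector *u<sub>i</sub>*. Presenting an input *c* sets
the initial activation

> a₀,ᵢ = scale · softmax(−‖uᵢ − c‖² / (C_m · T)),

where C_m is the median pairwise Euclidean distance of the input set
(so the exponent is dimensionless across feature spaces) and T is a
temperature: smaller T focuses the initial activation more sharply on
units similar to the input. The semantic map uses T = 0.7, the lexical
map T = 0.5.

Activation then *settles* in discrete steps through lateral connections:

> a_{t+1,i} = max(0, α a_{t,i} + β Σ_j a_{t,j} (w⁺_{ij} − w⁻_{ij})),

with persistence α = 0.8 and lateral gain β = 0.1. Excitatory weights
w⁺ follow a Gaussian of grid distance (standard deviation σ, in grid
units); inhibitory weights w⁻ are uniform over all other units. Both
outgoing weight sets are row-normalized to sum to one. Short-range
excitation plus long-range inhibition gradually concentrates activation;
the clamp at zero keeps the pattern a valid (nonnegative) measure for
the likelihood readout. Because every term is positively homogeneous,
the overall activation scale is a bookkeeping convention, not a degree
of freedom of the dynamics.

**Readout.** Units are partitioned into Voronoi cells M_c (each unit
belongs to the nearest training input; ties to the lowest input index).
The likelihood of input *c* at time *t* is L(c,t) = Σ_{i∈M_c} a_{t,i},
normalized over inputs; the Shannon entropy E_t of this distribution
(bits) measures the map's uncertainty. The map responds with the
maximum-likelihood input once E_t < 1 bit. An all-zero activation has an
undefined distribution and is treated as maximally uncertain, so a map
receiving no input cannot respond spuriously. The number of settle steps
to response is the model's response time (RT).

## Training

Maps train for 1000 epochs; each epoch presents every input once in
seeded-random order. Per presentation: initial activation, 30 settle
steps, then every unit moves toward the input in proportion to its
settled activation,

> uᵢ′ = (1 − η aᵢ) uᵢ + η aᵢ c.

η decays exponentially from 0.2 to 0.05 across epochs and σ from 2.0 to
0.25 (log-space interpolation; endpoints exact). Two numerical choices
required decisions the formulas above do not fix:

- **Activation scale in the learning rule.** Under the settling dynamics
  the total activation mass decays roughly like α^30 ≈ 10⁻³ during the
  30 training steps. Used raw, the per-unit learning rate η·aᵢ is then
  ~10⁻⁴ and 1000 epochs leave the map essentially at its random
  initialization. Since the scale is a free convention (homogeneity),
  the settled pattern is normalized to unit total mass before the
  update. The same normalization precedes the Hebbian update below,
  where it additionally keeps fast-settling colors from dominating the
  weights simply because their patterns decayed less.
- **Training-time temperature anneal.** With a fixed T the softmax
  learning neighborhood cannot separate input pairs much closer than the
  median pairwise distance: in the 16-color set, the four pairs at RGB
  distance 0.5 (red/maroon, white/silver, lime/green, blue/navy) merge
  and their Voronoi cells end up empty. The training-time temperature is
  therefore annealed exponentially from T to `temperature_end` (default
  0.05) alongside σ and η — the settling analogue of the shrinking
  winner neighborhood in a classical SOM. Post-training dynamics always
  use the stated task temperatures. Even so, roughly one map in five
  fails to separate white from silver fully (the tightest, collinear
  triple white/silver/gray); such maps name white as silver when no word
  input helps, which is visible as occasional no-input errors.

Unit vectors initialize uniformly in the per-dimension range of the
inputs. All randomness flows from a single seed; training is
bit-reproducible.

## Stimuli

The 16 colors are the CSS/HTML basic colors with RGB triples on a 0–1
scale (red = (1,0,0)); Spanish names in standard dictionary form with
broad IPA transcriptions. Each word is encoded phoneme-by-phoneme:
vowels as (height, backness, roundedness), consonants as (place, manner,
voicing) scaled to [0,1], plus a type flag per slot (vowel 1.0,
consonant 0.5, padding 0), concatenated over at most 8 phoneme slots
(32 dimensions). The assembled lexicon is rescaled to a fixed median
pairwise distance, `lexical_scale` (default 1.0 — the same metric scale
as the RGB set). This scale is a real parameter of the stimuli: because
the initial-activation exponent divides by C_m (not C_m²), the absolute
metric scale of the word space sets how sharply a word input focuses the
lexical map. At the raw encoding scale (≈2.9) word inputs are nearly
delta-shaped and an incongruent trial would answer with the distractor
at the first step; at unit scale word and color inputs focus their maps
comparably. Larger scales strengthen interference (longer incongruent
RTs, more distractor wins); this sensitivity is a property of the
reconstruction, since the original stimulus vectors are not published.

What the synthetic set does not capture: the actual confusability
structure of the original phonetic vectors. The slot-wise encoding keeps
the 16 words metrically well separated, so the trained model makes
fewer spontaneous (distractor-independent) errors than the reference
behavior (~94% vs ~84% overall accuracy) and correspondingly smaller RT
contrasts. Passing tests therefore demonstrate the mechanism — perfect
congruent naming, the congruent < no-input < incongruent ordering, the
speed–accuracy tradeoff — not the exact error rates of any particular
stimulus set.

## Associative routing

Associative weights w (semantic units × lexical units) train for 10
epochs: per presentation both maps settle on the same color until each
is below 1 bit of readout entropy, then

> w_{ij}′ = w_{ij} + θ aᵢ aⱼ, θ = 0.1,

with rows normalized to one after each epoch. Two decisions:

- **Response gating.** "Responding" units are taken at the level of the
  map's output: the settled activation is restricted to each map's
  maximum-likelihood Voronoi cell before the update. The 1-bit criterion
  tolerates up to ~40% residual mass in neighboring cells; ungated,
  that residue routes crowded colors (white/silver/gray) to several
  words at once, and even congruent trials for those colors stall past
  the 500-step cap. With the gate, routing purity exceeds 0.95 and
  congruent naming is perfect with no timeouts.
- **Initialization.** Uniform at 1e-8/N_lex: strictly positive (row
  normalization well defined, transfer before training is exactly
  uniform — the no-knowledge baseline) but negligible against the
  Hebbian increments, so trained rows reflect co-activation.

During the task, settled semantic activation is routed into the lexical
map each step: a_j += γ Σ_i a_i w_{ij}, with γ = r_sem = 0.05.

## The Stroop task

Per trial: the target color drives the semantic map at scale 1; the
distractor word drives the lexical map at scale r_lex (congruent: the
target's own word; incongruent: another word; no-input: nothing). Each
iteration settles both maps one step, transfers semantic→lexical, and
then checks the lexical entropy (the criterion sees post-transfer
activation); response = maximum-likelihood word once E_t < 1 bit, failure
at 500 steps. Trials are deterministic given a trained model. The
factorial design is 16 congruent + 16 no-input + 240 incongruent = 272
trials. `run_factorial` executes the identical update sequence for all
trials batched through matrix products (verified trial-for-trial against
the scalar loop).

Accuracy counts a trial correct only if the emitted word names the
semantic target; failed trials count as errors. RT statistics use
correct trials only. In place of a linear mixed model, condition
contrasts use per-color paired mean RT differences with a
within-color permutation test (exhaustive when the number of
reassignments is small, add-one Monte Carlo otherwise).

## Routing optimization

`sweep_rlex` runs the full factorial at r_lex = 0.0 … 1.0 in 0.05 steps
on one trained model (routing affects only the task loop) and scores
each point with q = minmax(e_i) + minmax(t_i) + minmax(t_c), where e_i
is the incongruent error rate over all 240 trials (failures included),
and t_i, t_c are mean correct-trial RTs (incongruent, congruent).
Min-max normalization is across the sweep, making q invariant to affine
rescaling of any metric; a constant metric contributes 0 with a warning.
The selected r_lex is the q-argmin, ties toward smaller r_lex (fewer
errors). A point with no converged congruent trial is excluded with a
warning; a point with no correct incongruent trial takes the sweep's
maximum t_i so it cannot win.

## Problem sizes and reproducibility

The experiments are desk-scale: a full train-and-evaluate cycle (two
20×20 maps × 1000 epochs, 10 associative epochs, 272 trials) takes about
a minute on one CPU core; the 21-point sweep adds ~1 minute. The
acceptance script replicates the factorial over 5 seeds and the sweep
over 2 seeds. One master seed fans out to independent substreams for the
two maps and the associative training, so any component can be rerun in
isolation; all artifacts embed the seed and a configuration digest.

## Known limitations

- The gray-axis triple (white/silver/gray) is metrically collinear and
  ~20% of seeds leave white and silver imperfectly separated; such maps
  show elevated no-input errors and congruent RTs for those colors.
- Error rates are dominated by the confusability of the reconstructed
  stimuli (see above) and sit above the reference behavior; RT contrasts
  are correspondingly compressed.
- Single lexical map (monolingual); no stimulus-onset asynchrony,
  practice, aging, or lesion manipulations; routing is two fixed scalar
  gains, not a learned controller.
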