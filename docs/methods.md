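# Methods

This note documents the statistical procedures, the synthetic-data
generator, and the numerical choices behind `turnload`, in the spirit of a
model-documentation page: what is computed, under which assumptions, and
what the bundled simulations do and do not demonstrate.

## Units of analysis

The unit is the **turn-at-talk**: a contiguous stretch of one speaker's
tagged words, taken as given in the input transcript (the pipeline does not
re-segment speech; how inter-pausal units were merged into turns is a
property of the upstream transcription). Turn **size** is the number of
grammatical words as tokenised by the tagger — contractions arrive
pre-split, so *I'm gonna* counts four words. Analyses use turns of 3–25
words, bounds inclusive; the retention fraction is reported so users can
audit the filter on their own data.

**Frequencies** are counted over word–tag combinations (*so* as adverb and
*so* as conjunction are distinct types) and normalised per 1,000 tokens of
the selected subset. Counting is subset-internal by design: the frequency
universe is exactly the turns being analysed, which keeps frequencies,
hapax status and model responses on one footing. Forms are case-folded
before keying (configurable), pooling orthographic variants of a type.
**Hapaxes** are types with subset-internal count 1; a whole-corpus hapax
mode would require the unfiltered corpus and is intentionally not the
default, since the analysis subset is the declared counting universe.

**Position** within a turn is `(index − 1) / (size − 1)`, exactly 0 for the
first and 1 for the last word, making turns of different sizes comparable.
Positions are undefined for one-word turns, which the size filter excludes.

## Word classes

Tag-pattern rules (first match wins) assign each token to one of three
classes: **content** (nouns, adjectives, adverbs, lexical verbs — not
auxiliaries or modals), **insert** (interjection tags, plus the forms
*well* and *so* under adverb tags, a known mis-tagging in conversational
corpora; the override deliberately fires only on adverb tags so *so* as
conjunction stays a function word), and **function** (all remaining tags).
Default maps ship for the c5 and c7 tag sets; they are partial on the
function side, and unmatched tags are admitted as function words with a
one-shot warning — the conservative choice, since the function class is the
definitional remainder. Maps export/import as YAML for editing.

Two positional profiles are computed: the descriptive
content/function/insert percentages (summing to 100 per position cell), and
the modelling variant with noun / function / insert shares of all tokens —
nouns, not all content words, are the class whose turn-final rise carries
the frequency drop, so they are the modelled level; other content words
remain in the denominator only.

## Pupil preprocessing

Raw streams are per-participant time series of left/right pupil areas in
pixels at a nominal 60 Hz, with blinks already encoded as missing samples
(no velocity-based blink detection is added). The chain is:

1. **Eye averaging** — elementwise mean; if one eye is missing the other's
   value is used (propagating missingness would discard usable data); both
   missing stays missing.
2. **Blink interpolation** — linear interpolation of missing runs inside
   consecutive, non-overlapping batches of 600 observations (~10 s at
   60 Hz). Edge runs of a batch take that batch's nearest valid value; a
   fully-missing batch is left missing and its windows are excluded. Batch
   seams therefore differ from whole-series interpolation only when a gap
   touches a seam; a `whole_series` switch is provided. Valid samples are
   never altered, and interpolated values are bounded by their neighbours.
3. **Baselining** — within each turn window, the first sample is subtracted
   from all samples, so every trajectory starts at 0. The order is fixed as
   interpolate → baseline: baselining on a gap-free first datum avoids
   anchoring a whole window to a blink. Note the first sample carries its
   own measurement noise, which baselining transfers to every bin of that
   window; this is inherent to onset-baselining and is shared by the
   per-window random noise the models absorb.
4. **Word-aligned binning** — the window's samples are split into as many
   contiguous bins as the turn has words; bin sizes differ by at most one
   sample and the remainder goes to the earliest bins (any ≤1-spread rule
   is admissible; this one is pinned for reproducibility). Pairs with fewer
   samples than words are excluded, with reasons itemised. Bins sit at the
   normalised positions of their word index — the same coordinate as the
   words — so frequency slopes and pupil slopes share their x-axis.

Units stay in pixels throughout; no millimetre conversion or luminance
correction is attempted. Samples are assigned to windows by the
participant's own window intervals; overlapping windows across speakers are
each served from the same stream.

## Models

All positional trends use **orthonormal polynomial** predictors built by
the classical three-term recurrence (equivalent to Gram–Schmidt on
`[x, x², …]` with the constant removed): columns have zero mutual inner
product and unit norm over the fitting points, so each degree's coefficient
is estimated orthogonally to the lower ones. The recurrence coefficients
are stored, making the basis evaluable at new points for prediction curves.

Factor codings: role is contrast-coded (speaker +0.5, recipient −0.5), so
main effects are averages over roles and an interaction is the
speaker-minus-recipient difference; word class is deviation-coded with
function words as the omitted level (noun and insert coefficients read as
offsets). Turn size enters z-scaled (both centred-only and scaled are
supported; scaling makes the control's coefficient comparable across
datasets).

Mixed models carry **random intercepts** by participant and by
conversation. Estimation is REML via a standard linear-mixed-model backend;
when one grouping factor is nested in the other (participants within
conversations) the outer factor is the grouping structure and the inner one
a variance component, with a crossed variance-component fallback otherwise.
Wald p-values use the normal (z) approximation; at the row counts of these
analyses (10³–10⁴) the difference from a finite-df approximation is
negligible relative to the sign/recovery questions being asked. Fits with a
variance estimated at the zero boundary are returned flagged as singular
rather than rejected — with a generator that programs no participant
variance in frequencies, boundary fits are the correct outcome. Percentage
profiles (class and hapax models) are aggregates over turns, so they have
no grouping structure and use OLS with classical SEs.

**Model selection** mirrors incremental growth-curve practice: first the
interactions of position with control variables are pruned while
non-significant (p > 0.05, worst first); then polynomial degree grows one
step at a time — each new degree enters with its factor (and retained
control) interactions — and the step is kept only if the new main term is
significant at 0.05. The trace of every decision is returned and written to
CSV. Selection decisions use Wald tests within the candidate fit; no
cross-model likelihood comparison is performed, so no ML refit is needed.

**Simple effects** use estimated-marginal-means logic: the trend within
role L is `β_trend + code(L) · β_interaction`, with SE from the fixed-effect
covariance and Bonferroni adjustment across the role family (conservative
and dependency-free; switchable to none).

## The synthetic-data generator

The generator emulates the joint structure the analysis assumes, with every
latent quantity logged for recovery tests.

*Corpus.* A Zipfian lexicon with exponent s = 1 is partitioned into four
classes: inserts (8 types, seeded with *oh, yeah, well, so…*; *well*/*so*
carry adverb tags to exercise the classification override), function words
(300 types, top ranks seeded with the pro-forms *i, you, it…* so the
pro-form heuristics see realistic material), nouns (4,000 types — the
hapax-rich tail), and other content words (1,500 types). Turn sizes follow
a truncated geometric on 3–25 (ratio 0.85, mean ≈ 8), giving the
short-turn-dominated size distribution of casual conversation. Each word's
class is drawn from position-composition curves: insert probability 0.70
at position 0 decaying fast, noun probability rising from 0.04 to ≈ 0.32 at
the final position, other content flat at 0.18, function words the
remainder. These curves induce, rather than hard-code, the S-shaped decline
of mean token frequency: the expected per-thousand frequency of a class-c
token is `1000/N · (1 + (N−1)·π_c·S2_c)` (π_c the class's token share,
S2_c its sum of squared type probabilities — a size-biased draw lands on
frequent types proportionally more often), and mixing these class
expectations along the composition curves yields the analytic positional
curve used as ground truth in recovery tests.

*Pupillometry.* Conversations lay their turns on a timeline (duration ≈
260 ms per word with lognormal jitter, exponential inter-turn gaps); 260 ms
per word at 60 Hz yields ≈ 15.7 samples per word bin, matching the
magnitude a glasses-type tracker produces on real conversational turns.
Every participant contributes a continuous two-eye stream (resting level
≈ 2000 px, per-eye noise SD 25 px) with Poisson blink gaps (0.15/s, mean
120 ms) hitting both eyes. Within a turn window the latent baselined
trajectory is, for the speaker, `slope · t` with
`slope = 20 + a_participant + c_conversation + b_s · slope_freq + ε_turn`
(SDs 4, 3, 8; coupling b_s = −0.10 px per unit frequency slope), and for
recipients `amp · (2t − t²)` — a rise-then-plateau quadratic with
amp = 15 px, the same random offsets, and zero coupling. Implementing the
coupling in the speaker's latent slope makes the slope-coupling model
correctly specified under the generator; the recipient null mirrors the
asymmetry the analysis is designed to detect.

*What the generator does not emulate:* semantic content, within-class
positional ordering (real early function words are pro-forms, late ones
prepositions — here class composition alone carries the positional
structure), luminance confounds, gaze, overlap and turn competition, and
pupil response latency. Passing recovery tests therefore shows the pipeline
estimates what it claims to estimate under its own assumptions — not that
those assumptions hold in any particular corpus.

## Simulation scales and tolerances

Recovery checks run at a default scale of ≈ 2,000 turns, 3 dyadic
conversations, 6 participants — enough for the programmed effects to sit
many SEs from zero while keeping a full pipeline pass in seconds. The cubic
frequency-trend recovery compares the fitted positional curve with the
cubic projection of the analytic expected curve, averaged over 5 seeds,
within 10% of the curve's range; single coefficients of the weaker
polynomial terms have SEs comparable to their values at this scale, so
curve-level (not coefficient-level) agreement is the meaningful criterion.
The speaker/recipient growth-curve asymmetry is checked over 100 replicates
of 800 turns in two dyads — a scale set by power analysis so the recipient
quadratic detects at |z| ≈ 4 while the speaker quadratic stays null.
Word-aligned binning attenuates latent slopes by roughly the bin-centre
factor (K−1)/K for K-word turns; recovered couplings are accordingly ~13%
smaller in magnitude than programmed, well inside the 3-SE recovery band.

Numerical details: orthogonality of polynomial columns holds to 1e-8 and is
tested against a brute-force Gram–Schmidt oracle; OLS estimates are checked
against normal equations to 1e-8; convergence failures raise only on
non-finite estimates, boundary fits are flagged; interpolation never alters
valid samples; the zero-variance mixed fit equals OLS exactly on balanced
designs (on unbalanced designs REML may legitimately estimate small
positive variances, so exact equivalence is a balanced-design property).

## Known limitations

- p-values from the z approximation are slightly anti-conservative in
  small-group settings (few conversations); with 2–3 conversations the
  conversation-level variance is weakly identified and often estimated at
  the boundary.
- The stepwise polynomial procedure inherits the usual stepwise caveats: a
  true high-degree trend whose intermediate degree is weak can stop the
  growth early; the selection trace makes such stops auditable.
- Hapax status, frequencies and profiles are all subset-internal; results
  are not comparable to whole-corpus frequency norms without recounting.
- The CLI covers the standard paths; unusual configurations (custom class
  maps with overlapping patterns, non-60 Hz streams) are supported through
  the Python API.
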