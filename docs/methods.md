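# Methods

## The screening problem

The package targets a prescreening situation: a parent of a 16–30-month-old
writes a free-text concern about their child's social-communication
development, and we want an automated estimate of whether formal screening
would flag the child — either on a 20-item binary autism-specific checklist
(with a structured follow-up stage) or on a broad 5-domain developmental
questionnaire. Free text alone is known to be a weak predictor for this
task; the method's core idea is that *one* automatically chosen checklist
question, tailored to the narrative, can supply most of the missing
information while keeping the burden on the parent minimal.

## Instrument scoring

The checklist scorer counts at-risk answers under a configurable key (which
answer indicates risk per item; the bundled default follows the published
convention of yes-indicates-risk on items 2, 5 and 12). Counts map to tiers:
low 0–2, medium 3–7, high 8–20. Two follow-up administrations are
implemented:

* **interspersed** — the follow-up for an item is asked immediately after a
  flagged answer, before any total exists, so all flagged items get
  follow-up regardless of tier; final score = number of confirmed items,
  screen-positive at ≥ 2;
* **standard two-stage** — follow-up only for the medium tier; low is
  negative and high positive outright.

The two agree on every medium-tier record and can differ only by the
interspersed variant *adding* screen-positives among low-tier children —
the property the tests assert.

The questionnaire scorer sums 6 items (0/5/10) per domain and classifies
each domain against a (refer, monitor) cutoff pair: refer below the −2 SD
equivalent, monitor between −2 and −1 SD. True age-normed cutoffs are
proprietary, so the bundled cutoff file contains synthetic values (flat
refer 25 / monitor 40) and is explicitly labelled as such; any real cutoff
table can be supplied as YAML. Missing responses are rejected rather than
imputed, matching a forced-completion web survey.

Six binary outcomes are derived per child: checklist tier medium/high,
follow-up final score ≥ 2, any-domain refer, personal-social refer,
communication refer, and the union of the last two.

## Text features

Tokens are lowercased alphabetic strings (apostrophes removed, digits and
punctuation treated as separators). A bundled ~170-word English stopword
list (configurable) is applied before n-gram extraction, so n-grams never
contain stopwords. The vocabulary holds all unigrams/bigrams/trigrams with
document frequency ≥ `min_df` (default 10, the published filter), ordered
kind-first then lexicographically — index assignment is therefore invariant
to corpus order. Features are binary presence by default (more robust for
2–253-word texts); counts are available by switch.

"Lexical affinities" are not operationally defined in the original
description, so they are implemented as unordered token pairs co-occurring
within a ±5-token window after stopword removal, ranked by document-level
pointwise mutual information, keeping the top 200 that also meet `min_df`.
The feature is off by default and every headline result holds without it.

## Regression trees with leaf variance

All predictors are CART-style regression trees grown by greedy variance
reduction. On binary labels a leaf's mean is a risk score in [0, 1]; the
leaf also stores the *population* variance of its training labels (variance
of a single-sample leaf is 0), which the selection stage consumes.
Numerical choices:

* tie-break among equal-gain splits: lowest feature index, then lowest
  threshold — fits are bit-reproducible;
* thresholds are midpoints of adjacent sorted values, falling back to the
  left value when the midpoint would round onto the right one (adjacent
  floats), so no child is ever empty;
* stopping: `max_depth` (default 4), `min_samples_leaf` (default 5, sized
  for cohorts of ~100–200), and zero/`min_variance_reduction` gain.

The defaults were chosen for n ≈ 115 cohorts; the depth-1 behaviour is
pinned to an exhaustive single-split search in the tests, and deeper trees
are checked against monotonicity and memorization properties rather than
bit-exact references, since the original implementation is unknown.

## Question selection

For each question *j* the package fits an *augmented* tree on text features
plus the recorded answer to *j* (appended as the last column), and a
*selection* tree on four inputs evaluated per child: f₁ the text-only
score, f₂/f₃ the augmented score with the answer forced to 0/1, and f₄
leaf-variance information for those three predictions. The selection label
is 1 iff the augmented score under the child's true answer is strictly more
extreme than f₁ in the direction of the true label (ties = 0). "Variance of
the 3 predictors at the node where the example is labeled" is ambiguous;
the default feeds the three leaf variances as three separate features
(`f4_mode="three_leaf_variances"`), with `mean_leaf_variance` and
`variance_of_outputs` available as alternative readings. One selector is
trained per question (not pooled across questions), and augmented trees are
trained on each child's actual recorded answer; the forced-0/1 evaluations
exist only at feature-construction time.

At prediction time all 20 selection trees are evaluated; if every decision
score is below the threshold (0.5, as in the source procedure) the
text-only score stands, otherwise the argmax question (ties to the lowest
index) is asked and its augmented tree scores the child.

## Evaluation protocol

Leave-one-out with no leakage: vocabulary, text tree, 20 augmented trees
and 20 selection trees are all refit on the n−1 training children of each
fold. Held-out scores are pooled and ranked once per outcome (rank-based
AUC with midrank ties); per-fold AUC is undefined for single examples. On
single-class training folds (possible only in very small cohorts) the fold
degrades to the constant training-mean score with no question. The
text-only vs text-plus-question comparison across the six outcomes uses the
Friedman rank test with midranks and tie correction, implemented in-package
because the two-method case is outside scipy's k ≥ 3 restriction; an exact
within-block permutation p-value is available.

## Cohort statistics

Odds ratios ad/(bc) with Woolf log-interval CIs (Haldane–Anscombe +0.5 on
any zero cell, flagged), Pearson chi-square *without* continuity
correction, Spearman correlations with a Bonferroni threshold α/m, and the
two-way random-effects absolute-agreement single-rater ICC with its F-based
CI. The formula choices are pinned by the published group counts: rebuilding
the 2×2 tables from those counts reproduces every printed odds ratio and
chi-square only with the uncorrected chi-square (Yates gives 8.3 where 9.6
is printed) and the Woolf interval. One printed CI bound (9.32) differs
from the exact Woolf value (9.3263) by the source's own rounding; the
package keeps the exact formula. The ICC form is not named in the source;
two-way absolute-agreement single-rater is the standard model for a small
panel of interchangeable clinical raters.

## Synthetic cohorts

A latent Bernoulli risk variable drives every observable channel:

* base risk rate 0.42 without family history; family history (prevalence
  0.574) multiplies the odds by 3.9, echoing the strongest reported
  family-history odds ratio, for an overall positivity near 0.6 — the high
  base rate expected of a self-selected concerned-parent sample;
* narratives are bags of words: length truncated-normal (72, 37) clipped to
  [2, 253]; each word comes from a weighted risk lexicon with probability
  0.14 (risk) / 0.09 (no risk), otherwise from a neutral filler list that
  includes stopwords. This yields deliberately *weak* text signal
  (text-only LOO AUC roughly 0.4–0.7), matching the weak text-only
  performance reported for concern narratives;
* checklist items flag with per-item sensitivity/specificity given latent
  risk — three strongly informative items (0.85/0.97) and seventeen weak
  ones (0.40/0.92), reflecting the reported pattern that a handful of items
  (following a point, pretend play, concern about deafness) carry most of
  the augmentation value; flagged items confirm on follow-up with
  probability 0.9 (risk) / 0.3 (no risk), so medium-tier children can
  resolve to low final scores;
* questionnaire items are drawn 0/5/10 with risk-dependent category
  probabilities, shifted hardest in the personal-social and communication
  domains.

The planted-signal variant makes a single designated question's answer
agree with latent risk at 0.95/0.95 while all other questions are coin
flips and the text stays weak: a correct selector must learn to ask exactly
that question. The matched null variant plants nothing. These two
conditions, evaluated by full LOO at n = 200 over several seeds, are the
package's reproduction of the headline direction: the selected question
raises pooled AUC substantially (mean gain ≥ 0.10 and the planted question
modal among selections) while the null condition shows no material gain.
The dedicated property test uses 5 planted and 5 null seeds; the
acceptance script uses 3 and 2, and the six-outcome direction check
averages 3 seeds at n = 115 — sizes chosen to keep full runs in the
minutes range on a single CPU while leaving the conclusions
noise-robust.

What the generator does *not* emulate: real English syntax and discourse,
item-specific wording effects, demographic covariates beyond age/sex/family
history, rater panels, and the correlation structure between measures in
the count-reconstructed fixture (its per-measure flags preserve every 2×2
margin against family history but not cross-measure joint distributions).
Passing tests therefore demonstrate that the algorithmic machinery behaves
as specified under the assumed generative structure — not that the method
achieves any particular accuracy on real parental narratives, and the
published absolute AUC values (functions of the original, undeposited
study data) are matched in direction only.

## Known limitations

* Exactly one augmenting question is supported — no sequential chains, and
  scores are not calibrated probabilities.
* The vocabulary filter applies stopword removal before the
  document-frequency cut; sources that filtered in the other order would
  keep a slightly different term set.
* Tree hyperparameters are defaults, not tuned; results are matched at the
  property level, never bit-exactly against the original implementation.
* The ICC's F-based CI assumes a complete raters × subjects matrix
  (no missing cells).
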