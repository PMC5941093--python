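# askone

Adaptive single-question augmentation of text-based developmental risk
screening.

Parents who suspect an autism spectrum disorder (ASD) in their toddler often
describe their concerns in free text — in web communities, survey platforms,
or intake forms — long before any formal screening happens. `askone`
implements a prescreening pipeline for exactly that situation: it predicts a
child's screening risk from the parent's narrative alone, decides whether
asking **one** well-chosen item from a 20-item yes/no autism checklist would
sharpen the prediction, and if so, which item. It is aimed at researchers in
developmental screening and digital phenotyping who want a reproducible,
testable implementation of the method, including the instrument scoring
rules and the cohort statistics that go with it.

## Method

**Text representation.** Narratives are tokenized, stopword-filtered, and
represented as binary bags of word n-grams (n = 1..3) plus optional
"lexical affinity" terms (word pairs co-occurring within a ±5-token window,
ranked by pointwise mutual information), keeping terms with document
frequency ≥ 10.

**Risk predictors.** Every predictor is a CART-style regression tree over
binary outcome labels; a leaf's mean is the risk score *f*(x) ∈ [0, 1] and
the leaf's training-label variance quantifies its uncertainty.

**Question selection.** For each candidate question *j* ∈ {1..20}, a second-
stage regression tree estimates whether augmenting the text predictor with
the answer to *j* would move the score in the right direction. Its features
are (f₁) the text-only score, (f₂) the augmented score with the answer
forced negative, (f₃) forced positive, and (f₄) the leaf variances of those
three predictions; its training label is 1 iff the augmented score with the
*true* answer is strictly more extreme in the direction of the true label
than f₁. At prediction time, if all 20 decision scores are below 0.5 no
question is asked; otherwise the argmax question is asked and the augmented
tree produces the final score.

**Evaluation.** Leave-one-out with full per-fold refitting (vocabulary and
all trees), pooled rank-based AUC per outcome, and a Friedman rank test
comparing text-only vs text-plus-question across the six outcomes: the
initial checklist tier (medium/high), its follow-up confirmation (final
score ≥ 2), global questionnaire risk (any domain below the −2 SD cutoff),
the personal-social and communication domains, and their union.

**Cohort statistics.** Odds ratios ad/(bc) with Woolf log-interval CIs,
uncorrected Pearson chi-square for 2×2 tables, Spearman correlations, a
Bonferroni threshold α/m, and the two-way random absolute-agreement
single-rater ICC.

No real participant data are distributed: a synthetic-cohort generator
produces cohorts with the structure the method assumes (latent risk driving
text, checklist answers, follow-up confirmations and questionnaire scores,
with family history multiplying the odds of risk), plus a fixture cohort
that reproduces the published family-history contingency counts exactly.

## Worked example

```bash
askone simulate --seed 7 --n 60 --out-dir sim
askone train --cohort sim/cohort.csv --outcome MCHAT_R --min-df 3 --out-dir model
askone predict --model-dir model \
    --text "my toddler makes no eye contact and never points" --answer 1
```

prints

```json
{
 "text_score": 0.16666666666666666,
 "chosen_question": "Q4",
 "final_score": 1.0
}
```

From the narrative alone the model estimates a risk score of 0.17 — on this
small training cohort the text carries little signal for this narrative. The
selector decides that asking checklist question Q4 is worthwhile, and given
an at-risk answer (`--answer 1`) the augmented predictor raises the final
risk score to 1.0: the single targeted question, not the text, carries the
decisive information here. `askone evaluate --cohort … --out-dir …` runs the full
leave-one-out comparison and writes per-outcome AUCs with a Friedman test;
`askone table1 --builtin-fixture` prints the family-history contingency
report (odds ratios, Woolf CIs, chi-square) from the count-reconstructed
cohort.

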