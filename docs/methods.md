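# Methods

## Problem and data model

The package predicts metabolic-pathway involvement of prokaryotic proteins
from two attribute families that are cheap to obtain for unannotated
entries: InterPro signature identifiers (protein families, domains, sites)
and the taxonomic lineage of the source organism. Pathway annotations are
hierarchical strings of up to three levels (super-pathway; pathway;
sub-pathway) optionally ending in a step marker `: step i/n`. The target
identity used throughout learning is the *full* canonical pathway string
including the step suffix; the hierarchy is consulted only when comparing
predictions against another system's annotations (identical / similar /
distinct).

Only pathway annotations with manual-assertion evidence are learned from.
The accepted ECO codes are ECO:0000269, ECO:0000303, ECO:0000305,
ECO:0000250, ECO:0000255 and ECO:0000244; annotations with other evidence
are dropped per annotation, and entries left without any pathway are
removed in learning mode. Entries that keep a pathway but have no
attributes at all still count toward N — they can never fire or support a
rule, but N is defined as the number of transactions in the database.

Whitespace in labels and taxon names is normalized (trimmed, internal runs
collapsed to one space, case preserved).

## Rule mining

Mining is a level-wise Apriori specialized to class-association rules:
candidate itemsets contain only attribute items, and consequents are single
pathway items. Rule support is *antecedent-based* — supp(rule) = supp(X),
the number of transactions where the rule is applicable — rather than the
classical supp(X ∪ Y); with confidence fixed at 100% the two coincide.
Defaults: absolute support ≥ 20, minimum confidence 1.0, antecedents of at
most 4 items. The antecedent-size cap keeps desk-scale runs tractable and
is configurable (`--max-antecedent`); candidate generation is the classic
sorted-prefix join with subset pruning. No redundancy pruning happens at
mining time; all filtering is left to the skyline selection.

Confidence thresholding uses a 1e-12 epsilon so that exact-ratio rules are
not lost to float round-off.

## Quality metrics and normalization

Each rule carries support, confidence, lift and a G-test p-value. The
G-statistic is computed as G = 2 Σ O ln(O/E) over the 2×2 table of X and Y
(0·ln 0 ≡ 0), compared against χ² with 1 df, without continuity or
Williams corrections. A zero row or column margin yields p = 1 (no
evidence of association).

For selection the four metrics are mapped to [0, 1] with 1 ideal:
support and confidence are already ratios; lift is divided by N, its
maximum over the database (for a confidence-1 rule this equals
1/supp_abs(Y)); the p-value is flipped to 1 − p. Components are clamped to
[0, 1]. Each rule's score is the Euclidean distance from its normalized
vector to (1, 1, 1, 1), ranging over [0, 2].

## Skyline selection

Two rules are comparable when they share the consequent and their
antecedents intersect; dominance is weak componentwise ≥ with at least one
strict component (standard Pareto convention). Selection is iterative:
pick the candidate with minimal distance to the ideal point, discard all
candidates comparable to it, repeat. Ties on distance are broken
lexicographically on (consequent, sorted antecedent strings) so the output
is independent of input order.

The first pick of each round is necessarily undominated among the rules
then remaining (dominance implies strictly smaller distance). Note that a
representative chosen in a later round may still be dominated by a rule
that an earlier, incomparable-to-it representative already discarded;
comparability is not transitive, so "undominated among all input rules" is
not attainable under this procedure. The tests audit exactly the
attainable property.

## Prediction models

Representatives are grouped by consequent into disjunctive models; clauses
are ordered by ascending distance. Models serialize to JSON (floats at
full round-trip precision, structural validation with JSON-pointer error
locations) and to a human-readable block format
(`[PREDICT]`/`[IF]`/`OR`/`[END]`, metric components joined by an en dash;
the parser also accepts plain hyphens, splitting carefully around
exponent notation).

Applying a model predicts its pathway for an entry whenever some clause's
antecedent is contained in the entry's attribute items; the prediction
keeps the minimum distance over firing clauses and a score of
2 − distance, so that higher is better and any firing clause scores
positively. Pairs with no firing clause implicitly score 0 in ROC
construction. This score convention is this package's own choice.

## Label comparison

Two labels are identical when their canonical strings match; similar when
one's level list is a strict prefix of the other's (ignoring steps), or
the level lists are equal and exactly one side carries a step; distinct
otherwise (including equal levels with two different steps). Steps are
treated as refinements within the same sub-pathway, so a step difference
against a step-free label is a granularity difference, not a conflict.

## Evaluation

The reference pathway set — pathways annotated in at least 20 entries — is
computed once on the full learning database, not per fold. Evaluation is
at the (protein, reference-pathway) pair level; a protein annotated with
two pathways of which one is predicted contributes one TP and one FN.
Degenerate ratios use 0/0 → 1.0 for precision and recall (no errors made)
and F1 = 0 when P + R = 0. AUC is the tie-corrected Mann–Whitney rank
statistic, identical to the trapezoidal ROC area.

Cross-validation uses uniform random fold assignment at the protein level
without stratification, k = 5 folds and 2 runs by default. The run seed is
derived as `(seed * 1000003 + run) mod 2^31`, so the second run uses a
different split. Fold-level confusion counts are *averaged* (not summed)
per run; across runs the report carries the mean and a deviation equal to
half the absolute difference of the two run values (half-range for more
runs). Reported three-decimal metric values use truncation, not rounding.

## Synthetic data generator

The generator emulates the statistical structure the miner assumes:
entries with a lineage drawn from a small binary synthetic taxonomy
(default depth 6, matching typical prokaryotic lineage lengths), planted
antecedent → pathway regularities, and noise. Each planted rule receives
exactly `carrier_count` carrier entries bearing its full antecedent;
`ceil((1 − contamination) · carrier_count)` of them are annotated with the
planted pathway under experimental evidence, while contaminated carriers
receive a decoy secondary pathway (sequence-similarity evidence) so that
they survive learning-mode filtering and depress the planted rule's
confidence to exactly 1 − contamination. Non-carrier entries draw noise
taxa and signatures independently at `noise_item_rate` from vocabularies
disjoint from all planted antecedents, and never contain a full planted
antecedent, so recovery assertions are exact. A `multi_pathway_rate`
fraction of annotated carriers gains a second, generic pathway to emulate
multi-pathway proteins. Planted antecedents may not be subsets of one
another (carrier counts would otherwise not be exact).

Defaults (200 entries; four planted rules of 30 carriers each with
antecedents of one or two signatures, one including a taxon; contamination
0; noise rate 0.1) give every planted rule comfortable margin over the
support-20 mining threshold while leaving 40% of entries unannotated.

What the generator does **not** emulate: realistic co-occurrence structure
of InterPro signatures, uneven pathway frequencies, partially overlapping
antecedents between pathways, or annotation errors under manual-assertion
evidence. Perfect recovery on this fixture therefore demonstrates
correctness of the pipeline's mechanics, not expected performance on real
knowledgebase data.

## Cross-validation fixture sizes

Recovery-under-CV tests use 160 entries, four planted rules with 40
carriers each: with five folds of 32 entries, a rule's training support is
40 minus a hypergeometric draw with mean 8, so training support stays at
or above the mining threshold of 20 with overwhelming probability, and
perfect recall with zero false positives is the closed-form expectation.

## Known limitations

- Mining is in-memory and quadratic-ish in candidates; it targets
  desk-scale databases (10⁴–10⁵ transactions), not full knowledgebase
  dumps.
- The flat-file reader handles only a subset of the UniProtKB text format
  (AC/OC/DR InterPro/CC PATHWAY) through Biopython's SwissProt parser and
  expects complete record framing (`ID` ... `//`).
- Confidence-1 rules with universal consequents have degenerate G-tables
  (a zero margin) and receive p = 1; they are still mined but rank poorly,
  which is the intended conservative behaviour.
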