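# Methods

This note documents the models, the synthetic study conditions, and the
numerical and design choices made where the underlying procedure was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pointer-augmented NER

The tagger is a sequence-labelling model over word tokens with three
jointly trained heads. Given contextual vectors O from the encoder, each
head is an affine map followed by an elementwise sigmoid: a label head
over the M₁ = 3 BIO classes and two pointer heads over M₂ = 2 classes
(pointer absent/present) marking entity starts and ends. Because the
squashing is per-class, each row is renormalized to a distribution
before the cross-entropy is taken; this satisfies both the sigmoid form
of the heads and the multi-class sum in the loss. The joint objective is

    L = (1/N) [ CE_label + λ (CE_start + CE_end) ]

with N the number of scored positions. Scored positions are the first
sub-token of each word; continuation sub-tokens and [CLS]/[SEP]/padding
are masked from the loss (standard convention). λ defaults to 1.0 — the
neutral choice in the absence of a published value — and is exposed.

**Decoding.** How the three heads are reconciled at inference is not
fixed by the model definition, so two modes ship:

- `paired` (default): threshold the renormalized start and end pointer
  probabilities at 0.5; pair each start with the *nearest* subsequent
  end within a maximum entity length (default 10 tokens); discard pairs
  containing a token whose best label is `O`; select greedily left to
  right without overlaps. An exhaustive-enumeration oracle in the tests
  verifies the implementation on all short sentences.
- `bio`: decode from the label head alone (argmax + orphan-I repair),
  kept for ablating the pointer contribution.

**Dictionary-tree denoising.** Training annotations are corrected
against a gazetteer trie over all dictionary surface forms: every
maximal longest match becomes one annotated entity, and gold spans
overlapping a match are union-merged with it, so a span whose boundary
was truncated (e.g. "hypothalamic nucleus" inside "anterior hypothalamic
nucleus") is extended back to the dictionary form. Sentences without
dictionary hits are untouched and the transform is idempotent
(property-tested). This longest-match correction is one defensible
operationalization of dictionary-based corpus denoising; it deliberately
never *removes* an annotation, only extends or merges.

**Augmentation** is whole-corpus repetition followed by a seeded
shuffle; factor 1 is the identity.

## Marker-based relation classification

Candidate pairs are all unordered pairs of non-overlapping mentions in a
sentence; the subject is always the earlier mention, so directionality
lives entirely in the 4-way label. The marked sequence wraps the two
spans in atomic special tokens `<s> … </s>` and `<o> … </o>` (added to
the tokenizer vocabulary so they never fragment). The head projects the
four marker vectors to class space (H → M each), concatenates (4M), and
applies an output map (4M → M); a softmax produces the distribution
consumed by the mean cross-entropy. The classifier is parameterized by
the label set: 2-class connectivity or 4-class directional. Options kept
off by default: inverse-frequency class weights (the severe class skew
is part of the study conditions) and an additional [CLS] sentence-vector
term in the head (the concatenation form above is the documented one).
Over-length sequences are truncated symmetrically around the two spans
so both entities always survive.

## Encoder

Both models share one encoder architecture: the token representation is
the sum of word, position and segment embeddings, followed by L
post-norm transformer blocks (multi-head self-attention + feed-forward,
residual connections, layer norm). It is implemented on a small
reverse-mode autodiff core (numpy, float64) whose gradients are checked
against central finite differences in the test suite. The encoder is a
pluggable contract — anything that maps sub-token ids to (n, H) vectors
with a sub-token→word alignment can stand behind the heads — and the
desk-scale default (H = 32, L = 2, 2 heads, FFN 64, Adam at 3·10⁻³)
trains on thousands of sentences in seconds. The tokenizer is a greedy
longest-match word-piece model built from the training corpus; unknown
words fall back to character pieces so alignment is always total.

## Evaluation protocol

- **Exact** span matching: predicted boundaries must equal the gold
  boundaries. **Lenient**: a predicted span counts iff it is contained
  in (or equals) a gold span — smaller or equal, never larger — with
  each gold span creditable once. Assignment is greedy in span order;
  because gold spans are disjoint, each prediction has at most one
  containing gold span, so greedy assignment is provably optimal (the
  tests verify this against a brute-force matcher anyway).
- P/R/F1 use the all-zeros convention for empty denominators. NER is
  micro-averaged (pooled tp/fp/fn); the 4-class task reports macro and
  micro, macro being the headline.
- Confusion matrices are gold × predicted in the fixed class order
  (unconnected, undirected, output, input); row-normalized entries are
  per-class recalls.
- Cross-validation rotates the test and validation blocks over a seeded
  unit shuffle (document- or sentence-level), reporting per-fold metrics
  and mean ± SD. Document-level folds never split a document.

## Ontology merging and staged linking

Sources are unified by exact canonical-name match (normalized: case-fold,
punctuation stripped, stopwords {of, the, a, an} dropped), falling back
to unambiguous abbreviation identity; unified entries accumulate synonym
unions and a cross-reference table of source ids. Abbreviation
collisions (the same short form naming different structures in different
nomenclatures) and species conflicts never unify and are logged.

Linking stages run exact → strip-directional → nested-gazetteer →
fuzzy, first success wins, and the result records the stage. The fuzzy
score over stopword-free word sets M (mention) and T (term/synonym) is
w·|M∩T|/|M| + (1−w)·|M∩T|/|T| with w = 0.5 and acceptance threshold 0.5,
both configurable; ties break by score, then fewer term words, then id.
Abbreviations participate in exact matching only — short forms are too
collision-prone for word-level fuzzing. Nested candidates come from the
gazetteer trie (strict sub-spans, longest surface first), which keeps
the build dependency-light while leaving an extension point for an
external nested-NER tool.

## Knowledge graph

Canonicalization maps (label, subj, obj) to triples: output → subj→obj,
input → obj→subj, undirected → one canonical-order undirected edge,
unconnected → none; self-links after normalization are dropped with a
log line. The store is a multigraph keyed by (source, target, relation)
with per-sentence evidence lists, deduplicated per (document, sentence,
pair, label) — evidence for the same pair in different sentences
accumulates. Undirected edges are stored as such rather than expanded
into two directed edges, preserving the three-way evidence distinction.
Mentions that fail linking go to a side table, never silently dropped.

## Synthetic study conditions

The generator emulates the structure of region-annotated corpora:

- a toy merged ontology (default 40 regions) of unique 1–5-word names
  built from a closed vocabulary of anatomical-style modifiers and head
  nouns, with synonyms ("nucleus of the anterior …" word-order variants,
  rate 0.3) and initial-letter acronyms (rate 0.5);
- template sentences per relation class with distinct trigger lexicons
  ("projects to" / "receives input from" / "is connected with" / none),
  plus ~10% filler sentences with one or zero mentions;
- the default 4-class mix (unconnected 0.8488, undirected 0.0527,
  output 0.0710, input 0.0275) follows the class frequencies of a
  manually annotated directional corpus in this domain;
- boundary noise truncates one boundary token of a fraction of *training*
  spans while ground truth stays clean, isolating the denoising ablation.

Because triggers are class-disjoint, the tasks are separable by
construction: recovery tests therefore measure implementation
correctness, not task difficulty. Passing them does **not** show that
the architecture reaches any particular accuracy on real prose, which
has shared vocabulary across classes, anaphora, nested mentions and
annotation disagreement; it shows the losses, decoding, training loop
and pipeline plumbing are sound, and the ablation machinery behaves
directionally as expected.

Problem sizes used by the test suite and acceptance script — chosen as
desk-scale defaults that keep a full run in tens of seconds: parameter
recovery on a 2,000-sentence corpus (6:1:1 document split, 12 epochs);
the denoising ablation on 600-sentence corpora (noise rate 0.3, 8
epochs, 5 seeds in the tests, 3 in the script); RE recovery on ~1,000
labelled pairs per seed; end-to-end evaluation on 60 fresh documents
against the gold graph.

## Numerical choices and degenerate inputs

- ε = 10⁻¹² clamps inside every log; losses are never NaN.
- Argmax ties resolve to the lowest class index; span decoding and all
  ranked lists have deterministic tie-breaks.
- All randomness (name sampling, templates, shuffles, initialization)
  flows from explicit integer seeds; repeated runs are bit-identical.
- Empty sentences cannot be encoded (error); an empty gazetteer makes
  denoising the identity (warned); pathological predictions decode to
  the empty span list; absent regions yield empty circuit summaries.

## Known limitations

- The compact encoder is not a pretrained biomedical language model;
  production-grade accuracy on real corpora requires plugging one in
  behind the encoder contract.
- Candidate relations are intra-sentence only; cross-sentence discourse
  links are out of scope.
- The fuzzy-linking weights are heuristics exposed as configuration, not
  values fitted to data.
- The merged-dictionary loader ships with toy fixtures; building a real
  Allen/NeuroNames/BAMS merge is a curation task outside this package.
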