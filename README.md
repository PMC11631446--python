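# neurotext

Literature mining of **directed brain-region connectivity**: pointer-augmented
named-entity recognition (NER) of neuroanatomical region mentions, marker-based
relation classification of the connectivity between two mentioned regions,
normalization of mentions to a merged nomenclature dictionary, and assembly of
the results into an evidence-bearing directional connectivity knowledge graph.

It is written for computational neuroscientists and biomedical text-mining
practitioners who want to chart input–output circuits (which regions a given
structure projects to, and which project to it) from sentences such as *"the
paraventricular hypothalamic nucleus projects to the median eminence"*, at the
scale of whole literature corpora.

## The models

**NER with start/end position pointers.** Sentences arrive as token sequences
S = ⟨s₁…sₙ⟩ with BIO labels Y (`B-BrainRegion`, `I-BrainRegion`, `O`). Each
word additionally carries two binary pointer tags: T marks entity **starts**
and D marks entity **ends**. Token representations are sums of word, position
and segment embeddings, xᵢ = xᵢʷ + xᵢᵖ + xᵢˢ ∈ ℝᴴ, passed through L transformer
layers, Oˡ = Trans(Oˡ⁻¹). Three affine-plus-sigmoid heads predict per word the
label distribution P_l, the start pointer P_s and the end pointer P_e, trained
jointly with

    L = (1/N) [ CE(P_l, Y) + λ ( CE(P_s, T) + CE(P_e, D) ) ],

where N counts scored word positions and λ weights the pointer objective
(default 1.0). Decoding pairs thresholded starts with the nearest subsequent
end and discards pairs whose tokens look like `O`; a `bio`-only decode mode is
kept for ablation.

**Relation extraction with entity markers.** A candidate sentence with two
region mentions is rewritten as

    [CLS] … <s> region₁ </s> … <o> region₂ </o> … [SEP]

and encoded; the four encoder vectors at the marker positions (s₁, s₂, e₁, e₂)
are each projected to class space, concatenated, and mapped to class scores
P(X) = W_o·Concat(W₁ˢs₁+b₁ˢ, W₂ˢs₂+b₂ˢ, W₁ᵉe₁+b₁ᵉ, W₂ᵉe₂+b₂ᵉ) + b_o, softmaxed
and trained with multi-class cross-entropy. One implementation serves the
2-class connectivity task and the 4-class directional task
(`unconnected | undirected | output | input`): *output* means the
first-mentioned region projects to the second, *input* the reverse, and the
knowledge-graph builder canonicalizes both into directed `projects_to` triples.

**Normalization.** Mentions are linked to dictionary ids in stages: exact match
(names, abbreviations, synonyms) → exact match after stripping directional
modifiers (*rostral*, *dorsal*, …) → exact match of nested sub-mentions found
by a gazetteer trie → word-overlap fuzzy scoring
`score = w·|M∩T|/|M| + (1−w)·|M∩T|/|T|` with acceptance threshold 0.5.

The package ships a compact trainable encoder (numpy, reverse-mode autodiff;
H=32, 2 layers by default) behind a pluggable encoder contract, plus a
synthetic-corpus generator with known ground truth so the entire pipeline
trains and evaluates offline in seconds. Evaluation implements the field's
exact and **lenient** span matching (predicted boundaries may be smaller than,
never larger than, the annotation), micro/macro P/R/F1, normalized confusion
matrices and a k-fold cross-validation harness.

## Worked example

```bash
neurotext simulate --seed 5 --out-dir data
neurotext train-ner --corpus data/ner.conll --epochs 4 --seed 5 --out ner_model
neurotext predict-ner --model ner_model --in data/ner_clean.conll --out pred.conll
neurotext eval --task ner --mode exact --gold data/ner_clean.conll \
    --pred pred.conll --report ner_report.json
```

prints

```
wrote 1000 sentences, 907 relation instances, 145 gold triples to data
trained on 1000 sentences; final loss 0.1463
tagged 1000 sentences -> pred.conll
{
 "precision": 0.9938028169014085,
 "recall": 0.9478774852229984,
 "f1": 0.9702970297029704,
 "mode": "exact"
}
```

i.e. after four epochs on 1,000 synthetic sentences the tagger recovers 97% of
region spans with exact boundaries. Continuing,

```bash
neurotext train-re --corpus data/relations.tsv --epochs 4 --seed 5 --out re_model
neurotext build-kg --ner-model ner_model --re-model re_model \
    --dict data/ontology.tsv --in data/ner_clean.conll --out-dir kg_out
```

ends with `115 edges, 116 evidence records -> kg_out/edges.tsv`: the directed
graph extracted by the full NER → RE → linking pipeline, each edge carrying its
sentence-level provenance (`kg_out/evidence.json`), with mentions that failed
dictionary linking listed in `kg_out/unlinked.tsv`.

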