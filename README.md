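# drugsieve

Question-driven literature mining for drug repurposing. Given a user
question ("what are anti-oxidant drugs?"), the pipeline builds a
sentence-level corpus database, ranks sentences by their relevance to the
question, extracts one candidate compound name from each relevant
sentence, and screens the candidates with physicochemical rules. It is
aimed at computational researchers triaging large literature sets for
repurposing hypotheses — e.g. searching for antioxidants that could
modulate Th17-driven neuroinflammation in depression.

## Method

Four phases share one currency: 512-dimensional sentence/token embeddings.

1. **Corpus build** — documents are segmented into sentences and tokens
   and persisted as a single JSON database.
2. **Embedding** — each sentence *s* and token *w* is embedded,
   `E(s), E(w) ∈ R^512`. A pretrained sentence encoder can be plugged in
   through an adapter; a deterministic fixture embedder (unit-norm token
   vectors, mean-of-tokens sentences) makes everything testable offline.
3. **Relevance** — a regressor `R` trained on question/answer pairs (MSE,
   Adam) predicts the answer embedding `R(E(q))`; sentences are ranked by
   the Euclidean distance `‖E(s) − R(E(q))‖₂`, smallest first.
4. **Extraction** — a second regressor `X` predicts a "generic compound"
   embedding from the sentence embedding; the extracted name is the
   sentence token nearest the prediction,
   `argmin_w ‖E(w) − X(E(s))‖₂`. Extraction quality is the sensitivity
   `true / (true + false)` over labeled sentence–drug pairs, compared
   against a uniform random-token baseline (expectation `1/L` for
   `L`-token sentences) and across eight alternative network designs
   (`A`–`H`: dense-only stacks vs recurrent cores), whose sensitivity
   profiles are clustered with K-means.

Candidate compounds are then filtered by Lipinski's rule of five
(MW ≤ 500, logP ≤ 5, H-bond donors ≤ 5, H-bond acceptors ≤ 10; each
exceeded threshold is a violation) plus externally supplied
blood–brain-barrier and pathogenicity annotations. Descriptors are
computed with RDKit on the largest connected fragment; TPSA follows the
Ertl scheme with S/P terms under MDL aromaticity (the combination that
reproduces the common web calculators — see `docs/methods.md`).

The neural layers (dense, 1-D convolution, simple RNN, LSTM, LeakyReLU,
PReLU, Adam, MSE/MAE) are implemented in numpy in `drugsieve.net`; every
layer's gradient is verified against central differences in the test
suite.

Slow encoders can be fronted by `drugsieve.embedding.EmbeddingCache`, a
compressed `.npz` sidecar whose arrays are keyed
`"<embedder name>|<blake2b-128 hex of the UTF-8 text>"`, one 512-vector
per entry.

## Worked example

Screen the ten-compound antioxidant case-study table (packaged with the
library) for orally drug-like, brain-penetrant candidates:

```pycon
>>> from drugsieve.chem import (case_study_compounds, compute_descriptors,
...                             filter_candidates, FilterCriteria)
>>> records = case_study_compounds()
>>> d = compute_descriptors("O=C1C=Cc2ccccc2O1")   # coumarin
>>> print(f"MW={d.mol_weight:.2f}  TPSA={d.tpsa:.2f}  HBD={d.hbd} HBA={d.hba}  violations={d.violations}")
MW=146.14  TPSA=26.30  HBD=0 HBA=2  violations=0
>>> kept, rejected = filter_candidates(
...     records, FilterCriteria(max_violations=0, require_bbb_positive=True))
>>> [r.name for r in kept]
['Coumarin', 'resveratrol', 'Bicalutamide']
>>> rejected[:2]
[('Acebutolol', 'not BBB+ (BBB-)'), ('beta-D-fructofuranose', 'not BBB+ (BBB-)')]
```

Coumarin's 146 Da, TPSA 26.3 Å² and zero violations match the published
reference values; of the ten candidates only coumarin, resveratrol and
bicalutamide combine zero rule-of-five violations with a BBB+ annotation.

The same flow from the shell, end to end on plain-text documents:

```bash
drugsieve build-db --input-dir papers/ --out corpus.json
drugsieve train-relevance --sciq sciq.json --seed 7 --out relevance.npz
drugsieve rank --corpus corpus.json --model relevance.npz \
          --question "what are anti-oxidant drugs" --top-k 20 --out ranked.tsv
drugsieve train-extract --data labeled_pairs.csv --arch H --seed 7 --out extract.npz
drugsieve extract --ranked ranked.tsv --model extract.npz --out compounds.tsv
drugsieve filter --compounds compounds_annotated.csv \
          --max-violations 0 --require-bbb --out filtered.csv
```

Every command writes a `<out>.run.json` sidecar recording the exact
configuration and seeds, and rebuilding from identical inputs reproduces
outputs byte for byte.

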