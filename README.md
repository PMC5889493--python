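# readrank

Ranking-based readability assessment for medical documents.

Instead of assigning an absolute grade level, `readrank` learns the *relative*
difficulty of documents from per-rater pairwise comparisons. Documents are
featurized with readability-formula statistics (FKGL inputs, Gunning-Fog
polysyllabic share, Dale-Chall difficult-word percentage), 10-bin corpus
word-frequency proportions, length counts, and two source-specific skip-gram
embeddings (one trained on wikipedia-style text, one on EHR-style notes,
both applied to every document — 416 features total under the default
200-dimensional embeddings). A linear max-margin ranker is trained on
within-rater difference vectors `x(harder) − x(easier)` and evaluated with
the tie-corrected Kendall coefficient of concordance (W) against each
rater's own ordering.

Because no real study data ship with the package, a synthetic-study
generator produces complete corpora with planted latent difficulty plus
simulated raters (side-by-side pairs matched within 50 tokens and 0.5 FKGL
grade, 1–10 ratings driven by latent difficulty plus noise, optional
"eccentric" reversed-scale raters), so every stage is testable end to end.

## CLI

```bash
readrank simulate --preset default --seed 1 --out study/
readrank embed     --corpus study/corpus --source ehr --out ehr_vectors.txt
readrank featurize --corpus study/corpus --out features.tsv
readrank train     --corpus study/corpus --ratings study/ratings.csv --out model.json
readrank rank      --model model.json --in study/corpus --out ranking.tsv
readrank evaluate  --corpus study/corpus --ratings study/ratings.csv \
                   --baseline fkgl --report report.json
readrank qc        --ratings study/ratings.csv --report qc.json \
                   --drop-eccentric --drop-controversial --out filtered.csv
readrank ablate    --corpus study/corpus --ratings study/ratings.csv --report ablation.json
```

`train` stratifies documents 60/20/20 by topic, tunes the SVM trade-off C on
the development split (selection metric: mean per-rater Kendall W), and
writes a JSON model archive carrying the weights, feature-layout version,
z-score statistics, and training diagnostics (example count, discordant
training pairs, total slack). `evaluate` reports per-rater and mean W, the
FKGL-formula baseline under the identical protocol, and a two-sided Wilcoxon
signed-rank comparison. `qc` computes pairwise rater concordance, per-rater
conformity (eccentric below 0.5), and the controversial-document screen
(max rating difference above 5 among documents rated by at least two
raters), with pair-integrity-preserving filtering for retraining.

## Data formats

- corpus: directory of UTF-8 `.txt` files + `manifest.csv`
  (`doc_id,source,topic,filename`; source ∈ {wikipedia, ehr}, topic ∈
  {cancer, diabetes, hypertension, other})
- ratings: `ratings.csv` (`rater_id,pair_id,doc_id,rating` with rating 1–10;
  each (rater, pair) holds exactly 2 documents)
- word vectors: standard text format (`vocab dim` header, one token + floats
  per line)
- frequency table: `token<TAB>count`; easy words: one word per line
- model: single JSON archive

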