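# phenoprompt

Prompt-based identification and extraction of rare-disease phenotype
entities — **rare disease**, **disease**, **symptom**, and **sign** — from
free text, together with the evaluation machinery needed to score and
debug such a system end-to-end without network access:

- **`phenoprompt.corpus`** — documents and typed character-offset entity
  spans, brat standoff (`.txt`/`.ann`) reading and writing (including
  discontinuous `;`-fragment annotations), a BIO tag codec, corpus
  statistics, and deterministic train/validation/test splitting.
- **`phenoprompt.prompts`** — zero- and few-shot prompt assembly from five
  building blocks (task instruction, task guidance with entity definitions
  and optional distinguishing characteristics, output specification, worked
  example, output-retrieval cue), in a conversational *simple sentence* or
  numbered *structured list* format; few-shot example selection either
  uniformly at random or by maximal text similarity (pluggable scorer;
  default is term-frequency cosine).
- **`phenoprompt.extraction`** — a completion-provider contract, a total
  parser for the labeled comma-separated response format, stop-word
  stripping, and grounding of extracted surface strings back to character
  spans (case-insensitive, leftmost-unconsumed substring search). Every
  provider call is recorded in a JSON-lines audit log.
- **`phenoprompt.evaluation`** — one-to-one exact/relaxed span matching
  (exact-first with augmenting-path completion, so assignment cardinality
  is provably maximal), micro-averaged precision/recall/F1 per type and
  overall, and a five-category error taxonomy (boundary, type,
  boundary+type, spurious, missed) with a count/percentage error table.
- **`phenoprompt.synthetic`** — a deterministic generator for corpora with
  known gold annotations, an error injector that corrupts gold into
  predictions with exactly specified per-category error counts, and a
  gold-echo mock provider for offline end-to-end identity tests.
- **`phenoprompt.cli`** — the `phenoprompt` command.

## CLI

```sh
# generate a synthetic annotated corpus (brat .txt/.ann pairs)
phenoprompt gen-fixtures --out corpus/ --n-docs 200 --seed 7

# corpus statistics (per-type totals, mean (SD) per text)
phenoprompt stats corpus/

# 8:1:1 split
phenoprompt split corpus/ --ratios 0.8,0.1,0.1 --seed 0 --out split.json

# render one prompt
phenoprompt build-prompt corpus/ doc0000 --format structured_list --characteristics

# run extraction with the offline mock provider, then score it
phenoprompt extract corpus/ --out preds/ --provider mock
phenoprompt evaluate corpus/ preds/ --mode exact --mode relaxed --out reports/
phenoprompt errors corpus/ preds/ --out reports/
```

`--provider` accepts `mock` (echoes the corpus' own gold annotations; useful
for pipeline identity checks) or an `http(s)://…` endpoint URL for an
OpenAI-style chat-completions API (API key read from the environment
variable named by `--api-key-env`; temperature defaults to 0). Exit codes:
0 success, 2 usage/config error, 3 data error, 4 provider failure. Every
writing command records its configuration and seeds in a `manifest.json`.

A flat key-value YAML file can supply defaults for any command via
`--config run.yaml`; explicit command-line flags override it.

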