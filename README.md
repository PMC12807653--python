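# transqc

Quality control for multilingual ontology text. `transqc` scores a
professional translation of an ontology text element (label, synonym,
definition, …) against machine forward- and back-translations using a
penalized, transformation-based similarity score, classifies each element as
**exact** / **passed** / **pending**, and maintains the TSV translation
ledger from which multilingual release templates are generated.

## How scoring works

For each translation unit two language pairs are compared:

* source-language pair — original ontology text vs. machine backtranslation
  of the professional translation;
* target-language pair — professional translation vs. machine forward
  translation of the original text.

Every admissible combination of character transformations (case, roman/arabic
numerals, diacritics, whitespace, punctuation) and word transformations
(tokenization, stemming, stopword removal, punctuation word-split) is applied
identically to both members of a pair. Each combination yields a fraction of
matching words `W_pct` and a score

```
score = W_pct − W_pct × (t·[tokenized] + W_n·W_wt + C_n·C_wt)
```

with default penalties `C_wt = 0.02` per character-transform type,
`W_wt = 0.05` per word-transform type, and `t = 0.15` for tokenization. The
best (maximum-score) combination is kept per pair; the two pair scores are
averaged and classified against a cutoff (default 0.75): a final score of 1
(both pairs raw-identical) is *exact*, above the cutoff is *passed*, at or
below is *pending* (flagged for manual review).

Machine translations are plain input columns — no translation service is ever
called.

## Modules

| module | purpose |
|---|---|
| `transqc.transforms` | character/word text transformations and pair normalization |
| `transqc.scoring` | exhaustive transformation search, score equation, classification, unit TSV I/O |
| `transqc.ledger` | master-table lifecycle: reconcile, task subsets, definition policy, release templates, reports |
| `transqc.calibrate` | grid-search recovery of penalty weights/cutoff from human accept/reject verdicts |
| `transqc.synthcorpus` | labeled synthetic bilingual corpora with controlled perturbations |
| `transqc.cli` | `transqc` command-line entry point |

## CLI

```bash
# generate a labeled synthetic corpus
transqc simulate -n 100 --seed 1 --mix 0.5 --outdir sim/

# score translation units, write scored.tsv + category report
transqc score --units sim/units.tsv --outdir out/
transqc score --units sim/units.tsv --outdir out/ --cutoff 0.8   # overrides

# recover weights/cutoff from labeled data
transqc calibrate --units sim/labeled.tsv --outdir cal/ --fixed-weights

# reconcile prior ledger against current ontology text triples
transqc reconcile --triples triples.tsv --ledger master.tsv --outdir rec/

# release templates and summary report from a master table
transqc release --ledger rec/master.tsv --outdir rel/
transqc report  --ledger rec/master.tsv --total labels 11946
```

Scoring options can also come from a YAML config file (`--config cfg.yaml`)
with keys `cutoff`, `char_weight`, `word_weight`, `token_penalty` and
optional per-language `stopwords:` file paths (UTF-8, one token per line,
`#` comments).

All TSV files are UTF-8, header row first, no quoting; literal tabs/newlines
in text are escaped as `\t` / `\n`. Release templates carry a second
directive row with language-tagged annotation directives (`…@en`, `…@es`)
for downstream ontology-template tooling.

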