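"""Curating a raw corpus and building its token vocabulary.

A synthetic corpus with deliberate defects (broken strings, duplicates) is
pushed through the curation pipeline; the report reconciles every input
molecule.  The surviving corpus is tokenized atom-wise and the vocabulary's
round-trip coverage is verified.

Run:  python examples/01_curate_and_tokenize.py
"""

from smilesclm import (FixtureSpec, build_vocabulary, coverage_check,
                       curate_corpus, generate_fixture_corpus, tokenize)
from smilesclm.curation import accepted_smiles

# a corpus with 10% unparseable strings and 10% duplicates, as a raw
# database export would have
raw = generate_fixture_corpus(FixtureSpec(
    n_molecules=300, invalid_fraction=0.10, duplicate_fraction=0.10, seed=7))

records, report = curate_corpus(raw)
print(f"input molecules      : {report.input_size}")
for reason, count in sorted(report.counts_per_step.items()):
    print(f"  rejected {reason:<16}: {count}")
print(f"curated corpus       : {report.output_size}")
print(f"bookkeeping conserves: {report.check_conservation()}")

corpus = accepted_smiles(records)
vocab = build_vocabulary(corpus)
print(f"\nvocabulary size      : {vocab.size} (3 specials + atom-wise tokens)")
print(f"round-trip coverage  : {coverage_check(corpus, vocab):.3f}")

example = corpus[0]
print(f"\nexample              : {example}")
print(f"tokens               : {tokenize(example)}")
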