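"""Pretraining the language model on a small corpus and sampling from it.

Trains the decoder-only Transformer for a few epochs on a 150-molecule
synthetic corpus (a deliberately short run so the example finishes in about a
minute), then samples strings at two temperatures and scores them with the
metric panel.  For a run that reaches >90% validity, raise n_molecules to 500
and max_epochs to 30 as in scripts/acceptance.py.

Run:  python examples/02_train_and_sample.py
"""

from smilesclm import (ClmConfig, FixtureSpec, GenerationConfig,
                       TrainingConfig, TransformerLM, build_vocabulary,
                       evaluate_generation, generate, generate_fixture_corpus,
                       tokenize, train)

corpus = generate_fixture_corpus(FixtureSpec(
    n_molecules=150, heteroatom_set=("C",), ring_fraction=0.0,
    max_heavy_atoms=12, seed=1))
vocab = build_vocabulary(corpus)
max_tok = max(len(tokenize(s)) for s in corpus)

model = TransformerLM(ClmConfig(vocab_size=vocab.size, max_len=max_tok + 4),
                      seed=0)
print(f"corpus {len(corpus)} molecules, vocabulary {vocab.size}, "
      f"model {model.n_parameters():,} parameters")

config = TrainingConfig(batch_size=8, warmup_steps=500, max_epochs=8, seed=0)
_, history = train(model, corpus, vocab, config)
print(f"trained {len(history.val_loss)} epochs "
      f"(val loss {history.val_loss[0]:.3f} -> {min(history.val_loss):.3f})")

for temperature in (1.0, 0.6):
    batch = generate(model, vocab, GenerationConfig(
        n_samples=200, temperature=temperature, max_len=max_tok + 2, seed=11))
    print(f"\ntemperature {temperature}: validity {100 * batch.validity:.1f}%")
    print("  samples:", batch.raw_strings[:5])

report = evaluate_generation(batch.raw_strings, corpus, seed=0)
print("\nmetric panel (temperature 0.6 batch):")
print(report.table())
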