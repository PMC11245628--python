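"""Extract per-word contextual embeddings through the adapter interface.

Words are fed to the embedding model one sentence at a time; sub-word
tokens are pooled (mean by default) so the output always has exactly one
column per word.  The deterministic mock adapter stands in for a real
pretrained model; a BERT-base-style adapter (13 layers x 768 units)
yields the full 9984-dimensional embedding.
"""

import timescales as ts

seq = ts.generate_word_sequence(40, sentence_len_mean=8, seed=3)

adapter = ts.MockAdapter(n_layers=13, width=768)
emb = ts.extract_embeddings(seq, adapter, context_mode="sentence", layers_used="all")
print(f"all layers:   p = {emb.p} ({adapter.n_layers} layers x {adapter.width} units), "
      f"w = {emb.w} words")

single = ts.extract_embeddings(seq, adapter, layers_used="single:6")
print(f"single layer: p = {single.p} (layer 6 only)")

rolling = ts.extract_embeddings(
    ts.generate_word_sequence(40, seed=3), ts.MockAdapter(n_layers=3, width=8),
    context_mode="rolling", rolling_window=16,
)
print(f"rolling context (16-word window): p = {rolling.p}, w = {rolling.w}")
# every mode conserves the word count: tokenization never adds or drops
# a column, and layer selection only changes the row count.
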