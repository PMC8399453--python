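"""Choosing the linking threshold H from the LCC sweep.

Links are placed between patents with c <= H. The sweep tabulates the
largest-connected-component size per H; the knee (just before unrelated
groups merge into one blob) is a good operating point.
"""

from patentscape import (
    GeneratorConfig,
    build_vectors,
    choose_threshold,
    generate_corpus,
    lcc_sweep,
    preprocess_corpus,
    similarity_matrix,
)

records, truth = generate_corpus(GeneratorConfig(n_patents=150, n_topics=3, seed=1))
streams = preprocess_corpus(records, "novelty")
vectors = build_vectors(streams, m=5)
matrix = similarity_matrix(vectors)

sweep = lcc_sweep(matrix)
print(sweep.to_string(index=False))
h = choose_threshold(sweep)
print(f"\nknee of the curve: H = {h}")
# Below the knee the LCC covers one planted topic; at H=1 every patent
# joins a single component, which carries no group information.
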