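"""Build the four-view heterogeneous graph over k-mer and sequence nodes.

The coexisting view is a negated pointwise-mutual-information score over
sequence-level co-occurrence (more negative = more strongly associated),
the similarity view is Hamming distance, the Jaccard view is
intersection-over-union of occurrence sets, and the inclusive view links
k-mers to the sequences containing them by tf-idf.
"""

import numpy as np

from gnnmotif import graph, sequences, simulate

pwm = simulate.make_pwm(width=8, ic_per_col=2.0, rng_seed=11)  # consensus PWM
cfg = simulate.PlantedMotifConfig(n_pos=30, motifs=[pwm], rng_seed=1)
positives, _ = simulate.simulate_dataset(cfg)
corpus = sequences.prepare_corpus(positives, seed=1)
g = graph.build_graph(corpus, lenk=5)

print(f"graph: m = {g.m} unique 5-mers, n = {g.n} sequence nodes")
print(f"views: Wco {g.Wco.shape}, Wsim {g.Wsim.shape}, "
      f"Wjac {g.Wjac.shape}, Winclu {g.Winclu.shape}")

consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=0))
k1, k2 = consensus[:5], consensus[1:6]  # two overlapping motif 5-mers
p1, p2 = g.vocab.index[k1], g.vocab.index[k2]
print(f"\ncoexisting weight of motif pair {k1}/{k2}: {g.Wco[p1, p2]:.4f} "
      "(negative = co-occur more than independence predicts)")
off_diag = g.Wco[np.triu_indices(g.m, 1)]
print(f"median off-diagonal coexisting weight: "
      f"{np.median(off_diag[off_diag != 0]):.4f}")
print(f"Jaccard of the same pair: {g.Wjac[p1, p2]:.3f} "
      "(they occur in nearly the same sequences)")
print(f"Hamming distance between them: {int(g.Wsim[p1, p2])}")
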