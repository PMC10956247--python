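"""Simulate a planted-motif corpus with known ground truth.

Builds a width-8 PWM at 1.8 bits per column, plants 1-3 instances in each
of 20 positive 101-bp sequences, and pairs each positive with a
base-shuffled negative.
"""

from gnnmotif import sequences, simulate

pwm = simulate.make_pwm(width=8, ic_per_col=1.8, rng_seed=11)
consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=0))
print(f"planted PWM consensus: {consensus}")
print(f"mean information content: "
      f"{simulate.pwm_information_content(pwm).mean():.3f} bits/column "
      f"(requested 1.8; near-consensus columns)")

cfg = simulate.PlantedMotifConfig(n_pos=20, motifs=[pwm], rng_seed=1)
positives, truth = simulate.simulate_dataset(cfg)
corpus = sequences.prepare_corpus(positives, seed=1)

print(f"\n{len(positives)} positives carrying {truth.n_sites()} planted sites;"
      f" corpus of {len(corpus)} after pairing with shuffled negatives")
rec, sites = positives[0], truth.sites[0]
print(f"\nfirst sequence ({rec.id}), planted at "
      f"{[(s.start, s.end) for s in sites]}:")
print(rec.bases)
marks = [" "] * len(rec.bases)
for s in sites:
    for i in range(s.start - 1, s.end):
        marks[i] = "^"
print("".join(marks), "<- motif instances")
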