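import numpy as np
import pytest

from gnnmotif import graph, metrics, model, motifs, sequences, simulate


@pytest.fixture(scope="session")
def planted_pwm():
    """Width-8 PWM at 1.8 bits/column used across the end-to-end suites."""
    return simulate.make_pwm(width=8, ic_per_col=1.8, rng_seed=11)


def run_pipeline(pwms, seed, n_pos=150):
    """Simulate, prepare, train and extract motifs for one corpus."""
    cfg = simulate.PlantedMotifConfig(n_pos=n_pos, motifs=list(pwms), rng_seed=seed)
    positives, truth = simulate.simulate_dataset(cfg)
    corpus = sequences.prepare_corpus(positives, seed=seed)
    g = graph.build_graph(corpus, lenk=5)
    state, history = model.train(
        g, corpus.labels, corpus.splits, model.TrainConfig(seed=seed)
    )
    out = model.forward(g, state)
    test_mask = corpus.split_mask("test")
    test_auc = metrics.auc_roc(corpus.labels[test_mask], out.y_hat[test_mask])
    motif_set = motifs.discover_motifs(g, out, corpus)
    return {
        "corpus": corpus,
        "truth": truth,
        "graph": g,
        "state": state,
        "history": history,
        "outputs": out,
        "test_auc": test_auc,
        "motif_set": motif_set,
    }


@pytest.fixture(scope="session")
def planted_runs(planted_pwm):
    """Three full pipeline runs (seeds 1-3) on the single-motif corpus."""
    return {seed: run_pipeline([planted_pwm], seed) for seed in (1, 2, 3)}


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small two-letter-alphabet corpus giving a vocabulary of m <= 8
    3-mers — used for gradient and equivariance checks."""
    rng = np.random.default_rng(5)
    records = []
    for i in range(6):
        bases = "".join("AC"[b] for b in rng.integers(0, 2, size=10))
        records.append(sequences.SequenceRecord(id=f"s{i}", bases=bases,
                                                label=int(i % 2)))
    for k, r in enumerate(records):
        r.split = "train" if k < 4 else ("val" if k == 4 else "test")
    return sequences.SequenceSet(records)
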