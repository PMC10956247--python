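"""Three-layer transductive GNN over the multi-view k-mer/sequence graph.

Layer 1 learns a k-mer embedding per view by propagating the row-normalized
initial embeddings over that view's weight matrix through a trainable
projection and a ReLU:

    Eco  = ReLU(Ect  Wco  W^co),   Esim = ReLU(Est Wsim W^sim),
    Ejac = ReLU(Ejt Wjac W^jac)

The three are concatenated into Msc (m x (dc+ds+dj)).  Layer 2 aggregates a
sequence embedding through the inclusive (tf-idf) view:

    Esq(i) = ReLU(Winclu[:, i]^T  Msc  W^inclu)

Layer 3 is a logistic output over Esq.  All sequence nodes — including
validation and test — participate in every forward pass (transductive), but
only training nodes contribute gradient; their labels are the only ones the
optimizer ever sees.

Training minimizes the "iterative" loss: the current epoch's per-sequence
binary cross-entropy plus the previous epoch's BCE scaled by its own
sigmoid.  The carried term is detached (a constant within the epoch), so it
shapes the reported loss trajectory without contributing second-order
gradient terms; at epoch 1 the carried term is zero and the objective is
plain BCE.

The forward/backward passes are written directly in numpy; gradients are
hand-derived and covered by a finite-difference check in the test suite.
Optimization uses a self-contained Adam (beta1=0.9, beta2=0.999, eps=1e-8)
with the learning rate decayed as lr0 * exp(-decay * epoch), epoch counted
from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import MultiViewGraph

PROB_CLIP = 1e-12


@dataclass(frozen=True)
class ModelDims:
    """Embedding widths for the three k-mer views and the sequence layer."""

    dc: int = 50
    ds: int = 50
    dj: int = 50
    dsq: int = 150

    def __post_init__(self):
        if min(self.dc, self.ds, self.dj, self.dsq) < 1:
            raise ValueError("all embedding dimensions must be positive")

    @property
    def d_kmer(self) -> int:
        return self.dc + self.ds + self.dj

    def require_mi_compatible(self) -> None:
        if self.dsq != self.d_kmer:
            raise ValueError(
                "motif discovery compares k-mer and sequence embeddings, "
                f"which requires dsq = dc + ds + dj (got dsq={self.dsq}, "
                f"dc+ds+dj={self.d_kmer}); adjust the dimensions"
            )


@dataclass
class ModelState:
    """All trainable parameters.

    The output layer is a single shared weight vector plus scalar bias by
    default; ``per_node_output`` switches to one weight row and bias per
    sequence node for fidelity experiments (masked nodes then receive no
    output-layer training signal).
    """

    Wco_train: np.ndarray  # (m, dc)
    Wsim_train: np.ndarray  # (m, ds)
    Wjac_train: np.ndarray  # (m, dj)
    Winclu_train: np.ndarray  # (dc+ds+dj, dsq)
    w_out: np.ndarray  # (dsq,) or (n, dsq) if per-node
    b_out: np.ndarray  # scalar array or (n,)
    dims: ModelDims = field(default_factory=ModelDims)
    per_node_output: bool = False

    def params(self) -> dict[str, np.ndarray]:
        return {
            "Wco_train": self.Wco_train,
            "Wsim_train": self.Wsim_train,
            "Wjac_train": self.Wjac_train,
            "Winclu_train": self.Winclu_train,
            "w_out": self.w_out,
            "b_out": self.b_out,
        }


def init_state(
    m: int,
    dims: ModelDims = ModelDims(),
    seed: int = 0,
    n: int | None = None,
    per_node_output: bool = False,
) -> ModelState:
    """Glorot-style zero-mean initialization, scale 1/sqrt(fan_in)."""
    if m < 1:
        raise ValueError("vocabulary size m must be >= 1")
    if per_node_output and n is None:
        raise ValueError("per-node output layer needs the sequence count n")
    rng = np.random.default_rng(seed)

    def draw(shape, fan_in):
        return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

    D = dims.d_kmer
    out_shape = (n, dims.dsq) if per_node_output else (dims.dsq,)
    b_shape = (n,) if per_node_output else ()
    return ModelState(
        Wco_train=draw((m, dims.dc), m),
        Wsim_train=draw((m, dims.ds), m),
        Wjac_train=draw((m, dims.dj), m),
        Winclu_train=draw((D, dims.dsq), D),
        w_out=draw(out_shape, dims.dsq),
        b_out=np.zeros(b_shape),
        dims=dims,
        per_node_output=per_node_output,
    )


@dataclass
class ForwardOutputs:
    """Activations of one forward pass (pre-activations kept for backprop)."""

    Eco: np.ndarray
    Esim: np.ndarray
    Ejac: np.ndarray
    Msc: np.ndarray  # stacked Esc rows, (m, dc+ds+dj)
    Esq: np.ndarray  # (n, dsq)
    y_hat: np.ndarray  # (n,)
    _pre: dict = field(default_factory=dict, repr=False)

    @property
    def Esc(self) -> np.ndarray:
        return self.Msc


class GraphTensors:
    """Constant matrices of one graph, premultiplied once per training run:
    X_view = E_view_t @ W_view (m x m) and A = Winclu^T (n x m).

    The inclusive aggregation is degree-normalized by default: each
    sequence's incident tf-idf weights are divided by the square root of
    their L1 sum, the usual graph-convolution compromise between raw
    summation (which saturates the output sigmoid for 101-bp sequences
    with ~100 incident k-mers) and plain averaging (which leaves gradient
    steps too small to converge in 30 full-batch epochs).  ``inclu_norm``
    accepts "sqrt", "l1" (mean aggregation) or "none" (literal sum).
    """

    def __init__(self, graph: MultiViewGraph, inclu_norm: str = "sqrt"):
        self.Xco = graph.Ect @ graph.Wco
        self.Xsim = graph.Est @ graph.Wsim
        self.Xjac = graph.Ejt @ graph.Wjac
        A = graph.Winclu.T.copy()
        degree = np.abs(A).sum(axis=1, keepdims=True)
        degree = np.where(degree == 0, 1.0, degree)
        if inclu_norm == "sqrt":
            A = A / np.sqrt(degree)
        elif inclu_norm == "l1":
            A = A / degree
        elif inclu_norm != "none":
            raise ValueError(f"unknown inclu_norm {inclu_norm!r}")
        self.A = A
        self.inclu_norm = inclu_norm
        self.m = graph.m
        self.n = graph.n


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward(graph: MultiViewGraph | GraphTensors, state: ModelState) -> ForwardOutputs:
    """Full three-layer forward pass over every node in the graph."""
    gt = graph if isinstance(graph, GraphTensors) else GraphTensors(graph)
    if gt.m != state.Wco_train.shape[0]:
        raise ValueError(
            f"graph has m={gt.m} k-mers but state was built for "
            f"m={state.Wco_train.shape[0]}"
        )
    eco = gt.Xco @ state.Wco_train
    esim = gt.Xsim @ state.Wsim_train
    ejac = gt.Xjac @ state.Wjac_train
    Eco, Esim, Ejac = np.maximum(eco, 0), np.maximum(esim, 0), np.maximum(ejac, 0)
    Msc = np.concatenate([Eco, Esim, Ejac], axis=1)
    Z = gt.A @ Msc  # (n, dc+ds+dj)
    esq = Z @ state.Winclu_train
    Esq = np.maximum(esq, 0)
    if state.per_node_output:
        logits = (Esq * state.w_out).sum(axis=1) + state.b_out
    else:
        logits = Esq @ state.w_out + float(state.b_out)
    y_hat = _sigmoid(logits)
    return ForwardOutputs(
        Eco=Eco, Esim=Esim, Ejac=Ejac, Msc=Msc, Esq=Esq, y_hat=y_hat,
        _pre={"eco": eco, "esim": esim, "ejac": ejac, "esq": esq, "Z": Z,
              "logits": logits, "gt": gt},
    )


def bce(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Per-sequence binary cross-entropy with probability clipping."""
    p = np.clip(y_hat, PROB_CLIP, 1.0 - PROB_CLIP)
    y = np.asarray(y, dtype=float)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def iterloss(prev_bce: np.ndarray, curr_bce: np.ndarray) -> np.ndarray:
    """Current BCE plus the previous epoch's BCE scaled by its own sigmoid.

    The carried term is a constant with respect to current parameters; at
    the first epoch ``prev_bce`` is all zeros and this reduces to BCE.
    """
    prev = np.asarray(prev_bce, dtype=float)
    return prev * _sigmoid(prev) + np.asarray(curr_bce, dtype=float)


def loss_and_grads(
    gt: GraphTensors,
    state: ModelState,
    y: np.ndarray,
    train_mask: np.ndarray,
) -> tuple[float, dict[str, np.ndarray], ForwardOutputs]:
    """Mean training-node BCE and its gradients w.r.t. every parameter.

    The iterative loss adds only a detached constant per epoch, so these
    are also the gradients of the mean training iterloss.
    """
    out = forward(gt, state)
    mask = np.asarray(train_mask, dtype=bool)
    n_train = int(mask.sum())
    if n_train == 0:
        raise ValueError("no training sequences: nothing to fit")
    y = np.asarray(y, dtype=float)
    mean_bce = float(bce(y, out.y_hat)[mask].mean())

    # exact d BCE / d logit = y_hat - y (clipping only guards the reported
    # loss value, as in the usual with-logits formulation)
    dlogit = np.zeros_like(out.y_hat)
    dlogit[mask] = (out.y_hat - y)[mask] / n_train

    pre = out._pre
    if state.per_node_output:
        g_w = dlogit[:, None] * out.Esq
        g_b = dlogit.copy()
        dEsq = dlogit[:, None] * state.w_out
    else:
        g_w = out.Esq.T @ dlogit
        g_b = np.array(dlogit.sum())
        dEsq = np.outer(dlogit, state.w_out)
    desq = dEsq * (pre["esq"] > 0)
    g_Wu = pre["Z"].T @ desq
    dZ = desq @ state.Winclu_train.T
    dMsc = gt.A.T @ dZ
    dc, ds = state.dims.dc, state.dims.ds
    dHco, dHsim, dHjac = np.split(dMsc, [dc, dc + ds], axis=1)
    g_Wc = gt.Xco.T @ (dHco * (pre["eco"] > 0))
    g_Ws = gt.Xsim.T @ (dHsim * (pre["esim"] > 0))
    g_Wj = gt.Xjac.T @ (dHjac * (pre["ejac"] > 0))
    grads = {
        "Wco_train": g_Wc,
        "Wsim_train": g_Ws,
        "Wjac_train": g_Wj,
        "Winclu_train": g_Wu,
        "w_out": g_w,
        "b_out": g_b,
    }
    return mean_bce, grads, out


@dataclass
class TrainConfig:
    """Training-loop settings: 30 full-batch epochs of Adam with a natural
    exponential learning-rate decay by default."""

    epochs: int = 30
    lr0: float = 0.001
    decay: float = 0.001
    loss: str = "iterloss"  # or "bce"
    seed: int = 0
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.loss not in ("iterloss", "bce"):
            raise ValueError("loss must be 'iterloss' or 'bce'")


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], betas, eps):
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=float) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=float) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    graph: MultiViewGraph,
    labels: np.ndarray,
    splits: list[str],
    config: TrainConfig = TrainConfig(),
    dims: ModelDims = ModelDims(),
    per_node_output: bool = False,
) -> tuple[ModelState, list[dict]]:
    """Full-batch transductive training.

    Every epoch runs one forward pass over the whole graph, evaluates the
    loss on training nodes only, and takes one Adam step at the decayed
    learning rate.  Per-sequence BCE is cached between epochs to form the
    carried iterloss term.  History rows record epoch (1-based), learning
    rate, mean training loss (iterloss or BCE as configured), mean training
    BCE, and validation AUC.
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels, dtype=float)
    splits = list(splits)
    if len(y) != graph.n or len(splits) != graph.n:
        raise ValueError("labels/splits length must match the graph's sequence count")
    train_mask = np.array([s == "train" for s in splits])
    val_mask = np.array([s == "val" for s in splits])
    if not train_mask.any():
        raise ValueError("no training sequences: nothing to fit")

    gt = GraphTensors(graph)
    state = init_state(graph.m, dims, seed=config.seed, n=graph.n,
                       per_node_output=per_node_output)
    opt = _Adam(state.params(), config.betas, config.eps)
    prev_bce = np.zeros(graph.n)
    history: list[dict] = []
    for epoch in range(config.epochs):
        lr = config.lr0 * float(np.exp(-config.decay * epoch))
        mean_bce, grads, out = loss_and_grads(gt, state, y, train_mask)
        curr_bce = bce(y, out.y_hat)
        if config.loss == "iterloss":
            train_loss = float(iterloss(prev_bce, curr_bce)[train_mask].mean())
        else:
            train_loss = mean_bce
        val_auc = np.nan
        if val_mask.any() and len(np.unique(y[val_mask])) == 2:
            val_auc = float(roc_auc_score(y[val_mask], out.y_hat[val_mask]))
        history.append({
            "epoch": epoch + 1,
            "lr": lr,
            "train_loss": train_loss,
            "train_bce": mean_bce,
            "val_auc": val_auc,
        })
        opt.step(state.params(), grads, lr)
        prev_bce = curr_bce
    return state, history


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, state: ModelState, epoch: int, seed: int) -> None:
    np.savez(
        path,
        Wco_train=state.Wco_train,
        Wsim_train=state.Wsim_train,
        Wjac_train=state.Wjac_train,
        Winclu_train=state.Winclu_train,
        w_out=state.w_out,
        b_out=state.b_out,
        dims=np.array([state.dims.dc, state.dims.ds, state.dims.dj, state.dims.dsq]),
        per_node_output=np.array(state.per_node_output),
        epoch=np.array(epoch),
        seed=np.array(seed),
    )


def load_checkpoint(path) -> tuple[ModelState, int, int]:
    with np.load(path) as z:
        dims = ModelDims(*(int(x) for x in z["dims"]))
        state = ModelState(
            Wco_train=z["Wco_train"],
            Wsim_train=z["Wsim_train"],
            Wjac_train=z["Wjac_train"],
            Winclu_train=z["Winclu_train"],
            w_out=z["w_out"],
            b_out=z["b_out"],
            dims=dims,
            per_node_output=bool(z["per_node_output"]),
        )
        return state, int(z["epoch"]), int(z["seed"])
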