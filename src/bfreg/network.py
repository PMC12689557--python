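"""Hierarchical gene→protein→pathway→survival network with Cox-loss training.

The model mirrors the biological hierarchy: every node starts from a linear
embedding of its scalar input, messages pass within each level along the
level's adjacency (optionally re-weighted by a learnable adjacency that keeps
known edges at full weight and penalizes unknown ones by a small factor
``alpha``), and propagation to the next level is masked elementwise by the
inter-level map so absent relations contribute exactly zero.  The single
survival node is read out to a scalar risk score, trained by minimizing the
Cox partial-likelihood loss

    L = − Σ_events ( H_i − log Σ_{j ∈ R_i} exp(H_j) ),

and evaluated with the concordance index on held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .hierarchy import BioHierarchy
from .synthetic import SyntheticCohort, standardized_log_expression

__all__ = [
    "BFRegNN",
    "TrainConfig",
    "FittedSurvivalModel",
    "cox_loss",
    "concordance_index",
    "train_model",
    "integrated_gradients",
    "Adam",
]

ALPHA_UNKNOWN_EDGE = 0.005   # penalty multiplier for edges absent from A^l


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _activation(name: str):
    if name == "logistic":
        return ad.sigmoid
    if name == "tanh":
        return ad.tanh
    if name == "identity":
        return lambda t: t
    if name == "mix":  # half identity, half logistic: keeps a linear path open
        return lambda t: t * 0.5 + ad.sigmoid(t) * 0.5
    raise ValueError(f"unknown activation {name!r}")


class BFRegNN:
    """The hierarchical survival network.

    Parameters
    ----------
    hierarchy:
        Topology (levels, adjacencies, masks).
    dim:
        Embedding dimension per node.
    rounds_per_level:
        Intra-level message-passing rounds before each cross-level step.
    learnable_adjacency:
        Levels at which the learnable adjacency replaces the binary one
        (known edges keep the learned weight, unknown edges are scaled by
        ``ALPHA_UNKNOWN_EDGE``); default gene level only.
    activation:
        Nonlinearity for update and cross-level steps ("logistic", "tanh",
        "identity", "mix").
    """

    PROP_LEVELS = ("gene", "protein", "pathway")

    def __init__(self, hierarchy: BioHierarchy, dim: int = 16,
                 rounds_per_level: int = 1,
                 learnable_adjacency=("gene",),
                 activation: str = "logistic",
                 mlp_hidden: int = 8, init_scale: float | None = None,
                 seed: int = 0):
        self.hierarchy = hierarchy
        self.dim = dim
        self.rounds = rounds_per_level
        self.learnable_levels = tuple(learnable_adjacency or ())
        self.act = _activation(activation)
        self.activation_name = activation
        self.mlp_hidden = mlp_hidden
        self.init_scale = init_scale
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng):
        d, h = self.dim, self.mlp_hidden
        hy = self.hierarchy
        P = self.params
        s = self.init_scale

        def t(x):
            return Tensor(x, requires_grad=True)

        P["emb"] = t(rng.normal(0, s or 1.0 / np.sqrt(d), size=(hy.n("gene"), d)))
        for lvl in self.PROP_LEVELS:
            P[f"w_self_{lvl}"] = t(1.0)
            deg = max(hy.adjacency[lvl].sum(axis=1).mean(), 1.0)
            P[f"w_msg_{lvl}"] = t(1.0 / deg)
            if lvl in self.learnable_levels:
                P[f"adj_W1_{lvl}"] = t(rng.normal(0, 1.0 / np.sqrt(2 * d), size=(2 * d, h)))
                P[f"adj_b1_{lvl}"] = t(np.zeros(h))
                P[f"adj_W2_{lvl}"] = t(rng.normal(0, 1.0 / np.sqrt(h), size=(h, 1)))
                P[f"adj_b2_{lvl}"] = t(np.zeros(1))
            n_src = hy.n(lvl)
            n_dst = hy.n(self._next_level(lvl))
            w_scale = s or 1.0 / np.sqrt(max(hy.maps[lvl].sum(axis=1).mean(), 1.0))
            P[f"W_{lvl}"] = t(rng.normal(0, w_scale, size=(n_dst, n_src)))
            P[f"b_{lvl}"] = t(np.zeros(n_dst))
        # small readout init: the learned direction, not the random one,
        # should dominate the final risk score
        P["w_out"] = t(rng.normal(0, min(s or 0.01, 0.01), size=d))
        P["b_out"] = t(0.0)

    @staticmethod
    def _next_level(lvl):
        order = ("gene", "protein", "pathway", "survival")
        return order[order.index(lvl) + 1]

    def parameters(self) -> dict:
        return self.params

    # -- forward pieces -----------------------------------------------------
    def init_embeddings(self, x) -> Tensor:
        """H_i^0 = x_i · e_i for every gene node; x is (batch, n_genes)."""
        x = Tensor.as_tensor(x)
        b, n = x.shape
        return x.reshape(b, n, 1) * self.params["emb"]

    def learnable_adjacency_weights(self, H: Tensor, level: str) -> Tensor:
        """Effective weighted adjacency: β_ij on known edges, α·β_ij elsewhere.

        β_ij is a two-layer perceptron on the concatenated pair of embeddings.
        """
        b, n, d = H.shape
        A = self.hierarchy.adjacency[level]
        scale = A + ALPHA_UNKNOWN_EDGE * (1.0 - A)
        ones_j = Tensor(np.ones((1, 1, n, 1)))
        ones_i = Tensor(np.ones((1, n, 1, 1)))
        zi = H.reshape(b, n, 1, d) * ones_j          # (b, n, n, d): row i
        zj = H.reshape(b, 1, n, d) * ones_i          # (b, n, n, d): col j
        pair = ad.concat([zi, zj], axis=-1)
        hid = ad.tanh(pair @ self.params[f"adj_W1_{level}"] + self.params[f"adj_b1_{level}"])
        beta = (hid @ self.params[f"adj_W2_{level}"] + self.params[f"adj_b2_{level}"])
        return beta.reshape(b, n, n) * Tensor(scale)

    def message_pass_intra(self, H: Tensor, level: str) -> Tensor:
        """One round: Ĥ_i = σ(w_self·H_i + w_msg·Σ_j a_ij H_j)."""
        if level in self.learnable_levels:
            eff = self.learnable_adjacency_weights(H, level)
            msgs = eff @ H                            # (b,n,n) @ (b,n,d)
        else:
            A = self.hierarchy.adjacency[level]
            if not A.any():
                msgs = Tensor(np.zeros(H.shape))
            else:
                msgs = Tensor(A) @ H                  # (n,n) @ (b,n,d)
        return self.act(self.params[f"w_self_{level}"] * H
                        + self.params[f"w_msg_{level}"] * msgs)

    def propagate_cross_level(self, H: Tensor, level: str) -> Tensor:
        """Ĥ^{l+1} = σ((M ⊙ W) H + b): masked positions contribute zero."""
        M = self.hierarchy.maps[level]
        eff = self.params[f"W_{level}"] * Tensor(M)
        n_dst = M.shape[0]
        out = eff @ H + self.params[f"b_{level}"].reshape(1, n_dst, 1)
        return self.act(out)

    def forward(self, x) -> Tensor:
        """Risk scores (batch,) from gene inputs (batch, n_genes)."""
        x = Tensor.as_tensor(x)
        if x.ndim != 2 or x.shape[1] != self.hierarchy.n("gene"):
            raise ValueError(
                f"expected inputs (batch, {self.hierarchy.n('gene')}), got {x.shape}"
            )
        H = self.init_embeddings(x)
        for lvl in self.PROP_LEVELS:
            for _ in range(self.rounds):
                H = self.message_pass_intra(H, lvl)
            H = self.propagate_cross_level(H, lvl)
        b = x.shape[0]
        return H.reshape(b, self.dim) @ self.params["w_out"] + self.params["b_out"]

    def predict(self, x) -> np.ndarray:
        return self.forward(x).data

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict):
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=np.float64)


# ---------------------------------------------------------------------------
# loss and metric
# ---------------------------------------------------------------------------

def cox_loss(scores, time, event) -> Tensor:
    """Cox partial-likelihood loss −Σ_events (H_i − log Σ_{j∈R_i} e^{H_j}).

    Risk sets are defined within the given batch: R_i = {j : t_j ≥ t_i}.
    Numerically stabilized by a max shift inside the log-sum-exp, so the loss
    is invariant to adding a constant to all scores.
    """
    scores = Tensor.as_tensor(scores)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ev_idx = np.flatnonzero(event == 1)
    if ev_idx.size == 0:
        raise ValueError("cox_loss requires at least one event")
    risk = (time[None, :] >= time[ev_idx, None]).astype(float)   # (k, n)
    c = float(scores.data.max())
    ex = ad.exp(scores - c)
    lse = ad.log(Tensor(risk) @ ex) + c
    return -(scores[ev_idx].sum() - lse.sum())


def concordance_index(scores, time, event) -> float:
    """Fraction of comparable pairs ordered concordantly by the risk score.

    A pair (i, j) is comparable when t_i < t_j and sample i had the event;
    it is concordant when the shorter-lived sample has the higher score.
    Score ties count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    comp = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = comp & (s[:, None] > s[None, :])
    ties = comp & (s[:, None] == s[None, :])
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, params: dict, lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimizer and architecture settings for survival training.

    The optimizer defaults are the reference schedule (Adam at 1e-4, batch
    32, up to 200 epochs, 80/20 split, patience 10).  The architecture
    defaults — embedding width 8, half-identity/half-logistic activation,
    small (0.05) initialization — are the package's training-facing choices:
    they keep a linear path open through the hierarchy and let the learned
    signal dominate the random initialization within the optimizer's reach.
    """

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    train_fraction: float = 0.8
    patience: int = 10
    dim: int = 8
    rounds_per_level: int = 1
    learnable_adjacency: tuple = ("gene",)
    activation: str = "mix"
    init_scale: float | None = 0.05
    full_risk_set: bool = False
    ema_decay: float | None = None   # Polyak averaging of parameters
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def scaled_to(cls, max_epochs: int, reference_epochs: int = 200,
                  reference_lr: float = 1e-4, **kwargs) -> "TrainConfig":
        """Optimizer settings scaled to a shorter run.

        The reference schedule is 200 epochs at learning rate 1e-4.  Cutting
        the epoch count divides the number of optimizer steps, so the
        learning rate rises in proportion to keep the total optimization
        length (epochs × learning rate) equal to the reference — a 50-epoch
        run uses 4e-4.
        """
        lr = reference_lr * reference_epochs / max_epochs
        return cls(max_epochs=max_epochs, learning_rate=lr, **kwargs)


@dataclass
class FittedSurvivalModel:
    """A trained network plus the input transform it was fitted with."""

    net: BFRegNN
    gene_ids: list
    log_mu: np.ndarray       # per-gene mean of log2 expression (training cohort)
    log_sd: np.ndarray       # per-gene SD of log2 expression
    report: dict = field(default_factory=dict)

    def transform(self, expression: pd.DataFrame) -> np.ndarray:
        """Raw TPM-like genes × samples -> standardized (samples, genes)."""
        x = np.log2(expression.loc[self.gene_ids].values + 1e-12)
        return ((x - self.log_mu[:, None]) / self.log_sd[:, None]).T

    def risk_scores(self, expression: pd.DataFrame) -> np.ndarray:
        return self.net.predict(self.transform(expression))


def train_model(hierarchy: BioHierarchy, cohort: SyntheticCohort,
                config: TrainConfig | None = None) -> FittedSurvivalModel:
    """Fit the network on a cohort's tumor samples by minibatch Cox loss.

    Samples are split train/validation by a seeded shuffle (80/20 by
    default); minibatch risk sets are computed within each batch.  Training
    stops early when the validation loss has not improved for ``patience``
    epochs, and the parameters from the best validation epoch are kept.  The
    attached report carries per-epoch train/validation losses and the final
    validation concordance index.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = list(hierarchy.nodes["gene"])
    missing = set(genes) - set(cohort.expression.index)
    if missing:
        raise ValueError(f"cohort lacks expression for genes: {sorted(missing)[:5]}")
    samples = cohort.tumor_samples
    raw = np.log2(cohort.expression.loc[genes, samples].values + 1e-12)
    mu, sd = raw.mean(axis=1), raw.std(axis=1)
    sd[sd == 0] = 1.0
    X = ((raw - mu[:, None]) / sd[:, None]).T            # (n_samples, n_genes)
    time = cohort.survival.loc[samples, "time"].values
    event = cohort.survival.loc[samples, "event"].values.astype(int)

    order = rng.permutation(len(samples))
    n_train = int(round(cfg.train_fraction * len(samples)))
    tr, va = order[:n_train], order[n_train:]
    if event[va].sum() == 0 or event[tr].sum() == 0:
        raise ValueError("train/validation split has no events")

    net = BFRegNN(hierarchy, dim=cfg.dim, rounds_per_level=cfg.rounds_per_level,
                  learnable_adjacency=cfg.learnable_adjacency,
                  activation=cfg.activation, init_scale=cfg.init_scale,
                  seed=cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)

    history = {"train_loss": [], "val_loss": [], "val_cindex": []}
    best_val, best_state, best_epoch, stale = np.inf, net.state_dict(), -1, 0
    ema = net.state_dict() if cfg.ema_decay else None
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(tr)
        batches = ([perm] if cfg.full_risk_set else
                   [perm[i:i + cfg.batch_size] for i in range(0, len(perm), cfg.batch_size)])
        ep_loss, n_ev = 0.0, 0
        for idx in batches:
            if event[idx].sum() == 0:
                continue
            opt.zero_grad()
            loss = cox_loss(net.forward(X[idx]), time[idx], event[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.item()}"
                )
            loss.backward()
            opt.step()
            if ema is not None:
                d = cfg.ema_decay
                for k, p in net.params.items():
                    ema[k] = d * ema[k] + (1 - d) * p.data
            ep_loss += loss.item()
            n_ev += int(event[idx].sum())
        if ema is not None:
            live = net.state_dict()
            net.load_state_dict(ema)
        val_scores = net.predict(X[va])
        vloss = cox_loss(Tensor(val_scores), time[va], event[va]).item()
        history["train_loss"].append(ep_loss / max(n_ev, 1))
        history["val_loss"].append(vloss / max(int(event[va].sum()), 1))
        history["val_cindex"].append(concordance_index(val_scores, time[va], event[va]))
        if vloss < best_val - 1e-9:
            best_val, best_state, best_epoch, stale = vloss, net.state_dict(), epoch, 0
        else:
            stale += 1
            if stale >= cfg.patience:
                if ema is not None:
                    net.load_state_dict(live)
                break
        if ema is not None:
            net.load_state_dict(live)
    net.load_state_dict(best_state)
    val_scores = net.predict(X[va])
    report = {
        "history": history,
        "best_epoch": best_epoch,
        "n_train": len(tr),
        "n_val": len(va),
        "val_cindex": concordance_index(val_scores, time[va], event[va]),
        "val_samples": [samples[i] for i in va],
        "train_samples": [samples[i] for i in tr],
    }
    return FittedSurvivalModel(net=net, gene_ids=genes, log_mu=mu, log_sd=sd,
                               report=report)


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

def integrated_gradients(net: BFRegNN, x: np.ndarray, baseline: np.ndarray | None = None,
                         steps: int = 64) -> np.ndarray:
    """Integrated-gradients attribution of the risk score to each gene input.

    IG_g = (x_g − x0_g) · mean_k ∂F/∂x_g at x0 + (k/steps)(x − x0), k=1..steps.
    As steps grows, Σ_g IG_g converges to F(x) − F(x0) (completeness).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    x0 = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=float).ravel()
    ks = (np.arange(1, steps + 1) / steps)[:, None]
    interp = x0[None, :] + ks * (x - x0)[None, :]
    inp = Tensor(interp, requires_grad=True)
    scores = net.forward(inp)
    scores.sum().backward()
    grads = inp.grad
    if not np.all(np.isfinite(grads)):
        raise FloatingPointError("non-finite gradients in integrated gradients")
    return (x - x0) * grads.mean(axis=0)
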