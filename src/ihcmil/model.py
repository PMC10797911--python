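"""Gated-attention multiple instance learning for percent-positivity regression.

A bag is a set of patch embeddings carrying one label: the percent of
positive tumor cells in the core (or mini-bag) the patches came from. The
network embeds each instance through a prepended fully-connected layer,
computes a gated attention weight per instance,

    s_k = w . ( tanh(V h_k) * sigmoid(U h_k) ),     a = softmax(s),

pools the embedded instances into a bag representation z = sum_k a_k h_k,
and regresses the label from z with a linear head. Training minimizes mean
squared error on labels rescaled to [0, 1]; an unweighted-mean (average
pooling) baseline shares the same embedder and head.

The whole model — forward pass, analytic gradients and the Adam optimizer —
is implemented in numpy so that training is deterministic, single-threaded
and dependency-free. Instances are sorted by a canonical key before pooling
so predictions are bit-exactly invariant to instance order.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

CHECKPOINT_SCHEMA = "ihcmil-abmil-v1"

MARKERS = ("c-MYC", "BCL2")


@dataclasses.dataclass
class Bag:
    """One core / mini-bag: an instance matrix plus a percent label."""

    bag_id: str
    instances: np.ndarray  # K x D
    label: float  # percent in [0, 100]
    marker: str = "c-MYC"

    def __post_init__(self) -> None:
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=np.float64))
        if self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance")
        if not 0.0 <= self.label <= 100.0:
            raise ValueError(f"label must be in [0, 100], got {self.label}")


@dataclasses.dataclass
class GatedAttentionParams:
    """All trainable parameters.

    ``W0, b0`` — prepended fully-connected embedder (input dim -> M, ReLU);
    ``Wv, bv`` / ``Wu, bu`` — the parallel tanh / sigmoid attention branches
    (M -> L); ``w_att, b_att`` — the final attention projection (L -> 1);
    ``w_head, b_head`` — the regression head (M -> 1) on the pooled bag
    embedding, producing the label on a 0-1 internal scale.
    """

    W0: np.ndarray
    b0: np.ndarray
    Wv: np.ndarray
    bv: np.ndarray
    Wu: np.ndarray
    bu: np.ndarray
    w_att: np.ndarray
    b_att: float
    w_head: np.ndarray
    b_head: float

    @property
    def input_dim(self) -> int:
        return self.W0.shape[1]

    def fields(self):
        return dataclasses.fields(self)

    @classmethod
    def init(cls, input_dim: int, M: int = 128, L: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        return cls(
            W0=glorot((M, input_dim)),
            b0=np.zeros(M),
            Wv=glorot((L, M)),
            bv=np.zeros(L),
            Wu=glorot((L, M)),
            bu=np.zeros(L),
            w_att=glorot((L, 1))[:, 0],
            b_att=0.0,
            w_head=glorot((M, 1))[:, 0],
            b_head=0.0,
        )


@dataclasses.dataclass
class AttentionOutput:
    """Per-instance weights a (simplex), pooled embedding z, prediction."""

    a: np.ndarray
    z: np.ndarray
    y_hat: float  # percent scale, clamped to [0, 100]


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Sort instances lexicographically so pooling order is reproducible."""
    return np.lexsort(X.T[::-1])


def _softmax(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max())
    return e / e.sum()


def _forward(X: np.ndarray, p: GatedAttentionParams, pooling: str):
    """Full forward pass; returns the cache needed for the backward pass."""
    order = _canonical_order(X)
    Xs = X[order]
    H = np.maximum(Xs @ p.W0.T + p.b0, 0.0)  # K x M
    if pooling == "attention":
        T = np.tanh(H @ p.Wv.T + p.bv)  # K x L
        S = 1.0 / (1.0 + np.exp(-(H @ p.Wu.T + p.bu)))  # K x L
        G = T * S
        s = G @ p.w_att + p.b_att  # K
        a = _softmax(s)
    elif pooling == "average":
        K = H.shape[0]
        a = np.full(K, 1.0 / K)
        T = S = G = None
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    z = a @ H  # M
    y = float(z @ p.w_head + p.b_head)  # 0-1 internal scale
    return {"order": order, "Xs": Xs, "H": H, "T": T, "S": S, "G": G, "a": a,
            "z": z, "y": y, "pooling": pooling}


def _backward(cache: dict, p: GatedAttentionParams, dy: float) -> dict:
    """Analytic gradients of a scalar loss wrt every parameter.

    ``dy`` is d(loss)/d(y) on the internal 0-1 scale. Verified against
    numerical differentiation in the test suite.
    """
    Xs, H, a, z = cache["Xs"], cache["H"], cache["a"], cache["z"]
    g = {}
    g["w_head"] = dy * z
    g["b_head"] = dy
    dz = dy * p.w_head  # M
    da = H @ dz  # K
    dH = np.outer(a, dz)  # K x M
    if cache["pooling"] == "attention":
        T, S, G = cache["T"], cache["S"], cache["G"]
        ds = a * (da - float(a @ da))  # softmax Jacobian-vector product
        g["w_att"] = G.T @ ds
        g["b_att"] = float(ds.sum())
        dG = np.outer(ds, p.w_att)  # K x L
        dpreT = dG * S * (1.0 - T**2)
        dpreS = dG * T * S * (1.0 - S)
        g["Wv"] = dpreT.T @ H
        g["bv"] = dpreT.sum(axis=0)
        g["Wu"] = dpreS.T @ H
        g["bu"] = dpreS.sum(axis=0)
        dH = dH + dpreT @ p.Wv + dpreS @ p.Wu
    else:
        for name in ("Wv", "bv", "Wu", "bu"):
            g[name] = np.zeros_like(getattr(p, name))
        g["w_att"] = np.zeros_like(p.w_att)
        g["b_att"] = 0.0
    dpreH = dH * (H > 0)
    g["W0"] = dpreH.T @ Xs
    g["b0"] = dpreH.sum(axis=0)
    return g


def gated_attention(
    embedded_instances: np.ndarray, params: GatedAttentionParams
) -> AttentionOutput:
    """Attention-pool already-embedded instances (rows are h_k, dim M).

    Returns the simplex weights a (non-negative, summing to 1), the pooled
    embedding z = sum a_k h_k, and the head's clamped percent prediction.
    """
    H = np.atleast_2d(np.asarray(embedded_instances, dtype=np.float64))
    if H.shape[1] != params.Wv.shape[1]:
        raise ValueError(
            f"instance dim {H.shape[1]} does not match attention input "
            f"{params.Wv.shape[1]}"
        )
    T = np.tanh(H @ params.Wv.T + params.bv)
    S = 1.0 / (1.0 + np.exp(-(H @ params.Wu.T + params.bu)))
    s = (T * S) @ params.w_att + params.b_att
    a = _softmax(s)
    z = a @ H
    y = float(np.clip((z @ params.w_head + params.b_head) * 100.0, 0.0, 100.0))
    return AttentionOutput(a=a, z=z, y_hat=y)


def predict_bag(
    bag: Bag, params: GatedAttentionParams, pooling: str = "attention"
) -> float:
    """Predict a bag's percent positivity, clamped to [0, 100] for reporting."""
    cache = _forward(bag.instances, params, pooling)
    return float(np.clip(cache["y"] * 100.0, 0.0, 100.0))


def bag_attention(bag: Bag, params: GatedAttentionParams) -> np.ndarray:
    """Raw attention weights in the bag's original instance order."""
    cache = _forward(bag.instances, params, "attention")
    a = np.empty_like(cache["a"])
    a[cache["order"]] = cache["a"]
    return a


@dataclasses.dataclass
class TrainConfig:
    """Training hyperparameters. All deterministic given the seed."""

    lr: float = 1e-3
    epochs: int = 150
    seed: int = 0
    pooling: str = "attention"
    hidden_m: int = 128
    hidden_l: int = 64
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


class _Adam:
    def __init__(self, params: GatedAttentionParams, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m = {f.name: np.zeros_like(np.asarray(getattr(params, f.name), dtype=float))
                  for f in params.fields()}
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self, params: GatedAttentionParams, grads: dict) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.adam_beta1**self.t
        bc2 = 1.0 - c.adam_beta2**self.t
        for name, g in grads.items():
            g = np.asarray(g, dtype=float)
            self.m[name] = c.adam_beta1 * self.m[name] + (1 - c.adam_beta1) * g
            self.v[name] = c.adam_beta2 * self.v[name] + (1 - c.adam_beta2) * g**2
            update = (c.lr * (self.m[name] / bc1)
                      / (np.sqrt(self.v[name] / bc2) + c.adam_eps))
            cur = getattr(params, name)
            if np.isscalar(cur):
                setattr(params, name, float(cur - update))
            else:
                setattr(params, name, cur - update)


def train(bags: list[Bag], config: TrainConfig | None = None) -> GatedAttentionParams:
    """Fit the model by MSE on labels rescaled to [0, 1].

    One Adam step per bag, bag order shuffled each epoch with the config
    seed; fixed seed gives bit-reproducible parameters. Warns (and returns a
    constant predictor) when every label is identical.
    """
    if config is None:
        config = TrainConfig()
    if len(bags) == 0:
        raise ValueError("no bags to train on")
    if len(bags) < 2:
        raise ValueError("training needs at least 2 bags")
    labels = np.array([b.label for b in bags])
    if np.ptp(labels) == 0:
        warnings.warn("all labels identical; model degenerates to a constant")
    dims = {b.instances.shape[1] for b in bags}
    if len(dims) != 1:
        raise ValueError(f"bags have inconsistent instance dims: {sorted(dims)}")
    (input_dim,) = dims
    params = GatedAttentionParams.init(
        input_dim, M=config.hidden_m, L=config.hidden_l, seed=config.seed
    )
    opt = _Adam(params, config)
    rng = np.random.default_rng(config.seed)
    targets = labels / 100.0
    idx = np.arange(len(bags))
    for _ in range(config.epochs):
        rng.shuffle(idx)
        for i in idx:
            cache = _forward(bags[i].instances, params, config.pooling)
            dy = 2.0 * (cache["y"] - targets[i])
            grads = _backward(cache, params, dy)
            opt.step(params, grads)
    return params


def mse_loss(bags: list[Bag], params: GatedAttentionParams, pooling: str) -> float:
    ys = np.array([_forward(b.instances, params, pooling)["y"] for b in bags])
    ts = np.array([b.label for b in bags]) / 100.0
    return float(np.mean((ys - ts) ** 2))


@dataclasses.dataclass
class CVResult:
    """Out-of-fold predictions plus the per-fold trained models."""

    table: "object"  # pandas DataFrame: bag_id, marker, fold, y_true, y_pred
    models: list[GatedAttentionParams]
    fold_assignment: np.ndarray


def cross_validate(
    bags: list[Bag],
    n_folds: int = 10,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> CVResult:
    """Ten-fold (by default) cross-validation with a 90/10 train/test split.

    Folds partition the bags disjointly and exhaustively with sizes
    differing by at most one; every bag is predicted exactly once by a
    model that never saw it.
    """
    import pandas as pd

    if config is None:
        config = TrainConfig()
    n = len(bags)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} bags, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % n_folds
    models = []
    rows = []
    for fold in range(n_folds):
        test_mask = fold_of == fold
        train_bags = [b for b, m in zip(bags, test_mask) if not m]
        fold_cfg = dataclasses.replace(config, seed=config.seed + fold)
        params = train(train_bags, fold_cfg)
        models.append(params)
        for i in np.flatnonzero(test_mask):
            rows.append(
                {
                    "bag_id": bags[i].bag_id,
                    "marker": bags[i].marker,
                    "fold": fold,
                    "y_true": bags[i].label,
                    "y_pred": predict_bag(bags[i], params, config.pooling),
                }
            )
    table = pd.DataFrame(rows)
    return CVResult(table=table, models=models, fold_assignment=fold_of)


def patient_level_predictions(table, patient_of=None):
    """Collapse per-core predictions to per-patient means.

    Patients may contribute one or two cores, each its own bag sharing the
    patient's label; the patient-level prediction is the mean of its core
    predictions. ``patient_of`` maps bag_id -> patient id (identity by
    default). Expects a prediction table with bag_id, marker, y_true,
    y_pred columns.
    """
    import pandas as pd

    df = table.copy()
    if patient_of is None:
        df["patient_id"] = df["bag_id"]
    else:
        df["patient_id"] = df["bag_id"].map(patient_of)
        if df["patient_id"].isna().any():
            missing = df.loc[df["patient_id"].isna(), "bag_id"].tolist()
            raise ValueError(f"bags without a patient mapping: {missing}")
    out = (
        df.groupby(["patient_id", "marker"], as_index=False)
        .agg(y_true=("y_true", "mean"), y_pred=("y_pred", "mean"),
             n_cores=("bag_id", "size"))
    )
    return out


# ---------------------------------------------------------------------------
# checkpoint serialization


def save_checkpoint(params: GatedAttentionParams, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema": CHECKPOINT_SCHEMA}
    for f in params.fields():
        v = getattr(params, f.name)
        payload[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
    path.write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> GatedAttentionParams:
    payload = json.loads(Path(path).read_text())
    schema = payload.pop("schema", None)
    if schema != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {schema!r}")
    kwargs = {
        k: (np.asarray(v, dtype=float) if isinstance(v, list) else float(v))
        for k, v in payload.items()
    }
    return GatedAttentionParams(**kwargs)
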