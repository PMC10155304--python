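"""Bernoulli restricted Boltzmann machine pharmacophenotyping.

An RBM with M visible units (one per medication order key) and K hidden
units (one per candidate pharmacophenotype) is trained by contrastive
divergence (CD-k) on the binary exposure matrix.  The energy of a joint
configuration (v, h) is

    E(v, h) = -b.v - c.h - h.W.v

with weights ``W`` (K x M), visible biases ``b`` and hidden biases
``c``.  The conditionals factorize: ``p(h_j = 1 | v) = sigmoid(c_j +
W[j].v)`` and ``p(v_m = 1 | h) = sigmoid(b_m + h.W[:, m])``.

Training uses the centered-gradient variant of CD by default: visible
units are offset by their data means and hidden units by a running mean
of their activations, and visible biases start at the empirical
log-odds.  This removes the incentive for hidden units to model the
overall exposure density and is the standard remedy for dead and
duplicated units in long CD runs.  A mild sparsity target (1/K by
default) further encourages each hidden unit to specialize to a
distinct co-prescription pattern.  Setting ``centered=False`` and
``sparsity_cost=0`` recovers textbook CD-k exactly.

After training, each medication's "activation pattern" is the mean
data-clamped activation of every hidden unit over the patients who
received that medication.  A medication joins every pharmacophenotype
whose unit is on average activated (probability above a threshold tau)
when the medication is given; medications activating no unit fall into
an explicit unassigned bucket labelled K+1.  Multi-membership is
allowed by default (phenotypes may overlap); an exclusive mode keeps
only the strongest activation.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "RBMModel",
    "PhenotypeAssignment",
    "train_rbm",
    "hidden_activation",
    "free_energy",
    "pseudo_log_likelihood",
    "exact_cd_gradient",
    "assign_medications",
]


@dataclass
class RBMModel:
    """Trained RBM parameters plus the training configuration, the
    pseudo-log-likelihood trace, and the per-medication conditional
    activation statistics recorded at the end of fitting."""

    W: np.ndarray                 # (K, M)
    visible_bias: np.ndarray      # (M,)
    hidden_bias: np.ndarray       # (K,)
    K: int
    epochs: int
    learning_rate: float
    cd_steps: int
    batch_size: int
    seed: int
    eval_interval: int
    centered: bool = True
    sparsity_target: float | None = None
    sparsity_cost: float = 0.0
    visible_offset: np.ndarray | None = None   # mu, data means (centered mode)
    hidden_offset: np.ndarray | None = None    # lambda, final running means
    cond_activation: np.ndarray | None = None  # (M, K) mean p(h|v) among receivers
    training_trace: list = field(default_factory=list)  # [(epoch, pll), ...]
    feature_names: list[str] | None = None

    @property
    def M(self) -> int:
        return self.W.shape[1]

    def to_json(self, path: str | os.PathLike) -> None:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        payload = {
            "W": self.W.tolist(),
            "visible_bias": self.visible_bias.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "K": self.K,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "cd_steps": self.cd_steps,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "eval_interval": self.eval_interval,
            "centered": self.centered,
            "sparsity_target": self.sparsity_target,
            "sparsity_cost": self.sparsity_cost,
            "visible_offset": arr(self.visible_offset),
            "hidden_offset": arr(self.hidden_offset),
            "cond_activation": arr(self.cond_activation),
            "training_trace": self.training_trace,
            "feature_names": self.feature_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RBMModel":
        with open(path) as fh:
            d = json.load(fh)

        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            W=np.asarray(d["W"], dtype=float),
            visible_bias=np.asarray(d["visible_bias"], dtype=float),
            hidden_bias=np.asarray(d["hidden_bias"], dtype=float),
            K=int(d["K"]),
            epochs=int(d["epochs"]),
            learning_rate=float(d["learning_rate"]),
            cd_steps=int(d["cd_steps"]),
            batch_size=int(d["batch_size"]),
            seed=int(d["seed"]),
            eval_interval=int(d["eval_interval"]),
            centered=bool(d["centered"]),
            sparsity_target=d["sparsity_target"],
            sparsity_cost=float(d["sparsity_cost"]),
            visible_offset=arr(d["visible_offset"]),
            hidden_offset=arr(d["hidden_offset"]),
            cond_activation=arr(d["cond_activation"]),
            training_trace=[tuple(t) for t in d["training_trace"]],
            feature_names=d.get("feature_names"),
        )


def _check_binary(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    vals = np.unique(X)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("X must be binary (entries in {0, 1})")
    return X.astype(float)


def train_rbm(
    X: np.ndarray,
    K: int = 5,
    epochs: int = 5000,
    learning_rate: float = 0.05,
    cd_steps: int = 1,
    batch_size: int = 32,
    seed: int = 0,
    eval_interval: int = 100,
    centered: bool = True,
    sparsity_target: float | None = None,
    sparsity_cost: float = 0.5,
    feature_names: list[str] | None = None,
) -> RBMModel:
    """Train by minibatch CD-k.

    Positive-phase hidden statistics use the data-clamped probabilities
    ``sigmoid(c + W v)``; the negative phase runs ``cd_steps``
    alternating Gibbs steps from the data (sampled hidden and visible
    states, probabilities for the final statistics).  Weights start at
    Normal(0, 0.01).

    In centered mode (default) the weight gradient is computed on
    offset variables ``(v - mu)`` and ``(h - lambda)`` with ``mu`` the
    visible data means and ``lambda`` an exponential running mean of the
    hidden activations, visible biases start at the empirical log-odds,
    and the bias gradients carry the matching correction terms.  The
    sparsity regularizer nudges hidden biases toward a mean activation
    of ``sparsity_target`` (default 1/K) with strength
    ``sparsity_cost``.  With ``centered=False`` offsets are zero,
    biases start at zero, and with ``sparsity_cost=0`` the update is
    textbook CD-k.

    The full-coordinate pseudo-log-likelihood is recorded every
    ``eval_interval`` epochs; evaluation draws nothing from the
    training RNG stream, so changing the cadence does not change the
    fitted parameters.
    """
    X = _check_binary(X)
    P, M = X.shape
    if P < 1:
        raise ValueError("X needs at least one row")
    if K < 1:
        raise ValueError("K must be >= 1")
    if feature_names is not None and len(feature_names) != M:
        raise ValueError("feature_names length must match the number of visible units")
    if sparsity_target is None:
        sparsity_target = 1.0 / K
    if not 0.0 < sparsity_target < 1.0:
        raise ValueError(f"sparsity_target must be in (0, 1), got {sparsity_target}")

    # one stream for training; a second child is reserved so adding
    # randomized evaluation later cannot perturb the training stream
    train_ss, _eval_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(train_ss)

    W = rng.normal(0.0, 0.01, size=(K, M))
    if centered:
        mu = X.mean(axis=0)
        p_clip = np.clip(mu, 1.0 / max(P, 2), 1.0 - 1.0 / max(P, 2))
        b = np.log(p_clip / (1.0 - p_clip))
        lam = np.full(K, 0.5)
    else:
        mu = np.zeros(M)
        b = np.zeros(M)
        lam = np.zeros(K)
    c = np.zeros(K)
    q = np.full(K, sparsity_target)  # running mean activation, for sparsity
    lr = float(learning_rate)
    trace: list[tuple[int, float]] = []
    model = RBMModel(
        W, b, c, K, epochs, lr, cd_steps, batch_size, seed, eval_interval,
        centered, sparsity_target, sparsity_cost, mu, lam, None, trace, feature_names,
    )

    trace.append((0, pseudo_log_likelihood(model, X, full=True)))
    for epoch in range(epochs):
        perm = rng.permutation(P)
        for start in range(0, P, batch_size):
            v0 = X[perm[start:start + batch_size]]
            nb = v0.shape[0]
            ph0 = expit(v0 @ W.T + c)
            hk = (rng.random(ph0.shape) < ph0).astype(float)
            for _ in range(cd_steps):
                pvk = expit(hk @ W + b)
                vk = (rng.random(pvk.shape) < pvk).astype(float)
                phk = expit(vk @ W.T + c)
                hk = (rng.random(phk.shape) < phk).astype(float)
            if centered:
                lam = 0.99 * lam + 0.01 * ph0.mean(axis=0)
            gW = ((ph0 - lam).T @ (v0 - mu) - (phk - lam).T @ (vk - mu)) / nb
            gb = (v0 - vk).mean(axis=0) - gW.T @ lam
            gc = (ph0 - phk).mean(axis=0) - gW @ mu
            if sparsity_cost > 0.0:
                q = 0.95 * q + 0.05 * ph0.mean(axis=0)
                gc = gc + sparsity_cost * (sparsity_target - q)
            W += lr * gW
            b += lr * gb
            c += lr * gc
        if (epoch + 1) % eval_interval == 0 or epoch == epochs - 1:
            if not (np.isfinite(W).all() and np.isfinite(b).all() and np.isfinite(c).all()):
                raise FloatingPointError(
                    f"RBM training diverged: non-finite parameters at epoch {epoch + 1}"
                )
            trace.append((epoch + 1, pseudo_log_likelihood(model, X, full=True)))

    model.hidden_offset = lam
    # per-medication activation pattern: mean p(h | v) among receivers
    ph_data = expit(X @ W.T + c)                      # (P, K)
    receivers = X.sum(axis=0)                         # (M,)
    cond = np.zeros((M, K))
    nz = receivers > 0
    cond[nz] = (X.T[nz] @ ph_data) / receivers[nz, None]
    model.cond_activation = cond
    return model


def hidden_activation(model: RBMModel, v: np.ndarray) -> np.ndarray:
    """``p(h = 1 | v) = sigmoid(c + W v)`` for a vector or row-matrix."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != model.M:
        raise ValueError(f"visible vector has length {v.shape[-1]}, model expects {model.M}")
    return expit(v @ model.W.T + model.hidden_bias)


def free_energy(model: RBMModel, V: np.ndarray) -> np.ndarray:
    """``F(v) = -b.v - sum_j softplus(c_j + W[j].v)`` (rows of V)."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    act = V @ model.W.T + model.hidden_bias
    return -(V @ model.visible_bias) - np.logaddexp(0.0, act).sum(axis=1)


def pseudo_log_likelihood(
    model: RBMModel,
    X: np.ndarray,
    rng: np.random.Generator | None = None,
    full: bool = False,
) -> float:
    """Pseudo-log-likelihood proxy averaged over rows.

    For a coordinate m, ``log p(v_m | v_-m) = log sigmoid(F(v~m) - F(v))``
    where ``v~m`` flips bit m.  ``full=True`` sums over every
    coordinate; the default evaluates one random coordinate per row and
    scales by M (the standard stochastic proxy, deterministic given the
    supplied RNG).
    """
    X = _check_binary(X)
    P, M = X.shape
    if P == 0:
        return 0.0
    fe = free_energy(model, X)
    if full:
        total = 0.0
        for m in range(M):
            Xf = X.copy()
            Xf[:, m] = 1.0 - Xf[:, m]
            total += log_expit(free_energy(model, Xf) - fe).sum()
        return float(total / P)
    if rng is None:
        rng = np.random.default_rng(0)
    idx = rng.integers(0, M, size=P)
    Xf = X.copy()
    Xf[np.arange(P), idx] = 1.0 - Xf[np.arange(P), idx]
    return float(M * log_expit(free_energy(model, Xf) - fe).mean())


def exact_cd_gradient(
    model: RBMModel, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected textbook CD-1 gradient for one data vector, by
    exhaustive enumeration of all hidden and visible states.

    Returns ``(dW, db, dc)``: the expectation over the one-step Gibbs
    chain h ~ p(h|v), v' ~ p(v|h) of the CD-1 statistics

        dW = p(h|v) v^T - E[p(h|v') v'^T],  db = v - E[v'],
        dc = p(h|v) - E[p(h|v')].

    These are the plain (uncentered) statistics; the centered update of
    :func:`train_rbm` is the same expectations taken on offset
    variables.  Only feasible for small models (enumerates 2^K * 2^M
    states); used as the analytic reference for the stochastic updates.
    """
    v = np.asarray(v, dtype=float).ravel()
    K, M = model.W.shape
    if v.shape[0] != M:
        raise ValueError(f"v has length {v.shape[0]}, model expects {M}")
    ph0 = hidden_activation(model, v)
    dW_neg = np.zeros((K, M))
    db_neg = np.zeros(M)
    dc_neg = np.zeros(K)
    for h_bits in itertools.product((0.0, 1.0), repeat=K):
        h = np.array(h_bits)
        p_h = float(np.prod(np.where(h == 1.0, ph0, 1.0 - ph0)))
        if p_h == 0.0:
            continue
        pv = expit(h @ model.W + model.visible_bias)
        for v_bits in itertools.product((0.0, 1.0), repeat=M):
            vp = np.array(v_bits)
            p_v = float(np.prod(np.where(vp == 1.0, pv, 1.0 - pv)))
            if p_v == 0.0:
                continue
            php = hidden_activation(model, vp)
            w = p_h * p_v
            dW_neg += w * np.outer(php, vp)
            db_neg += w * vp
            dc_neg += w * php
    dW = np.outer(ph0, v) - dW_neg
    db = v - db_neg
    dc = ph0 - dc_neg
    return dW, db, dc


@dataclass
class PhenotypeAssignment:
    """Medication -> pharmacophenotype membership map.

    ``membership`` maps each order key (or visible-unit index when the
    model carries no feature names) to a nonempty frozenset of labels in
    ``1..K``, or to ``{K+1}`` — the unassigned bucket — when no hidden
    unit activates for that medication.  Labels 1..K and K+1 never mix
    within one key."""

    membership: dict[object, frozenset]
    K: int
    tau: float

    @property
    def unassigned_label(self) -> int:
        return self.K + 1

    def labels(self) -> dict[object, int]:
        """Flatten to one label per key: the single member when unique,
        otherwise the smallest member label (used for reporting and
        partition-agreement metrics)."""
        return {k: min(s) for k, s in self.membership.items()}

    def to_frame(self):
        import pandas as pd

        rows = [
            {"order_key": k, "phenotype": lab}
            for k, s in self.membership.items()
            for lab in sorted(s)
        ]
        return pd.DataFrame(rows, columns=["order_key", "phenotype"])


def assign_medications(
    model: RBMModel,
    tau: float = 0.5,
    exclusive: bool = False,
    method: str = "auto",
) -> PhenotypeAssignment:
    """Assign each medication to the phenotypes whose hidden units it
    activates.

    ``method="activation"`` (the default when the model was fitted on
    data) uses the stored activation pattern: medication m joins every
    phenotype j whose unit's mean activation among patients receiving m
    exceeds ``tau`` (strict).  ``method="probe"`` instead probes the
    model with the one-hot visible vector ``e_m`` and thresholds
    ``p(h_j = 1 | e_m)`` — appropriate for hand-built or zero-offset
    models.  With ``exclusive=True`` only the single strongest
    activation is kept.  Medications activating no unit get the K+1
    bucket.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if method not in ("auto", "activation", "probe"):
        raise ValueError(f"unknown assignment method {method!r}")
    if method == "auto":
        method = "activation" if model.cond_activation is not None else "probe"
    if method == "activation":
        if model.cond_activation is None:
            raise ValueError("model carries no activation statistics; train on data "
                             "or use method='probe'")
        scores = np.asarray(model.cond_activation, dtype=float)  # (M, K)
    else:
        # hidden pre-activation for the one-hot input e_m is column m of c + W
        scores = expit(model.hidden_bias[:, None] + model.W).T   # (M, K)
    keys = model.feature_names if model.feature_names is not None else list(range(model.M))
    membership: dict[object, frozenset] = {}
    for m, key in enumerate(keys):
        active = np.nonzero(scores[m] > tau)[0]
        if len(active) == 0:
            membership[key] = frozenset({model.K + 1})
        elif exclusive:
            membership[key] = frozenset({int(np.argmax(scores[m])) + 1})
        else:
            membership[key] = frozenset(int(j) + 1 for j in active)
    return PhenotypeAssignment(membership, model.K, tau)
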