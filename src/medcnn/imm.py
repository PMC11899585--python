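"""The integrative mediation metric (IMM) network.

Each feature network k is read by its own convolutional branch — two 1D
convolutions (32 then 64 filters, kernel 5, stride 1, ReLU) each followed
by width-2 pooling (average by default, max available) — whose flattened
output is condensed by a linear unit into a scalar branch score P_k.  The K branch scores are concatenated
and a final linear unit maps them to the scalar IMM h(Z).  The whole model
is trained end-to-end by minimizing mean squared error to a target vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (DTYPE, Adam, AvgPool1d, Conv1d, Dense, Flatten,
                 MaxPool1d, ReLU, Sequential)

#: shortest feature network the two conv/pool stages support
MIN_NETWORK_SIZE = 8

CONV1_FILTERS = 32
CONV2_FILTERS = 64
KERNEL_SIZE = 5
POOL_WINDOW = 2


class InvalidArchitectureError(ValueError):
    """A network is too short for the fixed branch architecture."""


@dataclass
class TrainingMeta:
    seed: int
    epochs_total: int = 0
    learning_rate: float | None = None
    loss_history: list[float] = field(default_factory=list)


class IMMModel:
    """Composite CNN mapping a list of per-network matrices to the IMM."""

    def __init__(self, network_sizes, seed: int = 0, pooling: str = "avg"):
        self.network_sizes = tuple(int(j) for j in network_sizes)
        for k, J in enumerate(self.network_sizes):
            if J < MIN_NETWORK_SIZE:
                raise InvalidArchitectureError(
                    f"network {k} has {J} features; the branch architecture "
                    f"needs at least {MIN_NETWORK_SIZE}"
                )
        if pooling not in ("avg", "max"):
            raise ValueError("pooling must be 'avg' or 'max'")
        self.pooling = pooling
        pool_cls = AvgPool1d if pooling == "avg" else MaxPool1d
        rng = np.random.default_rng(seed)
        self.branches: list[Sequential] = []
        for J in self.network_sizes:
            flat = CONV2_FILTERS * (J // POOL_WINDOW // POOL_WINDOW)
            self.branches.append(
                Sequential([
                    Conv1d(1, CONV1_FILTERS, KERNEL_SIZE, rng),
                    ReLU(),
                    pool_cls(POOL_WINDOW),
                    Conv1d(CONV1_FILTERS, CONV2_FILTERS, KERNEL_SIZE, rng),
                    ReLU(),
                    pool_cls(POOL_WINDOW),
                    Flatten(),
                    Dense(flat, 1, rng),
                ])
            )
        self.head = Dense(len(self.network_sizes), 1, rng)
        self.meta = TrainingMeta(seed=seed)

    # -- plumbing ---------------------------------------------------------
    @property
    def K(self) -> int:
        return len(self.network_sizes)

    def params_and_grads(self):
        out = []
        for b in self.branches:
            out.extend(b.params_and_grads())
        out.extend(self.head.params_and_grads())
        return out

    def _check_input(self, Z: list[np.ndarray]) -> list[np.ndarray]:
        got = tuple(np.asarray(z).shape[1] for z in Z)
        if got != self.network_sizes:
            raise ValueError(
                f"network sizes mismatch: expected {self.network_sizes}, got {got}"
            )
        return [np.asarray(z, dtype=DTYPE) for z in Z]

    # -- forward / backward ----------------------------------------------
    def forward(self, Z: list[np.ndarray]) -> np.ndarray:
        """IMM for each sample; also returns via cache for backward."""
        P = [
            branch.forward(z[:, :, None])  # (B, J_k, 1) -> (B, 1)
            for branch, z in zip(self.branches, Z)
        ]
        self._P = np.concatenate(P, axis=1)  # (B, K)
        return self.head.forward(self._P)[:, 0]

    def backward(self, dh: np.ndarray) -> None:
        dP = self.head.backward(dh[:, None].astype(DTYPE))
        for k, branch in enumerate(self.branches):
            branch.backward(dP[:, k:k + 1])

    def predict(self, Z: list[np.ndarray], chunk: int = 1024) -> np.ndarray:
        """Deterministic IMM prediction, computed in memory-bounded chunks."""
        Z = self._check_input(Z)
        n = Z[0].shape[0]
        out = np.empty(n)
        for s in range(0, n, chunk):
            sl = slice(s, min(s + chunk, n))
            out[sl] = self.forward([z[sl] for z in Z]).astype(float)
        return out


def build_model(network_sizes, seed: int = 0, pooling: str = "avg") -> IMMModel:
    """Untrained composite model, one conv branch per feature network."""
    return IMMModel(network_sizes, seed=seed, pooling=pooling)


def train_imm(
    model: IMMModel,
    Z: list[np.ndarray],
    targets: np.ndarray,
    epochs: int = 100,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    rng: np.random.Generator | None = None,
    validation: tuple[list[np.ndarray], np.ndarray] | None = None,
    patience: int | None = None,
    lr_drops: int = 1,
    lr_drop_factor: float = 0.2,
) -> float:
    """Fit the model to scalar targets by mini-batch Adam on the MSE.

    Weights are updated in place (so the outer estimation loop can
    warm-start from the previous iteration).  Returns the final epoch's
    mean training loss; the per-epoch history accumulates in
    ``model.meta.loss_history``.

    With ``validation`` (a held-out (Z, targets) pair) and ``patience``,
    training monitors the validation MSE.  At each plateau (no improvement
    for ``patience`` consecutive epochs) the weights revert to the best
    seen so far and the learning rate is multiplied by ``lr_drop_factor``,
    up to ``lr_drops`` times; the next plateau stops training and restores
    the best-validation weights.  This keeps the network from memorizing
    sample noise in the targets — essential when the systematic part of
    the target signal is weak (e.g. under a null scenario) — while letting
    it refine a genuine signal at a finer step size.
    """
    Z = model._check_input(Z)
    r = np.asarray(targets, dtype=DTYPE)
    n = Z[0].shape[0]
    if any(z.shape[0] != n for z in Z) or len(r) != n:
        raise ValueError("row counts of Z and targets must agree")
    if not all(np.isfinite(z).all() for z in Z) or not np.isfinite(r).all():
        raise ValueError("non-finite feature or target values")
    if rng is None:
        rng = np.random.default_rng(model.meta.seed)

    def _mse() -> float:
        return float(np.mean((model.predict(Z) - r.astype(float)) ** 2))

    if epochs == 0:
        return _mse()

    use_val = validation is not None and patience is not None
    if use_val:
        Z_val = model._check_input(validation[0])
        r_val = np.asarray(validation[1], dtype=float)
        best_val = float(np.mean((model.predict(Z_val) - r_val) ** 2))
        best_weights = [p.copy() for p, _ in model.params_and_grads()]
        stall = 0
        drops_left = int(lr_drops)

    opt = Adam(model.params_and_grads(), lr=learning_rate)
    last = np.nan
    for _ in range(int(epochs)):
        perm = rng.permutation(n)
        total = 0.0
        for s in range(0, n, batch_size):
            idx = perm[s:s + batch_size]
            zb = [z[idx] for z in Z]
            pred = model.forward(zb)
            resid = pred - r[idx]
            total += float(np.sum(resid.astype(float) ** 2))
            model.backward((2.0 / len(idx)) * resid)
            opt.step()
        last = total / n
        model.meta.loss_history.append(last)
        if use_val:
            val = float(np.mean((model.predict(Z_val) - r_val) ** 2))
            if val < best_val:
                best_val = val
                best_weights = [p.copy() for p, _ in model.params_and_grads()]
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    for (p, _), w in zip(model.params_and_grads(),
                                         best_weights):
                        p[...] = w
                    if drops_left == 0:
                        break
                    drops_left -= 1
                    opt = Adam(model.params_and_grads(),
                               lr=opt.lr * lr_drop_factor)
                    stall = 0
    if use_val:
        for (p, _), w in zip(model.params_and_grads(), best_weights):
            p[...] = w
    model.meta.epochs_total += int(epochs)
    model.meta.learning_rate = learning_rate
    return last


def predict_imm(model: IMMModel, Z: list[np.ndarray]) -> np.ndarray:
    """One finite IMM value per sample (deterministic for fixed weights)."""
    return model.predict(Z)
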