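"""Dense networks for PRS regression, trained with Adam on minibatch MSE.

Three architectures are used throughout:

* the standard MLP — hidden layers of 50, 30 and 20 ReLU neurons and a
  linear output neuron (one per predicted score for the multi-predictor
  variant), trained with learning rate 1e-4 and batch size 5;
* an autoencoder that maps a subset of the SNPs to an estimate of the full
  SNP vector, hidden layers of ``n_full`` ReLU neurons and an output layer
  of ``n_full`` neurons with a sigmoid-times-two activation so predictions
  lie in (0, 2), trained with learning rate 5e-5;
* a skip variant whose last hidden layer output is concatenated with the
  raw input (unweighted passthrough) before the final mapping.

Everything is plain numpy: a trained model is an ordered list of
(weight-matrix, bias) pairs with activation tags, which is also exactly what
the text export serialises.  A linear predictor (optionally elastic-net
regularised) serves as the reweighting baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

STANDARD_HIDDEN = (50, 30, 20)
_ACTIVATIONS = ("relu", "linear", "sigmoid_times_two")


def relu(x):
    """Rectifier max(0, x), elementwise."""
    return np.maximum(0.0, x)


def _apply_activation(z: np.ndarray, tag: str) -> np.ndarray:
    if tag == "relu":
        return np.maximum(0.0, z)
    if tag == "linear":
        return z
    if tag == "sigmoid_times_two":
        return 2.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {tag!r}")


@dataclass(frozen=True)
class NetworkSpec:
    input_width: int
    hidden_widths: tuple[int, ...] = STANDARD_HIDDEN
    output_width: int = 1
    hidden_activation: str = "relu"
    output_activation: str = "linear"
    skip_input_to_last_hidden: bool = False

    def __post_init__(self) -> None:
        if self.input_width < 1 or self.output_width < 1:
            raise ValueError("widths must be positive")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("zero-width hidden layer")
        if self.output_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.output_activation!r}")
        if self.skip_input_to_last_hidden and not self.hidden_widths:
            raise ValueError("skip connection requires at least one hidden layer")

    @property
    def layer_shapes(self) -> list[tuple[int, int]]:
        """(rows, cols) of each weight matrix, input to output."""
        widths = [self.input_width, *self.hidden_widths]
        shapes = [(widths[i], widths[i + 1]) for i in range(len(widths) - 1)]
        last_in = widths[-1] + (self.input_width if self.skip_input_to_last_hidden else 0)
        shapes.append((last_in, self.output_width))
        return shapes

    @property
    def activations(self) -> list[str]:
        return [self.hidden_activation] * len(self.hidden_widths) + [self.output_activation]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 5
    max_epochs: int = 30
    patience: int = 3
    eval_every: int = 2000
    seed: int = 0
    objective: str = "mse"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.objective != "mse":
            raise ValueError("only the mse objective is supported")


AE_DEFAULT_CONFIG = TrainConfig(learning_rate=5e-5, batch_size=5)


@dataclass
class TrainedNetwork:
    """An ordered chain of (M_l, b_l) layers with activation tags.

    ``forward`` applies v_l = act_l(v_{l-1} @ M_l + b_l) layer by layer; for
    a skip network the last hidden output is concatenated with the raw input
    before the final layer.
    """

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_snp_ids: list[str] | None = None
    output_names: list[str] | None = None
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = self.spec.layer_shapes
        if len(self.weights) != len(shapes) or len(self.biases) != len(shapes):
            raise ValueError("layer count does not match spec")
        for w, b, shape in zip(self.weights, self.biases, shapes):
            if w.shape != shape or b.shape != (shape[1],):
                raise ValueError(f"layer shape {w.shape} does not chain (expected {shape})")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.spec.input_width:
            raise ValueError(
                f"input width {X.shape[1]} != network input width {self.spec.input_width}"
            )
        a = X
        acts = self.spec.activations
        for l in range(self.n_layers - 1):
            a = _apply_activation(a @ self.weights[l] + self.biases[l], acts[l])
        if self.spec.skip_input_to_last_hidden:
            a = np.hstack([a, X])
        out = _apply_activation(a @ self.weights[-1] + self.biases[-1], acts[-1])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = self.forward(X)
        return out[:, 0] if out.shape[1] == 1 else out

    def copy_params(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]


def _init_layers(spec: NetworkSpec, rng: np.random.Generator):
    weights, biases = [], []
    for rows, cols in spec.layer_shapes:
        bound = 1.0 / np.sqrt(rows)
        weights.append(rng.uniform(-bound, bound, size=(rows, cols)))
        biases.append(rng.uniform(-bound, bound, size=cols))
    return weights, biases


def build_mlp(
    input_width: int,
    hidden_widths: tuple[int, ...] = STANDARD_HIDDEN,
    output_width: int = 1,
    seed: int = 0,
    skip_input_to_last_hidden: bool = False,
    input_snp_ids: list[str] | None = None,
    output_names: list[str] | None = None,
) -> TrainedNetwork:
    """Randomly initialised MLP; the default is the standard 50/30/20 network
    with a linear output neuron.  Uniform fan-in initialisation, seeded."""
    spec = NetworkSpec(
        input_width=input_width,
        hidden_widths=tuple(hidden_widths),
        output_width=output_width,
        skip_input_to_last_hidden=skip_input_to_last_hidden,
    )
    weights, biases = _init_layers(spec, np.random.default_rng(seed))
    return TrainedNetwork(
        spec=spec, weights=weights, biases=biases,
        input_snp_ids=input_snp_ids, output_names=output_names,
    )


def build_autoencoder(
    n_input: int,
    n_full: int,
    seed: int = 0,
    input_snp_ids: list[str] | None = None,
    output_names: list[str] | None = None,
) -> TrainedNetwork:
    """Autoencoder mapping ``n_input`` retained SNPs to estimates of all
    ``n_full`` SNP values: two ReLU hidden layers of ``n_full`` neurons and a
    sigmoid-times-two output layer, so every output lies in (0, 2)."""
    if n_input < 1:
        raise ValueError("n_input must be >= 1")
    if n_input > n_full:
        raise ValueError("n_input cannot exceed n_full")
    spec = NetworkSpec(
        input_width=n_input,
        hidden_widths=(n_full, n_full),
        output_width=n_full,
        output_activation="sigmoid_times_two",
    )
    weights, biases = _init_layers(spec, np.random.default_rng(seed))
    return TrainedNetwork(
        spec=spec, weights=weights, biases=biases,
        input_snp_ids=input_snp_ids, output_names=output_names,
    )


# ---------------------------------------------------------------------------
# Training: minibatch MSE with Adam (beta1 0.9, beta2 0.999, eps 1e-8)
# ---------------------------------------------------------------------------


def _val_losses(net: TrainedNetwork, X_val, y_val) -> np.ndarray:
    err = net.forward(X_val) - y_val
    return np.mean(err * err, axis=0)


def train_regressor(
    net: TrainedNetwork,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig | None = None,
) -> TrainedNetwork:
    """Train ``net`` in place on minibatch MSE with Adam.

    Validation loss (per output column) is recorded every ``cfg.eval_every``
    iterations; training stops after ``cfg.max_epochs`` epochs or once the
    total validation loss has not improved for ``cfg.patience`` consecutive
    evaluations, and the parameters with the lowest validation loss seen are
    restored.  Reproducible from ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    X = np.ascontiguousarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    yv = np.asarray(y_val, dtype=float)
    if yv.ndim == 1:
        yv = yv[:, None]
    Xv = np.asarray(X_val, dtype=float)
    if y.shape[1] != net.spec.output_width:
        raise ValueError("y must have one column per output neuron")

    skip = net.spec.skip_input_to_last_hidden
    acts = net.spec.activations
    if acts[-1] not in ("linear", "sigmoid_times_two"):
        raise ValueError("unsupported output activation for training")
    L = len(net.weights)
    rng = np.random.default_rng(cfg.seed)
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    # Pack all parameters into one flat vector; layer matrices become views
    # into it so the whole Adam update is a handful of large vector ops
    # instead of many small per-layer ones.
    pieces = [(w.shape, w.size) for w in net.weights] + [(b.shape, b.size) for b in net.biases]
    total = sum(sz for _, sz in pieces)
    P = np.empty(total)
    G = np.zeros(total)
    Ws, bs, gWs, gbs = [], [], [], []
    off = 0
    for src, views, gviews in ((net.weights, Ws, gWs), (net.biases, bs, gbs)):
        for arr in src:
            P[off : off + arr.size] = arr.ravel()
            views.append(P[off : off + arr.size].reshape(arr.shape))
            gviews.append(G[off : off + arr.size].reshape(arr.shape))
            off += arr.size
    net.weights, net.biases = Ws, bs
    m = np.zeros(total)
    v = np.zeros(total)

    losses0 = _val_losses(net, Xv, yv)
    net.history = [{"iteration": 0, "val_loss": losses0}]
    best_loss = float(losses0.sum())
    best = P.copy()
    bad = 0
    n = X.shape[0]
    bsz = cfg.batch_size
    lr = cfg.learning_rate
    one_m_b1, one_m_b2 = 1.0 - beta1, 1.0 - beta2
    step = 0
    stop = False

    Xs = np.empty_like(X)
    ys = np.empty_like(y)
    hidden_cache: list[np.ndarray] = [None] * L  # post-activation per layer

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        np.take(X, order, axis=0, out=Xs)
        np.take(y, order, axis=0, out=ys)
        for start in range(0, n, bsz):
            xb = Xs[start : start + bsz]
            yb = ys[start : start + bsz]
            # forward
            a = xb
            for l in range(L - 1):
                a = np.maximum(a @ Ws[l] + bs[l], 0.0)
                hidden_cache[l] = a
            a_last = np.hstack([a, xb]) if skip else a
            z_out = a_last @ Ws[-1] + bs[-1]
            if acts[-1] == "linear":
                yhat = z_out
                delta = (2.0 / yb.size) * (yhat - yb)
            else:  # sigmoid_times_two
                yhat = 2.0 / (1.0 + np.exp(-z_out))
                delta = (2.0 / yb.size) * (yhat - yb) * yhat * (1.0 - 0.5 * yhat)
            if not np.all(np.isfinite(delta)):
                raise FloatingPointError(
                    f"non-finite loss at iteration {step} (lr {lr}, batch {bsz})"
                )
            # backward: write layer gradients into the packed gradient vector
            step += 1
            back = delta @ Ws[-1].T
            np.matmul(a_last.T, delta, out=gWs[-1])
            np.sum(delta, axis=0, out=gbs[-1])
            if skip:
                back = back[:, : net.spec.hidden_widths[-1]]
            for l in range(L - 2, -1, -1):
                d = back * (hidden_cache[l] > 0.0)
                a_prev = hidden_cache[l - 1] if l > 0 else xb
                if l > 0:
                    back = d @ Ws[l].T
                np.matmul(a_prev.T, d, out=gWs[l])
                np.sum(d, axis=0, out=gbs[l])
            # fused Adam step on the packed vector
            m *= beta1
            m += one_m_b1 * G
            v *= beta2
            G *= G
            v += one_m_b2 * G
            upd = m / (1.0 - beta1**step)
            denom = np.sqrt(v / (1.0 - beta2**step))
            denom += eps
            upd /= denom
            upd *= lr
            P -= upd

            if step % cfg.eval_every == 0:
                losses = _val_losses(net, Xv, yv)
                net.history.append({"iteration": step, "val_loss": losses})
                total_loss = float(losses.sum())
                if total_loss < best_loss:
                    best_loss = total_loss
                    best = P.copy()
                    bad = 0
                else:
                    bad += 1
                    if bad >= cfg.patience:
                        stop = True
                        break
        if stop:
            break

    final = _val_losses(net, Xv, yv)
    if float(final.sum()) < best_loss:
        best = P.copy()
    P[:] = best
    # detach parameters from the packed buffer
    net.weights = [w.copy() for w in Ws]
    net.biases = [b.copy() for b in bs]
    return net


def train_autoencoder(
    ae: TrainedNetwork,
    X_subset: np.ndarray,
    X_full: np.ndarray,
    X_subset_val: np.ndarray,
    X_full_val: np.ndarray,
    cfg: TrainConfig | None = None,
) -> TrainedNetwork:
    """Train the autoencoder to reconstruct the full SNP vector from the
    retained subset, minimising MSE against the original intact inputs."""
    return train_regressor(ae, X_subset, X_full, X_subset_val, X_full_val,
                           cfg or replace(AE_DEFAULT_CONFIG))


def predict_ae_mlp(
    ae: TrainedNetwork, mlp_full: TrainedNetwork, X_subset: np.ndarray
) -> np.ndarray:
    """AE-MLP composition: reconstruct the full SNP vector with the
    autoencoder, then score it with the full-SNP-trained MLP."""
    if ae.spec.output_width != mlp_full.spec.input_width:
        raise ValueError("AE output width does not match MLP input width")
    if (
        ae.output_names is not None
        and mlp_full.input_snp_ids is not None
        and list(ae.output_names) != list(mlp_full.input_snp_ids)
    ):
        raise ValueError("AE output SNP order does not match MLP input SNP order")
    return mlp_full.predict(ae.forward(X_subset))


# ---------------------------------------------------------------------------
# Linear predictor (reweighting baseline), optionally elastic net
# ---------------------------------------------------------------------------

DEFAULT_LAMBDA_GRID = (0.0, *np.logspace(-4, 0, 7))


@dataclass
class LinearModel:
    weights: np.ndarray
    intercept: float
    lambda1: float = 0.0
    lambda2: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept


def _solve_penalized(X, y, lam1, lam2):
    n = X.shape[0]
    if lam1 == 0.0 and lam2 == 0.0:
        Xa = np.hstack([X, np.ones((n, 1))])
        sol, _, rank, _ = np.linalg.lstsq(Xa, y, rcond=None)
        if rank < Xa.shape[1]:
            warnings.warn("rank-deficient design; using the minimum-norm solution")
        return sol[:-1], float(sol[-1])
    from sklearn.linear_model import ElasticNet

    # target: ||y - Xw||^2 + lam1*||w||_1 + lam2*||w||^2; sklearn minimises
    # (1/2n)||y - Xw||^2 + alpha*l1_ratio*||w||_1 + (alpha/2)*(1-l1_ratio)*||w||^2
    alpha = lam1 / (2 * n) + lam2 / n
    l1_ratio = (lam1 / (2 * n)) / alpha
    est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=True, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est.coef_.copy(), float(est.intercept_)


def fit_linear(
    X: np.ndarray,
    y: np.ndarray,
    elastic_net: tuple | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> LinearModel:
    """Ordinary least squares with an intercept; with ``elastic_net`` a
    (λ1 grid, λ2 grid) pair, grid-search the penalised form and pick the
    winner by validation MSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if elastic_net is None:
        w, b = _solve_penalized(X, y, 0.0, 0.0)
        return LinearModel(weights=w, intercept=b)
    if X_val is None or y_val is None:
        raise ValueError("elastic-net grid search requires validation data")
    lam1_grid, lam2_grid = elastic_net
    best = None
    for lam1 in lam1_grid:
        for lam2 in lam2_grid:
            w, b = _solve_penalized(X, y, float(lam1), float(lam2))
            mse = float(np.mean((np.asarray(X_val) @ w + b - np.asarray(y_val).ravel()) ** 2))
            if best is None or mse < best[0]:
                best = (mse, w, b, float(lam1), float(lam2))
    _, w, b, l1, l2 = best
    return LinearModel(weights=w, intercept=b, lambda1=l1, lambda2=l2)
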