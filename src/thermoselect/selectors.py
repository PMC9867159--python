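"""Variational- and concrete-dropout input gates as embedded feature selectors.

A small classifier (input gate layer -> two ReLU hidden layers with ordinary
dropout -> softmax) is trained while a per-feature stochastic gate sits
between the inputs and the first weight layer:

* variational gates multiply feature j by θ_j(1 + √α_j ε), ε ~ N(0,1), so the
  gate weight has the posterior N(θ_j, α_j θ_j²); the learned noise level α_j
  is the relevance signal (large α = the feature is indistinguishable from
  noise). The training loss is the mini-batch evidence-lower-bound estimator:
  N/M times the batch NLL plus a KL term (Molchanov's log-uniform-prior
  approximation), annealed by a Lagrange multiplier λ.
* concrete gates draw a relaxed Bernoulli drop indicator
  d = σ((logit ρ_j + logit ε)/t), ε ~ U(0,1), and multiply feature j by the
  keep gate 1 − d; the learned drop probability ρ_j is the relevance signal.
  The loss is the mean batch NLL plus λ times a smooth count of active
  features, mean_j (1 − ρ_j).

After training, a threshold τ on the effective drop probability yields a
sparse mask, and 1 − ρ_eff orders the features into a ranking.

Everything here is plain numpy with manual backpropagation and a hand-written
Adam optimizer; the networks involved are small enough that autodiff
frameworks would add nothing but weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CVSplit, zscore_apply, zscore_fit

VARIATIONAL, CONCRETE = "variational", "concrete"

# Molchanov log-uniform KL approximation constants
_K1, _K2, _K3 = 0.63576, 1.87320, 1.48695


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol for the gated classifier.

    The learning rate default depends on the gate kind (1e-2 for concrete,
    1e-3 for variational); pass ``lr`` explicitly to override.
    """

    lr: float | None = None
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 500
    batch_size: int = 32
    min_batch: int = 4  # a shorter final batch is merged into the previous one
    lambda_step: float = 2.5e-3  # λ anneal rate per epoch, capped at 1
    hidden: tuple[int, ...] = (64, 32)
    hidden_dropout: float = 0.2
    tau: float = 0.9
    temperature: float = 0.1  # concrete relaxation temperature
    init_drop_logit: float = -2.1972245773362196  # logit(0.1): gates mostly open
    init_log_alpha: float = -1.0
    seed: int = 0

    def resolve_lr(self, kind: str) -> float:
        if self.lr is not None:
            return self.lr
        return 1e-2 if kind == CONCRETE else 1e-3


# ---------------------------------------------------------------------------
# elementary sampling operations


def binary_dropout_mask(rho: float, shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Bernoulli mask with inverted scaling (expectation 1).

    Entries are 0 with probability ``rho`` (the drop probability) and
    1/(1−rho) otherwise.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"drop probability must lie in [0, 1), got {rho}")
    if rho == 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rho
    return keep / (1.0 - rho)


def sample_variational_weights(
    theta: np.ndarray, alpha: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reparameterized Gaussian-dropout weights w = θ(1 + √α ε), ε ~ N(0,1).

    Var(w) = α θ², matching the posterior N(θ, αθ²).
    """
    theta = np.asarray(theta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if (alpha < 0).any():
        raise ValueError("alpha must be non-negative")
    eps = rng.standard_normal(np.broadcast(theta, alpha).shape)
    return theta * (1.0 + np.sqrt(alpha) * eps)


def sample_concrete_gate(
    rho: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    """Relaxed Bernoulli keep-gate in (0, 1).

    The drop indicator is d = σ((log ρ − log(1−ρ) + log ε − log(1−ε))/t) with
    ε ~ U(0,1); the returned keep gate is 1 − d. Low temperatures t make the
    gate nearly binary.
    """
    rho = np.asarray(rho, dtype=float)
    if not ((rho > 0) & (rho < 1)).all():
        raise ValueError("rho must lie strictly in (0, 1)")
    if not 0.0 < t <= 1.0:
        raise ValueError(f"temperature must lie in (0, 1], got {t}")
    eps = rng.uniform(np.finfo(float).tiny, 1.0, size=np.shape(rho))
    u = (np.log(rho) - np.log1p(-rho) + np.log(eps) - np.log1p(-eps)) / t
    d = _sigmoid(u)
    return 1.0 - d


# ---------------------------------------------------------------------------
# losses


def variational_kl(log_alpha: np.ndarray) -> float:
    """KL(q||p) to the log-uniform prior, Molchanov's approximation, summed.

    Per feature: −(k1 σ(k2 + k3 log α) − 0.5 log(1 + 1/α) − k1). Monotonically
    decreasing in log α; tends to 0 as α → ∞.
    """
    log_alpha = np.asarray(log_alpha, dtype=float)
    if not np.isfinite(log_alpha).all():
        raise ValueError("non-finite log alpha")
    neg_kl = _K1 * _sigmoid(_K2 + _K3 * log_alpha) - 0.5 * np.log1p(np.exp(-log_alpha)) - _K1
    return float(-neg_kl.sum())


def variational_kl_grad(log_alpha: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`variational_kl` w.r.t. log α."""
    log_alpha = np.asarray(log_alpha, dtype=float)
    s = _sigmoid(_K2 + _K3 * log_alpha)
    # KL = -k1 σ(k2+k3 la) + 0.5 log(1+e^{-la}) + k1
    return -_K1 * _K3 * s * (1.0 - s) - 0.5 * _sigmoid(-log_alpha)


def concrete_penalty(rho: np.ndarray) -> float:
    """Smooth count of active features: mean_j P(feature j stays active).

    The CDF of the Bernoulli drop indicator at 0 is 1 − ρ_j, so the penalty
    is (1/D) Σ_j (1 − ρ_j): 1 when everything is kept, 0 when everything is
    dropped.
    """
    rho = np.asarray(rho, dtype=float)
    if not ((rho >= 0) & (rho <= 1)).all():
        raise ValueError("rho must lie in [0, 1]")
    return float(np.mean(1.0 - rho))


def lambda_schedule(epoch: int, step: float = 2.5e-3) -> float:
    """Linear λ anneal: min(1, step × epoch)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return min(1.0, step * epoch)


def sgvb_objective(
    log_likelihood_sum: float,
    kl_term: float,
    n_total: int,
    batch_size: int,
    lam: float,
) -> float:
    """Minimization form of the mini-batch evidence-lower-bound estimator.

    loss = −(N/M) Σ_batch log p(y|x, gates) + λ · KL
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if not (np.isfinite(log_likelihood_sum) and np.isfinite(kl_term)):
        raise ValueError("non-finite objective terms")
    return -(n_total / batch_size) * log_likelihood_sum + lam * kl_term


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# selector state and ranking results


@dataclass
class SelectorState:
    """Trained per-feature gate parameters of one selector."""

    kind: str  # "variational" | "concrete"
    feature_names: list[str]
    theta: np.ndarray  # gate weights (variational); unused ones for concrete
    noise_param: np.ndarray  # log α (variational) | drop-probability logit (concrete)
    temperature: float | None = None  # concrete only

    @property
    def drop_probability(self) -> np.ndarray:
        """Effective per-feature drop probability ρ_eff.

        Variational gates use ρ = α/(1+α), inverting α = ρ/(1−ρ); concrete
        gates carry ρ directly (via the logit parameter).
        """
        if self.kind == VARIATIONAL:
            return _sigmoid(self.noise_param)  # α/(1+α) = σ(log α)
        return _sigmoid(self.noise_param)

    @property
    def alpha(self) -> np.ndarray:
        if self.kind != VARIATIONAL:
            raise AttributeError("alpha only defined for variational selectors")
        return np.exp(self.noise_param)


@dataclass
class RankingResult:
    """A feature ranking with a binary keep mask, common to all methods."""

    method: str
    feature_names: list[str]
    scores: np.ndarray  # per-feature relevance, aligned with feature_names
    keep_mask: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if not (len(self.feature_names) == len(self.scores) == len(self.keep_mask)):
            raise ValueError("feature_names, scores and keep_mask lengths differ")

    @property
    def order(self) -> list[str]:
        """Feature names in descending relevance, ties broken by name."""
        idx = sorted(range(len(self.feature_names)),
                     key=lambda i: (-self.scores[i], self.feature_names[i]))
        return [self.feature_names[i] for i in idx]

    @property
    def sparse_rate(self) -> float:
        return float(1.0 - self.keep_mask.mean())

    def top(self, k: int) -> list[str]:
        return self.order[:k]

    def rank_of(self) -> dict[str, int]:
        """1-based rank per feature name."""
        return {name: i + 1 for i, name in enumerate(self.order)}

    def to_json(self) -> dict:
        return {
            "method": self.method,
            "feature_names": list(self.feature_names),
            "scores": self.scores.tolist(),
            "keep_mask": self.keep_mask.astype(int).tolist(),
            "sparse_rate": self.sparse_rate,
            "order": self.order,
        }

    @classmethod
    def from_json(cls, d: dict) -> "RankingResult":
        return cls(
            method=d["method"],
            feature_names=list(d["feature_names"]),
            scores=np.array(d["scores"], dtype=float),
            keep_mask=np.array(d["keep_mask"], dtype=bool),
        )

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        d = self.to_json()
        if extra:
            d.update(extra)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RankingResult":
        return cls.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# the gated MLP with manual backprop


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, betas: tuple[float, float]):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _init_params(kind: str, d: int, hidden: tuple[int, ...], config: TrainConfig,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    sizes = (d, *hidden, 2)
    for i, (fan_in, fan_out) in enumerate(zip(sizes, sizes[1:])):
        params[f"W{i}"] = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
        params[f"b{i}"] = np.zeros(fan_out)
    if kind == VARIATIONAL:
        # additive parametrization: gate = θ + σ ε with σ² = α θ², so the KL
        # can shrink θ and let α = σ²/θ² grow without bound for noise features
        params["theta"] = np.ones(d)
        params["noise"] = np.full(d, config.init_log_alpha)  # log σ² (θ=1 ⇒ = log α)
    else:
        params["theta"] = np.ones(d)  # fixed at 1; concrete gates scale inputs directly
        params["noise"] = np.full(d, config.init_drop_logit)  # logit of drop prob ρ
    return params


def _log_alpha(theta: np.ndarray, log_sigma2: np.ndarray) -> np.ndarray:
    """log α = log σ² − log θ² for the additive variational parametrization."""
    return log_sigma2 - np.log(theta**2 + 1e-10)


def _forward_backward(
    X: np.ndarray,
    y: np.ndarray,
    params: dict[str, np.ndarray],
    kind: str,
    config: TrainConfig,
    lam: float,
    n_total: int,
    n_hidden_layers: int,
    rng: np.random.Generator,
) -> tuple[float, float, dict[str, np.ndarray]]:
    """One training batch: total loss, mean per-sample NLL, and gradients."""
    m, d = X.shape

    # --- gate layer
    if kind == VARIATIONAL:
        # gate = θ + σ ε  ~  N(θ, σ²) with σ² = αθ²: identical in law to
        # θ(1 + √α ε), but trained through (θ, log σ²)
        sigma = np.exp(0.5 * params["noise"])
        eps = rng.standard_normal((m, d))
        gate = params["theta"] + sigma * eps  # (m, d)
    else:
        logit_rho = params["noise"]
        u = rng.uniform(np.finfo(float).tiny, 1.0, size=(m, d))
        pre = (logit_rho + np.log(u) - np.log1p(-u)) / config.temperature
        drop = _sigmoid(pre)
        gate = 1.0 - drop
    xt = X * gate

    # --- MLP forward with ordinary (inverted) dropout on hidden layers
    acts = [xt]
    drop_masks = []
    h = xt
    for i in range(n_hidden_layers):
        z = h @ params[f"W{i}"] + params[f"b{i}"]
        h = np.maximum(z, 0.0)
        mask = binary_dropout_mask(config.hidden_dropout, h.shape, rng)
        h = h * mask
        drop_masks.append((z, mask))
        acts.append(h)
    logits = h @ params[f"W{n_hidden_layers}"] + params[f"b{n_hidden_layers}"]

    # --- softmax cross-entropy
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    loglik = np.log(probs[np.arange(m), y] + 1e-300)
    nll_sum = -float(loglik.sum())

    if kind == VARIATIONAL:
        la = np.clip(_log_alpha(params["theta"], params["noise"]), -10, 10)
        reg = variational_kl(la)
        data_scale = n_total / m  # SGVB: N/M × batch sum
        loss = data_scale * nll_sum + lam * reg
    else:
        reg = concrete_penalty(_sigmoid(params["noise"]))
        data_scale = 1.0 / m  # batch mean
        loss = data_scale * nll_sum + lam * reg
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")

    # --- backward
    grads: dict[str, np.ndarray] = {}
    dlogits = probs.copy()
    dlogits[np.arange(m), y] -= 1.0  # d(nll_sum)/dlogits
    dlogits *= data_scale

    dh = dlogits
    for i in range(n_hidden_layers, -1, -1):
        a_prev = acts[i]
        grads[f"W{i}"] = a_prev.T @ dh
        grads[f"b{i}"] = dh.sum(axis=0)
        if i > 0:
            da = dh @ params[f"W{i}"].T
            z, mask = drop_masks[i - 1]
            dh = da * mask * (z > 0)
    dxt = dh @ params["W0"].T  # gradient w.r.t. gated inputs

    if kind == VARIATIONAL:
        dgate = dxt * X
        grads["theta"] = dgate.sum(axis=0)
        # d gate/d log σ² = σ ε / 2
        grads["noise"] = (dgate * eps * sigma * 0.5).sum(axis=0)
        # KL depends on log α = log σ² − log θ²: it pushes σ² up AND θ toward 0
        klp = variational_kl_grad(la)
        grads["noise"] += lam * klp
        grads["theta"] += lam * klp * (-2.0 * params["theta"] / (params["theta"] ** 2 + 1e-10))
    else:
        dgate = dxt * X  # d loss / d keep-gate
        # keep = 1 - σ(pre); d keep/d logit_rho = -σ'(pre)/t
        ddrop = -dgate
        dpre = ddrop * drop * (1.0 - drop)
        grads["noise"] = dpre.sum(axis=0) / config.temperature
        # penalty: λ · mean(1-ρ); d/d logit = -λ σ'(logit)/D
        rho = _sigmoid(params["noise"])
        grads["noise"] += lam * (-rho * (1.0 - rho) / d)
        grads["theta"] = np.zeros(d)

    return float(loss), nll_sum / m, grads


def train_selector(
    table: pd.DataFrame | np.ndarray,
    labels: np.ndarray | None = None,
    kind: str = CONCRETE,
    config: TrainConfig = TrainConfig(),
    standardize: bool = True,
) -> tuple[SelectorState, pd.DataFrame]:
    """Train a gated classifier and return the gate state plus a training log.

    ``table`` may be a DataFrame (a ``label`` column is used if ``labels`` is
    None) or a plain array. The log holds one row per epoch with the mean
    batch loss and the sparse rate at the configured τ.
    """
    if kind not in (VARIATIONAL, CONCRETE):
        raise ValueError(f"kind must be 'variational' or 'concrete', got {kind!r}")
    if isinstance(table, pd.DataFrame):
        from .preprocess import LABEL_COL, feature_columns

        cols = feature_columns(table)
        X = table[cols].to_numpy(dtype=float)
        if labels is None:
            if LABEL_COL not in table.columns:
                raise ValueError("labels not given and table lacks a label column")
            labels = table[LABEL_COL].to_numpy()
        names = list(cols)
    else:
        X = np.asarray(table, dtype=float)
        names = [f"f{j:03d}" for j in range(X.shape[1])]
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n, d = X.shape
    if n < 2 * config.batch_size:
        raise ValueError("need at least two batches per epoch")

    if standardize:
        mu, sd = zscore_fit(X)
        X = zscore_apply(X, mu, sd)

    rng = np.random.default_rng(config.seed)
    params = _init_params(kind, d, config.hidden, config, rng)
    opt = _Adam(params, config.resolve_lr(kind), config.betas)
    n_hidden = len(config.hidden)

    log_rows = []
    for epoch in range(config.epochs):
        lam = lambda_schedule(epoch, config.lambda_step)
        perm = rng.permutation(n)
        starts = list(range(0, n, config.batch_size))
        # merge a too-short final batch into the previous one
        if len(starts) > 1 and n - starts[-1] < config.min_batch:
            starts.pop()
        losses, data_losses = [], []
        for bi, s in enumerate(starts):
            e = starts[bi + 1] if bi + 1 < len(starts) else n
            idx = perm[s:e]
            try:
                loss, data_loss, grads = _forward_backward(
                    X[idx], y[idx], params, kind, config, lam, n, n_hidden, rng
                )
            except FloatingPointError as err:
                raise RuntimeError(f"non-finite loss at epoch {epoch}") from err
            opt.step(params, grads)
            losses.append(loss)
            data_losses.append(data_loss)
        if kind == VARIATIONAL:
            rho_eff = _sigmoid(np.clip(_log_alpha(params["theta"], params["noise"]), -60, 60))
        else:
            rho_eff = _sigmoid(params["noise"])
        log_rows.append(
            {
                "epoch": epoch,
                "lambda": lam,
                "loss": float(np.mean(losses)),
                "data_loss": float(np.mean(data_losses)),  # mean per-sample NLL
                "sparse_rate": float((rho_eff > config.tau).mean()),
            }
        )

    noise_param = params["noise"].copy()
    if kind == VARIATIONAL:
        noise_param = np.clip(_log_alpha(params["theta"], params["noise"]), -60, 60)
    state = SelectorState(
        kind=kind,
        feature_names=names,
        theta=params["theta"].copy(),
        noise_param=noise_param,
        temperature=config.temperature if kind == CONCRETE else None,
    )
    return state, pd.DataFrame(log_rows)


def rank_and_sparsify(state: SelectorState, tau: float = 0.9) -> RankingResult:
    """Threshold the effective drop probabilities into a ranking + keep mask.

    Relevance score is 1 − ρ_eff; a feature is kept when ρ_eff ≤ τ (the
    boundary is keep-inclusive; only strictly noisier gates are dropped).
    """
    rho_eff = state.drop_probability
    return RankingResult(
        method=f"{state.kind}_dropout",
        feature_names=list(state.feature_names),
        scores=1.0 - rho_eff,
        keep_mask=rho_eff <= tau,
    )


def aggregate_over_folds(results: list[RankingResult]) -> RankingResult:
    """Average per-feature relevance over folds and recompute the ordering.

    The keep mask is re-derived by majority vote over folds.
    """
    if not results:
        raise ValueError("no fold results to aggregate")
    names = results[0].feature_names
    for r in results[1:]:
        if r.feature_names != names:
            raise ValueError("fold results cover different feature sets")
    scores = np.mean([r.scores for r in results], axis=0)
    keep = np.mean([r.keep_mask for r in results], axis=0) >= 0.5
    return RankingResult(
        method=results[0].method,
        feature_names=list(names),
        scores=scores,
        keep_mask=keep,
    )


def train_selector_cv(
    table: pd.DataFrame,
    labels: np.ndarray,
    kind: str,
    folds: CVSplit,
    config: TrainConfig = TrainConfig(),
) -> tuple[RankingResult, list[pd.DataFrame]]:
    """Train one selector per training fold and aggregate the rankings."""
    from .preprocess import feature_columns

    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    per_fold, logs = [], []
    for f, (train, _) in enumerate(folds.iter_folds()):
        cfg = replace(config, seed=config.seed + f)
        sub = pd.DataFrame(X[train], columns=cols)
        state, log = train_selector(sub, y[train], kind=kind, config=cfg)
        per_fold.append(rank_and_sparsify(state, cfg.tau))
        logs.append(log)
    return aggregate_over_folds(per_fold), logs
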