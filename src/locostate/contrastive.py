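"""Supervised contrastive embedding of feature windows with KNN decoding.

The encoder is a temporal convolutional network: it maps the trailing
``receptive_field`` samples of the (z-scored) feature matrix to a point on
the unit sphere in ``output_dim`` dimensions (default 3). Training minimizes
an InfoNCE loss with cosine similarity at a fixed temperature: for each
anchor window a positive window is drawn from samples sharing the anchor's
state label within ``time_offset`` samples, and the other positives in the
batch act as negatives. Embeddings are evaluated with a cosine-metric
K-nearest-neighbor decoder (k = 3) and feature importance is the drop in
decoder f1 after permuting one feature column of the test block before
embedding.

The network and its gradients are implemented directly in NumPy (float32,
Adam optimizer), sized for CPU-scale training. The full-scale "paper"
profile (batch 512, 50,000 iterations) is retained as a named profile; the
default "desk" profile (batch 128, 2,000 iterations) is what tests and the
worked examples run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import (balanced_accuracy_score, confusion_matrix,
                             f1_score, precision_score, recall_score)
from sklearn.neighbors import NearestNeighbors

from .core import UNLABELED
from .errors import ConfigurationError, ShapeError, ValidationError

PROFILES = {
    "desk": dict(batch_size=128, max_iterations=2000),
    "paper": dict(batch_size=512, max_iterations=50000),
}


@dataclass
class EmbeddingConfig:
    """Hyperparameters of the contrastive encoder and its training."""

    receptive_field: int = 200  # samples; 1 s at the 200 Hz feature rate
    output_dim: int = 3
    hidden_width: int = 32
    temperature: float = 0.1
    batch_size: int = 128
    learning_rate: float = 5e-4
    max_iterations: int = 2000
    time_offset: int = 200  # positive-sampling range in samples
    seed: int = 0
    log_every: int = 25

    def __post_init__(self):
        if self.output_dim < 2:
            raise ConfigurationError("output_dim must be >= 2")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.receptive_field < 1:
            raise ConfigurationError("receptive_field must be >= 1")

    @staticmethod
    def profile(name: str, **overrides) -> "EmbeddingConfig":
        if name not in PROFILES:
            raise ConfigurationError(f"unknown profile {name!r}")
        return EmbeddingConfig(**{**PROFILES[name], **overrides})

    def with_(self, **overrides) -> "EmbeddingConfig":
        return replace(self, **overrides)


def conv_plan(receptive_field: int) -> list[tuple[int, int]]:
    """(kernel, stride) per layer; valid convolutions reducing R -> 1.

    The 1-s default (R = 200) uses the fixed 6-layer plan
    (8,8)(3,1)(3,2)(3,2)(3,1)(3,1); other receptive fields get an
    automatically built plan whose depth may differ.
    """
    if receptive_field == 200:
        return [(8, 8), (3, 1), (3, 2), (3, 2), (3, 1), (3, 1)]
    R = receptive_field
    if R == 1:
        return [(1, 1)]
    d = max(1, R // 25)
    while R % d:
        d -= 1
    plan: list[tuple[int, int]] = []
    L = R
    if d > 1:
        plan.append((d, d))
        L = R // d
    while L > 3:
        if (L - 3) % 2 == 0:
            plan.append((3, 2))
            L = (L - 3) // 2 + 1
        else:
            plan.append((2, 1))
            L -= 1
    if L == 3:
        plan.append((3, 1))
    elif L == 2:
        plan.append((2, 1))
    return plan


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))
_GELU_A = np.float32(0.044715)


def _gelu(x):
    """tanh-approximation GELU; returns (value, cached tanh term)."""
    t = np.tanh(_GELU_C * (x + _GELU_A * x * x * x))
    return np.float32(0.5) * x * (1.0 + t), t


def _gelu_grad(x, t):
    """GELU derivative reusing the cached tanh term (no transcendentals)."""
    inner = _GELU_C * (1.0 + 3.0 * _GELU_A * x * x)
    return np.float32(0.5) * (1.0 + t) + np.float32(0.5) * x * (1.0 - t * t) * inner


class _ConvEncoder:
    """Stack of valid 1-D convolutions with GELU, ending at length 1."""

    def __init__(self, n_features: int, cfg: EmbeddingConfig, rng: np.random.Generator):
        self.plan = conv_plan(cfg.receptive_field)
        widths = [n_features] + [cfg.hidden_width] * (len(self.plan) - 1) + [cfg.output_dim]
        self.params: list[list[np.ndarray]] = []
        for (k, _s), cin, cout in zip(self.plan, widths[:-1], widths[1:]):
            fan_in = k * cin
            w = rng.standard_normal((fan_in, cout)).astype(np.float32) * np.sqrt(2.0 / fan_in)
            b = np.zeros(cout, dtype=np.float32)
            self.params.append([w, b])
        self.widths = widths

    @staticmethod
    def _frames(a: np.ndarray, k: int, s: int) -> np.ndarray:
        # a: (B, L, C) -> (B, L_out, k*C), flatten order (k, C)
        v = sliding_window_view(a, k, axis=1)[:, ::s]  # (B, L_out, C, k)
        return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
            a.shape[0], v.shape[1], -1)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, R, F) float32 -> unit-norm (B, output_dim)."""
        cache = []
        a = x
        for li, ((k, s), (w, b)) in enumerate(zip(self.plan, self.params)):
            fr = self._frames(a, k, s)
            z = fr @ w + b
            if li < len(self.plan) - 1:
                a, t = _gelu(z)
            else:
                a, t = z, None
            if want_cache:
                cache.append((fr, z, t))
        z_out = a[:, 0, :]  # length-1 time axis
        norm = np.sqrt((z_out ** 2).sum(axis=1, keepdims=True))
        norm = np.maximum(norm, 1e-12).astype(np.float32)
        y = z_out / norm
        if want_cache:
            return y, (cache, z_out, norm)
        return y

    def backward(self, dy: np.ndarray, cache_pack) -> list[list[np.ndarray]]:
        cache, z_out, norm = cache_pack
        y = z_out / norm
        dz = (dy - y * (y * dy).sum(axis=1, keepdims=True)) / norm
        da = dz[:, None, :]  # back to (B, 1, C)
        grads = [None] * len(self.params)
        for li in range(len(self.plan) - 1, -1, -1):
            k, s = self.plan[li]
            w, _b = self.params[li]
            fr, z, t = cache[li]
            dzl = da if li == len(self.plan) - 1 else da * _gelu_grad(z, t)
            B, L_out, _ = dzl.shape
            grads[li] = [
                fr.reshape(-1, fr.shape[-1]).T @ dzl.reshape(-1, dzl.shape[-1]),
                dzl.sum(axis=(0, 1)),
            ]
            if li > 0:
                dfr = (dzl @ w.T).reshape(B, L_out, k, -1)
                cin = dfr.shape[-1]
                L_in = (L_out - 1) * s + k
                da_prev = np.zeros((B, L_in, cin), dtype=np.float32)
                pos = s * np.arange(L_out)
                for ki in range(k):
                    da_prev[:, pos + ki, :] += dfr[:, :, ki, :]
                da = da_prev
        return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [[np.zeros_like(p) for p in group] for group in params]
        self.v = [[np.zeros_like(p) for p in group] for group in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for gi, group in enumerate(params):
            for pi, p in enumerate(group):
                g = grads[gi][pi].astype(np.float32)
                self.m[gi][pi] = self.b1 * self.m[gi][pi] + (1 - self.b1) * g
                self.v[gi][pi] = self.b2 * self.v[gi][pi] + (1 - self.b2) * g * g
                mh = self.m[gi][pi] / c1
                vh = self.v[gi][pi] / c2
                p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _window_view(X: np.ndarray, rf: int) -> np.ndarray:
    # (n, F) -> view (n - rf + 1, F, rf); gather + transpose at use site
    return sliding_window_view(X, rf, axis=0)


def _gather_windows(view: np.ndarray, ends: np.ndarray, rf: int) -> np.ndarray:
    """Windows ending (inclusive) at sample indices ``ends`` -> (B, rf, F)."""
    w = view[ends - rf + 1]  # (B, F, rf)
    return np.ascontiguousarray(w.transpose(0, 2, 1), dtype=np.float32)


def _run_bounds(runs: np.ndarray):
    starts = np.zeros(len(runs), dtype=np.int64)
    current = 0
    for i in range(1, len(runs)):
        if runs[i] != runs[i - 1]:
            current = i
        starts[i] = current
    return starts


class ContrastiveEmbedding:
    """Model object: feature matrix + labels + config; ``fit()`` trains."""

    def __init__(self, X, labels, runs=None, config: EmbeddingConfig | None = None,
                 feature_names: list[str] | None = None):
        self.X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        if self.X.ndim != 2:
            raise ShapeError("X must be 2-D (samples x features)")
        self.labels = np.asarray(labels, dtype=object)
        if self.labels.shape[0] != self.X.shape[0]:
            raise ShapeError("labels must match sample count")
        self.runs = (np.asarray(runs, dtype=object) if runs is not None
                     else np.zeros(len(self.X), dtype=object))
        self.config = config or EmbeddingConfig()
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{j}" for j in range(self.X.shape[1])])
        rf = self.config.receptive_field
        if self.X.shape[0] < rf:
            raise ShapeError("fewer samples than the receptive field")
        run_starts = _run_bounds(self.runs)
        idx = np.arange(len(self.X))
        # a window is valid when it lies entirely inside one run
        self.valid = idx - (rf - 1) >= run_starts
        self.anchor_pool = np.flatnonzero(self.valid & (self.labels != UNLABELED))
        if len(self.anchor_pool) < self.config.batch_size:
            raise ConfigurationError(
                f"{len(self.anchor_pool)} labeled window positions < batch_size "
                f"{self.config.batch_size}")
        self._by_label = {
            lab: self.anchor_pool[self.labels[self.anchor_pool] == lab]
            for lab in set(self.labels[self.anchor_pool].tolist())}
        for lab, pool in self._by_label.items():
            if len(pool) < 2:
                raise ConfigurationError(
                    f"label {lab!r} has too few windows for positive sampling")

    def _sample_positive(self, t: int, rng: np.random.Generator) -> int:
        lab = self.labels[t]
        off = self.config.time_offset
        lo, hi = t - off, t + off
        seg = self._by_label[lab]
        lo_i = np.searchsorted(seg, lo)
        hi_i = np.searchsorted(seg, hi, side="right")
        cands = seg[lo_i:hi_i]
        cands = cands[(cands != t) & (self.runs[cands] == self.runs[t])]
        if len(cands) == 0:
            cands = seg[seg != t]
        return int(cands[rng.integers(len(cands))])

    def fit(self) -> "EmbeddingResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        enc = _ConvEncoder(self.X.shape[1], cfg, rng)
        opt = _Adam(enc.params, cfg.learning_rate)
        view = _window_view(self.X, cfg.receptive_field)
        tau = cfg.temperature
        trace: list[tuple[int, float]] = []
        B = cfg.batch_size
        for it in range(cfg.max_iterations):
            anchors = self.anchor_pool[rng.integers(len(self.anchor_pool), size=B)]
            positives = np.array([self._sample_positive(t, rng) for t in anchors])
            xb = _gather_windows(view, np.concatenate([anchors, positives]),
                                 cfg.receptive_field)
            yb, cb = enc.forward(xb, want_cache=True)
            ya, yp = yb[:B], yb[B:]
            S = (ya @ yp.T) / tau
            S -= S.max(axis=1, keepdims=True)
            expS = np.exp(S)
            Z = expS.sum(axis=1, keepdims=True)
            loss = float(np.mean(np.log(Z[:, 0]) - S[np.arange(B), np.arange(B)]))
            if not np.isfinite(loss):
                raise ValidationError(f"non-finite InfoNCE loss at iteration {it}")
            dS = (expS / Z - np.eye(B, dtype=np.float32)) / B
            dyb = np.concatenate([(dS @ yp) / tau, (dS.T @ ya) / tau])
            grads = enc.backward(dyb.astype(np.float32), cb)
            opt.step(enc.params, grads)
            if it % cfg.log_every == 0 or it == cfg.max_iterations - 1:
                trace.append((it, loss))
        return EmbeddingResults(enc, cfg, trace, self.feature_names)


class EmbeddingResults:
    """Trained encoder: deterministic embedding, loss trace, summary."""

    def __init__(self, encoder: _ConvEncoder, config: EmbeddingConfig,
                 loss_trace, feature_names):
        self.encoder = encoder
        self.config = config
        self.loss_trace = list(loss_trace)
        self.feature_names = list(feature_names)

    @property
    def initial_loss(self) -> float:
        return self.loss_trace[0][1]

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1][1]

    def embed(self, X, runs=None, hop: int = 1,
              feature_names: list[str] | None = None):
        """Embed every valid (within-run, trailing) window position.

        Returns ``(coords, positions)`` where positions are sample indices of
        window ends. ``feature_names`` reorders columns when the input block
        stores features in a different order than the encoder was trained on.
        """
        X = np.asarray(X, dtype=np.float32)
        if feature_names is not None:
            if sorted(feature_names) != sorted(self.feature_names):
                raise ShapeError("feature names do not match the trained encoder")
            order = [list(feature_names).index(n) for n in self.feature_names]
            X = X[:, order]
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ShapeError(
                f"expected {len(self.feature_names)} feature columns, got {X.shape}")
        rf = self.config.receptive_field
        if X.shape[0] < rf:
            raise ShapeError("input shorter than the receptive field")
        runs = (np.asarray(runs, dtype=object) if runs is not None
                else np.zeros(len(X), dtype=object))
        run_starts = _run_bounds(runs)
        idx = np.arange(len(X))
        positions = idx[(idx - (rf - 1) >= run_starts)][::hop]
        view = _window_view(np.ascontiguousarray(X), rf)
        coords = np.empty((len(positions), self.config.output_dim), dtype=np.float32)
        chunk = 1024
        for s0 in range(0, len(positions), chunk):
            sl = slice(s0, min(s0 + chunk, len(positions)))
            coords[sl] = self.encoder.forward(
                _gather_windows(view, positions[sl], rf))
        return coords, positions

    def summary(self) -> str:
        plan = ", ".join(f"(k={k},s={s})" for k, s in self.encoder.plan)
        return "\n".join([
            "Supervised contrastive embedding",
            "=" * 32,
            f"receptive field: {self.config.receptive_field} samples   "
            f"output dim: {self.config.output_dim}",
            f"layers: {plan}",
            f"temperature: {self.config.temperature}   batch: {self.config.batch_size}   "
            f"iterations: {self.config.max_iterations}",
            f"InfoNCE loss: {self.initial_loss:.4f} -> {self.final_loss:.4f}",
        ])


def knn_evaluate(train_coords, train_labels, test_coords, test_labels,
                 k: int = 3, positive_class: str | None = None) -> dict:
    """Cosine-distance KNN vote; ties broken by the nearest neighbor."""
    train_coords = np.asarray(train_coords, dtype=float)
    test_coords = np.asarray(test_coords, dtype=float)
    train_labels = np.asarray(train_labels, dtype=object)
    test_labels = np.asarray(test_labels, dtype=object)
    if len(train_coords) == 0:
        raise ConfigurationError("empty training set for KNN")
    if k > len(train_coords):
        raise ConfigurationError(f"k={k} exceeds training size {len(train_coords)}")
    nn = NearestNeighbors(n_neighbors=k, metric="cosine").fit(train_coords)
    _dist, ind = nn.kneighbors(test_coords)
    pred = np.empty(len(test_coords), dtype=object)
    for i, row in enumerate(ind):
        votes = train_labels[row]
        uniq, counts = np.unique(votes.astype(str), return_counts=True)
        winners = uniq[counts == counts.max()]
        if len(winners) == 1:
            pred[i] = winners[0]
        else:
            # tie: the nearest neighbor whose label is among the winners
            pred[i] = next(v for v in votes if str(v) in set(winners))
    classes = sorted(set(train_labels.tolist()) | set(test_labels.tolist()))
    cm = confusion_matrix(test_labels, pred, labels=classes).astype(float)
    rs = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, rs, out=np.full_like(cm, np.nan), where=rs > 0)
    out = {
        "classes": classes,
        "confusion": cm_norm,
        "f1_macro": float(f1_score(test_labels, pred, average="macro", zero_division=0)),
        "balanced_accuracy": float(balanced_accuracy_score(test_labels, pred)),
        "predictions": pred,
    }
    if positive_class is not None:
        kw = dict(labels=[positive_class], average="macro", zero_division=0)
        out["f1"] = float(f1_score(test_labels, pred, **kw))
        out["precision"] = float(precision_score(test_labels, pred, **kw))
        out["recall"] = float(recall_score(test_labels, pred, **kw))
    return out


def embedding_importance(results: EmbeddingResults, train_coords, train_labels,
                         X_test, y_test, runs_test=None, hop: int = 1,
                         seed: int = 0, k: int = 3) -> pd.Series:
    """Drop in KNN macro f1 after permuting one test feature before embedding."""
    rng = np.random.default_rng(seed)
    X_test = np.asarray(X_test, dtype=np.float32)
    y_test = np.asarray(y_test, dtype=object)
    coords, pos = results.embed(X_test, runs_test, hop=hop)
    keep = y_test[pos] != UNLABELED
    base = knn_evaluate(train_coords, train_labels, coords[keep],
                        y_test[pos][keep], k=k)["f1_macro"]
    drops = {}
    for j, name in enumerate(results.feature_names):
        Xp = X_test.copy()
        Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
        c, p = results.embed(Xp, runs_test, hop=hop)
        score = knn_evaluate(train_coords, train_labels, c[keep],
                             y_test[p][keep], k=k)["f1_macro"]
        drops[name] = base - score
    return pd.Series(drops)


def single_feature_embedding(X, labels, runs, feature_name: str,
                             feature_names: list[str],
                             config: EmbeddingConfig | None = None,
                             plan=None, hop: int = 5, k: int = 3):
    """Train an embedding on one feature column and score it by KNN f1.

    Used to compare candidate biomarkers head-to-head (e.g. HB-LG amplitude
    vs Hjorth complexity): the returned metrics carry the per-fold macro f1
    under the run-grouped plan, or a single half-split of runs when no plan
    is given. Returns ``(last fold's EmbeddingResults, metrics DataFrame)``.
    """
    if feature_name not in feature_names:
        raise ConfigurationError(f"unknown feature {feature_name!r}")
    X = np.asarray(X, dtype=np.float32)
    labels = np.asarray(labels, dtype=object)
    runs = (np.asarray(runs, dtype=object) if runs is not None
            else np.zeros(len(X), dtype=object))
    col = X[:, [list(feature_names).index(feature_name)]]
    cfg = config or EmbeddingConfig()
    if plan is None:
        unique = list(dict.fromkeys(runs.tolist()))
        half = max(1, len(unique) // 2)
        folds = [(unique[:half], unique[half:])]
    else:
        folds = plan.folds
    rows, res = [], None
    for fold_id, (train_runs, test_runs) in enumerate(folds):
        tr = np.isin(runs, train_runs)
        te = np.isin(runs, test_runs)
        res = ContrastiveEmbedding(col[tr], labels[tr], runs[tr],
                                   cfg.with_(seed=cfg.seed + fold_id),
                                   feature_names=[feature_name]).fit()
        ctr, ptr = res.embed(col[tr], runs[tr], hop=hop)
        cte, pte = res.embed(col[te], runs[te], hop=hop)
        keep_tr = labels[tr][ptr] != UNLABELED
        keep_te = labels[te][pte] != UNLABELED
        ev = knn_evaluate(ctr[keep_tr], labels[tr][ptr][keep_tr],
                          cte[keep_te], labels[te][pte][keep_te], k=k)
        rows.append({"fold": fold_id, "f1_macro": ev["f1_macro"],
                     "balanced_accuracy": ev["balanced_accuracy"]})
    return res, pd.DataFrame(rows)


def temperature_scan(X, labels, runs, temperatures=(0.05, 0.1, 0.5, 1.0),
                     config: EmbeddingConfig | None = None,
                     hop: int = 5, k: int = 3) -> pd.DataFrame:
    """Optional utility: final loss and decoder f1 across temperatures.

    The production temperature (0.1) was chosen by a scan of this kind;
    this helper re-runs such a scan at whatever scale the config sets.
    """
    cfg = config or EmbeddingConfig()
    runs_arr = (np.asarray(runs, dtype=object) if runs is not None
                else np.zeros(len(X), dtype=object))
    unique = list(dict.fromkeys(runs_arr.tolist()))
    half = max(1, len(unique) // 2)
    rows = []
    for tau in temperatures:
        res, metrics = None, None
        model_cfg = cfg.with_(temperature=float(tau))
        tr = np.isin(runs_arr, unique[:half])
        te = np.isin(runs_arr, unique[half:])
        res = ContrastiveEmbedding(np.asarray(X, dtype=np.float32)[tr],
                                   np.asarray(labels, dtype=object)[tr],
                                   runs_arr[tr], model_cfg).fit()
        ctr, ptr = res.embed(np.asarray(X, dtype=np.float32)[tr],
                             runs_arr[tr], hop=hop)
        cte, pte = res.embed(np.asarray(X, dtype=np.float32)[te],
                             runs_arr[te], hop=hop)
        y = np.asarray(labels, dtype=object)
        ev = knn_evaluate(ctr, y[tr][ptr], cte, y[te][pte], k=k)
        rows.append({"temperature": float(tau), "final_loss": res.final_loss,
                     "f1_macro": ev["f1_macro"]})
    return pd.DataFrame(rows)


def shuffle_labels(labels, seed: int = 0) -> np.ndarray:
    """Shuffled-label control: permute labels over labeled samples only."""
    labels = np.asarray(labels, dtype=object).copy()
    rng = np.random.default_rng(seed)
    mask = labels != UNLABELED
    vals = labels[mask]
    labels[mask] = vals[rng.permutation(len(vals))]
    return labels
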