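"""CSF / white-matter-lesion segmentation and ensemble fusion.

The segmenter is a compact voxelwise residual network: a fixed multi-scale
convolutional filter bank (Gaussian smoothings, Laplacians-of-Gaussian and a
gradient magnitude of the z-scored CT) acts as the encoder, and a trainable
stack of residual dense blocks with a softmax head — written in numpy with
hand-rolled backprop and Adam — emits per-voxel class probabilities for
{background, CSF, WML}.  The scale knobs (``n_residual_blocks``,
``base_channels``, ``epochs``...) make the model large or small; the desk
preset is a few thousand parameters, which is enough for CT-contrast classes.

Segmentation is repeated K times (independently seeded trainings) and the K
probability maps are merged with a correlation-weighted fusion rule:

1. compute the Pearson correlation ``c_ij`` between each pair of probability
   maps over the analysis domain;
2. for each member i, count ``n_i`` = number of j with
   ``c_ij > min(0.8, 0.9 * max(c_ij))`` (the max over distinct pairs);
3. weight ``w_i = n_i / sum(n_i)``;
4. threshold the weighted mean probability at 0.5.

Members that disagree with the consensus therefore get small weights, which
is what makes the ensemble robust to a stray bad training run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "SegmenterConfig",
    "TrainedSegmenter",
    "EnsembleSet",
    "CLASS_NAMES",
    "extract_features",
    "train_segmenter",
    "train_ensemble",
    "predict_ensemble",
    "fuse_ensemble",
    "crossvalidate",
    "dice",
]

CLASS_NAMES = ("background", "csf", "wml")


@dataclass(frozen=True)
class SegmenterConfig:
    """Scale and training parameters of the voxelwise residual network."""

    n_residual_blocks: int = 2
    base_channels: int = 16
    feature_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    samples_per_volume: int = 4000
    class_weight: str = "calibrated"   # "calibrated" | "inverse_frequency"
    seed: int = 0

    @property
    def n_layers(self) -> int:
        """Dense layers: input projection + 2 per residual block + head."""
        return 2 + 2 * self.n_residual_blocks

    @property
    def n_features(self) -> int:
        return 2 + 2 * len(self.feature_sigmas)


def extract_features(ct: Volume, sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)) -> np.ndarray:
    """Fixed filter-bank encoder: (n_features, nx, ny, nz) float32."""
    x = ct.data.astype(np.float32)
    feats = [x]
    for s in sigmas:
        feats.append(ndimage.gaussian_filter(x, s))
    for s in sigmas:
        feats.append(ndimage.gaussian_laplace(x, s))
    feats.append(ndimage.gaussian_gradient_magnitude(x, 1.0))
    return np.stack(feats).astype(np.float32)


# --------------------------------------------------------------------------
class _ResidualNet:
    """Residual MLP with softmax head; float64 numpy, Adam, backprop."""

    def __init__(self, n_in: int, channels: int, n_blocks: int, n_out: int, rng: np.random.Generator):
        def he(shape):
            return rng.normal(0.0, np.sqrt(2.0 / shape[0]), size=shape)

        self.params: dict[str, np.ndarray] = {"W_in": he((n_in, channels)), "b_in": np.zeros(channels)}
        self.n_blocks = n_blocks
        for b in range(n_blocks):
            self.params[f"W{b}a"] = he((channels, channels))
            self.params[f"b{b}a"] = np.zeros(channels)
            self.params[f"W{b}b"] = he((channels, channels))
            self.params[f"b{b}b"] = np.zeros(channels)
        self.params["W_out"] = he((channels, n_out))
        self.params["b_out"] = np.zeros(n_out)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def forward(self, X: np.ndarray, cache: bool = False):
        P = self.params
        h = X @ P["W_in"] + P["b_in"]
        m_in = h > 0
        h = h * m_in
        caches = {"X": X, "m_in": m_in, "h_in": h} if cache else None
        for b in range(self.n_blocks):
            a = h @ P[f"W{b}a"] + P[f"b{b}a"]
            ma = a > 0
            ar = a * ma
            z = ar @ P[f"W{b}b"] + P[f"b{b}b"]
            if cache:
                caches[f"h{b}"] = h
                caches[f"ma{b}"] = ma
                caches[f"ar{b}"] = ar
            h = h + z
        logits = h @ P["W_out"] + P["b_out"]
        if cache:
            caches["h_last"] = h
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return (probs, caches) if cache else probs

    def train_step(self, X, y_onehot, sample_w, lr) -> float:
        probs, c = self.forward(X, cache=True)
        n = X.shape[0]
        eps = 1e-12
        loss = float(-(sample_w[:, None] * y_onehot * np.log(probs + eps)).sum() / sample_w.sum())
        g_logits = (probs - y_onehot) * sample_w[:, None] / sample_w.sum()
        grads: dict[str, np.ndarray] = {}
        P = self.params
        grads["W_out"] = c["h_last"].T @ g_logits
        grads["b_out"] = g_logits.sum(axis=0)
        gh = g_logits @ P["W_out"].T
        for b in reversed(range(self.n_blocks)):
            gz = gh  # residual add passes gradient through both branches
            grads[f"W{b}b"] = c[f"ar{b}"].T @ gz
            grads[f"b{b}b"] = gz.sum(axis=0)
            gar = gz @ P[f"W{b}b"].T
            ga = gar * c[f"ma{b}"]
            grads[f"W{b}a"] = c[f"h{b}"].T @ ga
            grads[f"b{b}a"] = ga.sum(axis=0)
            gh = gh + ga @ P[f"W{b}a"].T
        gh = gh * c["m_in"]
        grads["W_in"] = c["X"].T @ gh
        grads["b_in"] = gh.sum(axis=0)
        self._adam_t += 1
        b1, b2, eps_a = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g**2
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps_a)
        return loss


@dataclass
class TrainedSegmenter:
    net: _ResidualNet
    config: SegmenterConfig
    class_weights: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def predict(
        self,
        ct: Volume,
        mask: np.ndarray | None = None,
        features: np.ndarray | None = None,
    ) -> dict[str, Volume]:
        """Per-voxel class probability volumes (sum to 1 everywhere).

        ``features`` may carry a precomputed filter-bank output (as from
        :func:`extract_features`) to avoid recomputing it per ensemble member.
        """
        feats = (
            extract_features(ct, self.config.feature_sigmas) if features is None else features
        )
        F = feats.reshape(feats.shape[0], -1).T
        F = (F - self.feature_mean) / self.feature_sd
        if mask is None:
            probs = self.net.forward(F)
        else:
            flat = mask.ravel().astype(bool)
            probs = np.zeros((F.shape[0], len(CLASS_NAMES)))
            probs[:, 0] = 1.0
            if flat.any():
                probs[flat] = self.net.forward(F[flat])
        out = {}
        for k, name in enumerate(CLASS_NAMES):
            out[name] = ct.like(probs[:, k].reshape(ct.shape))
        return out


def _sample_training_set(
    pairs: list[tuple[Volume, Volume]],
    config: SegmenterConfig,
    masks: list[np.ndarray] | None,
    rng: np.random.Generator,
    feature_cache: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified voxel subsample across volumes; oversamples CSF and WML."""
    Xs, ys = [], []
    shares = {0: 0.40, 1: 0.35, 2: 0.25}
    for i, (ct, lab) in enumerate(pairs):
        feats = (
            extract_features(ct, config.feature_sigmas)
            if feature_cache is None
            else feature_cache[i]
        )
        F = feats.reshape(feats.shape[0], -1).T
        labels = lab.data.ravel()
        dom = masks[i].ravel().astype(bool) if masks is not None else np.ones(labels.size, bool)
        per_class = {k: int(config.samples_per_volume * s) for k, s in shares.items()}
        chosen: list[np.ndarray] = []
        short = 0
        for k in (2, 1, 0):
            idx = np.flatnonzero(dom & (labels == k))
            want = per_class[k] + (short if k == 0 else 0)
            if idx.size <= want:
                chosen.append(idx)
                short += want - idx.size
            else:
                chosen.append(rng.choice(idx, size=want, replace=False))
        sel = np.concatenate(chosen)
        Xs.append(F[sel])
        ys.append(labels[sel])
    return np.concatenate(Xs), np.concatenate(ys).astype(int)


def train_segmenter(
    pairs: list[tuple[Volume, Volume]],
    config: SegmenterConfig | None = None,
    masks: list[np.ndarray] | None = None,
    feature_cache: list[np.ndarray] | None = None,
) -> TrainedSegmenter:
    """Train the voxelwise residual network on (z-scored CT, class labels) pairs.

    Label volumes use codes 0=background, 1=CSF, 2=WML.  ``masks`` optionally
    restricts training voxels (normally the brain mask).  Deterministic given
    ``config.seed``; inverse-frequency class weights handle the extreme
    imbalance between background and lesion voxels.
    """
    cfg = config or SegmenterConfig()
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    rng = np.random.default_rng(cfg.seed)
    X, y = _sample_training_set(pairs, cfg, masks, rng, feature_cache)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mean) / sd
    counts = np.bincount(y, minlength=len(CLASS_NAMES)).astype(float)
    present = counts > 0
    if not present.all():
        absent = [CLASS_NAMES[k] for k in np.flatnonzero(~present)]
        warnings.warn(f"classes absent from training labels: {absent}; weights zeroed")
    cw = np.zeros(len(CLASS_NAMES))
    if cfg.class_weight == "inverse_frequency":
        cw[present] = counts[present].sum() / (present.sum() * counts[present])
    elif cfg.class_weight == "calibrated":
        # importance weights that undo the stratified oversampling, so the
        # softmax probabilities stay calibrated to the in-mask prevalence
        # (the downstream fusion threshold is fixed at 0.5)
        true_counts = np.zeros(len(CLASS_NAMES))
        for i, (_, lab) in enumerate(pairs):
            dom = masks[i].astype(bool) if masks is not None else np.ones(lab.shape, bool)
            true_counts += np.bincount(lab.data[dom].ravel().astype(int), minlength=len(CLASS_NAMES))
        f_true = true_counts / max(true_counts.sum(), 1)
        f_sample = counts / counts.sum()
        cw[present] = f_true[present] / f_sample[present]
    else:
        raise ValueError(f"unknown class_weight mode {cfg.class_weight!r}")
    net = _ResidualNet(cfg.n_features, cfg.base_channels, cfg.n_residual_blocks, len(CLASS_NAMES), rng)
    onehot = np.eye(len(CLASS_NAMES))[y]
    sw_all = cw[y]
    n = X.shape[0]
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            b = order[s : s + cfg.batch_size]
            losses.append(net.train_step(X[b], onehot[b], sw_all[b], cfg.learning_rate))
        history.append(float(np.mean(losses)))
    return TrainedSegmenter(net, cfg, cw, mean, sd, history)


def train_ensemble(
    pairs: list[tuple[Volume, Volume]],
    config: SegmenterConfig | None = None,
    K: int = 10,
    masks: list[np.ndarray] | None = None,
) -> list[TrainedSegmenter]:
    """K independently seeded trainings — the source of ensemble variability."""
    cfg = config or SegmenterConfig()
    if K < 2:
        raise ValueError("ensemble needs K >= 2")
    from dataclasses import replace

    cache = [extract_features(ct, cfg.feature_sigmas) for ct, _ in pairs]
    return [
        train_segmenter(pairs, replace(cfg, seed=cfg.seed + k), masks, feature_cache=cache)
        for k in range(K)
    ]


def predict_ensemble(
    models: TrainedSegmenter | list[TrainedSegmenter],
    ct: Volume,
    K: int | None = None,
    mask: np.ndarray | None = None,
) -> dict[str, list[Volume]]:
    """K probability volumes per class.

    A single model is replicated K times (members are then identical — the
    degenerate deterministic ensemble); a list of models yields one member
    per model.
    """
    if isinstance(models, TrainedSegmenter):
        if K is None or K < 2:
            raise ValueError("replicating a single model requires K >= 2")
        models = [models] * K
    elif K is not None and K != len(models):
        raise ValueError("K does not match the number of models")
    if len(models) < 2:
        raise ValueError("ensemble needs K >= 2")
    members: dict[str, list[Volume]] = {name: [] for name in CLASS_NAMES}
    feats = extract_features(ct, models[0].config.feature_sigmas)
    for m in models:
        probs = m.predict(ct, mask=mask, features=feats)
        for name in CLASS_NAMES:
            members[name].append(probs[name])
    return members


# --------------------------------------------------------------------------
@dataclass
class EnsembleSet:
    """K probability maps of one class plus the fusion products."""

    members: list[Volume]
    corr: np.ndarray
    counts: np.ndarray
    weights: np.ndarray
    fused_prob: Volume
    fused: Volume
    threshold_used: float


def fuse_ensemble(
    members: list[Volume],
    domain_mask: np.ndarray | None = None,
    include_self: bool = True,
    prob_threshold: float = 0.5,
) -> EnsembleSet:
    """Correlation-weighted fusion of K probability maps (see module docs).

    The pair-correlation threshold is ``min(0.8, 0.9 * max_offdiag(c_ij))``;
    the diagonal (c_ii = 1) is counted in ``n_i`` but excluded from the max,
    which would otherwise pin the threshold at 0.8 for every ensemble.
    Members with zero variance over the domain have undefined correlations
    and are excluded from the counts (weight 0) with a warning.
    """
    K = len(members)
    if K < 2:
        raise ValueError("fusion needs K >= 2 members")
    ref = members[0]
    for m in members[1:]:
        if not m.same_grid(ref):
            raise ValueError("ensemble members must share one grid")
    dom = (
        np.ones(ref.shape, bool) if domain_mask is None else domain_mask.astype(bool)
    ).ravel()
    V = np.stack([m.data.ravel()[dom] for m in members]).astype(np.float64)
    sds = V.std(axis=1)
    valid = sds > 1e-12 * np.maximum(1.0, np.abs(V).max(axis=1))
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} ensemble member(s) with zero variance excluded")
    corr = np.full((K, K), np.nan)
    if valid.any():
        Vc = (V[valid] - V[valid].mean(axis=1, keepdims=True)) / sds[valid][:, None]
        sub = (Vc @ Vc.T) / V.shape[1]
        corr[np.ix_(valid, valid)] = sub
    off = corr[~np.eye(K, dtype=bool)]
    finite_off = off[np.isfinite(off)]
    thr = min(0.8, 0.9 * finite_off.max()) if finite_off.size else 0.8
    counts = np.zeros(K, dtype=int)
    for i in range(K):
        if not valid[i]:
            continue
        for j in range(K):
            if not include_self and j == i:
                continue
            cij = corr[i, j]
            if np.isfinite(cij) and cij > thr:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("no member passed the correlation threshold; uniform weights over valid members")
        weights = valid.astype(float) / max(valid.sum(), 1)
    else:
        weights = counts / total
    fused_prob = np.zeros(ref.shape, dtype=np.float64)
    for w, m in zip(weights, members):
        fused_prob += w * m.data
    fused = fused_prob >= prob_threshold
    return EnsembleSet(
        members=list(members),
        corr=corr,
        counts=counts,
        weights=weights,
        fused_prob=ref.like(fused_prob),
        fused=ref.like(fused),
        threshold_used=float(thr),
    )


# --------------------------------------------------------------------------
@dataclass
class CVResult:
    fold_assignment: np.ndarray
    models: list[TrainedSegmenter]
    predictions: list[dict[str, Volume]]


def crossvalidate(
    pairs: list[tuple[Volume, Volume]],
    folds: int = 10,
    config: SegmenterConfig | None = None,
    masks: list[np.ndarray] | None = None,
) -> CVResult:
    """K-fold cross-validation: every sample predicted exactly once out-of-fold."""
    cfg = config or SegmenterConfig()
    n = len(pairs)
    if folds > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(cfg.seed)
    assignment = np.array_split(rng.permutation(n), folds)
    fold_of = np.empty(n, dtype=int)
    for f, idx in enumerate(assignment):
        fold_of[idx] = f
    models = []
    predictions: list[dict[str, Volume] | None] = [None] * n
    for f in range(folds):
        train_idx = np.flatnonzero(fold_of != f)
        test_idx = np.flatnonzero(fold_of == f)
        model = train_segmenter(
            [pairs[i] for i in train_idx],
            cfg,
            None if masks is None else [masks[i] for i in train_idx],
        )
        models.append(model)
        for i in test_idx:
            predictions[i] = model.predict(pairs[i][0], None if masks is None else masks[i])
    return CVResult(fold_of, models, predictions)  # type: ignore[arg-type]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 1.0
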