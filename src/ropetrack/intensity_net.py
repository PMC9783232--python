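"""Exercise-intensity regression with domain-adversarial training.

A residual CNN maps the (optionally GAN-enhanced) breathing mel
spectrogram to a feature vector, the normalized jump speed is appended,
one head regresses intensity (bounded to [0, 100]) and an adversarial
head classifies the recording domain from the intensity-weighted
feature vector. The feature path receives the domain gradient with its
sign reversed (scaled by alpha), realizing L = L_r - alpha * L_t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breath_profile import MelSpectrogram, to_image
from .nn import Adam, Conv2d, Linear, Module, Tensor
from .nn import autograd as ag
from .synthetic_scenes import DomainLabel

__all__ = [
    "IntensitySample",
    "DannConfig",
    "intensity_ground_truth",
    "IntensityDann",
    "dann_losses",
    "train_dann",
    "evaluate_cross_domain",
]

H_MIN, H_MAX = 120.0, 180.0


@dataclass(frozen=True)
class IntensitySample:
    spectrogram: MelSpectrogram
    speed: float
    intensity_r: float
    heart_rate: float
    domain: DomainLabel

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_r <= 100:
            raise ValueError("intensity_r must lie in [0, 100]")
        if H_MIN <= self.heart_rate <= H_MAX:
            expected = intensity_ground_truth(self.heart_rate)
            if abs(expected - self.intensity_r) > 100.0 / (H_MAX - H_MIN):
                raise ValueError(
                    f"intensity {self.intensity_r:.2f} inconsistent with "
                    f"heart rate {self.heart_rate} (expected ~{expected:.2f})"
                )


@dataclass
class DannConfig:
    alpha: float = 0.1
    lr: float = 1e-3
    # the linear domain head tracks a feature extractor that moves fast at
    # desk scale; a faster head keeps its accuracy a meaningful read-out
    lr_domain_head: float = 1e-2
    epochs: int = 10
    batch_size: int = 32
    base_channels: int = 8
    feature_dim: int = 32
    image_size: int = 64
    seed: int = 0
    domain_adaptation: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def intensity_ground_truth(h: float, h_min: float = H_MIN, h_max: float = H_MAX) -> float:
    """r = (h - h_min) / (h_max - h_min) * 100, with h clipped into range."""
    if h <= 0:
        raise ValueError("heart rate must be positive")
    h = float(np.clip(h, h_min, h_max))
    return (h - h_min) / (h_max - h_min) * 100.0


class _ResBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.c1 = Conv2d(channels, channels, 3, rng=rng)
        self.c2 = Conv2d(channels, channels, 3, rng=rng, gain=0.5)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.c2(ag.leaky_relu(self.c1(x)))


class IntensityDann(Module):
    """Feature extractor + intensity estimator + weighted domain head."""

    def __init__(self, n_domains: int, config: DannConfig | None = None):
        cfg = config or DannConfig()
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        self.config = cfg
        self.n_domains = n_domains
        self.conv_in = Conv2d(1, c, 3, stride=2, rng=rng)
        self.res1 = _ResBlock(c, rng)
        self.conv_mid = Conv2d(c, 2 * c, 3, stride=2, rng=rng)
        self.res2 = _ResBlock(2 * c, rng)
        self.conv_out = Conv2d(2 * c, 2 * c, 3, stride=2, rng=rng)
        # pool over time only, keeping the frequency axis: the mel-row
        # position of spectral features carries both intensity and
        # domain-timbre information that global pooling would erase
        rows = cfg.image_size // 8
        self.fc_pool = Linear(2 * c * rows, cfg.feature_dim, rng=rng)
        self.fc_r1 = Linear(cfg.feature_dim + 1, 32, rng=rng)
        self.fc_r2 = Linear(32, 1, rng=rng)
        self.fc_d = Linear(cfg.feature_dim + 1, n_domains, rng=rng)

    def features(self, x: Tensor, speed: np.ndarray) -> Tensor:
        h = ag.leaky_relu(self.conv_in(x))
        h = self.res1(h)
        h = ag.leaky_relu(self.conv_mid(h))
        h = self.res2(h)
        h = ag.leaky_relu(self.conv_out(h))
        pooled = ag.mean(h, axis=3)  # (B, C, rows): time-average only
        b, c, rows = pooled.data.shape
        feats = ag.leaky_relu(self.fc_pool(ag.reshape(pooled, (b, c * rows))))
        v = Tensor(np.asarray(speed, dtype=np.float64).reshape(-1, 1))
        return ag.concat([feats, v], axis=1)

    def __call__(
        self, x: Tensor, speed: np.ndarray, alpha: float | None = None
    ) -> tuple[Tensor, Tensor, Tensor | None]:
        """Returns (r_hat in [0,100], features, domain logits or None)."""
        cfg = self.config
        feats = self.features(x, speed)
        r_hat = ag.sigmoid(self.fc_r2(ag.leaky_relu(self.fc_r1(feats)))) * Tensor(100.0)
        logits = None
        if cfg.domain_adaptation:
            a = cfg.alpha if alpha is None else alpha
            # intensity weight is a constant w.r.t. the domain loss so the
            # adversary cannot win by driving r_hat to zero
            w = Tensor(r_hat.data.reshape(-1, 1) / 100.0)
            weighted = feats * w
            logits = self.fc_d(ag.grad_reverse(weighted, lam=a))
        return r_hat, feats, logits


def dann_losses(
    r_true: np.ndarray,
    r_hat,
    domain_logits,
    domain_labels: np.ndarray | None,
    alpha: float,
) -> tuple[Tensor, Tensor | None, float]:
    """(L_r, L_t, L_total = L_r - alpha * L_t) on the percent scale."""
    r_true = np.asarray(r_true, dtype=np.float64).reshape(-1)
    if r_true.size == 0:
        raise ValueError("need at least one labelled sample")
    r_hat = r_hat if isinstance(r_hat, Tensor) else Tensor(np.asarray(r_hat))
    diff = r_hat - Tensor(r_true.reshape(r_hat.data.shape))
    l_r = ag.mean(diff**2)
    l_t = None
    total = l_r.item()
    if domain_logits is not None:
        logits = (
            domain_logits
            if isinstance(domain_logits, Tensor)
            else Tensor(np.asarray(domain_logits, dtype=np.float64))
        )
        labels = np.asarray(domain_labels, dtype=np.int64)
        if labels.min() < 0 or labels.max() >= logits.data.shape[1]:
            raise ValueError("domain label outside the known domain set")
        l_t = ag.softmax_cross_entropy(logits, labels)
        total = l_r.item() - alpha * l_t.item()
    return l_r, l_t, total


def _dataset_arrays(samples, image_size: int):
    x = np.stack([to_image(s.spectrogram, image_size)[None] for s in samples])
    v = np.array([s.speed for s in samples], dtype=np.float64)
    r = np.array([s.intensity_r for s in samples], dtype=np.float64)
    d = np.array([s.domain.domain_id for s in samples], dtype=np.int64)
    return x, v, r, d


def train_dann(
    samples: list[IntensitySample],
    config: DannConfig | None = None,
    domain_index: dict[int, int] | None = None,
) -> tuple[IntensityDann, list[dict]]:
    """Train the regressor; returns the model and a per-epoch history.

    ``domain_index`` maps raw domain ids to contiguous class indices;
    by default it is built from the domains present in ``samples``.
    History rows log L_r, L_t, L_total = L_r - alpha*L_t and the
    domain-classification accuracy on the training data.
    """
    cfg = config or DannConfig()
    if not samples:
        raise ValueError("empty training set")
    x, v, r, d_raw = _dataset_arrays(samples, cfg.image_size)
    if domain_index is None:
        domain_index = {did: i for i, did in enumerate(sorted(set(d_raw.tolist())))}
    d = np.array([domain_index[i] for i in d_raw], dtype=np.int64)
    n_domains = len(domain_index)
    if cfg.domain_adaptation and n_domains < 2:
        raise ValueError("domain adaptation requires at least two training domains")

    v_lo, v_hi = float(v.min()), float(v.max())
    v_norm = (v - v_lo) / (v_hi - v_lo) if v_hi > v_lo else np.zeros_like(v)

    model = IntensityDann(n_domains, cfg)
    model.speed_norm = (v_lo, v_hi)  # stored for inference
    model.domain_index = dict(domain_index)
    head_params = model.fc_d.parameters()
    head_ids = {id(p) for p in head_params}
    opt = Adam([p for p in model.parameters() if id(p) not in head_ids], lr=cfg.lr)
    opt_head = Adam(head_params, lr=cfg.lr_domain_head)
    rng = np.random.default_rng(cfg.seed + 1)

    history: list[dict] = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_lr, ep_lt, n_batches = 0.0, 0.0, 0
        correct, counted = 0, 0
        for k in range(0, n, cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            model.zero_grad()
            r_hat, _, logits = model(Tensor(x[idx]), v_norm[idx])
            l_r, l_t, _ = dann_losses(r[idx], r_hat, logits, d[idx], cfg.alpha)
            # backprop L_r + L_t with intensities rescaled to [0,1] and a
            # 10x regression emphasis so the feature extractor's update is
            # not dominated by either objective at desk scale; the
            # gradient reversal inside the model scales the domain
            # gradient on the feature path by -alpha, so theta_f descends
            # (a scaled) L_r - alpha * L_t while theta_t descends L_t and
            # theta_r descends L_r. Logged losses stay on the percentage
            # scale of the stated formulas.
            loss = l_r * Tensor(1e-3)
            if l_t is not None:
                loss = loss + l_t
            loss.backward()
            opt.step()
            opt_head.step()
            ep_lr += l_r.item()
            if l_t is not None:
                ep_lt += l_t.item()
                pred = np.argmax(logits.data, axis=1)
                correct += int(np.sum(pred == d[idx]))
                counted += idx.size
            n_batches += 1
        row = {
            "epoch": epoch,
            "l_r": ep_lr / n_batches,
            "l_t": ep_lt / n_batches if counted else None,
            "domain_accuracy": correct / counted if counted else None,
        }
        row["l_total"] = row["l_r"] - cfg.alpha * (row["l_t"] or 0.0)
        history.append(row)
    return model, history


def predict_intensity(model: IntensityDann, images: np.ndarray, speeds: np.ndarray) -> np.ndarray:
    v_lo, v_hi = getattr(model, "speed_norm", (0.0, 1.0))
    v = np.asarray(speeds, dtype=np.float64)
    v_norm = (v - v_lo) / (v_hi - v_lo) if v_hi > v_lo else np.zeros_like(v)
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None]
    r_hat, _, _ = model(Tensor(x), v_norm)
    return r_hat.data.reshape(-1).astype(np.float64)


def evaluate_cross_domain(
    model: IntensityDann, samples: list[IntensitySample]
) -> dict:
    """MAE (percentage points) overall and per domain, plus domain accuracy
    over the samples whose domain the discriminator knows."""
    if not samples:
        raise ValueError("empty evaluation set")
    x, v, r, d_raw = _dataset_arrays(samples, model.config.image_size)
    preds = predict_intensity(model, x[:, 0], v)
    err = np.abs(preds - r)
    per_domain = {
        int(did): float(err[d_raw == did].mean()) for did in sorted(set(d_raw.tolist()))
    }
    domain_acc = None
    if model.config.domain_adaptation:
        index = getattr(model, "domain_index", {})
        known = np.array([did in index for did in d_raw])
        if known.any():
            v_lo, v_hi = getattr(model, "speed_norm", (0.0, 1.0))
            v_norm = (v - v_lo) / (v_hi - v_lo) if v_hi > v_lo else np.zeros_like(v)
            _, _, logits = model(Tensor(x[known]), v_norm[known])
            pred_cls = np.argmax(logits.data, axis=1)
            true_cls = np.array([index[did] for did in d_raw[known]])
            domain_acc = float(np.mean(pred_cls == true_cls))
    return {
        "mae": float(err.mean()),
        "per_domain_mae": per_domain,
        "domain_accuracy": domain_acc,
        "n": int(err.size),
    }
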