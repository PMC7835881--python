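"""Episode sampling, the joint BCE + Dice objective, the training loop and
the n-way-1-shot evaluation protocol.

Training mirrors inference: each episode draws two single-sample support sets
over the same n classes; the network scores all n^2 ordered pairs of
embeddings (binary match labels) and, when the decoder is enabled, predicts
foreground probability maps for both sets, scored against the ground-truth
masks with a soft Dice term. At test time one support set is replaced by the
target subtomogram and the prediction is the softmax-argmax over the n
per-class match logits; test classes are never seen in training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .model import ModelConfig, OneShotNet, normalize_volume
from .nn import Adam, clip_grad_norm
from .simulate import SubtomogramRecord, TomoDataset

__all__ = [
    "Episode",
    "TrainConfig",
    "EvalReport",
    "TrainResult",
    "sample_episode",
    "bce_loss",
    "dice_loss",
    "total_loss",
    "train",
    "evaluate_nway",
]

_EPS_SCORE = 1e-7
_EPS_DICE = 1e-6


@dataclass
class Episode:
    set_a: list[SubtomogramRecord]
    set_b: list[SubtomogramRecord]
    labels: np.ndarray  # (n, n) binary; labels[i, j] = [class(a_i) == class(b_j)]

    @property
    def n_way(self) -> int:
        return len(self.set_a)


@dataclass
class TrainConfig:
    n_way: int = 2
    episodes_per_epoch: int = 8
    epochs: int = 20
    learning_rate: float = 1e-3
    decoder_lr_scale: float = 1.0  # multiplier on learning_rate for P_VD
    grad_clip: float = 5.0  # global gradient-norm ceiling per update
    augment: bool = True   # random 90-degree rotations/flips of each record
    seed: int = 0

    def __post_init__(self):
        if self.n_way < 2:
            raise ValueError("n_way must be >= 2")


@dataclass
class TrainResult:
    model: OneShotNet
    loss_history: list[dict]  # per-epoch {"total", "bce", "dice"}


@dataclass
class EvalReport:
    n_way: int
    snr: float
    accuracy: float
    n_episodes: int
    per_class_dsc: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


# --------------------------------------------------------------------------
# episodes


def sample_episode(dataset: TomoDataset, n_way: int,
                   rng: np.random.Generator, split: str = "train") -> Episode:
    """Draw two single-sample support sets over the same n classes."""
    by_class = dataset.by_class(split)
    classes = sorted(by_class)
    if len(classes) < n_way:
        raise ValueError(
            f"{split} split has {len(classes)} classes, need {n_way}"
        )
    chosen = [classes[i] for i in rng.choice(len(classes), n_way, replace=False)]
    set_a, set_b_pool = [], []
    for c in chosen:
        recs = by_class[c]
        if len(recs) >= 2:
            i, j = rng.choice(len(recs), 2, replace=False)
        else:
            warnings.warn(f"class {c!r} has a single record; sets share it")
            i = j = 0
        set_a.append(recs[i])
        set_b_pool.append(recs[j])
    order = rng.permutation(n_way)
    set_b = [set_b_pool[i] for i in order]
    labels = np.array(
        [[int(a.class_label == b.class_label) for b in set_b] for a in set_a],
        dtype=np.float64,
    )
    return Episode(set_a, set_b, labels)


# --------------------------------------------------------------------------
# losses


def bce_loss(score, label):
    """Binary cross-entropy -y log(s) - (1-y) log(1-s), mean over elements.

    Scores are clipped to [1e-7, 1 - 1e-7]. Tensor in -> Tensor out
    (differentiable); plain numbers in -> float out.
    """
    if isinstance(score, Tensor):
        y = label if isinstance(label, Tensor) else Tensor(np.asarray(label))
        s = score.clip(_EPS_SCORE, 1.0 - _EPS_SCORE)
        loss = -(y * s.log() + (1.0 - y) * (1.0 - s).log())
        return loss.mean()
    s = np.clip(np.asarray(score, dtype=np.float64), _EPS_SCORE, 1 - _EPS_SCORE)
    y = np.asarray(label, dtype=np.float64)
    return float(np.mean(-y * np.log(s) - (1 - y) * np.log(1 - s)))


def _soft_dsc(pred, gt):
    """Mean soft Dice over a batch: (2 sum(p*g)+eps)/(sum p + sum g + eps)."""
    if isinstance(pred, Tensor):
        g = Tensor(np.asarray(gt, dtype=np.float32))
        axes = tuple(range(1, pred.ndim))
        inter = (pred * g).sum(axis=axes)
        sizes = pred.sum(axis=axes) + g.sum(axis=axes)
        return ((2.0 * inter + _EPS_DICE) / (sizes + _EPS_DICE)).mean()
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    axes = tuple(range(1, p.ndim))
    inter = (p * g).sum(axis=axes)
    sizes = p.sum(axis=axes) + g.sum(axis=axes)
    return float(np.mean((2.0 * inter + _EPS_DICE) / (sizes + _EPS_DICE)))


def dice_loss(pred_a, pred_b, gt_a, gt_b):
    """Two-set soft Dice loss: 2 - DSC(pred_a, gt_a) - DSC(pred_b, gt_b).

    0 when both predictions equal their masks, 2 when fully disjoint. Each
    DSC term is the batch mean. Empty ground truth with empty prediction is
    treated as perfect via the epsilon smoothing.
    """
    d1 = _soft_dsc(pred_a, gt_a)
    d2 = _soft_dsc(pred_b, gt_b)
    if isinstance(d1, Tensor) or isinstance(d2, Tensor):
        return 2.0 - d1 - d2
    return float(2.0 - d1 - d2)


def total_loss(l_dsc, l_bce):
    """Unit-weight sum of the Dice and BCE terms."""
    return l_dsc + l_bce


# --------------------------------------------------------------------------
# training


def _rand_rot90(vol: np.ndarray, mask: np.ndarray, rng: np.random.Generator):
    """Random cube-symmetry rotation applied jointly to volume and mask."""
    k1, k2, k3 = rng.integers(4), rng.integers(4), rng.integers(4)
    for k, axes in ((k1, (0, 1)), (k2, (0, 2)), (k3, (1, 2))):
        if k:
            vol = np.rot90(vol, k, axes)
            mask = np.rot90(mask, k, axes)
    return vol, mask


def _episode_loss(model: OneShotNet, episode: Episode,
                  rng: np.random.Generator | None = None):
    n = episode.n_way
    vols, masks = [], []
    for r in episode.set_a + episode.set_b:
        v, m = normalize_volume(r.volume), r.gt_mask
        if rng is not None:
            v, m = _rand_rot90(v, m, rng)
        vols.append(v)
        masks.append(m)
    vols = np.ascontiguousarray(np.stack(vols))
    latent, feats = model.encode_with_features(vols)
    emb = model.feature_encode(latent)          # (2n, e)
    ia = np.repeat(np.arange(n), n)
    ib = np.tile(np.arange(n, 2 * n), n)
    dist = (emb[ia] - emb[ib]).abs()            # (n^2, e)
    logits = model.match_logit(dist).reshape(n * n)
    # BCE evaluated in logit space (same value as bce_loss(sigmoid(z), y)
    # up to clipping, but with gradients that survive saturation)
    y = Tensor(episode.labels.reshape(n * n))
    l_bce = -(y * logits.logsigmoid() + (1.0 - y) * (-logits).logsigmoid()).mean()
    if model.config.decoder_enabled:
        probs = model.volume_decode(
            latent, feats if model.config.decoder_skips else None)
        masks = np.ascontiguousarray(np.stack(masks)).astype(np.float32)
        l_dsc = dice_loss(probs[:n], probs[n:], masks[:n], masks[n:])
    else:
        l_dsc = Tensor(np.zeros(()))
    return total_loss(l_dsc, l_bce), l_dsc, l_bce


def train(dataset: TomoDataset, model_config: ModelConfig,
          train_config: TrainConfig) -> TrainResult:
    """Episodic training on the training split only."""
    ss = np.random.SeedSequence(train_config.seed)
    rng_episode, rng_aug = [np.random.default_rng(s) for s in ss.spawn(2)]
    model = OneShotNet(model_config)
    all_params = model.parameters()
    dec_modules = list(model.dec_levels) + (
        [model.dec_out] if model.dec_out is not None else [])
    dec_params = [p for m in dec_modules for p in m.parameters()]
    dec_ids = {id(p) for p in dec_params}
    opts = [Adam([p for p in all_params if id(p) not in dec_ids],
                 lr=train_config.learning_rate)]
    if dec_params:
        opts.append(Adam(dec_params, lr=train_config.learning_rate
                         * train_config.decoder_lr_scale))
    history: list[dict] = []
    for epoch in range(train_config.epochs):
        tot = np.zeros(3)
        for _ in range(train_config.episodes_per_epoch):
            ep = sample_episode(dataset, train_config.n_way, rng_episode, "train")
            loss, l_dsc, l_bce = _episode_loss(
                model, ep, rng_aug if train_config.augment else None
            )
            if not np.isfinite(loss.data).all():
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            for opt in opts:
                opt.zero_grad()
            loss.backward()
            clip_grad_norm(all_params, train_config.grad_clip)
            for opt in opts:
                opt.step()
            tot += [float(loss.data), float(l_dsc.data), float(l_bce.data)]
        tot /= train_config.episodes_per_epoch
        history.append({"total": tot[0], "dice": tot[1], "bce": tot[2]})
    return TrainResult(model, history)


# --------------------------------------------------------------------------
# evaluation


def _octahedral_rotations(v: np.ndarray):
    """The 24 proper rotations of a cube applied to volume v."""
    for face in (v, np.rot90(v, 1, (0, 2)), np.rot90(v, 2, (0, 2)),
                 np.rot90(v, 3, (0, 2)), np.rot90(v, 1, (0, 1)),
                 np.rot90(v, 3, (0, 1))):
        for k in range(4):
            yield np.rot90(face, k, (1, 2))


def _embed_all(model: OneShotNet, records: list[SubtomogramRecord],
               chunk: int = 16, rotation_average: bool = False) -> np.ndarray:
    vols = [normalize_volume(r.volume) for r in records]
    if rotation_average:
        out = np.empty((len(records), model.config.embedding_dim), np.float32)
        for i, v in enumerate(vols):
            batch = np.ascontiguousarray(
                np.stack(list(_octahedral_rotations(v))))
            out[i] = model.embed(batch).data.mean(axis=0)
        return out
    embs = []
    for i in range(0, len(vols), chunk):
        embs.append(model.embed(np.stack(vols[i:i + chunk])).data)
    return np.concatenate(embs)


def evaluate_nway(
    model: OneShotNet,
    dataset: TomoDataset,
    n_way: int,
    n_episodes: int,
    rng: np.random.Generator,
    split: str = "test",
    crf_params=None,
    max_dsc_records_per_class: int | None = None,
    scorer=None,
    rotation_average: bool = False,
) -> EvalReport:
    """n-way-1-shot accuracy over episodes plus per-class segmentation DSC.

    Each episode draws n support records (one per class) and one target from
    a support class (a different record when available); the prediction is
    the softmax-argmax over the n per-class match logits. Embeddings are
    computed once per record (the model is frozen during evaluation).
    `scorer(support_classes, target_class, logits, rng) -> index` may replace
    the network's decision rule, e.g. for protocol calibration checks.
    """
    by_class = dataset.by_class(split)
    classes = sorted(by_class)
    if len(classes) < n_way:
        raise ValueError(f"{split} split has {len(classes)} classes, need {n_way}")
    records = [r for c in classes for r in by_class[c]]
    class_of = np.array([classes.index(r.class_label) for r in records])
    idx_by_class = [np.where(class_of == c)[0] for c in range(len(classes))]
    emb = _embed_all(model, records, rotation_average=rotation_average)
    head_w = model.head.weight.data
    head_b = model.head.bias.data

    correct = 0
    for _ in range(n_episodes):
        chosen = rng.choice(len(classes), n_way, replace=False)
        support = np.array([rng.choice(idx_by_class[c]) for c in chosen])
        t_pos = rng.integers(n_way)
        t_class = chosen[t_pos]
        pool = idx_by_class[t_class]
        alt = pool[pool != support[t_pos]]
        target = rng.choice(alt) if len(alt) else support[t_pos]
        dists = np.abs(emb[support] - emb[target])
        logits = (dists @ head_w + head_b).ravel()
        if scorer is not None:
            pred = scorer([classes[c] for c in chosen], classes[t_class],
                          logits, rng)
        else:
            pred = int(np.argmax(logits))  # softmax is monotone in the logit
        correct += int(pred == t_pos)
    accuracy = correct / n_episodes

    per_class_dsc: dict[str, tuple[float, float]] = {}
    if model.config.decoder_enabled and max_dsc_records_per_class != 0:
        from .crf import dsc_metric, mean_field_refine

        for c in classes:
            recs = by_class[c]
            if max_dsc_records_per_class is not None:
                recs = recs[:max_dsc_records_per_class]
            scores = []
            for r in recs:
                v = normalize_volume(r.volume)
                prob = model.predict_probability(v).data[0]
                if crf_params is not None:
                    mask = mean_field_refine(prob, v, crf_params)
                else:
                    mask = prob > 0.5
                scores.append(dsc_metric(mask, r.gt_mask))
            per_class_dsc[c] = (float(np.mean(scores)), float(np.std(scores)))

    return EvalReport(n_way, dataset.snr, accuracy, n_episodes, per_class_dsc)
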