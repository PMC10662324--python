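"""Severity classifier and class activation mapping.

A compact VGG-family CNN (stacks of 3x3 convolutions with 2x2 max pooling)
with a global-average-pooling (GAP) head maps each 304 x 30 x 1 normalized
scalogram to one of four severity classes.  The GAP + single-linear-layer
head makes the original class activation mapping exact: the map for class
``c`` is the weighted sum of the final convolutional feature maps with that
class's head weights, rectified and bilinearly upsampled to scalogram
coordinates.  Summing the map over the VLF/LF/HF frequency rows gives the
band-attribution fractions reported per class.

Evaluation uses subject-grouped cross-validation: all windows of a subject
stay on one side of every fold, so accuracy reflects generalization to
unseen subjects, not within-subject memorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

from ._nn import Adam, VGGSmallNet, softmax
from .dataset import CLASS_NAMES, CVSplit, Dataset
from .timefreq import GRID, N_FREQ, N_TIME

N_CLASSES = 4


@dataclass
class ModelConfig:
    """Architecture and optimization hyper-parameters.

    ``blocks`` lists (filters, reps) per conv block; each block ends in a
    2x2 max pool.  ``stem_pool`` average-pools the frequency axis by that
    factor before the first convolution (304 rows -> 76 at the default 4):
    the 1.3 mHz bin spacing oversamples the spectral structure enormously,
    and pooling it early cuts compute fourfold without losing band
    structure.  Three blocks then reduce 76 x 30 to a 9 x 3 feature map —
    above the 4 x 2 minimum the GAP head needs.
    """

    blocks: tuple = ((8, 1), (16, 1), (32, 1))
    stem_pool: int = 4
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 12
    min_epochs: int = 3
    early_stop_train_acc: float = 0.995
    log1p: bool = True
    class_weights: bool = False    # inverse-frequency loss weighting
    seed: int = 0


@dataclass
class ModelMetrics:
    confusion: np.ndarray          # (4, 4) counts, rows = truth
    accuracy: float
    f1: dict                       # class name -> F1 (or None if absent)
    auc: dict                      # class name -> one-vs-rest AUC (or None)


@dataclass
class CAMMap:
    map: np.ndarray                # (304, 30), >= 0
    class_index: int
    band_fractions: dict           # {'vlf','lf','hf'} summing to 1
    degenerate: bool = False


@dataclass
class Model:
    net: VGGSmallNet
    config: ModelConfig
    scaler_mu: float
    scaler_sd: float
    history: list = field(default_factory=list)    # per-epoch (loss, train_acc)

    def _prep(self, X: np.ndarray) -> np.ndarray:
        z = np.log1p(X) if self.config.log1p else X
        return ((z - self.scaler_mu) / self.scaler_sd)[:, None, :, :]

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        Z = self._prep(np.asarray(X, dtype=np.float64))
        out = []
        for i in range(0, Z.shape[0], batch):
            logits, _ = self.net.forward(Z[i:i + batch])
            out.append(softmax(logits))
        return np.concatenate(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax breaks ties toward the lowest class index
        return self.predict_proba(X).argmax(axis=1)

    def feature_maps(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        Z = self._prep(np.asarray(X, dtype=np.float64))
        out = []
        for i in range(0, Z.shape[0], batch):
            _, fmap = self.net.forward(Z[i:i + batch])
            out.append(fmap)
        return np.concatenate(out)


def train(config: ModelConfig, X: np.ndarray, y: np.ndarray,
          seed: int | None = None) -> Model:
    """Mini-batch Adam on softmax cross-entropy; log1p + scalar
    standardization of the inputs is fit on this training set and stored
    with the model."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    seed = config.seed if seed is None else seed
    z = np.log1p(X) if config.log1p else X
    mu = float(z.mean())
    sd = float(z.std()) or 1.0
    net = VGGSmallNet(config.blocks, N_CLASSES, X.shape[1:], seed=seed,
                      stem_pool=config.stem_pool)
    model = Model(net=net, config=config, scaler_mu=mu, scaler_sd=sd)
    Z = ((z - mu) / sd)[:, None, :, :]
    opt = Adam(net.weights(), lr=config.lr)
    rng = np.random.default_rng(seed + 1)
    n = Z.shape[0]
    if config.class_weights:
        counts = np.bincount(y, minlength=N_CLASSES).astype(float)
        wclass = np.where(counts > 0, n / (N_CLASSES * np.maximum(counts, 1)), 0.0)
    else:
        wclass = np.ones(N_CLASSES)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = Z[idx], y[idx]
            logits, _, cache = net.forward(xb, want_cache=True)
            p = softmax(logits)
            wb = wclass[yb]
            loss = -np.sum(wb * np.log(p[np.arange(len(yb)), yb] + 1e-12)) \
                / max(wb.sum(), 1e-12)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= (wb / max(wb.sum(), 1e-12))[:, None]
            net.backward(dlogits, cache)
            opt.step(net.weights(), net.grads())
        acc = correct / n
        model.history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                              "train_acc": acc})
        if epoch + 1 >= config.min_epochs and acc >= config.early_stop_train_acc:
            break
    return model


def evaluate(model: Model, X: np.ndarray, y: np.ndarray) -> ModelMetrics:
    """Window-level confusion, accuracy, per-class F1 and one-vs-rest AUC.
    A class absent from the test set gets F1/AUC reported as None."""
    y = np.asarray(y, dtype=int)
    proba = model.predict_proba(X)
    pred = proba.argmax(axis=1)
    labels = list(range(N_CLASSES))
    conf = confusion_matrix(y, pred, labels=labels)
    acc = float((pred == y).mean())
    f1_vals = f1_score(y, pred, labels=labels, average=None, zero_division=0.0)
    f1, auc = {}, {}
    for c, name in enumerate(CLASS_NAMES):
        present = bool((y == c).any())
        f1[name] = float(f1_vals[c]) if present else None
        if present and bool((y != c).any()):
            auc[name] = float(roc_auc_score((y == c).astype(int), proba[:, c]))
        else:
            auc[name] = None
    return ModelMetrics(confusion=conf, accuracy=acc, f1=f1, auc=auc)


@dataclass
class CVResult:
    pooled: ModelMetrics
    per_fold: list
    models: list


def cross_validate(dataset: Dataset, split: CVSplit, config: ModelConfig,
                   keep_models: bool = True) -> CVResult:
    """Train/evaluate per fold; pooled confusion is the sum of fold
    confusions and pooled accuracy its normalized trace."""
    split.check_disjoint(dataset)
    per_fold, models = [], []
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for f, (tr, te) in enumerate(zip(split.train_idx, split.test_idx)):
        model = train(config, dataset.X[tr], dataset.y[tr],
                      seed=config.seed + f)
        metrics = evaluate(model, dataset.X[te], dataset.y[te])
        conf += metrics.confusion
        per_fold.append(metrics)
        models.append(model if keep_models else None)
    total = conf.sum()
    acc = float(np.trace(conf) / total) if total else 0.0
    pooled = ModelMetrics(confusion=conf, accuracy=acc,
                          f1={c: None for c in CLASS_NAMES},
                          auc={c: None for c in CLASS_NAMES})
    return CVResult(pooled=pooled, per_fold=per_fold, models=models)


def _bilinear_resize(m: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = m.shape
    ri = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    ci = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    r0 = np.clip(np.floor(ri).astype(int), 0, h - 1)
    r1 = np.clip(r0 + 1, 0, h - 1)
    c0 = np.clip(np.floor(ci).astype(int), 0, w - 1)
    c1 = np.clip(c0 + 1, 0, w - 1)
    fr = np.clip(ri - r0, 0.0, 1.0)[:, None]
    fc = np.clip(ci - c0, 0.0, 1.0)[None, :]
    top = m[np.ix_(r0, c0)] * (1 - fc) + m[np.ix_(r0, c1)] * fc
    bot = m[np.ix_(r1, c0)] * (1 - fc) + m[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def cam(model: Model, window: np.ndarray, target_class: int) -> CAMMap:
    """Class activation map for one 304 x 30 window.

    CAM_c = ReLU( sum_k w[c, k] * featuremap_k ), bilinearly upsampled to the
    scalogram grid; band fractions are the VLF/LF/HF row sums over the total.
    An all-zero map falls back to band-fraction shares proportional to row
    counts and is flagged degenerate.
    """
    fmap = model.feature_maps(window[None])[0]          # (C, Hf, Wf)
    weights = model.net.Wh[target_class]                # (C,)
    raw = np.maximum(np.tensordot(weights, fmap, axes=1), 0.0)
    up = np.maximum(_bilinear_resize(raw, N_FREQ, N_TIME), 0.0)
    total = float(up.sum())
    if total <= 0:
        fractions = {b: float(GRID.mask(b).sum()) / N_FREQ
                     for b in ("vlf", "lf", "hf")}
        return CAMMap(map=up, class_index=target_class,
                      band_fractions=fractions, degenerate=True)
    fractions = {b: float(up[GRID.mask(b), :].sum() / total)
                 for b in ("vlf", "lf", "hf")}
    return CAMMap(map=up, class_index=target_class, band_fractions=fractions)


def band_attribution_report(cams_by_class: dict) -> dict:
    """Per-class mean +/- SD of the VLF/LF/HF attribution fractions.
    Classes with no maps are omitted (with a warning entry)."""
    report = {}
    for cls, maps in cams_by_class.items():
        if not maps:
            report[cls] = {"warning": "no maps for this class"}
            continue
        fr = {b: np.array([m.band_fractions[b] for m in maps])
              for b in ("vlf", "lf", "hf")}
        report[cls] = {
            "n": len(maps),
            **{b: {"mean": float(v.mean()), "sd": float(v.std(ddof=0))}
               for b, v in fr.items()},
        }
    return report
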