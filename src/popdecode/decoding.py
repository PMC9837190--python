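"""Character decoders on windowed population firing rates.

An LSTM (or CNN) maps each 60-step x n-units window to a per-character
probability distribution over {YES, NO, DNK}. Training minimises the
masked Kullback-Leibler loss: per character, KL(one-hot truth ||
prediction) — i.e. the negative log-probability of the true label —
averaged over characters, with DNK-labelled characters contributing
exactly zero. Evaluation uses 5-fold cross-validation with a 70/10/20
train/validation/test split, epoch selection by mean validation
F1-score, a label-shuffle chance model, and classical baselines.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .labeling import DNK, NO, YES, FoldPlan, WindowSampleSet
from .nn import Adam, CNNDecoder, LSTMDecoder, backward, predict_proba
from .nn import softmax_cross_entropy

__all__ = ["DecoderSpec", "TrainedDecoder", "MetricsReport", "kld_loss",
           "kld_loss_batch", "train_decoder", "predict_activations",
           "predict_label_probs", "binarize", "evaluate_metrics",
           "fold_metrics", "shuffled_chance", "baseline_classifiers"]

EPS = 1e-8


@dataclass
class DecoderSpec:
    architecture: str = "lstm"          # "lstm" | "cnn"
    n_characters: int = 4
    window: int = 60
    hidden: int = 128                   # LSTM units per layer
    num_layers: int = 2
    fc_hidden: int = 128
    channels: tuple = (16, 32, 64)      # CNN conv channels
    kernel: int = 3
    cnn_pools: tuple | None = None      # per-block pool shapes, e.g. ((2,1),(2,2))
    learning_rate: float = 1e-3
    lr_decay: float = 1.0               # multiplicative decay per epoch
    batch_size: int = 64
    max_epochs: int = 100
    patience: int | None = None         # epochs without val improvement
    seed: int = 0


@dataclass
class TrainedDecoder:
    spec: DecoderSpec
    models: list                        # one per trained fold
    fold_ids: list[int]
    unit_ids: np.ndarray
    scaler: tuple[np.ndarray, np.ndarray]   # per-unit (mean, sd)
    history: list[dict] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


def kld_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Masked KLD loss for one sample.

    ``pred``: (C, 3) probability rows; ``truth``: (C,) labels in
    {YES, NO, DNK}. For one-hot ground truth KL(truth || pred) reduces to
    -log pred(true label); DNK characters contribute 0; the mean over all
    C characters is returned.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth)
    if pred.ndim != 2 or pred.shape[1] != 3 or pred.shape[0] != len(truth):
        raise ValueError("pred must be (n_characters, 3) matching truth")
    p = np.clip(pred, EPS, 1.0)
    losses = np.where(truth == DNK, 0.0,
                      -np.log(p[np.arange(len(truth)),
                                np.clip(truth, 0, 2)]))
    return float(losses.mean())


def kld_loss_batch(probs: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """Vectorised masked KLD loss; returns one loss per sample."""
    p = np.clip(probs, EPS, 1.0)
    n, c, _ = p.shape
    picked = -np.log(p[np.arange(n)[:, None], np.arange(c)[None, :],
                       np.clip(truths, 0, 2)])
    return np.where(truths == DNK, 0.0, picked).mean(axis=1)


def _make_model(spec: DecoderSpec, n_units: int, seed: int):
    if spec.architecture == "lstm":
        return LSTMDecoder(n_units, spec.n_characters, spec.hidden,
                           spec.num_layers, spec.fc_hidden, seed=seed)
    if spec.architecture == "cnn":
        return CNNDecoder(n_units, spec.n_characters, spec.channels,
                          spec.kernel, spec.fc_hidden, spec.window,
                          seed=seed, pools=spec.cnn_pools)
    raise ValueError(f"unknown architecture {spec.architecture!r}")


def _macro_f1(pred_bin: np.ndarray, truth: np.ndarray) -> float:
    f1s = []
    for c in range(truth.shape[1]):
        mask = truth[:, c] != DNK
        t = truth[mask, c] == YES
        p = pred_bin[mask, c]
        tp = np.sum(t & p)
        fp = np.sum(~t & p)
        fn = np.sum(t & ~p)
        f1s.append(0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn))
    return float(np.mean(f1s))


def train_decoder(samples: WindowSampleSet, spec: DecoderSpec,
                  plan: FoldPlan, folds: list[int] | None = None,
                  max_train_samples: int | None = None,
                  verbose: bool = False) -> TrainedDecoder:
    """Train one model per requested fold; keep the epoch checkpoint with
    the best mean validation F1. No class weighting is applied."""
    if folds is None:
        folds = list(range(plan.n_folds))
    x_all, y_all = samples.x, samples.y
    models, history = [], []
    scaler = None
    for fold in folds:
        rng = np.random.default_rng((spec.seed, fold))
        idx = plan.folds[fold]
        train_idx = idx["train"]
        if max_train_samples is not None and len(train_idx) > max_train_samples:
            train_idx = rng.choice(train_idx, size=max_train_samples,
                                   replace=False)
        for c in range(spec.n_characters):
            labs = y_all[train_idx, c]
            if min((labs == YES).sum(), (labs == NO).sum()) < 2:
                warnings.warn(f"character {c}: degenerate training split")
        mu = x_all[train_idx].mean(axis=(0, 1))
        sd = x_all[train_idx].std(axis=(0, 1))
        sd[sd == 0] = 1.0
        if scaler is None:
            scaler = (mu, sd)

        def transform(x, mu=mu, sd=sd):
            return (x - mu) / sd

        model = _make_model(spec, x_all.shape[2],
                            seed=int(rng.integers(2 ** 31)))
        opt = Adam(model.parameters(), lr=spec.learning_rate)
        x_val = transform(x_all[idx["val"]])
        y_val = y_all[idx["val"]]
        best_f1, best_state, best_epoch = -1.0, None, -1
        stale = 0
        for epoch in range(spec.max_epochs):
            model.train()
            opt.lr = spec.learning_rate * spec.lr_decay ** epoch
            order = rng.permutation(len(train_idx))
            for start in range(0, len(order), spec.batch_size):
                sel = train_idx[order[start:start + spec.batch_size]]
                xb = transform(x_all[sel])
                yb = y_all[sel].astype(int)
                mask = (yb != DNK).astype(xb.dtype)
                logits = model(xb)
                loss = softmax_cross_entropy(logits, yb, mask)
                opt.zero_grad()
                backward(loss)
                opt.step()
            probs = predict_proba(model, x_val)
            val_f1 = _macro_f1(probs[:, :, YES] > 0.5, y_val)
            if verbose:
                print(f"fold {fold} epoch {epoch}: val F1 {val_f1:.3f}")
            if val_f1 > best_f1:
                best_f1, best_state, best_epoch = val_f1, model.state_dict(), epoch
                stale = 0
            else:
                stale += 1
                if spec.patience is not None and stale > spec.patience:
                    break
        model.load_state_dict(best_state)
        model.eval()
        models.append(model)
        history.append({"fold": fold, "best_epoch": best_epoch,
                        "best_val_f1": best_f1})
    return TrainedDecoder(spec=spec, models=models, fold_ids=list(folds),
                          unit_ids=samples.unit_ids.copy(), scaler=scaler,
                          history=history)


def predict_activations(decoder: TrainedDecoder, x: np.ndarray,
                        unit_ids: np.ndarray | None = None,
                        average_folds: bool = True) -> np.ndarray:
    """Per-character probability of YES ("model activation") in [0, 1].

    ``x`` is raw (n, window, n_units) firing rates in the decoder's unit
    order. Returns (n, C), fold-averaged by default, else (folds, n, C).
    """
    if unit_ids is not None:
        missing = [u for u in decoder.unit_ids if u not in set(unit_ids)]
        if missing:
            raise ValueError(f"input is missing decoder units {missing}")
        order = [int(np.flatnonzero(np.asarray(unit_ids) == u)[0])
                 for u in decoder.unit_ids]
        x = x[:, :, order]
    mu, sd = decoder.scaler
    xt = ((x - mu) / sd).astype(np.float32)
    acts = np.stack([predict_proba(m, xt)[:, :, YES] for m in decoder.models])
    return acts.mean(axis=0) if average_folds else acts


def predict_label_probs(decoder: TrainedDecoder, x: np.ndarray,
                        average_folds: bool = True) -> np.ndarray:
    """Full (n, C, 3) probability tensors, optionally fold-averaged."""
    mu, sd = decoder.scaler
    xt = ((x - mu) / sd).astype(np.float32)
    probs = np.stack([predict_proba(m, xt) for m in decoder.models])
    return probs.mean(axis=0) if average_folds else probs


def binarize(activations: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 iff the activation exceeds the threshold (0.5 maps to 0)."""
    return activations > threshold


@dataclass
class MetricsReport:
    per_character: list[dict]
    macro: dict

    def __getitem__(self, key):
        return self.macro[key]


def evaluate_metrics(pred_bin: np.ndarray, truth: np.ndarray
                     ) -> MetricsReport:
    """Confusion counts and accuracy/recall/precision/F1 per character.

    ``pred_bin``: (n, C) boolean YES predictions; ``truth``: (n, C) labels;
    DNK truths are excluded. F1 is defined as 0 when TP = FP = FN = 0.
    """
    if truth.size == 0:
        raise ValueError("empty input")
    per_char = []
    for c in range(truth.shape[1]):
        mask = truth[:, c] != DNK
        t = truth[mask, c] == YES
        p = np.asarray(pred_bin)[mask, c]
        tp, tn = int(np.sum(t & p)), int(np.sum(~t & ~p))
        fp, fn = int(np.sum(~t & p)), int(np.sum(t & ~p))
        n_yes, n_no = tp + fn, tn + fp
        conf = np.full((2, 2), np.nan)
        if n_yes:
            conf[0] = [tp / n_yes, fn / n_yes]
        if n_no:
            conf[1] = [fp / n_no, tn / n_no]
        recall = tp / n_yes if n_yes else np.nan
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        if tp == 0:
            f1 = 0.0
        else:
            f1 = 2.0 / (1.0 / recall + 1.0 / precision)
        per_char.append({
            "TP": tp, "TN": tn, "FP": fp, "FN": fn, "confusion": conf,
            "accuracy": (tp + tn) / (tp + tn + fp + fn),
            "recall": recall, "precision": precision, "f1": f1})
    macro = {}
    for k in ("accuracy", "recall", "precision", "f1"):
        vals = [d[k] for d in per_char if not np.isnan(d[k])]
        macro[k] = float(np.mean(vals)) if vals else float("nan")
    return MetricsReport(per_character=per_char, macro=macro)


def fold_metrics(decoder: TrainedDecoder, samples: WindowSampleSet,
                      plan: FoldPlan) -> list[MetricsReport]:
    """Per trained fold, metrics on that fold's held-out test set."""
    reports = []
    for model_i, fold in enumerate(decoder.fold_ids):
        test = plan.folds[fold]["test"]
        sub = TrainedDecoder(decoder.spec, [decoder.models[model_i]],
                             [fold], decoder.unit_ids, decoder.scaler)
        act = predict_activations(sub, samples.x[test])
        reports.append(evaluate_metrics(binarize(act), samples.y[test]))
    return reports


def shuffled_chance(samples: WindowSampleSet, spec: DecoderSpec,
                    plan: FoldPlan, n_shuffles: int, seed: int,
                    folds: list[int] | None = None,
                    max_train_samples: int | None = None) -> list[dict]:
    """Chance model: permute whole label vectors across samples (keeping
    the joint label structure), retrain, and collect test metrics."""
    rng = np.random.default_rng(seed)
    results = []
    for s in range(n_shuffles):
        perm = rng.permutation(samples.n_samples)
        shuffled = WindowSampleSet(samples.x, samples.y[perm],
                                   samples.frame_times, samples.unit_ids,
                                   samples.n_dropped)
        sspec = replace(spec, seed=int(rng.integers(2 ** 31)))
        dec = train_decoder(shuffled, sspec, plan, folds=folds,
                            max_train_samples=max_train_samples)
        reports = fold_metrics(dec, shuffled, plan)
        results.append({
            "f1": np.mean([[d["f1"] for d in r.per_character]
                           for r in reports], axis=0),
            "accuracy": np.mean([[d["accuracy"] for d in r.per_character]
                                 for r in reports], axis=0)})
    return results


def baseline_classifiers(samples: WindowSampleSet, plan: FoldPlan,
                         seed: int = 0, folds: list[int] | None = None,
                         methods=("nb_prior", "logreg", "linear_svm")
                         ) -> dict[str, MetricsReport]:
    """Classical baselines on flattened windows, same folds as the deep
    models.

    ``nb_prior`` learns each character's label marginal on the training
    split and emits random predictions from it; ``logreg`` and
    ``linear_svm`` fit one linear classifier per character.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import LinearSVC

    if folds is None:
        folds = list(range(plan.n_folds))
    rng = np.random.default_rng(seed)
    n_char = samples.y.shape[1]
    out = {}
    for method in methods:
        preds_all, truth_all = [], []
        for fold in folds:
            idx = plan.folds[fold]
            xtr = samples.x[idx["train"]].reshape(len(idx["train"]), -1)
            xte = samples.x[idx["test"]].reshape(len(idx["test"]), -1)
            mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
            sd[sd == 0] = 1.0
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
            ytr, yte = samples.y[idx["train"]], samples.y[idx["test"]]
            pred = np.zeros((len(xte), n_char), dtype=bool)
            for c in range(n_char):
                tr_mask = ytr[:, c] != DNK
                yes = ytr[tr_mask, c] == YES
                if method == "nb_prior":
                    q = yes.mean() if tr_mask.any() else 0.0
                    pred[:, c] = rng.random(len(xte)) < q
                else:
                    if yes.all() or not yes.any():
                        pred[:, c] = yes.any()
                        continue
                    if method == "logreg":
                        clf = LogisticRegression(max_iter=200)
                    else:
                        clf = LinearSVC()
                    clf.fit(xtr[tr_mask], yes)
                    pred[:, c] = clf.predict(xte).astype(bool)
            preds_all.append(pred)
            truth_all.append(yte)
        out[method] = evaluate_metrics(np.concatenate(preds_all),
                                       np.concatenate(truth_all))
    return out
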