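"""Knockout importance analysis: which brain regions carry the decoding.

A trained decoder is re-evaluated with the input columns of a unit group
(all units of a region, or all units on one microwire electrode) replaced
by zeros, in rate space. The change in the per-character KLD loss
relative to the intact input, normalized by the number of knocked
neurons, measures how much the model relied on that group. The synergy
statistic — region knockout loss minus the sum of its electrodes'
knockout losses, both un-normalized — is positive when a region carries
more information jointly than its parts do separately.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import (DecoderSpec, TrainedDecoder, fold_metrics,
                       predict_label_probs, train_decoder)
from .labeling import DNK, FoldPlan, WindowSampleSet

__all__ = ["KnockoutResult", "knockout_eval", "region_knockout",
           "electrode_knockout", "synergy_statistic", "split_retrain",
           "summarize_importance", "clopper_pearson"]


class KnockoutResult:
    def __init__(self, scope: str, target: str, delta_kld: np.ndarray,
                 n_neurons: int, region: str | None = None):
        self.scope = scope
        self.target = target
        self.region = region if region is not None else target
        self.delta_kld = np.asarray(delta_kld)          # (C,) un-normalized
        self.n_neurons = int(n_neurons)
        self.normalized = self.delta_kld / self.n_neurons

    def __repr__(self):
        return (f"KnockoutResult({self.scope}:{self.target}, n="
                f"{self.n_neurons}, norm={np.round(self.normalized, 3)})")


def _per_character_loss(decoder: TrainedDecoder, x: np.ndarray,
                        y: np.ndarray) -> np.ndarray:
    """Mean KLD loss per character over non-DNK samples, averaged across
    the decoder's fold models."""
    probs = predict_label_probs(decoder, x, average_folds=False)
    n_char = y.shape[1]
    out = np.zeros(n_char)
    idx = np.arange(x.shape[0])
    for c in range(n_char):
        mask = y[:, c] != DNK
        lab = np.clip(y[mask, c].astype(int), 0, 2)
        losses = []
        for fold_probs in probs:
            p = np.clip(fold_probs[mask, c, lab], 1e-8, 1.0)
            losses.append(-np.log(p).mean())
        out[c] = np.mean(losses)
    return out


def knockout_eval(decoder: TrainedDecoder, samples: WindowSampleSet,
                  group_unit_ids, scope: str = "region",
                  target: str = "", eval_idx: np.ndarray | None = None,
                  baseline: np.ndarray | None = None,
                  region: str | None = None) -> KnockoutResult:
    """Zero the rate columns of a unit group and measure the loss change.

    The evaluation set defaults to all samples (the paper's choice of
    the whole training dataset); pass ``eval_idx`` to restrict it. A
    precomputed ``baseline`` (intact per-character loss on the same
    evaluation set) avoids recomputation when iterating over groups.
    """
    group = list(group_unit_ids)
    if not group:
        raise ValueError("empty knockout group")
    id_to_col = {u: i for i, u in enumerate(decoder.unit_ids)}
    missing = [u for u in group if u not in id_to_col]
    if missing:
        raise ValueError(f"unknown unit ids {missing}")
    x = samples.x if eval_idx is None else samples.x[eval_idx]
    y = samples.y if eval_idx is None else samples.y[eval_idx]
    if baseline is None:
        baseline = _per_character_loss(decoder, x, y)
    xk = x.copy()
    xk[:, :, [id_to_col[u] for u in group]] = 0.0
    knocked = _per_character_loss(decoder, xk, y)
    return KnockoutResult(scope, target, knocked - baseline, len(group),
                          region=region)


def _groups(units: pd.DataFrame, by_electrode: bool):
    for (hemi, region), sub in units.groupby(["hemisphere", "region"],
                                             sort=True):
        key = f"{hemi}-{region}"
        if by_electrode:
            for el, esub in sub.groupby("electrode_id", sort=True):
                yield f"{key}-e{el}", key, esub.unit_id.tolist()
        else:
            yield key, key, sub.unit_id.tolist()


def region_knockout(decoder: TrainedDecoder, samples: WindowSampleSet,
                    units: pd.DataFrame,
                    eval_idx: np.ndarray | None = None
                    ) -> list[KnockoutResult]:
    x = samples.x if eval_idx is None else samples.x[eval_idx]
    y = samples.y if eval_idx is None else samples.y[eval_idx]
    base = _per_character_loss(decoder, x, y)
    return [knockout_eval(decoder, samples, ids, "region", key,
                          eval_idx=eval_idx, baseline=base, region=region)
            for key, region, ids in _groups(units, by_electrode=False)]


def electrode_knockout(decoder: TrainedDecoder, samples: WindowSampleSet,
                       units: pd.DataFrame,
                       eval_idx: np.ndarray | None = None
                       ) -> list[KnockoutResult]:
    x = samples.x if eval_idx is None else samples.x[eval_idx]
    y = samples.y if eval_idx is None else samples.y[eval_idx]
    base = _per_character_loss(decoder, x, y)
    return [knockout_eval(decoder, samples, ids, "electrode", key,
                          eval_idx=eval_idx, baseline=base, region=region)
            for key, region, ids in _groups(units, by_electrode=True)]


def synergy_statistic(region_results: list[KnockoutResult],
                      electrode_results: list[KnockoutResult]
                      ) -> pd.DataFrame:
    """Per (region, character): region ΔKLD minus the summed electrode
    ΔKLDs (both un-normalized, same evaluation set and fold models)."""
    rows = []
    for reg in region_results:
        elecs = [e for e in electrode_results if e.region == reg.region]
        if not elecs:
            raise ValueError(f"no electrode results for region {reg.region}")
        n_elec_units = sum(e.n_neurons for e in elecs)
        if n_elec_units != reg.n_neurons:
            raise ValueError(
                f"electrode results for {reg.region} cover {n_elec_units} "
                f"units but the region has {reg.n_neurons}")
        elec_sum = np.sum([e.delta_kld for e in elecs], axis=0)
        stat = reg.delta_kld - elec_sum
        for c, v in enumerate(stat):
            rows.append({"region": reg.region, "character": c,
                         "synergy": float(v)})
    return pd.DataFrame(rows)


def synergy_test(values: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank of the synergy collection against zero.

    Returns (median, p). With all-zero differences the test is undefined
    and p = 1 is reported.
    """
    values = np.asarray(values, dtype=float)
    if np.allclose(values, 0):
        return 0.0, 1.0
    res = stats.wilcoxon(values)
    return float(np.median(values)), float(res.pvalue)


def split_retrain(samples: WindowSampleSet, units: pd.DataFrame,
                  important_regions: list[str], spec: DecoderSpec,
                  plan: FoldPlan, folds: list[int] | None = None,
                  max_imbalance: float = 0.2,
                  max_train_samples: int | None = None):
    """Train two decoders from scratch on complementary unit sets
    (important regions vs. the rest) and compare per-character F1s.

    Returns (important MetricsReports, remainder MetricsReports,
    rank-sum p-value). The split must leave the two sides within
    ``max_imbalance`` of the total unit count of each other.
    """
    keys = units.apply(lambda r: f"{r.hemisphere}-{r.region}", axis=1)
    in_imp = keys.isin(important_regions) | units.region.isin(
        important_regions)
    ids_a = units.unit_id[in_imp].to_numpy()
    ids_b = units.unit_id[~in_imp].to_numpy()
    total = len(units)
    if abs(len(ids_a) - len(ids_b)) > max_imbalance * total:
        raise ValueError(
            f"unit split {len(ids_a)}/{len(ids_b)} exceeds the balance "
            "constraint; regroup regions to equalise the two sides")
    reports = []
    for ids in (ids_a, ids_b):
        cols = [int(np.flatnonzero(samples.unit_ids == u)[0]) for u in ids]
        sub = WindowSampleSet(samples.x[:, :, cols], samples.y,
                              samples.frame_times, np.asarray(ids),
                              samples.n_dropped)
        dec = train_decoder(sub, spec, plan, folds=folds,
                            max_train_samples=max_train_samples)
        reports.append(fold_metrics(dec, sub, plan))
    f1_a = np.concatenate([[d["f1"] for d in r.per_character]
                           for r in reports[0]])
    f1_b = np.concatenate([[d["f1"] for d in r.per_character]
                           for r in reports[1]])
    p = float(stats.ranksums(f1_a, f1_b).pvalue)
    return reports[0], reports[1], p


def clopper_pearson(k: int, n: int, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Exact binomial proportion confidence interval, as fractions."""
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def summarize_importance(values_by_region: dict[str, np.ndarray],
                         threshold: float = 0.5,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per region: how often the normalized ΔKLD exceeds the threshold.

    Values are pooled across participants and characters; the proportion
    is reported as a percentage with its exact Clopper-Pearson interval.
    Regions with no values are omitted.
    """
    rows = []
    for region, values in values_by_region.items():
        values = np.asarray(values, dtype=float)
        n = len(values)
        if n == 0:
            continue
        k = int((values > threshold).sum())
        lo, hi = clopper_pearson(k, n, alpha)
        rows.append({"region": region, "k": k, "n": n,
                     "proportion_pct": 100.0 * k / n,
                     "ci_low_pct": 100.0 * lo, "ci_high_pct": 100.0 * hi})
    return pd.DataFrame(rows)
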