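"""Reproducibility experiments: the package's benchmark analyses run
end-to-end on synthetic recordings.

Each function generates its own data from a seed, runs the relevant
pipeline stage, and returns summary numbers. Problem sizes are scaled
for a single CPU: decoder-recovery uses the full 42-minute timeline with
40 units but trains on a subsample of windows for a bounded number of
epochs; the knockout and synergy experiments use shorter (8-minute)
sessions with smaller recurrent decoders. docs/methods.md discusses
these choices.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .clustering import default_config, run_stage2
from .decoding import (DecoderSpec, shuffled_chance, fold_metrics,
                       train_decoder)
from .importance import (electrode_knockout, region_knockout,
                         synergy_statistic, synergy_test)
from .labeling import build_frame_labels, make_fold_plan, make_window_samples
from .memory import association_matrix, glm_activation
from .preprocess import bin_and_resample, filter_low_rate_units
from .synthetic import (PopulationSpec, TimelineConfig, UnitSpec,
                        generate_character_timeline, generate_embeddings,
                        make_population, simulate_spikes)

__all__ = ["decoder_recovery", "knockout_ordering", "synergy_experiment",
           "glm_recovery", "glm_null_calibration", "association_recovery",
           "clustering_recovery"]


def _movie_windows(seed: int, pop: PopulationSpec, duration_s: float,
                   prevalence: float = 0.15):
    cfg = TimelineConfig(prevalence=prevalence, duration_s=duration_s)
    timeline = generate_character_timeline(cfg, seed)
    spikes = filter_low_rate_units(simulate_spikes(timeline, pop, seed + 10_000))
    rates = bin_and_resample(spikes)
    samples = make_window_samples(rates, build_frame_labels(timeline))
    return timeline, spikes, samples


def decoder_recovery(seed: int, n_shuffles: int = 10) -> dict:
    """Both decoder architectures on a 40-unit, 4-character, 42-minute
    synthetic session with strong tuning (gain 3, prevalence 0.15),
    against a 10-shuffle label-permutation chance model.

    Returns per-architecture per-character test F1 (fold 0) and the
    maximum shuffled-chance F1.
    """
    pop = make_population(
        ["occipital", "superior_temporal", "frontal", "cingulate",
         "hippocampus"],
        {"occipital": 0, "superior_temporal": 1, "frontal": 2,
         "cingulate": 3},                 # hippocampus untuned
        n_electrodes=8, units_per_electrode=1, baseline_hz=2.0, gain=3.0)
    _, _, samples = _movie_windows(seed, pop, duration_s=2520.0)
    plan = make_fold_plan(samples.n_samples, seed)
    out: dict = {"n_samples": samples.n_samples}
    lstm_spec = DecoderSpec(architecture="lstm", hidden=32, fc_hidden=32,
                            max_epochs=8, batch_size=256,
                            learning_rate=3e-3, seed=seed)
    cnn_spec = DecoderSpec(architecture="cnn", channels=(8, 16),
                           kernel=(3, 1), cnn_pools=((2, 1), (3, 1)),
                           fc_hidden=64, max_epochs=8, batch_size=128,
                           learning_rate=3e-3, lr_decay=0.8, seed=seed)
    for name, spec, max_train in (("lstm", lstm_spec, 6000),
                                  ("cnn", cnn_spec, 8000)):
        dec = train_decoder(samples, spec, plan, folds=[0],
                            max_train_samples=max_train)
        rep = fold_metrics(dec, samples, plan)[0]
        out[f"{name}_f1"] = np.array([d["f1"] for d in rep.per_character])
        out[f"{name}_accuracy"] = np.array(
            [d["accuracy"] for d in rep.per_character])
    chance = shuffled_chance(samples, lstm_spec, plan, n_shuffles,
                             seed + 1, folds=[0], max_train_samples=3000)
    out["shuffle_f1"] = np.array([c["f1"] for c in chance])
    out["shuffle_max_f1"] = float(out["shuffle_f1"].max())
    return out


def knockout_ordering(seed: int, n_runs: int = 20) -> dict:
    """Across seeded runs, does the uniquely informative region rank
    first by normalized knockout ΔKLD?"""
    regions = ["occipital", "frontal", "parietal"]
    successes = 0
    for r in range(n_runs):
        run_seed = seed + 37 * r
        units, uid = [], 0
        for region in regions:
            for el in range(8):
                gains = np.ones(4)
                if region == "occipital":   # character-selective electrodes
                    gains[el % 4] = 3.0
                for _ in range(2):
                    units.append(UnitSpec(uid, region, "L", el, 2.0, gains))
                    uid += 1
        pop = PopulationSpec(units=units, rho=0.0)
        _, spikes, samples = _movie_windows(run_seed, pop, duration_s=600.0)
        plan = make_fold_plan(samples.n_samples, run_seed)
        spec = DecoderSpec(architecture="lstm", hidden=16, fc_hidden=16,
                           max_epochs=4, batch_size=256, learning_rate=3e-3,
                           seed=run_seed)
        dec = train_decoder(samples, spec, plan, folds=[0])
        rng = np.random.default_rng(run_seed)
        eval_idx = rng.choice(samples.n_samples, size=2500, replace=False)
        results = region_knockout(dec, samples, spikes.units,
                                  eval_idx=eval_idx)
        mean_norm = {r.target: r.normalized.mean() for r in results}
        best = max(mean_norm, key=mean_norm.get)
        successes += int(best == "L-occipital")
    return {"n_runs": n_runs, "successes": successes,
            "success_rate": successes / n_runs}


def synergy_experiment(seed: int, n_participants: int = 9) -> dict:
    """Region-minus-sum-of-electrodes synergy under independent (rho=0)
    and correlated (rho=0.5) within-region coding.

    Each simulated participant has four regions, each tuned to one
    character, so every region carries a modest share of the loss and
    the statistic is collected over all (region, character) pairs per
    participant, as in a pooled-regions summary.
    """
    regions = {"occipital": 0, "superior_temporal": 1, "frontal": 2,
               "cingulate": 3}
    out = {}
    for rho in (0.0, 0.5):
        values = []
        for p in range(n_participants):
            run_seed = seed + 101 * p
            units, uid = [], 0
            for region, char in regions.items():
                gains = np.ones(4)
                gains[char] = 2.5
                for el in range(4):
                    for _ in range(2):
                        units.append(UnitSpec(uid, region, "L", el, 2.0,
                                              gains.copy()))
                        uid += 1
            pop = PopulationSpec(units=units, rho=rho)
            _, spikes, samples = _movie_windows(run_seed, pop,
                                                duration_s=480.0)
            plan = make_fold_plan(samples.n_samples, run_seed)
            spec = DecoderSpec(architecture="lstm", hidden=16, fc_hidden=16,
                               max_epochs=4, batch_size=256,
                               learning_rate=3e-3, seed=run_seed)
            dec = train_decoder(samples, spec, plan, folds=[0])
            rng = np.random.default_rng(run_seed + 7)
            eval_idx = rng.choice(samples.n_samples, size=2000, replace=False)
            reg = region_knockout(dec, samples, spikes.units,
                                  eval_idx=eval_idx)
            ele = electrode_knockout(dec, samples, spikes.units,
                                     eval_idx=eval_idx)
            syn = synergy_statistic(reg, ele)
            values.extend(syn.synergy.tolist())
        median, p_val = synergy_test(np.asarray(values))
        out[rho] = {"values": np.asarray(values), "median": median,
                    "p": p_val}
    return {"median_rho0": out[0.0]["median"], "p_rho0": out[0.0]["p"],
            "median_rho05": out[0.5]["median"], "p_rho05": out[0.5]["p"],
            "n_pairs": len(out[0.5]["values"])}


def _synthetic_clip_design(rng: np.random.Generator, n_clips: int,
                           n_char: int = 4):
    import pandas as pd
    presence = rng.random((n_clips, n_char)) < 0.3
    clips = pd.DataFrame({
        "clip_id": np.arange(n_clips),
        "response_seen": rng.random(n_clips) < 0.5,
        "is_target": rng.random(n_clips) < 0.5})
    return clips, presence


def glm_recovery(seed: int, n_runs: int = 50, n_clips: int = 200,
                 presence_coef: float = 0.39, seen_coef: float = 0.24,
                 noise_sd: float = 0.3) -> dict:
    """Parameter recovery of the activation GLM: planted presence/seen
    effects on synthetic clip activations; fraction of runs whose 95%
    CIs cover the planted values."""
    rng = np.random.default_rng(seed)
    cover_p = cover_s = 0
    for _ in range(n_runs):
        clips, presence = _synthetic_clip_design(rng, n_clips)
        seen = np.repeat(clips.response_seen.to_numpy(float), 4)
        act = (presence_coef * presence.astype(float).ravel()
               + seen_coef * seen
               + rng.normal(0, noise_sd, 4 * n_clips)
               ).reshape(n_clips, 4)
        res = glm_activation(act, clips, presence)
        lo, hi = res.conf_int.loc["presence"]
        cover_p += int(lo <= presence_coef <= hi)
        lo, hi = res.conf_int.loc["seen"]
        cover_s += int(lo <= seen_coef <= hi)
    return {"n_runs": n_runs,
            "presence_coverage": cover_p / n_runs,
            "seen_coverage": cover_s / n_runs}


def glm_null_calibration(seed: int, n_runs: int = 200,
                         n_clips: int = 200) -> dict:
    """With a zero planted seen-effect, the GLM's seen p-values should be
    uniform; tested by Kolmogorov-Smirnov."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_runs):
        clips, presence = _synthetic_clip_design(rng, n_clips)
        act = (0.39 * presence.astype(float).ravel()
               + rng.normal(0, 0.3, 4 * n_clips)).reshape(n_clips, 4)
        res = glm_activation(act, clips, presence)
        pvals.append(float(res.pvalues["seen"]))
    ks = stats.kstest(pvals, "uniform")
    return {"n_runs": n_runs, "ks_p": float(ks.pvalue),
            "pvals": np.asarray(pvals)}


def association_recovery(seed: int, duration_s: float = 2520.0) -> dict:
    """Recovered scene co-occurrence conditionals vs. the planted ones."""
    cfg = TimelineConfig(prevalence=0.15, duration_s=duration_s)
    timeline = generate_character_timeline(cfg, seed)
    recovered = association_matrix(timeline.scene_table())
    err = np.abs(recovered - timeline.planted_conditionals)
    return {"max_abs_error": float(np.nanmax(err)),
            "recovered": recovered,
            "planted": timeline.planted_conditionals}


def clustering_recovery(seed: int) -> dict:
    """Full Stage-2 identity clustering on planted embeddings."""
    crops = generate_embeddings(4, 12, noise_sd=0.5, faceless_fraction=0.2,
                                seed=seed)
    result = run_stage2(crops, default_config(crops, 4, seed=seed))
    return {"n_components": len(result.components),
            "n_iterations": result.n_iterations,
            "purity": result.purity,
            "completeness": result.completeness}
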