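"""Memory-test analyses: activation GLM, character associations, and
model coactivation structure.

A decoder trained on movie viewing is applied to the recognition-test
recording. Its per-character activation (probability of visual
presence), summed over a two-second window after clip onset and
averaged across folds, is modelled as a function of the character's
presence in the clip, the participant's subjective "seen" response, and
the clip's target/lure status. Character associations from scene
co-occurrence are compared against the model's conditional coactivation
probabilities, and coactivation is contrasted between the clip-viewing
and response phases.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .decoding import TrainedDecoder, predict_activations
from .preprocess import RateMatrix, bin_and_resample
from .synthetic import MemorySession

__all__ = ["clip_presence", "session_activations", "summed_activation",
           "GLMResult", "glm_activation", "mtl_knockout_memory_glm",
           "association_matrix", "coactivation_matrix",
           "correlate_association_coactivation",
           "compare_phase_coactivation"]


def clip_presence(clips: pd.DataFrame, prevalence_threshold: float = 0.2,
                  size_threshold: float = 0.0) -> np.ndarray:
    """Per-clip, per-character presence: occurrence fraction at or above
    the prevalence threshold AND maximum size at or above the size
    threshold."""
    if not (0 <= prevalence_threshold <= 1 and 0 <= size_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    n_char = sum(c.startswith("presence_frac_") for c in clips.columns)
    frac = clips[[f"presence_frac_{c}" for c in range(n_char)]].to_numpy()
    size = clips[[f"max_size_{c}" for c in range(n_char)]].to_numpy()
    return (frac >= prevalence_threshold) & (size >= size_threshold)


def session_windows(rates: RateMatrix, step_hz: float = 7.5,
                    window_steps: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Sliding rate windows over a session at ``step_hz``.

    Returns (times, x) with x of shape (n, window_steps, n_units)."""
    fs = rates.sample_rate_hz
    half = window_steps // 2
    duration = rates.rates.shape[1] / fs
    times = np.arange(1.0, duration - 1.0, 1.0 / step_hz)
    rt = rates.rates.T.astype(np.float32, copy=False)
    idx = []
    kept = []
    for t in times:
        center = int(round((t - rates.t0) * fs))
        if center - half < 0 or center + half > rt.shape[0]:
            continue
        idx.append(np.arange(center - half, center + half))
        kept.append(t)
    return np.asarray(kept), rt[np.asarray(idx)]


def session_activations(decoder: TrainedDecoder, session: MemorySession,
                        step_hz: float = 7.5,
                        mtl_knockout_units: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fold-averaged activation traces over a memory session.

    Returns (times, activations (n, C)). With ``mtl_knockout_units`` the
    corresponding rate columns are zeroed before decoding."""
    rates = bin_and_resample(session.spikes)
    times, x = session_windows(rates, step_hz=step_hz)
    if mtl_knockout_units is not None and len(mtl_knockout_units):
        cols = [int(np.flatnonzero(rates.unit_ids == u)[0])
                for u in mtl_knockout_units]
        x = x.copy()
        x[:, :, cols] = 0.0
    acts = predict_activations(decoder, x)
    return times, acts


def summed_activation(times: np.ndarray, acts: np.ndarray,
                      clips: pd.DataFrame, window_s: float = 2.0,
                      anchor: str = "onset") -> np.ndarray:
    """Activation summed over a window per clip: [onset, onset + 2 s) by
    default; ``anchor`` in {"onset", "offset", "pre_response"}."""
    out = np.zeros((len(clips), acts.shape[1]))
    for i, row in clips.iterrows():
        if anchor == "onset":
            lo = row.onset_s
        elif anchor == "offset":
            lo = row.offset_s
        elif anchor == "pre_response":
            lo = row.response_offset_s - window_s
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        sel = (times >= lo) & (times < lo + window_s)
        out[i] = acts[sel].sum(axis=0)
    return out


@dataclass
class GLMResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    terms: list[str]
    result: object

    def __getitem__(self, term: str) -> float:
        return float(self.params[term])


def glm_activation(activation_sum: np.ndarray, clips: pd.DataFrame,
                   presence: np.ndarray,
                   terms=("presence", "seen", "target"),
                   interaction: bool = False,
                   appearance_freq: np.ndarray | None = None) -> GLMResult:
    """Gaussian-identity GLM of per-(clip, character) summed activation.

    Main terms: character-in-clip, clip-marked-seen, clip-is-target;
    optional presence x seen interaction and appearance-frequency
    covariate."""
    if len(clips) < 30:
        raise ValueError("need at least 30 clips for the activation GLM")
    n_clips, n_char = activation_sum.shape
    cols = {}
    if "presence" in terms:
        cols["presence"] = presence.astype(float).ravel()
    if "seen" in terms:
        cols["seen"] = np.repeat(clips.response_seen.to_numpy(dtype=float),
                                 n_char)
    if "target" in terms:
        cols["target"] = np.repeat(clips.is_target.to_numpy(dtype=float),
                                   n_char)
    if interaction:
        cols["presence_x_seen"] = cols["presence"] * cols["seen"]
    if appearance_freq is not None:
        cols["appearance_freq"] = np.asarray(appearance_freq,
                                             dtype=float).ravel()
    design = pd.DataFrame(cols)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise ValueError(f"degenerate design: constant column(s) {constant}")
    x = sm.add_constant(design)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        corr = design.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear columns {worst}")
    model = sm.GLM(activation_sum.ravel(), x,
                   family=sm.families.Gaussian())
    res = model.fit()
    ci = res.conf_int()
    ci.columns = ["low", "high"]
    return GLMResult(params=res.params, bse=res.bse, pvalues=res.pvalues,
                     conf_int=ci, terms=list(design.columns), result=res)


def mtl_knockout_memory_glm(decoder: TrainedDecoder, session: MemorySession,
                            mtl_regions, presence: np.ndarray | None = None,
                            terms=("presence", "seen", "target"),
                            step_hz: float = 7.5
                            ) -> tuple[GLMResult, GLMResult]:
    """Activation GLM before and after zeroing all MTL units.

    Knockout is re-evaluation only: the decoder is unchanged, its MTL
    input columns are replaced by zeros."""
    units = session.spikes.units
    mtl_lower = {r.lower() for r in mtl_regions}
    mtl_ids = units.unit_id[units.region.str.lower().isin(mtl_lower)
                            ].to_numpy()
    if len(mtl_ids) == 0:
        warnings.warn("no MTL units; knockout GLM equals the intact GLM")
    if presence is None:
        presence = clip_presence(session.clips)
    out = []
    for knock in (None, mtl_ids):
        times, acts = session_activations(decoder, session, step_hz=step_hz,
                                          mtl_knockout_units=knock)
        summed = summed_activation(times, acts, session.clips)
        out.append(glm_activation(summed, session.clips, presence,
                                  terms=terms))
    return out[0], out[1]


def association_matrix(scene_table: pd.DataFrame) -> np.ndarray:
    """p(c_i | c_j): summed duration of scenes containing both characters
    over summed duration of scenes containing the conditioned character
    c_j. Columns of characters that never appear are NaN."""
    chars = [c for c in scene_table.columns if c.startswith("char_")]
    n = len(chars)
    pres = scene_table[chars].to_numpy(dtype=bool)
    dur = scene_table["duration_s"].to_numpy(dtype=float)
    out = np.full((n, n), np.nan)
    for j in range(n):
        denom = dur[pres[:, j]].sum()
        if denom <= 0:
            continue
        for i in range(n):
            out[i, j] = dur[pres[:, i] & pres[:, j]].sum() / denom
    return out


def phase_activated(times: np.ndarray, acts: np.ndarray,
                    clips: pd.DataFrame, phase: str,
                    threshold: float = 0.5) -> np.ndarray:
    """Per trial, per character: did the activation exceed the threshold
    anywhere in the phase ("clip" viewing or "response" time)?"""
    if phase not in ("clip", "response"):
        raise ValueError("phase must be 'clip' or 'response'")
    n_char = acts.shape[1]
    activated = np.zeros((len(clips), n_char), dtype=bool)
    for i, row in clips.iterrows():
        lo, hi = ((row.onset_s, row.offset_s) if phase == "clip"
                  else (row.response_onset_s, row.response_offset_s))
        sel = (times >= lo) & (times < hi)
        if sel.any():
            activated[i] = acts[sel].max(axis=0) > threshold
    return activated


def coactivation_matrix(times: np.ndarray, acts: np.ndarray,
                        clips: pd.DataFrame, phase: str,
                        threshold: float = 0.5) -> np.ndarray:
    """P_model(c_i | c_j): trials where both characters activate over
    trials where the conditioned character c_j activates; NaN where c_j
    never activates."""
    act = phase_activated(times, acts, clips, phase, threshold)
    n = act.shape[1]
    out = np.full((n, n), np.nan)
    for j in range(n):
        nj = act[:, j].sum()
        if nj == 0:
            continue
        for i in range(n):
            out[i, j] = np.sum(act[:, i] & act[:, j]) / nj
    return out


def correlate_association_coactivation(assoc: np.ndarray,
                                       coact: np.ndarray
                                       ) -> tuple[float, float]:
    """Spearman correlation over the off-diagonal entries; diagonal
    values are excluded, undefined pairs dropped pairwise."""
    n = assoc.shape[0]
    off = ~np.eye(n, dtype=bool)
    a, b = assoc[off], coact[off]
    ok = ~(np.isnan(a) | np.isnan(b))
    res = stats.spearmanr(a[ok], b[ok])
    return float(res.statistic), float(res.pvalue)


def compare_phase_coactivation(coact_clip: np.ndarray,
                               coact_response: np.ndarray
                               ) -> tuple[float, float]:
    """Wilcoxon sign-rank of the paired conditional probabilities between
    response time and clip viewing. Returns (p, median difference)."""
    a, b = coact_clip.ravel(), coact_response.ravel()
    ok = ~(np.isnan(a) | np.isnan(b))
    diffs = b[ok] - a[ok]
    if len(diffs) < 6:
        warnings.warn("fewer than 6 defined pairs; test underpowered")
    if np.allclose(diffs, 0):
        return 1.0, 0.0
    res = stats.wilcoxon(b[ok], a[ok])
    return float(res.pvalue), float(np.median(diffs))
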