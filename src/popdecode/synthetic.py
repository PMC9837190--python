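"""Synthetic recordings with the statistical structure of a movie-viewing
single-unit experiment.

The generator emulates, at the level of summary statistics, a session in
which a participant watches a ~42-minute episode while single units are
recorded on region-organised microwire electrodes, followed by a
clip-recognition memory test:

* a character timeline built scene-first: scenes carry character subsets
  drawn from an explicit co-occurrence model, scenes are tiled by cuts,
  and characters are visible piecewise-constantly within cuts (with
  planted dialogue alternations that later receive DNK labels);
* inhomogeneous-Poisson spiking with per-character multiplicative rate
  gains, character-size modulation, per-region shared log-normal gain
  noise (the within-region correlation control), and optional global
  synchronous bursts used as artifact fixtures;
* a memory session of half target / half lure clips with a two-parameter
  (hit rate / false-alarm rate) response model and a plantable
  reinstatement drive restricted to MTL-tagged units;
* crop-cluster embedding sets with planted identities for the
  supernode-clustering stage.

Every generator is deterministic given its seed.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TimelineConfig", "CharacterTimeline", "UnitSpec", "PopulationSpec",
    "SpikeDataset", "MemorySessionSpec", "MemorySession", "CropCluster",
    "CropClusterSet", "generate_character_timeline", "simulate_spikes",
    "generate_memory_session", "generate_embeddings", "make_population",
    "default_cooccurrence",
]


def default_cooccurrence(n_characters: int = 4) -> np.ndarray:
    """Default pairwise co-occurrence weight matrix (unit diagonal).

    Entry (i, j), i != j, is the probability that character j joins a
    scene anchored by character i.
    """
    w = np.full((n_characters, n_characters), 0.15)
    for i in range(n_characters):
        w[i, i] = 1.0
        if i + 1 < n_characters:
            w[i, i + 1] = w[i + 1, i] = 0.35
    return w


@dataclass
class TimelineConfig:
    n_characters: int = 4
    duration_s: float = 2520.0
    frame_rate_hz: float = 7.5          # 30 fps downsampled by 4
    prevalence: float | np.ndarray = 0.10
    mean_scene_s: float = 12.0
    mean_cut_s: float = 4.0
    dialogue_rate_per_min: float = 1.2  # drives DNK labels
    visibility: float = 0.8             # P(on screen in a cut | in the scene)
    cooccurrence: np.ndarray | None = None
    size_beta: tuple[float, float] = (2.0, 5.0)
    size_max: float = 0.5               # reference: half frame

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        prev = np.broadcast_to(np.asarray(self.prevalence, dtype=float),
                               (self.n_characters,)).copy()
        if np.any(prev < 0) or np.any(prev > 1):
            raise ValueError("prevalence must lie in [0, 1]")
        self.prevalence = prev
        if self.cooccurrence is None:
            self.cooccurrence = default_cooccurrence(self.n_characters)
        w = np.asarray(self.cooccurrence, dtype=float)
        if w.shape != (self.n_characters, self.n_characters):
            raise ValueError("co-occurrence matrix has wrong shape")
        if np.any(w < 0) or np.any(w > 1) or not np.allclose(np.diag(w), 1.0):
            raise ValueError("co-occurrence weights must be in [0,1] with "
                             "unit diagonal")
        self.cooccurrence = w


@dataclass
class CharacterTimeline:
    frame_times: np.ndarray            # (F,) seconds, strictly increasing
    occupancy: np.ndarray              # (F, C) bool
    size: np.ndarray                   # (F, C) fraction of frame in [0, 0.5]
    cuts: list[tuple[float, float]]
    scenes: list[tuple[float, float]]
    scene_sets: np.ndarray             # (S, C) bool, planted per-scene subsets
    ambiguity_intervals: list[tuple[float, float, frozenset]]
    planted_conditionals: np.ndarray   # (C, C) exact P(i in S | j in S)
    config: TimelineConfig

    @property
    def n_characters(self) -> int:
        return self.occupancy.shape[1]

    @property
    def duration_s(self) -> float:
        return self.config.duration_s

    def scene_table(self) -> pd.DataFrame:
        """Scenes with durations and the characters *observed* in them."""
        rows = []
        for s, (start, end) in enumerate(self.scenes):
            in_scene = (self.frame_times >= start) & (self.frame_times < end)
            present = self.occupancy[in_scene].any(axis=0)
            rows.append({"scene_id": s, "start_s": start, "end_s": end,
                         "duration_s": end - start,
                         **{f"char_{c}": bool(present[c])
                            for c in range(self.n_characters)}})
        return pd.DataFrame(rows)


def _subset_distribution(pi: np.ndarray, p_empty: float, w: np.ndarray
                         ) -> dict[frozenset, float]:
    """Exact subset distribution of the anchor + pairwise-inclusion model.

    With probability ``p_empty`` the scene is empty; otherwise an anchor
    character i is drawn from ``pi`` and every other character j joins
    independently with probability w[i, j].
    """
    n = len(pi)
    dist: dict[frozenset, float] = {}
    for members in itertools.chain.from_iterable(
            itertools.combinations(range(n), r) for r in range(n + 1)):
        s = frozenset(members)
        p = p_empty if not s else 0.0
        for i in s:
            q = pi[i]
            for j in range(n):
                if j == i:
                    continue
                q *= w[i, j] if j in s else 1.0 - w[i, j]
            p += (1.0 - p_empty) * q
        if p > 0:
            dist[s] = p
    return dist


def _solve_scene_model(config: TimelineConfig,
                       visibility: np.ndarray | float | None = None
                       ) -> tuple[np.ndarray, float, np.ndarray]:
    """Find anchor probabilities and empty-scene probability so that the
    per-character scene-membership marginals equal prevalence/visibility."""
    n = config.n_characters
    w = config.cooccurrence.copy()
    if visibility is None:
        visibility = config.visibility
    target = np.asarray(config.prevalence) / visibility
    if np.any(target > 1):
        raise ValueError("prevalence not achievable at this visibility")
    zero = target <= 0
    w[:, zero] = 0.0
    np.fill_diagonal(w, 1.0)
    # marginal_i = sum_j u_j * M[j, i], with u = (1 - p_empty) * pi
    m = w.T.copy()
    u = np.linalg.solve(m, target)
    if np.any(u < -1e-9):
        raise ValueError("co-occurrence weights incompatible with the "
                         "requested prevalence")
    u = np.clip(u, 0.0, None)
    total = u.sum()
    if total > 1 + 1e-9:
        raise ValueError("requested prevalence too high for scene model")
    p_empty = max(0.0, 1.0 - total)
    pi = u / total if total > 0 else np.full(n, 1.0 / n)
    return pi, p_empty, w


def generate_character_timeline(config: TimelineConfig, seed: int
                                ) -> CharacterTimeline:
    rng = np.random.default_rng(seed)
    n = config.n_characters
    dur = config.duration_s

    # Dialogue alternation shows each speaker only ~half the time, which
    # depresses empirical prevalence below the scene-membership marginal
    # times visibility; correct the solve target iteratively with the
    # exact expected deficit under the subset distribution.
    v = config.visibility
    n_cuts_est = dur / config.mean_cut_s
    n_dialogue_est = config.dialogue_rate_per_min * dur / 60.0
    v_eff = np.full(n, v)
    for _ in range(3):
        pi, p_empty, w = _solve_scene_model(config, v_eff)
        dist = _subset_distribution(pi, p_empty, w)
        marg = np.zeros(n)
        pair_exp = np.zeros(n)   # E[ (2/|S|) 1(|S|>=2) 1(c in S) ]
        elig = 0.0
        for s, p in dist.items():
            for i in s:
                marg[i] += p
            if len(s) >= 2:
                elig += p
                for i in s:
                    pair_exp[i] += p * 2.0 / len(s)
        if elig <= 0:
            break
        f_cut = min(1.0, n_dialogue_est / (n_cuts_est * elig))
        with np.errstate(invalid="ignore", divide="ignore"):
            deficit = np.where(marg > 0,
                               f_cut * (v - 0.5) * pair_exp / marg, 0.0)
        v_eff = np.clip(v - deficit, 0.05, 1.0)

    # planted conditionals P(i in S | j in S), exact under the scene model
    marg = np.zeros(n)
    pair = np.zeros((n, n))
    for s, p in dist.items():
        for i in s:
            marg[i] += p
            for j in s:
                pair[i, j] += p
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = pair / marg[None, :]

    # scene skeleton: gamma(2) durations, balanced subset assignment;
    # durations are rescaled within each subset group so that every
    # group's total screen time matches its count share, which makes the
    # duration-weighted co-occurrence statistics track the planted ones
    n_scenes = max(1, int(round(dur / config.mean_scene_s)))
    subsets = list(dist.keys())
    probs = np.array([dist[s] for s in subsets])
    counts = np.floor(probs * n_scenes).astype(int)
    rem = probs * n_scenes - counts
    short = n_scenes - counts.sum()
    for idx in np.argsort(-rem)[:short]:
        counts[idx] += 1
    assignment = np.repeat(np.arange(len(subsets)), counts)
    rng.shuffle(assignment)

    scene_dur = np.maximum(rng.gamma(2.0, config.mean_scene_s / 2.0, n_scenes),
                           2.0)
    mean_len = dur / n_scenes
    for a in range(len(subsets)):
        sel = assignment == a
        if sel.any():
            scene_dur[sel] *= (sel.sum() * mean_len) / scene_dur[sel].sum()
    scene_edges = np.concatenate([[0.0], np.cumsum(scene_dur)])
    scene_edges[-1] = dur
    scenes = [(scene_edges[k], scene_edges[k + 1]) for k in range(n_scenes)]

    scene_sets = np.zeros((n_scenes, n), dtype=bool)
    for k, a in enumerate(assignment):
        for c in subsets[a]:
            scene_sets[k, c] = True

    # frames
    n_frames = int(round(dur * config.frame_rate_hz))
    frame_times = np.arange(n_frames) / config.frame_rate_hz
    occupancy = np.zeros((n_frames, n), dtype=bool)
    size = np.zeros((n_frames, n))

    # cuts tile each scene
    cuts: list[tuple[float, float]] = []
    cut_scene: list[int] = []
    for k, (start, end) in enumerate(scenes):
        t = start
        while t < end - 1e-9:
            length = max(1.0, rng.gamma(2.0, config.mean_cut_s / 2.0))
            cut_end = min(end, t + length)
            if end - cut_end < 1.0:
                cut_end = end
            cuts.append((t, cut_end))
            cut_scene.append(k)
            t = cut_end

    n_dialogue = int(round(config.dialogue_rate_per_min * dur / 60.0))
    eligible = [ci for ci, (s, e) in enumerate(cuts)
                if scene_sets[cut_scene[ci]].sum() >= 2 and (e - s) >= 2.0]
    dialogue_cuts = set(
        rng.choice(eligible, size=min(n_dialogue, len(eligible)),
                   replace=False).tolist()) if eligible else set()

    ambiguity: list[tuple[float, float, frozenset]] = []
    a_beta, b_beta = config.size_beta
    dialogue_pair: dict[int, np.ndarray] = {}
    for ci in sorted(dialogue_cuts):
        members = np.flatnonzero(scene_sets[cut_scene[ci]])
        pair_idx = rng.choice(members, size=2, replace=False)
        dialogue_pair[ci] = pair_idx
        cs, ce = cuts[ci]
        ambiguity.append((cs, ce, frozenset(int(c) for c in pair_idx)))

    scene_cuts: dict[int, list[int]] = {}
    for ci, k in enumerate(cut_scene):
        scene_cuts.setdefault(k, []).append(ci)

    for k in range(n_scenes):
        members = np.flatnonzero(scene_sets[k])
        if members.size == 0:
            continue
        cut_ids = scene_cuts.get(k, [])
        for c in members:
            pair_appearances = [ci for ci in cut_ids
                                if ci in dialogue_pair
                                and c in dialogue_pair[ci]]
            regular = [ci for ci in cut_ids if ci not in pair_appearances]
            visible = [ci for ci in regular
                       if rng.random() < config.visibility]
            if not visible and not pair_appearances and regular:
                # every scene member appears in at least one cut, so the
                # observed scene character set equals the planted subset
                visible = [regular[rng.integers(len(regular))]]
            for ci in visible:
                cs, ce = cuts[ci]
                in_cut = (frame_times >= cs) & (frame_times < ce)
                occupancy[in_cut, c] = True
                size[in_cut, c] = rng.beta(a_beta, b_beta) * config.size_max

    # dialogue cuts: the two speakers alternate in ~1 s blocks
    for ci, pair_idx in dialogue_pair.items():
        cs, ce = cuts[ci]
        idx = np.flatnonzero((frame_times >= cs) & (frame_times < ce))
        block = np.floor((frame_times[idx] - cs) / 1.0).astype(int) % 2
        for which, c in enumerate(pair_idx):
            occupancy[idx, c] = False
            size[idx, c] = 0.0
            sel = idx[block == which]
            occupancy[sel, c] = True
            size[sel, c] = rng.beta(a_beta, b_beta) * config.size_max
    return CharacterTimeline(
        frame_times=frame_times, occupancy=occupancy, size=size, cuts=cuts,
        scenes=scenes, scene_sets=scene_sets, ambiguity_intervals=ambiguity,
        planted_conditionals=np.nan_to_num(cond, nan=0.0), config=config)


# ---------------------------------------------------------------------------
# spiking


@dataclass
class UnitSpec:
    unit_id: int
    region: str
    hemisphere: str
    electrode_id: int
    baseline_hz: float
    gains: np.ndarray          # (C,) multiplicative rate gain per character
    latency_s: float = 0.0

    def __post_init__(self):
        if self.baseline_hz < 0:
            raise ValueError("baseline rate must be >= 0")
        self.gains = np.asarray(self.gains, dtype=float)
        if np.any(self.gains < 0):
            raise ValueError("gains must be >= 0")


@dataclass
class PopulationSpec:
    units: list[UnitSpec]
    rho: float = 0.0           # within-region shared log-gain noise strength
    size_ref: float = 0.15     # character size at which the full gain applies
    noise_tau_s: float = 3.0   # timescale of the shared regional fluctuation

    def __post_init__(self):
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for u in self.units:
            key = f"{u.hemisphere}-{u.region}"
            if key not in seen:
                seen.append(key)
        return seen

    def units_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"unit_id": u.unit_id, "region": u.region,
              "hemisphere": u.hemisphere, "electrode_id": u.electrode_id,
              "baseline_hz": u.baseline_hz} for u in self.units])


def make_population(regions: list[str], tuned_character: dict[str, int],
                    n_electrodes: int = 8, units_per_electrode: int = 1,
                    baseline_hz: float = 2.0, gain: float = 3.0,
                    n_characters: int = 4, rho: float = 0.0,
                    hemisphere: str = "L", latency_s: float = 0.0,
                    ) -> PopulationSpec:
    """Convenience builder: each region's units share one tuned character
    (``tuned_character[region]``, or -1 for an untuned region)."""
    units = []
    uid = 0
    for region in regions:
        char = tuned_character.get(region, -1)
        for el in range(n_electrodes):
            for _ in range(units_per_electrode):
                gains = np.ones(n_characters)
                if char >= 0:
                    gains[char] = gain
                units.append(UnitSpec(uid, region, hemisphere, el,
                                      baseline_hz, gains, latency_s))
                uid += 1
    return PopulationSpec(units=units, rho=rho)


@dataclass
class SpikeDataset:
    events: pd.DataFrame       # columns: unit_id, time_s (sorted per unit)
    units: pd.DataFrame        # unit_id, region, hemisphere, electrode_id, ...
    duration_s: float

    @property
    def n_units(self) -> int:
        return len(self.units)

    def spike_times(self, unit_id: int) -> np.ndarray:
        return self.events.loc[self.events.unit_id == unit_id,
                               "time_s"].to_numpy()

    def total_spikes(self) -> int:
        return len(self.events)


def _rate_on_epochs(timeline: CharacterTimeline, unit: UnitSpec,
                    size_ref: float, epoch_mid: np.ndarray) -> np.ndarray:
    """Per-epoch firing rate (Hz) from character occupancy and size."""
    frame_idx = np.clip(
        np.floor((epoch_mid - unit.latency_s)
                 * timeline.config.frame_rate_hz).astype(int),
        0, len(timeline.frame_times) - 1)
    log_rate = np.full(len(epoch_mid), np.log(max(unit.baseline_hz, 1e-12)))
    occ = timeline.occupancy[frame_idx]
    sz = timeline.size[frame_idx]
    for c in range(timeline.n_characters):
        g = unit.gains[c]
        if g == 1.0:
            continue
        mod = np.clip(sz[:, c] / size_ref, 0.0, 2.0)
        log_rate += np.where(occ[:, c], np.log(max(g, 1e-12)) * mod, 0.0)
    return np.exp(log_rate)


def _shared_region_noise(rng: np.random.Generator, sigma: float,
                         n_epochs: int, epoch_s: float,
                         tau_s: float) -> np.ndarray:
    """Slow multiplicative log-normal gain shared by a region's units.

    Drawn per block of ``tau_s`` seconds so the fluctuation persists
    across a whole decoding window: within-region correlation then acts
    as a redundancy ceiling (one electrode carries nearly the same
    information as all of them), rather than averaging out."""
    if sigma <= 0:
        return np.ones(n_epochs)
    block = max(1, int(round(tau_s / epoch_s)))
    n_blocks = n_epochs // block + 1
    z = rng.normal(-0.5 * sigma ** 2, sigma, n_blocks)
    return np.exp(np.repeat(z, block)[:n_epochs])


def simulate_spikes(timeline: CharacterTimeline, pop: PopulationSpec,
                    seed: int, epoch_s: float = 0.1,
                    burst_times: list[float] | None = None,
                    burst_gain: float = 20.0) -> SpikeDataset:
    rng = np.random.default_rng(seed)
    dur = timeline.duration_s
    n_epochs = int(np.ceil(dur / epoch_s))
    epoch_mid = (np.arange(n_epochs) + 0.5) * epoch_s

    sigma = pop.rho  # shared log-normal gain sd per region
    region_noise: dict[str, np.ndarray] = {
        key: _shared_region_noise(rng, sigma, n_epochs, epoch_s,
                                  pop.noise_tau_s)
        for key in pop.regions}

    burst_mult = np.ones(n_epochs)
    if burst_times:
        for t in burst_times:
            k = int(t / epoch_s)
            if 0 <= k < n_epochs:
                burst_mult[k] *= burst_gain

    rows_unit = []
    rows_time = []
    for unit in pop.units:
        rate = _rate_on_epochs(timeline, unit, pop.size_ref, epoch_mid)
        rate = rate * region_noise[f"{unit.hemisphere}-{unit.region}"]
        rate = rate * burst_mult
        counts = rng.poisson(rate * epoch_s)
        total = int(counts.sum())
        if total:
            offsets = rng.random(total) * epoch_s
            starts = np.repeat(np.arange(n_epochs) * epoch_s, counts)
            times = np.sort(starts + offsets)
            rows_unit.append(np.full(total, unit.unit_id))
            rows_time.append(times)
    if rows_unit:
        events = pd.DataFrame({
            "unit_id": np.concatenate(rows_unit).astype(int),
            "time_s": np.concatenate(rows_time)})
    else:
        events = pd.DataFrame({"unit_id": pd.Series(dtype=int),
                               "time_s": pd.Series(dtype=float)})
    return SpikeDataset(events=events, units=pop.units_table(),
                        duration_s=dur)


# ---------------------------------------------------------------------------
# memory session


MTL_REGIONS = ("hippocampus", "amygdala", "entorhinal", "parahippocampal")


@dataclass
class MemorySessionSpec:
    n_clips: int = 150
    clip_len_s: float = 5.0
    response_len_s: float = 3.0
    gap_s: float = 1.0
    hit_rate: float = 0.8            # P(respond "seen" | target)
    false_alarm_rate: float = 0.2    # P(respond "seen" | lure)
    reinstatement_gain: float = 0.6  # fraction of the tuned log-gain re-expressed
    assoc_drive: float = 0.0         # response-phase associative drive strength
    presence_threshold: float = 0.2  # clip-content characters
    mtl_regions: tuple[str, ...] = MTL_REGIONS

    def __post_init__(self):
        if not 100 <= self.n_clips <= 300:
            warnings.warn("n_clips outside the typical 100-300 range",
                          stacklevel=3)


@dataclass
class MemorySession:
    clips: pd.DataFrame
    spikes: SpikeDataset
    duration_s: float
    spec: MemorySessionSpec


def generate_memory_session(spec: MemorySessionSpec,
                            timeline: CharacterTimeline,
                            lure_timeline: CharacterTimeline,
                            pop: PopulationSpec, seed: int) -> MemorySession:
    rng = np.random.default_rng(seed)
    n = spec.n_clips
    n_target = n // 2
    is_target = np.zeros(n, dtype=bool)
    is_target[rng.choice(n, size=n_target, replace=False)] = True

    n_char = timeline.n_characters
    period = spec.clip_len_s + spec.response_len_s + spec.gap_s
    duration = n * period
    fr = timeline.config.frame_rate_hz

    rows = []
    source_info = []
    for k in range(n):
        src = timeline if is_target[k] else lure_timeline
        max_onset = src.duration_s - spec.clip_len_s - 1.0
        src_onset = rng.uniform(1.0, max_onset)
        onset = k * period
        offset = onset + spec.clip_len_s
        in_clip = ((src.frame_times >= src_onset)
                   & (src.frame_times < src_onset + spec.clip_len_s))
        occ = src.occupancy[in_clip]
        szs = src.size[in_clip]
        frac = occ.mean(axis=0) if occ.size else np.zeros(n_char)
        max_size = szs.max(axis=0) if szs.size else np.zeros(n_char)
        seen = rng.random() < (spec.hit_rate if is_target[k]
                               else spec.false_alarm_rate)
        rows.append({
            "clip_id": k, "onset_s": onset, "offset_s": offset,
            "response_onset_s": offset,
            "response_offset_s": offset + spec.response_len_s,
            "is_target": bool(is_target[k]), "response_seen": bool(seen),
            **{f"presence_frac_{c}": frac[c] for c in range(n_char)},
            **{f"max_size_{c}": max_size[c] for c in range(n_char)}})
        source_info.append((src, src_onset))
    clips = pd.DataFrame(rows)

    # spiking on a 100 ms epoch grid over the session
    epoch_s = 0.1
    n_epochs = int(np.ceil(duration / epoch_s))
    epoch_mid = (np.arange(n_epochs) + 0.5) * epoch_s
    region_noise = {key: _shared_region_noise(rng, pop.rho, n_epochs,
                                              epoch_s, pop.noise_tau_s)
                    for key in pop.regions}

    cond = timeline.planted_conditionals
    unit_logrates = []
    is_mtl = np.array([u.region.lower() in
                       {r.lower() for r in spec.mtl_regions}
                       for u in pop.units])
    for ui, unit in enumerate(pop.units):
        log_rate = np.full(n_epochs, np.log(max(unit.baseline_hz, 1e-12)))
        unit_logrates.append(log_rate)

    for k in range(n):
        src, src_onset = source_info[k]
        row = clips.iloc[k]
        clip_sel = ((epoch_mid >= row.onset_s) & (epoch_mid < row.offset_s))
        resp_sel = ((epoch_mid >= row.response_onset_s)
                    & (epoch_mid < row.response_offset_s))
        src_times = src_onset + (epoch_mid[clip_sel] - row.onset_s)
        frame_idx = np.clip((src_times * fr).astype(int),
                            0, len(src.frame_times) - 1)
        occ = src.occupancy[frame_idx]
        szs = src.size[frame_idx]
        content = np.array([row[f"presence_frac_{c}"] >= spec.presence_threshold
                            for c in range(n_char)])
        for ui, unit in enumerate(pop.units):
            log_rate = unit_logrates[ui]
            # visual drive during clip viewing
            for c in range(n_char):
                g = unit.gains[c]
                if g == 1.0:
                    continue
                logg = np.log(max(g, 1e-12))
                mod = np.clip(szs[:, c] / pop.size_ref, 0.0, 2.0)
                log_rate[clip_sel] += np.where(occ[:, c], logg * mod, 0.0)
                if is_mtl[ui] and row.response_seen and content[c]:
                    # reinstatement of the encoding-time footprint
                    drive = spec.reinstatement_gain * logg
                    log_rate[clip_sel] += drive
                    log_rate[resp_sel] += drive
                if spec.assoc_drive > 0 and row.response_seen:
                    partners = content & (np.arange(n_char) != c)
                    if partners.any():
                        strength = float(np.max(cond[c, partners]))
                        log_rate[resp_sel] += (spec.assoc_drive * strength
                                               * logg)
        # end unit loop
    rows_unit, rows_time = [], []
    for ui, unit in enumerate(pop.units):
        rate = np.exp(unit_logrates[ui])
        rate *= region_noise[f"{unit.hemisphere}-{unit.region}"]
        counts = rng.poisson(rate * epoch_s)
        total = int(counts.sum())
        if total:
            starts = np.repeat(np.arange(n_epochs) * epoch_s, counts)
            times = np.sort(starts + rng.random(total) * epoch_s)
            rows_unit.append(np.full(total, unit.unit_id))
            rows_time.append(times)
    if rows_unit:
        events = pd.DataFrame({
            "unit_id": np.concatenate(rows_unit).astype(int),
            "time_s": np.concatenate(rows_time)})
    else:
        events = pd.DataFrame({"unit_id": pd.Series(dtype=int),
                               "time_s": pd.Series(dtype=float)})
    spikes = SpikeDataset(events=events, units=pop.units_table(),
                          duration_s=duration)
    return MemorySession(clips=clips, spikes=spikes, duration_s=duration,
                         spec=spec)


# ---------------------------------------------------------------------------
# crop-cluster embeddings


@dataclass
class CropCluster:
    cluster_id: int
    embeddings: np.ndarray     # (n_crops, d)
    has_face: np.ndarray       # (n_crops,) bool
    frame_span: tuple[float, float]
    identity: int              # planted ground truth


@dataclass
class CropClusterSet:
    clusters: list[CropCluster]
    dim: int
    noise_sd: float

    def __post_init__(self):
        if any(len(c.embeddings) == 0 for c in self.clusters):
            raise ValueError("clusters must be nonempty")
        if any(c.embeddings.shape[1] != self.dim for c in self.clusters):
            raise ValueError("all embeddings must share dimension d")


def generate_embeddings(n_identities: int, clusters_per_identity: int,
                        noise_sd: float, faceless_fraction: float, seed: int,
                        dim: int = 128, separation: float = 10.0,
                        crops_per_cluster: int = 30,
                        outlier_fraction: float = 0.25,
                        outlier_offset: float = 1.0) -> CropClusterSet:
    """Planted-identity crop-cluster embeddings.

    Identity centroids are Gaussian with per-coordinate scale
    ``separation * noise_sd``; each cluster sits at a small offset from
    its identity centroid, except an ``outlier_fraction`` of clusters
    (poor tracking conditions) whose offsets have per-coordinate scale
    ``outlier_offset * noise_sd`` — these are what the candidate
    absorption stage has to recover. Crops add isotropic noise_sd noise;
    ``faceless_fraction`` of crops carry no usable face.
    """
    if n_identities < 1:
        raise ValueError("n_identities must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    centroids = rng.normal(0.0, separation * max(noise_sd, 1e-12),
                           (n_identities, dim))
    clusters = []
    cid = 0
    for ident in range(n_identities):
        for j in range(clusters_per_identity):
            scale = (outlier_offset if rng.random() < outlier_fraction
                     else 0.05)
            offset = rng.normal(0.0, scale * noise_sd, dim)
            emb = (centroids[ident] + offset
                   + rng.normal(0.0, noise_sd, (crops_per_cluster, dim)))
            has_face = rng.random(crops_per_cluster) >= faceless_fraction
            if not has_face.any():
                has_face[0] = True
            span = (j * 10.0 + rng.uniform(0, 0.5), j * 10.0 + 8.0)
            clusters.append(CropCluster(cid, emb, has_face, span, ident))
            cid += 1
    return CropClusterSet(clusters=clusters, dim=dim, noise_sd=noise_sd)
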