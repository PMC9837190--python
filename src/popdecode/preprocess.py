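"""Spike-train preprocessing: unit filtering, artifact detection, and
binning/resampling into uniform firing-rate matrices.

The pipeline mirrors standard single-unit hygiene for long naturalistic
recordings: units firing below 0.05 Hz on average are discarded, 100-ms
bins with synchronous activity across several regions are flagged as
artifacts, and the cleaned spikes are binned at 20 ms and linearly
interpolated onto a uniform output grid (30 Hz by default, so that a
2-second window holds exactly 60 samples).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import SpikeDataset

__all__ = ["RateMatrix", "filter_low_rate_units", "detect_artifact_bins",
           "bin_and_resample", "bin_counts"]

MIN_RATE_HZ = 0.05


@dataclass
class RateMatrix:
    rates: np.ndarray          # (n_units, n_samples), spikes/s
    sample_rate_hz: float
    t0: float
    unit_ids: np.ndarray
    excluded: np.ndarray = field(default=None)  # (n_samples,) bool

    def __post_init__(self):
        if self.excluded is None:
            self.excluded = np.zeros(self.rates.shape[1], dtype=bool)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.rates.shape[1]) / self.sample_rate_hz

    def subset_units(self, unit_ids) -> "RateMatrix":
        idx = [int(np.flatnonzero(self.unit_ids == u)[0]) for u in unit_ids]
        return RateMatrix(self.rates[idx], self.sample_rate_hz, self.t0,
                          np.asarray(unit_ids), self.excluded.copy())


def filter_low_rate_units(spikes: SpikeDataset, duration_s: float | None = None
                          ) -> SpikeDataset:
    """Drop units whose mean rate is below 0.05 Hz (boundary retained)."""
    if duration_s is None:
        duration_s = spikes.duration_s
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if len(spikes.units) == 0:
        return spikes
    counts = spikes.events.groupby("unit_id").size()
    keep = [u for u in spikes.units.unit_id
            if counts.get(u, 0) / duration_s >= MIN_RATE_HZ]
    units = spikes.units[spikes.units.unit_id.isin(keep)].reset_index(drop=True)
    events = spikes.events[spikes.events.unit_id.isin(keep)].reset_index(
        drop=True)
    return SpikeDataset(events=events, units=units,
                        duration_s=spikes.duration_s)


def bin_counts(spikes: SpikeDataset, bin_s: float) -> tuple[np.ndarray,
                                                            np.ndarray]:
    """Per-unit spike counts on a uniform [0, duration) grid of width bin_s.

    Returns (counts with shape (n_units, n_bins), bin left edges)."""
    n_bins = int(np.ceil(spikes.duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts = np.zeros((len(spikes.units), n_bins))
    for i, uid in enumerate(spikes.units.unit_id):
        t = spikes.spike_times(uid)
        if len(t):
            counts[i], _ = np.histogram(t, bins=edges)
    return counts, edges[:-1]


def detect_artifact_bins(spikes: SpikeDataset, z_thresh: float = 5.0,
                         min_regions: int = 3, bin_s: float = 0.1
                         ) -> np.ndarray:
    """Flag 100-ms bins with synchronous firing across multiple regions.

    A bin is an artifact when the z-scored population count exceeds
    ``z_thresh`` and at least ``min_regions`` distinct regions are each
    above their own ``z_thresh``. Returns a boolean mask over bins.
    """
    counts, _ = bin_counts(spikes, bin_s)
    n_bins = counts.shape[1]
    regions = spikes.units.region.to_numpy()
    unique_regions = np.unique(regions)
    if len(unique_regions) < 2:
        warnings.warn("fewer than 2 regions; artifact detection skipped")
        return np.zeros(n_bins, dtype=bool)

    def zscore(x):
        sd = x.std()
        return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd

    pop_z = zscore(counts.sum(axis=0))
    region_hot = np.zeros((len(unique_regions), n_bins), dtype=bool)
    for r, region in enumerate(unique_regions):
        region_hot[r] = zscore(counts[regions == region].sum(axis=0)) > z_thresh
    return (pop_z > z_thresh) & (region_hot.sum(axis=0) >= min_regions)


def bin_and_resample(spikes: SpikeDataset, bin_ms: float = 20.0,
                     out_hz: float = 30.0,
                     artifact_mask: np.ndarray | None = None,
                     artifact_bin_s: float = 0.1) -> RateMatrix:
    """Bin spikes at ``bin_ms`` and linearly interpolate the rates onto a
    uniform grid at ``out_hz``.

    Counts are scaled to rates (count / bin width) before interpolation;
    bins follow the half-open convention [t, t + dt). An optional artifact
    mask (over ``artifact_bin_s`` bins) is carried onto the output grid.
    """
    if out_hz <= 0:
        raise ValueError("out_hz must be positive")
    bin_s = bin_ms / 1000.0
    counts, edges = bin_counts(spikes, bin_s)
    centers = edges + bin_s / 2.0
    n_out = int(np.floor(spikes.duration_s * out_hz))
    out_times = np.arange(n_out) / out_hz
    rates = np.empty((counts.shape[0], n_out))
    for i in range(counts.shape[0]):
        rates[i] = np.interp(out_times, centers, counts[i] / bin_s)
    excluded = np.zeros(n_out, dtype=bool)
    if artifact_mask is not None and artifact_mask.any():
        bad_bins = np.flatnonzero(artifact_mask)
        for b in bad_bins:
            lo, hi = b * artifact_bin_s, (b + 1) * artifact_bin_s
            excluded |= (out_times >= lo - 1e-12) & (out_times < hi)
    return RateMatrix(rates=rates, sample_rate_hz=out_hz, t0=0.0,
                      unit_ids=spikes.units.unit_id.to_numpy(),
                      excluded=excluded)
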