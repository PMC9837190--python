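import pytest

from popdecode.decoding import DecoderSpec, train_decoder
from popdecode.labeling import build_frame_labels, make_fold_plan, \
    make_window_samples
from popdecode.preprocess import bin_and_resample, filter_low_rate_units
from popdecode.synthetic import TimelineConfig, generate_character_timeline, \
    make_population, simulate_spikes


@pytest.fixture(scope="session")
def movie_data():
    """A 10-minute synthetic session: four regions each tuned (gain 3)
    to one character, 8 units per region."""
    cfg = TimelineConfig(prevalence=0.15, duration_s=600.0)
    timeline = generate_character_timeline(cfg, seed=1)
    pop = make_population(
        ["occipital", "superior_temporal", "frontal", "hippocampus"],
        {"occipital": 0, "superior_temporal": 1, "frontal": 2,
         "hippocampus": 3},
        n_electrodes=8, units_per_electrode=1, baseline_hz=2.0, gain=3.0)
    spikes = filter_low_rate_units(simulate_spikes(timeline, pop, seed=2))
    rates = bin_and_resample(spikes)
    labels = build_frame_labels(timeline)
    samples = make_window_samples(rates, labels)
    plan = make_fold_plan(samples.n_samples, seed=0)
    return {"timeline": timeline, "pop": pop, "spikes": spikes,
            "rates": rates, "labels": labels, "samples": samples,
            "plan": plan}


@pytest.fixture(scope="session")
def trained_lstm(movie_data):
    spec = DecoderSpec(architecture="lstm", hidden=24, fc_hidden=24,
                       max_epochs=9, batch_size=256, learning_rate=3e-3,
                       seed=1)
    return train_decoder(movie_data["samples"], spec, movie_data["plan"],
                         folds=[0])
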