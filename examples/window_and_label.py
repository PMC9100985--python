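"""Turn a recording into labeled forecasting samples.

Slides the 20 s observation / 5 min delay / 1 min class-observation template
every 30 s over an episode recording and tallies what survives the
exclusion rules.
"""

from ibpforecast import EpisodeSpec, SamplerConfig, SimConfig, generate_samples, simulate
from ibpforecast.sampler import Label, exclusion_tally

rec = simulate(
    SimConfig(
        duration_s=1800,
        episodes=(EpisodeSpec(onset_s=700, ramp_s=40, plateau_s=180, recovery_s=12, plateau_map=55.0),),
        map_noise_sd=1.0,
        seed=5,
    )
)
samples = generate_samples(rec, SamplerConfig())
print("tally:", exclusion_tally(samples))
for s in samples:
    if s.label is Label.HYPOTENSION:
        print(
            f"hypotension sample: observes {s.obs.start / rec.fs:.0f}-{s.obs.end / rec.fs:.0f} s, "
            f"forecasts the minute {s.class_obs.start / rec.fs:.0f}-{s.class_obs.end / rec.fs:.0f} s"
        )

# Exactly one hypotension sample survives per episode: the window whose class
# minute is the episode's first sub-65 minute. Later windows over the same
# event are suppressed (duplicate_event) or excluded because hypotension is
# already ongoing in their delay (event_in_obs_or_delay).
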