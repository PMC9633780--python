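"""Elapsed time since phoneme onset is itself decodable from a dynamic code.

Two demonstrations on isolated-response epochs:
1. a latency decoder trained on pure noise collapses to the mean label
   (250 ms) with r ~ 0, while a drifting code makes latency decodable;
2. the decoder-coefficient topography of a drifting code traces a smooth,
   structured path through sensor space, unlike shuffled-label nulls.
"""

import numpy as np

from phonoseq.dynamics import decode_latency, group_trajectory_test, permutation_p
from phonoseq.lexicon import annotate_stream, build_feature_table, toy_lexicon
from phonoseq.preprocess import EpochSet, epoch_events
from phonoseq.simulate import SimulationConfig, default_layout, make_code, sample_stream, simulate_recording

rng = np.random.default_rng(0)
times = np.arange(201) / 250.0 - 0.2

# 1a. pure noise: the decoder can only predict the mean latency
noise_ep = EpochSet(X=rng.standard_normal((700, 20, 201)), times=times, fs=250.0)
res = decode_latency(noise_ep, seed=0)
print(f"pure noise: mean predicted latency {res.predicted_ms.mean():.1f} ms "
      f"(label grid 100-400 ms), r = {res.r:.3f}")

# 1b. drifting code: the pattern itself encodes elapsed time
code = make_code(default_layout(24), ["f"], 1.5625, rng, response_window=0.6)
W = code.patterns(np.clip(times, 0, None))[0] * code.envelope(times)[None, :]
drift_ep = EpochSet(X=W[None] + 0.3 * rng.standard_normal((400, 24, 201)),
                    times=times, fs=250.0)
res2 = decode_latency(drift_ep, seed=0)
print(f"drifting code: r = {res2.r:.3f} (latency is linearly readable)")

# 2. trajectory structure of the coefficient topographies (4 simulated
#    subjects sharing the planted code, RMS-combined as for real brains)
lex = toy_lexicon()
cfg = SimulationConfig(snr=2.0, confound_gain=0.0)
layout = default_layout(24)
code = make_code(layout, ["voicing"], 6.25, rng)
studies = []
for s in range(4):
    events, _ = sample_stream(lex, 120, cfg, rng)
    ann = annotate_stream(events, lex, build_feature_table(lex.inventory()))
    rec = simulate_recording(events, ann, code, cfg, rng)
    epochs = epoch_events(rec, ann["onset_s"].to_numpy())
    studies.append((epochs, ann.iloc[epochs.annotation_index]["voicing"].to_numpy()))

obs, null = group_trajectory_test(studies, layout, n_perm=100,
                                  rng=np.random.default_rng(1))
print(f"\ntrajectory structure (range/step x SD): observed {obs:.2f}, "
      f"null mean {null.mean():.2f}, p = {permutation_p(obs, null):.3f}")
print("A smooth, far-ranging coefficient path rejects the shuffled-label null:")
print("the code moves systematically through sensor space as latency elapses.")
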