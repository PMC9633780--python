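"""How many previous phonemes does an instantaneous response contain?

Synthesises responses to all 24 orderings of {b, p, s, z} by shifting each
phoneme's spatiotemporal template 100 ms per position and summing, then
reconstructs the feature vector of the phoneme h steps back from each
phoneme-locked epoch with ridge regression.  Under ideal (zero-noise)
conditions the current phoneme is recovered perfectly; similarity decays
with history lag as the overlapping responses fade.
"""

import numpy as np

from phonoseq.seqsim import AnagramSet, reconstruct_history, synthesize_sequence_responses
from phonoseq.simulate import default_layout, make_code

code = make_code(default_layout(32), ["voicing", "plosive"], 6.25,
                 np.random.default_rng(0))
templates = code.tensor(100.0)[:, :, :30]  # (features, channels, 300 ms)

for noise_sd, label in [(0.0, "ideal (no noise)"), (0.3, "noise factor SD 0.3")]:
    ana = AnagramSet(noise_sd=noise_sd)
    data, onsets, labels = synthesize_sequence_responses(
        ana, templates, fs=100.0, rng=np.random.default_rng(1))
    res = reconstruct_history(data, onsets, labels, fs=100.0, max_history=4,
                              n_perm=1000, seed=0)
    sims = res.table["cosine_similarity"].round(3).tolist()
    ps = res.table["p_value"].tolist()
    print(f"{label}: {len(onsets)} epochs "
          f"({len(ana.sequences)} sequences x 4 phonemes x {ana.n_repetitions} reps)")
    for lag, sim, p in zip(res.table["lag"], sims, ps):
        print(f"  lag {lag} ({'current' if lag == 0 else f'{lag} back'}): "
              f"cosine similarity {sim:+.3f}, p = {p:.4g}")
    print()

print("Lag 0 at zero noise is exact (cosine 1.0): the epoch is a linear")
print("mixture the ridge inverts. Similarity falls with lag as the older")
print("response overlaps the epoch less, and is flat at chance beyond the")
print("template's 300 ms extent.")
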