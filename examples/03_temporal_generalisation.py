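"""Static vs dynamic codes in the temporal-generalisation matrix.

Two otherwise identical studies differ only in whether the planted channel
pattern is fixed over latency (static) or rotates smoothly (dynamic,
informative ~80 ms).  A decoder trained at one latency is evaluated at all
others: static codes give a square suprathreshold region (rows as long as
the diagonal); dynamic codes give a narrow diagonal whose principal axis
sits at 45 degrees when test dynamics match training dynamics.
"""

import numpy as np

from phonoseq.lexicon import annotate_stream, build_feature_table, toy_lexicon
from phonoseq.preprocess import epoch_events
from phonoseq.simulate import SimulationConfig, default_layout, make_code, sample_stream, simulate_recording
from phonoseq.tempgen import diag_vs_rows, group_tmap, ridge_angle, tg_fit_eval

N_SUBJECTS = 4  # independent synthetic "participants"


def subject_tg(drift, subject, n_words=120):
    lex = toy_lexicon()
    cfg = SimulationConfig(snr=2.0, confound_gain=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(drift * 100), subject]))
    events, _ = sample_stream(lex, n_words, cfg, rng)
    ann = annotate_stream(events, lex, build_feature_table(lex.inventory()))
    layout = default_layout(24)
    code = make_code(layout, ["voicing", "plosive"], drift, rng)
    rec = simulate_recording(events, ann, code, cfg, rng)
    epochs = epoch_events(rec, ann["onset_s"].to_numpy())
    Y = ann.iloc[epochs.annotation_index][["voicing", "plosive"]].to_numpy()
    return tg_fit_eval(epochs, Y, n_splits=3, seed=0, decim=4)


for drift, label in [(0.0, "static"), (6.25, "dynamic (80 ms)")]:
    surfaces = []
    for s in range(N_SUBJECTS):
        tg = subject_tg(drift, s)
        surfaces.append(tg.surface())
    tmap = group_tmap(surfaces)
    stats = diag_vs_rows(tg, 4.0, surface=tmap)
    print(f"{label:>16}: diagonal {stats.diag_duration_ms:.0f} ms, "
          f"mean row {stats.mean_row_duration_ms:.0f} ms, "
          f"row/diag ratio {stats.ratio:.2f}")
    if drift > 0:
        angle = ridge_angle(tmap > 4.0, tg.times_train, tg.times_test)
        print(f"{'':>16}  suprathreshold ridge angle: {angle:.1f} degrees")

print("\nA ratio near 1 means any trained pattern works at all latencies")
print("(static code); a small ratio means each pattern is short-lived while")
print("the information itself persists — the signature of a dynamic code.")
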