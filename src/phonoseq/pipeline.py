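"""End-to-end orchestration: synthetic study -> decoding analyses -> report.

A run directory is self-describing: the resolved configuration, the seed and
a per-stage log are written next to the artefacts, and re-running the same
configuration and seed reproduces the artefacts bit for bit (per-timepoint
RNG streams are derived by counter, so results do not depend on execution
order or parallelism).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import b2b as b2b_mod
from . import dynamics as dyn_mod
from . import preprocess as pre_mod
from . import seqsim as seq_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from . import tempgen as tg_mod
from .lexicon import ANNOTATION_FEATURES, PHONETIC_FEATURES, annotate_stream, build_feature_table, toy_lexicon

__all__ = ["PipelineConfig", "PRESETS", "run_pipeline", "make_report", "ALL_STAGES"]

log = logging.getLogger("phonoseq")

#: Simulation presets: the study conditions each run emulates.  The dynamic
#: drift rate (6.25 rotations/s) makes any given spatial pattern informative
#: for ~80 ms (the pattern-overlap cosine crosses zero 40 ms either side of
#: the training latency) while the response itself lasts ~300 ms.
PRESETS = {
    "clean": {"snr": 2.0, "drift_rate": 6.25},
    "realistic": {"snr": 0.05, "drift_rate": 6.25},
    "static-control": {"snr": 2.0, "drift_rate": 0.0},
}

ALL_STAGES = ["simulate", "preprocess", "b2b", "tempgen", "dynamics", "seqsim",
              "latency", "stats", "report"]

_DEPS = {
    "preprocess": ["simulate"],
    "b2b": ["preprocess"],
    "tempgen": ["preprocess"],
    "dynamics": ["preprocess"],
    "seqsim": ["dynamics"],
    "latency": ["preprocess"],
    "stats": ["b2b"],
    "report": [],
}


@dataclass
class PipelineConfig:
    """Resolved run configuration; unknown keys are rejected at load time."""

    preset: str = "clean"
    seed: int = 0
    out_dir: str = "runs/phonoseq"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    n_words: int = 150
    n_channels: int = 32
    n_subjects: int = 1
    n_splits: int = 10
    decim: int = 4
    n_jobs: int = 1
    snr: float | None = None  # overrides the preset
    drift_rate: float | None = None
    confound_gain: float = 1.0

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def resolved(self) -> dict:
        d = asdict(self)
        preset = PRESETS[self.preset]
        if d["snr"] is None:
            d["snr"] = preset["snr"]
        if d["drift_rate"] is None:
            d["drift_rate"] = preset["drift_rate"]
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _require(run: Path, stage: str, *paths):
    for p in paths:
        if not (run / p).exists():
            dep = ", ".join(_DEPS.get(stage, [])) or "an earlier stage"
            raise FileNotFoundError(
                f"stage {stage!r} is missing {p!r}: run {dep} first"
            )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the requested stages in dependency order; returns the run dir."""
    cfg = config.resolved()
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    with open(run / "config.yaml", "w") as f:
        yaml.safe_dump(cfg, f)
    handler = logging.FileHandler(run / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    try:
        for stage in [s for s in ALL_STAGES if s in config.stages]:
            t0 = time.time()
            _STAGE_FN[stage](run, cfg)
            log.info("stage %s done in %.1f s", stage, time.time() - t0)
        with open(run / "meta.json", "w") as f:
            json.dump(meta, f, indent=2)
    finally:
        log.removeHandler(handler)
        handler.close()
    return run


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _sim_config(cfg) -> sim_mod.SimulationConfig:
    return sim_mod.SimulationConfig(
        snr=cfg["snr"], confound_gain=cfg["confound_gain"], seed=cfg["seed"]
    )


def _stage_simulate(run: Path, cfg):
    lex = toy_lexicon()
    sim_cfg = _sim_config(cfg)
    rng_stream = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 1]))
    events, _ = sim_mod.sample_stream(lex, cfg["n_words"], sim_cfg, rng_stream)
    ftable = build_feature_table(lex.inventory())
    ann = annotate_stream(events, lex, ftable)
    ann.to_csv(run / "annotation.tsv", sep="\t", index=False)
    layout = sim_mod.default_layout(cfg["n_channels"])
    np.save(run / "layout.npy", layout.coords)
    for s in range(cfg["n_subjects"]):
        rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 2, s]))
        code = sim_mod.make_code(layout, PHONETIC_FEATURES, cfg["drift_rate"], rng)
        rec = sim_mod.simulate_recording(events, ann, code, sim_cfg, rng)
        rec.layout = layout
        sim_mod.write_recording(rec, run / f"recording_s{s}.h5")
    log.info("simulated %d events, %d subject(s)", len(events), cfg["n_subjects"])


def _stage_preprocess(run: Path, cfg):
    _require(run, "preprocess", "annotation.tsv", "recording_s0.h5")
    import pandas as pd

    ann = pd.read_csv(run / "annotation.tsv", sep="\t")
    for s in range(cfg["n_subjects"]):
        rec = sim_mod.read_recording(run / f"recording_s{s}.h5")
        trf = pre_mod.fit_trf(rec.data, rec.envelope, rec.pitch, fs=rec.fs)
        resid = pre_mod.residualize(rec, trf)
        epochs = pre_mod.epoch_events(resid, ann["onset_s"].to_numpy())
        pre_mod.write_epochs(epochs, run / f"epochs_s{s}.h5")
        log.info("subject %d: %d epochs (%d dropped), TRF score %.3f",
                 s, epochs.n_trials, len(epochs.dropped), trf.score)


def _nonconstant(df, names):
    """Feature columns with variance in this stream (absent classes logged)."""
    keep = [c for c in names if df[c].std() > 0]
    dropped = sorted(set(names) - set(keep))
    if dropped:
        log.warning("dropping constant feature columns (absent from stream): %s",
                    ", ".join(dropped))
    return keep


def _stage_b2b(run: Path, cfg):
    _require(run, "b2b", "epochs_s0.h5", "annotation.tsv")
    import pandas as pd

    ann = pd.read_csv(run / "annotation.tsv", sep="\t")
    for s in range(cfg["n_subjects"]):
        epochs = pre_mod.read_epochs(run / f"epochs_s{s}.h5")
        sub = ann.iloc[epochs.annotation_index]
        cols = _nonconstant(sub, ANNOTATION_FEATURES)
        Y = sub[cols].to_numpy()
        res = b2b_mod.b2b_timecourse(
            epochs, Y, n_splits=cfg["n_splits"], seed=cfg["seed"],
            feature_names=cols, n_jobs=cfg["n_jobs"],
        )
        b2b_mod.variance_shares(res)
        b2b_mod.write_b2b(res, run / f"b2b_s{s}.h5")
        df = pd.DataFrame(res.rhat.T, columns=res.feature_names)
        df.insert(0, "time_s", res.times)
        df.to_csv(run / f"b2b_shares_s{s}.tsv", sep="\t", index=False)


def _stage_tempgen(run: Path, cfg):
    _require(run, "tempgen", "epochs_s0.h5", "annotation.tsv")
    import h5py
    import pandas as pd

    ann = pd.read_csv(run / "annotation.tsv", sep="\t")
    with h5py.File(run / "tg.h5", "w") as f:
        for s in range(cfg["n_subjects"]):
            epochs = pre_mod.read_epochs(run / f"epochs_s{s}.h5")
            sub = ann.iloc[epochs.annotation_index]
            cols = _nonconstant(sub, PHONETIC_FEATURES)
            Y = sub[cols].to_numpy()
            groups = {}
            for k in (1, 2, 3):
                m = sub["pos_from_onset"].to_numpy() == k
                if m.sum() >= 20:
                    groups[f"P{k}"] = m
            tgs = tg_mod.tg_fit_eval(
                epochs, Y, n_splits=max(2, cfg["n_splits"] // 2), seed=cfg["seed"],
                decim=cfg["decim"], eval_groups=groups or None,
                feature_names=cols,
            )
            if not isinstance(tgs, dict):
                tgs = {"all": tgs}
            for name, tg in tgs.items():
                g = f.create_group(f"tg/s{s}/{name}")
                g.create_dataset("scores", data=tg.scores)
                g.create_dataset("times", data=tg.times_train)
    log.info("temporal generalisation surfaces written")


def _stage_dynamics(run: Path, cfg):
    _require(run, "dynamics", "epochs_s0.h5", "annotation.tsv")
    import pandas as pd

    ann = pd.read_csv(run / "annotation.tsv", sep="\t")
    layout = sim_mod.SensorLayout(np.load(run / "layout.npy"))
    epochs = pre_mod.read_epochs(run / "epochs_s0.h5")
    sub = ann.iloc[epochs.annotation_index]
    cols = _nonconstant(sub, PHONETIC_FEATURES)
    Y = sub[cols].to_numpy()
    W = dyn_mod.unregularized_coefficients(epochs, Y)
    np.save(run / "coefficients.npy", W)
    with open(run / "coefficient_features.json", "w") as f:
        json.dump(cols, f)
    rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 3]))
    rows = []
    for fi, name in enumerate(cols[:1]):  # voicing trajectory
        traj = dyn_mod.project_trajectory(W[fi], layout)
        metric = dyn_mod.trajectory_structure(traj)
        null = dyn_mod.trajectory_null_metrics(epochs, Y[:, fi], layout,
                                               n_perm=50, rng=rng)
        rows.append({"feature": name, "structure": metric,
                     "p": dyn_mod.permutation_p(metric, null)})
        pd.DataFrame({"time_s": epochs.times, "x": traj.x, "y": traj.y}).to_csv(
            run / f"trajectory_{name}.tsv", sep="\t", index=False)
    pd.DataFrame(rows).to_csv(run / "trajectory_structure.tsv", sep="\t", index=False)


def _stage_seqsim(run: Path, cfg):
    _require(run, "seqsim", "coefficients.npy", "epochs_s0.h5")
    epochs = pre_mod.read_epochs(run / "epochs_s0.h5")
    W = np.load(run / "coefficients.npy")
    import json as _json
    with open(run / "coefficient_features.json") as f:
        coef_cols = _json.load(f)
    iv = coef_cols.index("voicing")
    ip = coef_cols.index("plosive")
    t = epochs.times
    sel = (t >= 0) & (t <= 0.3)
    templates = W[[iv, ip]][:, :, sel]
    ana = seq_mod.AnagramSet(noise_sd=0.1)
    rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 4]))
    data, onsets, labels = seq_mod.synthesize_sequence_responses(
        ana, templates, fs=epochs.fs, rng=rng)
    res = seq_mod.reconstruct_history(data, onsets, labels, fs=epochs.fs,
                                      n_perm=1000, seed=cfg["seed"])
    res.table.to_csv(run / "seqsim.tsv", sep="\t", index=False)


def _stage_latency(run: Path, cfg):
    _require(run, "latency", "epochs_s0.h5")
    import pandas as pd

    epochs = pre_mod.read_epochs(run / "epochs_s0.h5")
    res = dyn_mod.decode_latency(epochs, seed=cfg["seed"])
    pd.DataFrame({
        "true_ms": res.true_ms, "predicted_ms": res.predicted_ms, "fold": res.fold,
    }).to_csv(run / "latency_predictions.tsv", sep="\t", index=False)
    with open(run / "latency_summary.json", "w") as f:
        json.dump({"pearson_r": res.r,
                   "per_fold_r": list(map(float, res.per_fold_r))}, f, indent=2)


def _stage_stats(run: Path, cfg):
    _require(run, "stats", "b2b_s0.h5")
    betas, times = [], None
    for s in range(cfg["n_subjects"]):
        res = b2b_mod.read_b2b(run / f"b2b_s{s}.h5")
        idx = [i for i, n in enumerate(res.feature_names) if n in PHONETIC_FEATURES]
        betas.append(res.beta[idx].mean(axis=0))
        times = res.times
    out = {"n_subjects": cfg["n_subjects"]}
    if cfg["n_subjects"] >= 5:
        rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 5]))
        cres = stats_mod.one_sample_cluster_test(
            np.stack(betas), n_perm=1000, tail=1, times_ms=times * 1000, rng=rng)
        out["clusters"] = [
            {"start_ms": c.start, "end_ms": c.end, "sum_t": c.sum_t, "p": c.p}
            for c in cres.clusters
        ]
    else:
        out["note"] = "group cluster test requires n_subjects >= 5"
    with open(run / "stats.json", "w") as f:
        json.dump(out, f, indent=2)


def _stage_report(run: Path, cfg):
    make_report(run)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "b2b": _stage_b2b,
    "tempgen": _stage_tempgen,
    "dynamics": _stage_dynamics,
    "seqsim": _stage_seqsim,
    "latency": _stage_latency,
    "stats": _stage_stats,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def make_report(run_dir) -> list[Path]:
    """Render summary figures from whatever artefacts the run produced.

    Renders the panels whose inputs exist and warns about the rest; an empty
    run directory is an error.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run = Path(run_dir)
    if not run.exists() or not any(run.iterdir()):
        raise FileNotFoundError(f"empty run directory: {run}")
    made = []

    shares = run / "b2b_shares_s0.tsv"
    if shares.exists():
        df = pd.read_csv(shares, sep="\t")
        fig, ax = plt.subplots(figsize=(7, 4))
        t = df["time_s"] * 1000
        for block, cols in [("phonetic", PHONETIC_FEATURES),
                            ("information", ["surprisal", "entropy", "log_seq_freq"])]:
            ax.plot(t, df[cols].mean(axis=1), label=block)
        ax.axvline(0, color="k", lw=0.5)
        ax.set(xlabel="time from phoneme onset (ms)", ylabel="variance share")
        ax.legend()
        fig.savefig(run / "fig_shares.png", dpi=120)
        plt.close(fig)
        made.append(run / "fig_shares.png")

    tg_file = run / "tg.h5"
    if tg_file.exists():
        import h5py

        with h5py.File(tg_file, "r") as f:
            names = list(f["tg/s0"])
            surfaces = {}
            times = None
            for name in names:
                g = f[f"tg/s0/{name}"]
                surfaces[name] = g["scores"][()].mean(axis=0)
                times = g["times"][()]
        pos = {n: s for n, s in surfaces.items() if n.startswith("P")}
        fig, ax = plt.subplots(figsize=(7, 4))
        if pos:
            comp = tg_mod.align_to_word_clock(pos, times=times)
            stack = np.nanmax(
                np.stack([np.where(np.isnan(s), -np.inf, s) for s in comp.surfaces.values()]),
                axis=0,
            )
            ax.imshow(stack, aspect="auto", origin="lower",
                      extent=[comp.times_test[0] * 1000, comp.times_test[-1] * 1000,
                              comp.times_train[0] * 1000, comp.times_train[-1] * 1000])
            ax.set(xlabel="test time from word onset (ms)", ylabel="train time (ms)")
        else:
            name = names[0]
            ax.imshow(surfaces[name], aspect="auto", origin="lower",
                      extent=[times[0] * 1000, times[-1] * 1000,
                              times[0] * 1000, times[-1] * 1000])
            ax.set(xlabel="test time (ms)", ylabel="train time (ms)")
        fig.savefig(run / "fig_tg.png", dpi=120)
        plt.close(fig)
        made.append(run / "fig_tg.png")

    traj = run / "trajectory_voicing.tsv"
    if traj.exists():
        df = pd.read_csv(traj, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 4))
        sc = ax.scatter(df["x"], df["y"], c=df["time_s"] * 1000, cmap="viridis", s=8)
        fig.colorbar(sc, label="time (ms)")
        ax.set(xlabel="left-right cosine distance", ylabel="posterior-anterior cosine distance")
        fig.savefig(run / "fig_trajectory.png", dpi=120)
        plt.close(fig)
        made.append(run / "fig_trajectory.png")

    seq = run / "seqsim.tsv"
    if seq.exists():
        df = pd.read_csv(seq, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(df["lag"], df["cosine_similarity"], "o-")
        ax.set(xlabel="history lag (phonemes back)", ylabel="cosine similarity",
               ylim=(-0.1, 1.05))
        fig.savefig(run / "fig_seqsim.png", dpi=120)
        plt.close(fig)
        made.append(run / "fig_seqsim.png")

    lat = run / "latency_predictions.tsv"
    if lat.exists():
        df = pd.read_csv(lat, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        jitter = (np.random.default_rng(0).uniform(-4, 4, len(df)))
        ax.scatter(df["true_ms"] + jitter, df["predicted_ms"], s=2, alpha=0.2)
        ax.axhline(250, ls="--", color="k", lw=0.8)
        ax.set(xlabel="true latency (ms)", ylabel="predicted latency (ms)")
        fig.savefig(run / "fig_latency.png", dpi=120)
        plt.close(fig)
        made.append(run / "fig_latency.png")

    if not made:
        import warnings

        warnings.warn("no renderable artefacts found; run analysis stages first")
    return made
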