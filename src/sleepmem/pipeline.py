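"""End-to-end orchestration: simulate -> preprocess -> detect -> spectra ->
score -> stats, with a reproducibility manifest.

Every stage is file-based (EDF, CSV, JSON) so stages can be re-run
individually from the CLI. A manifest records the resolved configuration
hash, the seed, package versions and the SHA-256 of every output; a rerun
with the same configuration and seed reproduces every CSV byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .behavior import difference_scores, score_sessions, table1_summary
from .events import (DetectorConfig, couple_so_spindles,
                     detect_slow_oscillations, detect_spindles, density_table)
from .io import (architecture_row, bandpass_filter, mark_artifact_epochs,
                 read_edf, read_hypnogram_csv,
                 rereference_contralateral_mastoid, sleep_architecture,
                 write_edf, write_hypnogram_csv)
from .simulate import (BehaviorSimConfig, EEGSimConfig, generate_behavior,
                       generate_eeg)
from .spectral import DEFAULT_BANDS, stage_band_power
from .stats import holm_bonferroni, paired_t, rm_anova_2x2x2, sleep_memory_screen

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_NAMES"]

CONDITIONS = ("placebo", "zolpidem")
STAGE_NAMES = ("simulate", "preprocess", "detect", "spectra", "score",
               "stats", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run.

    Either ``simulate=True`` (the default; synthetic EEG + behavior) or
    explicit input paths (``eeg_dir`` with ``<subject>_<condition>.edf``
    and hypnogram CSVs, plus a ``trials_file``) must be provided.
    """

    out_dir: str = "sleepmem_out"
    simulate: bool = True
    eeg_dir: str | None = None
    hypnogram_dir: str | None = None
    trials_file: str | None = None
    n_eeg_subjects: int = 6
    eeg: EEGSimConfig = field(default_factory=EEGSimConfig)
    behavior: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    alpha_spectral: float = 0.0025
    alpha_events: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.simulate and not (self.eeg_dir and self.hypnogram_dir
                                      and self.trials_file):
            raise ValueError(
                "configuration error: simulation disabled but eeg_dir / "
                "hypnogram_dir / trials_file not all provided")
        if isinstance(self.eeg, dict):
            self.eeg = EEGSimConfig(**self.eeg)
        if isinstance(self.behavior, dict):
            self.behavior = BehaviorSimConfig(**self.behavior)
        if isinstance(self.detector, dict):
            self.detector = DetectorConfig(**self.detector)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        if "behavior" in obj and "true_dprime" in obj["behavior"]:
            td = obj["behavior"]["true_dprime"]
            if isinstance(td, dict) and td and isinstance(
                    next(iter(td)), str) and "," in next(iter(td)):
                obj["behavior"]["true_dprime"] = {
                    _parse_cell_key(k): v for k, v in td.items()}
        obj.update(overrides)
        return cls(**obj)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _jsonable(obj):
    """Recursively convert tuple keys / numpy scalars for JSON hashing."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _parse_cell_key(key: str) -> tuple[str, int, str]:
    cond, test, val = (s.strip() for s in key.split(","))
    return (cond, int(test), val)


def _record_seed(base_seed: int, subject: int, cond: str) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(subject),
                                 CONDITIONS.index(cond)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _record_paths(root: Path, subject: int, cond: str, kind: str):
    stem = f"sub{subject:02d}_{cond}"
    d = root / kind
    return d / f"{stem}.edf", d / f"{stem}_hypnogram.csv", d / f"{stem}_truth.json"


def _iter_records(cfg: PipelineConfig):
    for subject in range(cfg.n_eeg_subjects):
        for cond in CONDITIONS:
            yield subject, cond


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    (out / "raw").mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        for subject, cond in _iter_records(cfg):
            rec_cfg = dataclasses.replace(
                cfg.eeg, seed=_record_seed(cfg.seed, subject, cond))
            rec, hyp, truth = generate_eeg(rec_cfg)
            edf, hypf, truthf = _record_paths(out, subject, cond, "raw")
            write_edf(edf, rec)
            write_hypnogram_csv(hypf, hyp)
            truth.to_json(truthf)
        beh_cfg = dataclasses.replace(cfg.behavior, seed=int(cfg.seed) + 10_000)
        ds = generate_behavior(beh_cfg)
        ds.write(out / "behavior")
    else:
        for subject, cond in _iter_records(cfg):
            src_edf = Path(cfg.eeg_dir) / f"sub{subject:02d}_{cond}.edf"
            src_hyp = Path(cfg.hypnogram_dir) / f"sub{subject:02d}_{cond}.csv"
            edf, hypf, _ = _record_paths(out, subject, cond, "raw")
            edf.write_bytes(src_edf.read_bytes())
            hypf.write_bytes(src_hyp.read_bytes())
        (out / "behavior").mkdir(parents=True, exist_ok=True)
        (out / "behavior" / "trials.csv").write_bytes(
            Path(cfg.trials_file).read_bytes())


def stage_preprocess(cfg: PipelineConfig, out: Path) -> None:
    (out / "proc").mkdir(exist_ok=True)
    arch_rows, mask_rows = [], []
    for subject, cond in _iter_records(cfg):
        edf, hypf, _ = _record_paths(out, subject, cond, "raw")
        rec = read_edf(edf)
        hyp = read_hypnogram_csv(hypf)
        rec = rereference_contralateral_mastoid(rec)
        rec = bandpass_filter(rec)
        mask = mark_artifact_epochs(rec, hyp)
        arch = sleep_architecture(hyp)
        row = {"subject": subject, "condition": cond}
        row.update(architecture_row(arch))
        arch_rows.append(row)
        for i, ok in enumerate(mask):
            mask_rows.append({"subject": subject, "condition": cond,
                              "epoch_index": i, "artifact_free": bool(ok)})
        pedf, phypf, _ = _record_paths(out, subject, cond, "proc")
        write_edf(pedf, rec)
        write_hypnogram_csv(phypf, hyp)
    (out / "derived").mkdir(exist_ok=True)
    pd.DataFrame(arch_rows).to_csv(out / "derived" / "architecture.csv",
                                   index=False)
    pd.DataFrame(mask_rows).to_csv(out / "derived" / "masks.csv", index=False)


def _load_proc(cfg: PipelineConfig, out: Path, subject: int, cond: str):
    pedf, phypf, _ = _record_paths(out, subject, cond, "proc")
    rec = read_edf(pedf)
    hyp = read_hypnogram_csv(phypf)
    masks = pd.read_csv(out / "derived" / "masks.csv")
    m = masks[(masks["subject"] == subject) & (masks["condition"] == cond)]
    mask = m.sort_values("epoch_index")["artifact_free"].to_numpy(dtype=bool)
    return rec, hyp, mask


def stage_detect(cfg: PipelineConfig, out: Path) -> None:
    ev_rows, cp_rows, dens = [], [], []
    for subject, cond in _iter_records(cfg):
        rec, hyp, mask = _load_proc(cfg, out, subject, cond)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spindles = detect_spindles(rec, hyp, mask, cfg.detector)
            sos = detect_slow_oscillations(rec, hyp, mask, cfg.detector)
        coupled = couple_so_spindles(sos, spindles, cfg.detector)
        for sp in spindles:
            ev_rows.append({"subject": subject, "condition": cond,
                            "channel": sp.channel, "type": "spindle",
                            "start_s": sp.start_s, "end_s": sp.end_s,
                            "anchor_s": sp.peak_s,
                            "amplitude": sp.peak_amplitude,
                            "stage": sp.stage})
        for so in sos:
            ev_rows.append({"subject": subject, "condition": cond,
                            "channel": so.channel, "type": "slow_oscillation",
                            "start_s": so.zc_down1_s, "end_s": so.zc_down2_s,
                            "anchor_s": so.trough_s,
                            "amplitude": so.trough_amp_uv,
                            "stage": so.stage})
        for ce in coupled:
            cp_rows.append({"subject": subject, "condition": cond,
                            "channel": ce.channel, "stage": ce.stage,
                            "so_trough_s": ce.so.trough_s,
                            "spindle_peak_s": ce.spindle.peak_s,
                            "offset_s": ce.offset_s})
        dens.append(density_table(spindles, sos, coupled, hyp,
                                  subject=subject, condition=cond))
    pd.DataFrame(ev_rows).to_csv(out / "derived" / "events.csv", index=False)
    pd.DataFrame(cp_rows).to_csv(out / "derived" / "coupling.csv", index=False)
    (pd.concat(dens, ignore_index=True) if dens else pd.DataFrame()).to_csv(
        out / "derived" / "densities.csv", index=False)


def stage_spectra(cfg: PipelineConfig, out: Path) -> None:
    tables = []
    for subject, cond in _iter_records(cfg):
        rec, hyp, mask = _load_proc(cfg, out, subject, cond)
        tables.append(stage_band_power(rec, hyp, mask, bands=cfg.bands,
                                       subject=subject, condition=cond))
    pd.concat(tables, ignore_index=True).to_csv(
        out / "derived" / "band_power.csv", index=False)


def stage_score(cfg: PipelineConfig, out: Path) -> None:
    trials = pd.read_csv(out / "behavior" / "trials.csv")
    scores = score_sessions(trials)
    diffs = difference_scores(scores)
    scores.to_csv(out / "behavior" / "scores.csv", index=False)
    diffs.to_csv(out / "behavior" / "diffs.csv", index=False)
    table1_summary(scores).to_csv(out / "behavior" / "table1_summary.csv",
                                  index=False)


def _memory_features(scores: pd.DataFrame) -> pd.DataFrame:
    """Wide per subject x condition memory variables for the screens."""
    wide = scores.pivot_table(index=["subject", "condition"],
                              columns=["test", "valence"], values="dprime",
                              aggfunc="first")
    wide.columns = [f"dprime_t{t}_{v}" for t, v in wide.columns]
    return wide.reset_index()


def _spectral_features(bp: pd.DataFrame) -> pd.DataFrame:
    """Relative-power features: SWA/delta at F-average, theta/sigma at C."""
    sel = bp[((bp["channel"] == "F") & bp["band"].isin(["SWA", "delta"]))
             | ((bp["channel"] == "C")
                & bp["band"].isin(["theta", "slow_sigma", "fast_sigma"]))]
    wide = sel.pivot_table(index=["subject", "condition"],
                           columns=["stage", "channel", "band"],
                           values="rel_pct", aggfunc="first")
    wide.columns = [f"{s}_{c}_{b}_rel" for s, c, b in wide.columns]
    return wide.reset_index()


def _event_features(dens: pd.DataFrame) -> pd.DataFrame:
    sel = dens[dens["channel"].isin(["C3", "C4"])]
    wide = sel.pivot_table(
        index=["subject", "condition"], columns=["stage", "channel"],
        values=["spindle_density_per_min", "coupling_density_per_min"],
        aggfunc="first")
    wide.columns = [f"{s}_{c}_{v.replace('_per_min', '')}"
                    for v, s, c in wide.columns]
    return wide.reset_index()


def stage_stats(cfg: PipelineConfig, out: Path) -> None:
    (out / "stats").mkdir(exist_ok=True)
    scores = pd.read_csv(out / "behavior" / "scores.csv")
    subjects = out / "behavior" / "subjects.csv"
    covariate = None
    if subjects.exists():
        sdf = pd.read_csv(subjects)
        covariate = sdf.set_index("subject")["weight_kg"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for value in ("dprime", "accuracy_pct", "fa_rate"):
            res = rm_anova_2x2x2(scores, covariate=covariate, value=value)
            pd.DataFrame([dataclasses.asdict(r) for r in res]).to_csv(
                out / "stats" / f"anova_{value}.csv", index=False)

    arch = pd.read_csv(out / "derived" / "architecture.csv")
    rows = []
    metrics = ["TST_min", "S1_min", "S2_min", "S3_min", "REM_min",
               "WASO_min", "SE_pct"]
    wide = arch.pivot_table(index="subject", columns="condition",
                            values=metrics).dropna()
    for mtr in metrics:
        res = paired_t(wide[(mtr, "zolpidem")], wide[(mtr, "placebo")])
        rows.append({"metric": mtr, "t": res.t, "df": res.df, "p": res.p,
                     "degenerate": res.degenerate})
    tt = pd.DataFrame(rows)
    tt["holm_reject_05"] = holm_bonferroni(tt["p"].fillna(1.0), alpha=0.05)
    tt.to_csv(out / "stats" / "paired_t_architecture.csv", index=False)

    bp = pd.read_csv(out / "derived" / "band_power.csv")
    dens = pd.read_csv(out / "derived" / "densities.csv")
    mem = _memory_features(scores)
    screen_spec = sleep_memory_screen(_spectral_features(bp), mem,
                                      alpha_corrected=cfg.alpha_spectral)
    screen_spec.to_csv(out / "stats" / "screen_spectral.csv", index=False)
    screen_ev = sleep_memory_screen(_event_features(dens), mem,
                                    alpha_corrected=cfg.alpha_events)
    screen_ev.to_csv(out / "stats" / "screen_events.csv", index=False)


def stage_report(cfg: PipelineConfig, out: Path) -> dict:
    outputs = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            outputs[str(p.relative_to(out))] = _sha256(p)
    manifest = {
        "sleepmem_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": int(cfg.seed),
        "config_hash": cfg.config_hash(),
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run every stage; returns the output manifest.

    If a manifest from a previous run with the same configuration hash
    exists and all recorded outputs still match, the run is skipped
    (cheap content-hash cache) unless ``force=True``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mpath = out / "manifest.json"
    if mpath.exists() and not force:
        try:
            old = json.loads(mpath.read_text())
            if old.get("config_hash") == config.config_hash() and all(
                    (out / rel).exists() and _sha256(out / rel) == h
                    for rel, h in old["outputs"].items()):
                return old
        except (json.JSONDecodeError, KeyError):
            pass
    stages = [
        ("simulate", stage_simulate),
        ("preprocess", stage_preprocess),
        ("detect", stage_detect),
        ("spectra", stage_spectra),
        ("score", stage_score),
        ("stats", stage_stats),
    ]
    for name, fn in stages:
        try:
            fn(config, out)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return stage_report(config, out)
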