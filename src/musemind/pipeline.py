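"""End-to-end orchestration: simulate -> HRV -> EEG -> surveys -> stats.

A run is described by a :class:`RunConfig` (typically loaded from YAML).
Every stage parameter and derived seed is echoed into ``manifest.json`` in
the output directory, and rerunning the same config reproduces identical
outputs: all randomness flows from the one config seed through
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eeg import band_power_table, normalize_psd, preprocess, read_eeg_csv, write_eeg_csv
from .hrv import (
    ExclusionRecord,
    hr_to_rr,
    interpolate_or_exclude,
    metrics_frame,
    read_hr_csv,
    windowed_metrics,
    write_hr_csv,
)
from .psychometrics import SCALES, cronbach_alpha, diff_scores, score_survey
from .session import SessionTimeline, default_timeline
from .stats import (
    delta_vs_delta,
    friedman,
    paired_tests,
    rm_anova_gg,
    simple_regression,
    tukey_posthoc,
)
from .synthetic import EEGSimParams, HRSimParams, SurveySimParams, simulate_eeg, simulate_hr, simulate_surveys

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "build_rm_table"]

_TIMELINE_KEYS = {"order", "baseline_dur", "section_dur", "inter_gap"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run; unknown keys rejected."""

    seed: int = 0
    out_dir: str = "musemind_run"
    n_participants: int = 8
    timeline: dict = field(default_factory=dict)
    hr_sim: dict = field(default_factory=dict)
    eeg_sim: dict = field(default_factory=dict)
    survey_sim: dict = field(default_factory=dict)
    hrv_max_missing_frac: float = 0.20
    eeg_max_missing_frac: float = 0.50
    post_shift: dict = field(default_factory=lambda: {"suds": -1.0, "sms": 0.5, "asc": 10.0, "scs": 0.5})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad_tl = set(cfg.timeline) - _TIMELINE_KEYS
        if bad_tl:
            raise ValueError(f"unknown timeline keys: {sorted(bad_tl)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "timeline" not in raw:
            raise ValueError("config is missing the required 'timeline' key")
        return cls.from_dict(raw)

    def make_timeline(self) -> SessionTimeline:
        return default_timeline(**self.timeline)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """n independent child seeds, each below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def make_fixtures(config: RunConfig, out_dir: Path | None = None) -> Path:
    """Write the synthetic cohort (raw CSVs + ground-truth sidecars)."""
    out = Path(out_dir or config.out_dir) / "fixtures"
    out.mkdir(parents=True, exist_ok=True)
    timeline = config.make_timeline()
    seeds = _spawn_seeds(config.seed, config.n_participants * 2 + 1)
    truth_index: dict[str, dict] = {}
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        hr_params = replace(HRSimParams(**config.hr_sim), seed=seeds[2 * p])
        hr, hr_truth = simulate_hr(hr_params, timeline, pid)
        write_hr_csv(hr, out / f"{pid}_hr.csv")
        eeg_params = replace(EEGSimParams(**config.eeg_sim), seed=seeds[2 * p + 1])
        rec, eeg_truth = simulate_eeg(eeg_params, timeline, pid)
        write_eeg_csv(rec, out / f"{pid}_eeg.csv")
        pd.DataFrame({"t": hr_truth["t"], "rr_true": hr_truth["rr_true"]}).to_csv(
            out / f"{pid}_rr_true.csv", index=False
        )
        truth_index[pid] = {
            "n_missing_hr": int(hr_truth["missing_idx"].size),
            "eeg_band_power": eeg_truth["band_power"],
            "n_blinks": eeg_truth["n_blinks"],
        }
    sv_params = SurveySimParams(
        n_participants=config.n_participants,
        post_shift=config.post_shift,
        seed=seeds[-1],
        **config.survey_sim,
    )
    simulate_surveys(sv_params).to_csv(out / "surveys.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_index, fh, indent=1)
    return out


def build_rm_table(metrics: pd.DataFrame, metric: str = "sdnn") -> pd.DataFrame:
    """Session x Time design table for the two-way RM-ANOVA.

    Sessions are baseline / music / no_music; Time bins are the three 5-min
    sub-windows. The single baseline value is repeated across Time bins,
    mirroring the three-bars-per-window reporting layout (a reporting
    convention, not a statistical claim about the baseline).
    """
    hm = metrics[metrics["metric"] == metric]
    # Time bins are the 5-min sub-windows actually present (e.g. 0-5, 5-10,
    # 10-15 for full 15-min sections), excluding whole-section and 1-min rows.
    suffixes = [
        w.split("/", 1)[1]
        for w in hm["window"].unique()
        if "/" in w and "-" in w.split("/", 1)[1]
    ]
    bins = sorted(set(suffixes), key=lambda s: float(s.split("-")[0]))
    rows = []
    for pid, grp in hm.groupby("participant"):
        by_win = grp.set_index("window")["value"]
        if "baseline" not in by_win.index:
            continue
        for tb in bins:
            rows.append({"participant": pid, "session": "baseline", "time": tb,
                         "value": by_win["baseline"]})
            for sess in ("music", "no_music"):
                key = f"{sess}/{tb}"
                if key in by_win.index:
                    rows.append({"participant": pid, "session": sess, "time": tb,
                                 "value": by_win[key]})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: Path | None = None) -> dict:
    """Run every stage on a synthetic cohort and write tables + manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = make_fixtures(config, out)
    timeline = config.make_timeline()
    exclusions: list[dict] = []

    # --- HRV ---------------------------------------------------------------
    hrv_frames = []
    pids = [f"P{p + 1:02d}" for p in range(config.n_participants)]
    for pid in pids:
        series = read_hr_csv(fixtures / f"{pid}_hr.csv", pid)
        rr = interpolate_or_exclude(hr_to_rr(series), config.hrv_max_missing_frac)
        if isinstance(rr, ExclusionRecord):
            exclusions.append(asdict(rr))
            continue
        hrv_frames.append(metrics_frame(windowed_metrics(rr, timeline), pid))
    hrv_metrics = pd.concat(hrv_frames, ignore_index=True) if hrv_frames else pd.DataFrame()
    hrv_metrics.to_csv(out / "hrv_metrics.csv", index=False)

    # --- EEG ---------------------------------------------------------------
    bp_frames, norm_frames = [], []
    for pid in pids:
        rec = read_eeg_csv(fixtures / f"{pid}_eeg.csv", pid)
        result = preprocess(rec, config.eeg_max_missing_frac)
        if isinstance(result, ExclusionRecord):
            exclusions.append(asdict(result))
            continue
        clean, _ = result
        bp = band_power_table(clean, timeline)
        bp_frames.append(bp)
        norm_frames.append(normalize_psd(bp))
    band_table = pd.concat(bp_frames, ignore_index=True) if bp_frames else pd.DataFrame()
    norm_table = pd.concat(norm_frames, ignore_index=True) if norm_frames else pd.DataFrame()
    band_table.to_csv(out / "eeg_band_powers.csv", index=False)
    norm_table.to_csv(out / "eeg_normalized.csv", index=False)

    # --- Surveys -----------------------------------------------------------
    responses = pd.read_csv(fixtures / "surveys.csv")
    scored = score_survey(responses)
    diffs = diff_scores(scored)
    scored.to_csv(out / "survey_scores.csv", index=False)
    diffs.to_csv(out / "survey_diffs.csv", index=False)
    alphas = {}
    for name in SCALES:
        pre = responses[(responses["scale"] == name) & (responses["timepoint"] == "pre")]
        mat = pre.pivot(index="participant", columns="item", values="value").to_numpy()
        alphas[name] = cronbach_alpha(mat)

    # --- Stats -------------------------------------------------------------
    stats_out: dict = {"cronbach_alpha": alphas}
    rm_table = build_rm_table(hrv_metrics, "sdnn")
    if not rm_table.empty:
        n_bins = rm_table["time"].nunique()
        within = ["session", "time"] if n_bins >= 2 else "session"
        anova = rm_anova_gg(rm_table, dv="value", within=within, subject="participant")
        anova.to_csv(out / "rm_anova_sdnn.csv", index=False)
        stats_out["rm_anova_sdnn"] = anova.to_dict("records")
        last_bin = sorted(rm_table["time"].unique(), key=lambda s: float(s.split("-")[0]))[-1]
        wide = rm_table[rm_table["time"] == last_bin].pivot(
            index="participant", columns="session", values="value").dropna()
        tk = tukey_posthoc(wide.to_numpy(), list(wide.columns))
        tk.to_csv(out / "tukey_sdnn_last_window.csv", index=False)
    paired = {}
    for name in SCALES:
        sw = scored[scored["scale"] == name].pivot(
            index="participant", columns="timepoint", values="total")
        res = paired_tests(sw["pre"], sw["post"])
        paired[name] = {"W": res.statistic, "p": res.p}
    stats_out["survey_wilcoxon"] = paired
    if not norm_table.empty:
        alpha_music = norm_table[
            (norm_table["band"] == "alpha") & (norm_table["condition"] == "music")
        ].pivot(index="participant", columns="channel", values="normalized").dropna()
        if len(alpha_music) >= 2:
            fr = friedman(alpha_music.to_numpy())
            stats_out["friedman_alpha_music"] = {"chi2": fr.statistic, "p": fr.p}
    last_label = timeline.sections[-1].label
    sub_wins = [
        w for w in hrv_metrics["window"].unique()
        if w.startswith(f"{last_label}/") and "-" in w.split("/", 1)[1]
    ]
    last_window = sorted(sub_wins, key=lambda w: float(w.split("/")[1].split("-")[0]))[-1]
    dvd = delta_vs_delta(hrv_metrics, diffs, "sdnn", "suds", window=last_window)
    if len(dvd) >= 3:
        reg = simple_regression(dvd["x"], dvd["y"])
        stats_out["sdnn_vs_suds_regression"] = {
            "slope": reg.statistic, "p": reg.p, **reg.extra,
        }

    manifest = {
        "musemind_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "exclusions": exclusions,
        "stats": stats_out,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest
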