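"""End-to-end orchestration: session directory -> analysis report.

Two experiments are supported.  The *threshold* experiment relates
startle magnitude to received level and extracts the startle threshold
(first fitted value above the no-sound control); the *rise-time*
experiment relates magnitude to stimulus rise time and extracts the
rise time at which responses are expected to vanish.  Reports are pure
functions of (input directory, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accel import (
    AccelRecord,
    AnalysisWindow,
    control_baseline,
    highpass,
    read_accel,
    startle_metrics,
)
from .glm import GlmConvergenceError, predict_with_intervals, select_model
from .thresholds import (
    Audiogram,
    ThresholdEstimate,
    rise_time_threshold,
    sensation_level,
    startle_threshold,
)

log = logging.getLogger("startlekit")

__all__ = ["RunConfig", "SessionData", "load_session", "compute_metrics",
           "run_threshold_experiment", "run_rise_time_experiment"]


@dataclass
class RunConfig:
    """Configuration for one experiment run."""

    session_dir: str | Path
    experiment: str = "threshold"  # {"threshold", "rise_time"}
    seed: int = 0
    onset_s: float = 1.0
    window_s: float = 1.0
    ear_offset_db: float = 0.0
    audiograms: dict[str, Audiogram] = field(default_factory=dict)
    frequency_khz: float = 10.0
    context: dict = field(default_factory=dict)
    responses: tuple[str, ...] = ("pp_vedba", "max_norm_jerk")
    output_dir: str | Path | None = None
    make_plots: bool = False
    risetime_extrapolation_factor: float = 5.0


@dataclass
class SessionData:
    trials: pd.DataFrame
    records: dict[tuple[int, int], AccelRecord]  # (session, trial) -> record
    controls: dict[int, AccelRecord]  # session -> no-sound control record


def load_session(path: str | Path, fs: float = 320.0) -> SessionData:
    """Load a session directory written by
    :func:`startlekit.simulate.write_session_dir` (or hand-assembled in
    the same layout: ``trials.csv`` + per-trial accelerometer CSVs +
    per-session ``accel_control_s<N>.csv``)."""
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    records = {}
    for _, row in trials.iterrows():
        rec = read_accel(path / row["accel_file"], fs=fs)
        records[(int(row["session"]), int(row["trial"]))] = rec
    controls = {}
    for f in sorted(path.glob("accel_control_s*.csv")):
        controls[int(f.stem.rsplit("_s", 1)[1])] = read_accel(f, fs=fs)
    if not controls and (path / "accel_control.csv").exists():
        controls[1] = read_accel(path / "accel_control.csv", fs=fs)
    if not controls:
        raise FileNotFoundError(f"no control record found in {path}")
    return SessionData(trials=trials, records=records, controls=controls)


def compute_metrics(
    session: SessionData,
    onset_s: float = 1.0,
    window_s: float = 1.0,
    seed: int = 0,
    latency_k: float = 8.0,
) -> tuple[pd.DataFrame, dict]:
    """High-pass filter every record, compute startle metrics in the
    analysis window after stimulus onset, and measure the no-sound
    control baselines (five pseudorandom windows on the control record).

    Returns ``(trial_table, baselines)``: pooled control means (over all
    sessions' no-sound controls) for p-p VeDBA (m s^-2), max norm jerk
    (m s^-3) and the jerk MAD used by the latency detector, plus the
    per-session values under ``"per_session"``.
    """
    per_session: dict[int, dict[str, float]] = {}
    for s, control in session.controls.items():
        control_f = highpass(control)
        per_session[s] = {
            m: control_baseline(control_f, seed=seed, metric=m)
            for m in ("pp_vedba", "max_norm_jerk", "jerk_mad")
        }
    baselines = {
        m: float(np.mean([v[m] for v in per_session.values()]))
        for m in ("pp_vedba", "max_norm_jerk", "jerk_mad")
    }
    baselines["per_session"] = per_session
    rows = []
    for _, row in session.trials.iterrows():
        key = (int(row["session"]), int(row["trial"]))
        rec = session.records[key]
        filtered = highpass(rec)
        onset = float(row.get("onset_s", onset_s))
        win = AnalysisWindow(start=rec.t0 + onset, duration=window_s)
        m = startle_metrics(filtered, win,
                            baseline_jerk_mad=baselines["jerk_mad"], k=latency_k)
        clipped = bool(row.get("clipped", rec.clipped))
        out = dict(row)
        out.update({
            "pp_vedba": m.pp_vedba, "max_norm_jerk": m.max_norm_jerk,
            "latency_s": m.latency, "clipped": clipped,
        })
        rows.append(out)
    table = pd.DataFrame(rows)
    n_clip = int(table["clipped"].sum())
    if n_clip:
        log.warning("excluding %d clipped trial(s)", n_clip)
    return table[~table["clipped"]].reset_index(drop=True), baselines


def _grid_for(table: pd.DataFrame, var_col: str, pad: float = 10.0) -> dict:
    vals = table[var_col].dropna()
    return {"var": "RL" if var_col == "RL" else "rise_time",
            "lo": round(float(vals.min()) - pad, 1),
            "hi": round(float(vals.max()) + pad, 1), "step": 0.1}


def _analyse_response(
    table: pd.DataFrame,
    response: str,
    baselines: dict,
    cfg: RunConfig,
) -> dict:
    """Model selection, prediction and threshold for one response metric."""
    data = table[~table["is_control"]].copy()
    primary = "RL" if cfg.experiment == "threshold" else "rise_time"
    links = ("log", "inverse") if cfg.experiment == "threshold" else \
            ("identity", "log", "inverse")
    try:
        fit, candidates = select_model(
            data, response=response, primary=primary, links=links,
            context=cfg.context,
        )
    except GlmConvergenceError as exc:
        return {"response": response, "error": str(exc), "threshold": None}

    p_primary = float(fit.p_values.get(primary, np.nan))
    significant = bool(p_primary < 0.05)
    held = {"trial": 6.5}

    if cfg.experiment == "threshold":
        grid = _grid_for(data, "RL")
    else:
        max_rt = float(data["rise_time_ms"].max())
        grid = {"var": "rise_time", "lo": 0.0,
                "hi": round(cfg.risetime_extrapolation_factor * max_rt, 1),
                "step": 0.1}

    baseline = baselines[response]
    session_in_model = any(c.startswith("session") for c in fit.design_info["columns"])

    def one_threshold(held_at: dict, bl: float) -> tuple[ThresholdEstimate, dict]:
        try:
            curve = predict_with_intervals(fit, grid, held_at)
        except ValueError as exc:
            return ThresholdEstimate(None, bl, valid=False,
                                     reason_invalid=str(exc)), {}
        if cfg.experiment == "threshold":
            est = startle_threshold(curve, bl, rl_significant=significant)
        else:
            if not significant:
                est = ThresholdEstimate(None, bl, valid=False,
                                        reason_invalid="rise_time p >= 0.05")
            else:
                est = rise_time_threshold(curve, bl,
                                          observed_max=float(data["rise_time_ms"].max()))
        return est, {"grid": [curve.grid[0], curve.grid[-1]],
                     "fitted_range": [float(curve.fitted.min()),
                                      float(curve.fitted.max())]}

    per_session = {}
    if session_in_model:
        # session retained: threshold against each session's own
        # no-sound control, reported as the arithmetic mean
        ests = []
        session_bl = baselines.get("per_session", {})
        for lev in sorted(data["session"].unique()):
            bl = session_bl.get(int(lev), {}).get(response, baseline)
            est, _ = one_threshold({**held, "session": lev}, bl)
            per_session[int(lev)] = None if est.value is None else est.value
            if est.valid:
                ests.append(est.value)
        if ests:
            est = ThresholdEstimate(float(np.mean(ests)), baseline,
                                    baseline_scope="per_session")
        else:
            est = ThresholdEstimate(None, baseline, valid=False,
                                    reason_invalid="no session-level crossing")
        curve_info = {"per_session": per_session}
    else:
        est, curve_info = one_threshold(held, baseline)

    if cfg.experiment == "threshold" and est.value is not None:
        est_at_ear = est.value + cfg.ear_offset_db
    else:
        est_at_ear = est.value

    sensation = {}
    if est_at_ear is not None and cfg.audiograms:
        for name, aud in cfg.audiograms.items():
            try:
                sensation[name] = sensation_level(est_at_ear, aud, cfg.frequency_khz)
            except ValueError as exc:
                sensation[name] = None
                log.warning("sensation level (%s): %s", name, exc)

    return {
        "response": response,
        "model": fit.to_dict(),
        "candidates": candidates.to_dict(orient="records"),
        "p_primary": p_primary,
        "significant": significant,
        "baseline": baseline,
        "threshold": est_at_ear,
        "threshold_valid": est.valid,
        "reason_invalid": est.reason_invalid,
        "extrapolated": est.extrapolated,
        "sensation_levels": sensation,
        "curve_info": curve_info,
    }


def _run(cfg: RunConfig) -> dict:
    session = load_session(cfg.session_dir)
    table, baselines = compute_metrics(
        session, onset_s=cfg.onset_s, window_s=cfg.window_s, seed=cfg.seed
    )
    report: dict = {
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "n_trials": int((~table["is_control"]).sum()) if "is_control" in table
                    else len(table),
        "baselines": {k: (v if isinstance(v, dict) else float(v))
                      for k, v in baselines.items()},
        "responses": {},
    }
    if "is_control" not in table:
        table["is_control"] = False
    for response in cfg.responses:
        report["responses"][response] = _analyse_response(
            table, response, baselines, cfg
        )

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=_jsonable)
        )
        if cfg.make_plots:
            _plot_report(table, report, out)
    return report


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and np.isnan(x):
        return None
    return str(x)


def run_threshold_experiment(cfg: RunConfig) -> dict:
    """Analyse a level-varying playback session: metrics, AICc model
    selection, dose-response curves, startle thresholds and sensation
    levels per response metric."""
    cfg.experiment = "threshold"
    return _run(cfg)


def run_rise_time_experiment(cfg: RunConfig) -> dict:
    """Analyse a rise-time-varying session: link selected among
    identity/log/inverse by AICc, slope with CI, and the rise-time
    threshold (flagged when extrapolated beyond the tested range)."""
    cfg.experiment = "rise_time"
    df = pd.read_csv(Path(cfg.session_dir) / "trials.csv")
    if df["rise_time_ms"].nunique() < 3:
        raise ValueError("rise-time experiment needs >= 3 distinct rise times")
    return _run(cfg)


def _plot_report(table: pd.DataFrame, report: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xcol = "RL" if report["experiment"] == "threshold" else "rise_time_ms"
    fig, axes = plt.subplots(1, len(report["responses"]), figsize=(10, 4))
    axes = np.atleast_1d(axes)
    for ax, (resp, res) in zip(axes, report["responses"].items()):
        d = table[~table["is_control"]]
        ax.plot(d[xcol], d[resp], "o", ms=4)
        ax.axhline(res.get("baseline", np.nan), color="k", lw=1)
        if res.get("threshold") is not None:
            ax.axvline(res["threshold"], color="r", ls="--", lw=1)
        ax.set_xlabel(xcol)
        ax.set_ylabel(resp)
        ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(out / "dose_response.png", dpi=120)
    plt.close(fig)
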