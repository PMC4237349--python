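"""Full analysis pipeline: drag calibration -> respirometry -> Ucrit ->
kinematics -> impairment.

``run_pipeline`` consumes a directory of schema CSVs (any subset of
``drag_calib.csv``, ``traces.csv``, ``ucrit_steps.csv``,
``landmarks.csv``), runs every stage whose inputs are present, and
returns a JSON-serialisable report mirroring the experimental summary
tables: per eel x condition energetic endpoints (SMR, c, Uopt, COTmin,
Ucrit), per-condition kinematic regressions, and the drag-impairment
fit with field predictions.  Missing stages are skipped with an
explicit notice, never silently; every filtering decision (rejected
MO2 slopes, extrapolations) is logged into the report's provenance
list.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import impairment as imp
from . import kinematics as kin
from .drag import FluidEnv, MEASURED_CURVES, fit_drag_curve, standard_dummies, validate_agreement
from .errors import DragtagError, InsufficientDataError
from .io import RunConfig, read_table
from .kinematics import SITE_POSITIONS_BL
from .respirometry import (
    BlockingContext,
    O2Trace,
    cot_min,
    fit_metabolic_model,
    mo2_from_trace,
    uopt,
)
from .ucrit import UcritProtocol, ucrit_from_steps

__all__ = ["run_pipeline"]

#: Fallbacks when no cohort morphometrics table accompanies the data
#: (experimental cohort means: 0.649 kg, 0.657 m).
DEFAULT_BODY_MASS = 0.6494
DEFAULT_BODY_LENGTH = 0.657

#: Condition label -> (nominal drag N, attachment site) for the
#: impairment stage; mirrors the swim-trial sequence.
TREATMENTS = {
    "control1": (0.0, "A"),
    "support_B": (0.0, "B"),
    "small_A": (0.05, "A"),
    "intermediate_A": (0.1, "A"),
    "intermediate_B": (0.1, "B"),
    "large_A": (0.2, "A"),
    "control2": (0.0, "A"),
}


def _blocking_ctx(config: RunConfig, fish_area: float) -> BlockingContext | None:
    if not config.blocking_enabled or fish_area <= 0:
        return None
    return BlockingContext(
        fish_area=fish_area,
        tunnel_area=config.tunnel_area_mm2,
        tau=config.tau,
        lam=config.lam,
        exponent=config.blocking_exponent,
    )


def _stage_drag(data_dir: Path, config: RunConfig, log: list) -> dict | None:
    path = data_dir / "drag_calib.csv"
    if not path.exists():
        return None
    df = read_table(path, "drag_calib")
    env = FluidEnv(config.density, config.drag_coefficient, config.reference_speed)
    specs = {s.label: s for s in standard_dummies(env)}
    out = {}
    for label, grp in df.groupby("dummy_label"):
        curve = fit_drag_curve(
            list(zip(grp["speed_m_s"], grp["force_N"], grp["replicate"]))
        )
        entry = {
            "quad_coeff": curve.quad_coeff,
            "lin_coeff": curve.lin_coeff,
            "fit_r2": curve.fit_r2,
            "speed_range": list(curve.speed_range),
        }
        if label in specs:
            entry["relative_difference_at_ref"] = validate_agreement(
                curve, specs[label], env
            )
        out[str(label)] = entry
        log.append({"stage": "drag", "dummy": str(label), "n_rows": len(grp)})
    return out


def _stage_respirometry(
    data_dir: Path,
    config: RunConfig,
    fish_areas: dict,
    fish_masses: dict,
    log: list,
) -> dict | None:
    path = data_dir / "traces.csv"
    if not path.exists():
        return None
    df = read_table(path, "traces")
    results: dict = {}
    for (eel_id, cond), grp in df.groupby(["eel_id", "condition"]):
        ctx = _blocking_ctx(config, fish_areas.get(eel_id, 0.0))
        samples = []
        for speed, trial in grp.groupby("speed_m_s"):
            trace = O2Trace(
                times=trial["time_h"].to_numpy(),
                o2=trial["o2_mg_L"].to_numpy(),
                chamber_volume=config.chamber_volume,
                fish_mass=fish_masses.get(eel_id, DEFAULT_BODY_MASS),
                tunnel_speed=float(speed),
            )
            sample = mo2_from_trace(trace, config.min_r2, config.alpha, ctx)
            samples.append(sample)
            if not sample.accepted:
                log.append(
                    {
                        "stage": "respirometry",
                        "eel_id": eel_id,
                        "condition": cond,
                        "speed": float(speed),
                        "event": "mo2_rejected",
                        "r2": sample.r2,
                        "p": sample.p_value,
                    }
                )
        try:
            model = fit_metabolic_model(samples)
        except InsufficientDataError as exc:
            log.append(
                {
                    "stage": "respirometry",
                    "eel_id": eel_id,
                    "condition": cond,
                    "event": "fit_skipped",
                    "reason": str(exc),
                }
            )
            continue
        results.setdefault(cond, {})[eel_id] = {
            "smr": model.smr,
            "c": model.c,
            "fit_r2": model.fit_r2,
            "uopt": uopt(model),
            "cot_min": cot_min(model),
            "n_accepted": sum(s.accepted for s in samples),
        }
    return results


def _stage_ucrit(
    data_dir: Path, config: RunConfig, fish_areas: dict, log: list
) -> dict | None:
    path = data_dir / "ucrit_steps.csv"
    if not path.exists():
        return None
    df = read_table(path, "ucrit_steps")
    protocol = UcritProtocol(
        speed_increment=config.speed_increment,
        interval=config.interval_min,
        start_speed=config.start_speed,
    )
    results: dict = {}
    for (eel_id, cond), grp in df.groupby(["eel_id", "condition"]):
        grp = grp.sort_values("step_speed_m_s")
        ctx = _blocking_ctx(config, fish_areas.get(eel_id, 0.0))
        res = ucrit_from_steps(
            grp["step_speed_m_s"].to_list(),
            grp["completed_min"].to_list(),
            protocol,
            ctx,
        )
        results.setdefault(cond, {})[eel_id] = {
            "u_crit": res.u_crit,
            "last_completed_speed": res.last_completed_speed,
            "fatigue_time": res.fatigue_time,
            "corrected": res.corrected,
        }
        log.append({"stage": "ucrit", "eel_id": eel_id, "condition": cond})
    return results


def _stage_kinematics(
    data_dir: Path, config: RunConfig, body_lengths: dict, log: list
) -> dict | None:
    path = data_dir / "landmarks.csv"
    if not path.exists():
        return None
    df = read_table(path, "landmarks")
    rng = np.random.default_rng(config.seed)
    results: dict = {}
    for (eel_id, cond), grp in df.groupby(["eel_id", "condition"]):
        body_length = body_lengths.get(eel_id, DEFAULT_BODY_LENGTH)
        samples = []
        for speed, sp in grp.groupby("speed_m_s"):
            tracks = {}
            for site, tr in sp.groupby("site"):
                tr = tr.sort_values("time_s")
                times = tr["time_s"].to_numpy()
                dt = np.median(np.diff(times))
                tracks[site] = kin.LandmarkTrack(
                    times=times,
                    lateral=tr["lateral_m"].to_numpy(),
                    frame_rate=1.0 / dt,
                    swim_speed=float(speed),
                    site=str(site),
                )
            if "tail" not in tracks:
                continue
            total = float(tracks["tail"].times[-1] - tracks["tail"].times[0])
            seg = min(config.segment_length_s, total / config.n_blocks)
            n_slots = max(1, int((total / config.n_blocks) // seg))
            windows = kin.select_segments(
                n_slots * seg * config.n_blocks, seg, config.n_blocks, rng
            )
            fs, amps = [], {s: [] for s in tracks}
            ws = []
            sep = (SITE_POSITIONS_BL["B"] - SITE_POSITIONS_BL["A"]) * body_length
            for w in windows:
                try:
                    fs.append(kin.tailbeat_frequency(tracks["tail"], w))
                except DragtagError:
                    continue
                for s, t in tracks.items():
                    amps[s].append(kin.amplitude(t, w))
                if "A" in tracks and "B" in tracks:
                    try:
                        ws.append(kin.wave_speed(tracks["A"], tracks["B"], sep, w))
                    except DragtagError:
                        pass
            if not fs:
                log.append(
                    {
                        "stage": "kinematics",
                        "eel_id": eel_id,
                        "condition": cond,
                        "speed": float(speed),
                        "event": "no_valid_windows",
                    }
                )
                continue
            f = float(np.mean(fs))
            a_cm = float(np.mean(amps.get("tail", [np.nan])))
            samples.append(
                kin.KinematicSample(
                    speed=float(speed),
                    f=f,
                    a=a_cm,
                    a_A=float(np.mean(amps["A"])) if amps.get("A") else float("nan"),
                    a_B=float(np.mean(amps["B"])) if amps.get("B") else float("nan"),
                    W=float(np.mean(ws)) if ws else float("nan"),
                    st=kin.strouhal(a_cm / 100.0, f, float(speed)),
                )
            )
        entry: dict = {
            "samples": [s.__dict__ for s in samples],
        }
        try:
            ffit = kin.fit_kinematic(samples, "f")
            entry["f_fit"] = {
                "intercept": ffit.intercept,
                "slope": ffit.slope,
                "r2": ffit.r2,
            }
            good_w = [s for s in samples if np.isfinite(s.W)]
            wfit = kin.fit_kinematic(good_w, "W")
            entry["W_fit"] = {
                "intercept": wfit.intercept,
                "slope": wfit.slope,
                "r2": wfit.r2,
            }
        except DragtagError as exc:
            log.append(
                {
                    "stage": "kinematics",
                    "eel_id": eel_id,
                    "condition": cond,
                    "event": "fit_skipped",
                    "reason": str(exc),
                }
            )
        results.setdefault(cond, {})[eel_id] = entry
    return results


def _stage_impairment(
    resp: dict | None, ucr: dict | None, config: RunConfig, log: list
) -> dict | None:
    if not resp or not ucr:
        return None
    control = "control1"
    if control not in resp or control not in ucr:
        return None

    def endpoints(cond: str) -> pd.DataFrame | None:
        if cond not in resp or cond not in ucr:
            return None
        eels = sorted(set(resp[cond]) & set(ucr[cond]))
        if not eels:
            return None
        return pd.DataFrame(
            {
                "eel_id": eels,
                "ucrit": [ucr[cond][e]["u_crit"] for e in eels],
                "cot_min": [resp[cond][e]["cot_min"] for e in eels],
            }
        )

    ctrl = endpoints(control)
    effects = []
    for cond, (drag, site) in TREATMENTS.items():
        if drag == 0 or site != "A":
            continue
        trt = endpoints(cond)
        if trt is None:
            continue
        common = sorted(set(ctrl["eel_id"]) & set(trt["eel_id"]))
        effects.extend(
            imp.percent_effects(
                ctrl[ctrl["eel_id"].isin(common)],
                trt[trt["eel_id"].isin(common)],
                drag,
            )
        )
        log.append({"stage": "impairment", "condition": cond, "n_eels": len(common)})
    if not effects:
        return None
    try:
        fit_u = imp.fit_impairment(effects, "ucrit")
        fit_c = imp.fit_impairment(effects, "cotmin")
    except InsufficientDataError as exc:
        log.append({"stage": "impairment", "event": "fit_skipped", "reason": str(exc)})
        return None
    div = imp.endpoint_divergence(
        fit_u, fit_c, [0.05, 0.1, 0.15, 0.2], config.divergence_threshold
    )
    return {
        "effects": [e.__dict__ for e in effects],
        "ucrit_fit": {
            "lin_coeff": fit_u.lin_coeff,
            "quad_coeff": fit_u.quad_coeff,
            "lin_se": fit_u.lin_se,
            "quad_se": fit_u.quad_se,
            "fit_r2": fit_u.fit_r2,
        },
        "cotmin_fit": {
            "lin_coeff": fit_c.lin_coeff,
            "quad_coeff": fit_c.quad_coeff,
            "lin_se": fit_c.lin_se,
            "quad_se": fit_c.quad_se,
            "fit_r2": fit_c.fit_r2,
        },
        "divergence": div.to_dict(orient="records"),
    }


def run_pipeline(
    config: RunConfig,
    data_dir: str | Path,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every pipeline stage whose inputs exist under ``data_dir``.

    A ``cohort.csv`` morphometrics table (eel_id, body_mass_kg,
    body_length_m, fish_area_mm2), if present, supplies per-individual
    masses, lengths and cross-sections; otherwise experimental cohort
    means are used.  Returns the report dict; with ``out_dir`` set,
    also writes ``report.json`` plus per-stage summary CSVs.
    Re-running on the same inputs and seed produces byte-identical
    output.  An empty data directory raises
    :class:`InsufficientDataError` listing what was expected.
    """
    data_dir = Path(data_dir)
    expected = ["drag_calib.csv", "traces.csv", "ucrit_steps.csv", "landmarks.csv"]
    present = [f for f in expected if (data_dir / f).exists()]
    if not present:
        raise InsufficientDataError(
            f"no pipeline inputs in {data_dir}; expected any of {expected}"
        )
    fish_areas: dict = {}
    fish_masses: dict = {}
    body_lengths: dict = {}
    if (data_dir / "cohort.csv").exists():
        cohort = read_table(data_dir / "cohort.csv", "cohort")
        fish_areas = dict(zip(cohort["eel_id"], cohort["fish_area_mm2"]))
        fish_masses = dict(zip(cohort["eel_id"], cohort["body_mass_kg"]))
        body_lengths = dict(zip(cohort["eel_id"], cohort["body_length_m"]))
    log: list[dict] = []
    report: dict = {
        "config": {k: v for k, v in vars(config).items()},
        "inputs": present,
        "skipped": [f for f in expected if f not in present],
    }
    report["drag"] = _stage_drag(data_dir, config, log)
    resp = _stage_respirometry(data_dir, config, fish_areas, fish_masses, log)
    report["respirometry"] = resp
    ucr = _stage_ucrit(data_dir, config, fish_areas, log)
    report["ucrit"] = ucr
    report["kinematics"] = _stage_kinematics(data_dir, config, body_lengths, log)
    report["impairment"] = _stage_impairment(resp, ucr, config, log)
    report["provenance"] = log

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float)
        )
        _write_summaries(report, out)
    return report


def _write_summaries(report: dict, out: Path) -> None:
    resp = report.get("respirometry")
    if resp:
        rows = [
            {"condition": cond, "eel_id": eel, **vals}
            for cond, eels in resp.items()
            for eel, vals in eels.items()
        ]
        pd.DataFrame(rows).to_csv(out / "energetics_summary.csv", index=False)
    ucr = report.get("ucrit")
    if ucr:
        rows = [
            {"condition": cond, "eel_id": eel, **vals}
            for cond, eels in ucr.items()
            for eel, vals in eels.items()
        ]
        pd.DataFrame(rows).to_csv(out / "ucrit_summary.csv", index=False)
    kin_rep = report.get("kinematics")
    if kin_rep:
        rows = []
        for cond, eels in kin_rep.items():
            for eel, entry in eels.items():
                for s in entry.get("samples", []):
                    rows.append({"condition": cond, "eel_id": eel, **s})
        if rows:
            pd.DataFrame(rows).to_csv(out / "kinematics_summary.csv", index=False)
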