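"""Embedded study cohort table and end-to-end pipeline.

The 15-subject kinetic-results table (three groups of five: exclusive
e-cigarette users EC, combustible-cigarette smokers CIG, never-users CON;
columns V_T, K1, K1/k2, BP_ND, vB from floating-vB 2TC fits) is embedded
verbatim as the reproduction fixture, and ``reproduce_summary`` recomputes
its per-group / pooled mean +/- SD rows and the Kruskal-Wallis P row.

``run_pipeline`` drives the full chain — simulate (or ingest) subjects,
build the metabolite-corrected plasma input, fit 1TC/2TC/Logan with AIC
selection, then cohort statistics — into one deterministic JSON-able report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import input_function as ifn
from . import kinetics, stats, synthetic
from .core import PAPER_FRAMING, ValidationError, make_frame_schedule

__all__ = [
    "CohortTable",
    "load_table1",
    "reproduce_summary",
    "run_pipeline",
    "round2",
    "PARAM_COLUMNS",
    "PRINTED_SUMMARY",
]

PARAM_COLUMNS = ["VT", "K1", "K1_over_k2", "BPND", "vB"]
GROUPS = ["EC", "CIG", "CON"]

# (subject_id, sex, group, V_T, K1, K1/k2, BP_ND, vB)
_TABLE1_ROWS = [
    ("EC-07", "F", "EC", 1.17, 1.62, 0.51, 1.31, 0.15),
    ("EC-10", "M", "EC", 0.63, 1.42, 0.28, 1.23, 0.16),
    ("EC-13", "F", "EC", 0.99, 1.58, 0.42, 1.34, 0.18),
    ("EC-20", "M", "EC", 1.20, 2.67, 0.39, 2.12, 0.18),
    ("EC-23", "M", "EC", 0.83, 1.26, 0.31, 1.66, 0.13),
    ("CIG-12", "M", "CIG", 1.10, 2.71, 0.57, 0.93, 0.14),
    ("CIG-14", "M", "CIG", 4.74, 2.29, 3.42, 0.39, 0.14),
    ("CIG-17", "M", "CIG", 1.14, 3.24, 0.52, 1.21, 0.16),
    ("CIG-22", "F", "CIG", 1.45, 2.70, 0.66, 1.29, 0.11),
    ("CIG-24", "F", "CIG", 1.06, 1.62, 0.51, 1.09, 0.15),
    ("CON-01", "F", "CON", 1.15, 1.95, 0.58, 0.98, 0.18),
    ("CON-03", "M", "CON", 1.04, 1.85, 0.48, 1.17, 0.15),
    ("CON-05", "M", "CON", 0.91, 1.37, 0.40, 1.27, 0.15),
    ("CON-06", "F", "CON", 1.53, 3.19, 0.74, 1.07, 0.17),
    ("CON-09", "M", "CON", 1.18, 1.62, 0.56, 1.13, 0.13),
]

#: published summary block (mean, sd) per group and parameter, plus the
#: Kruskal-Wallis P row, for side-by-side display in `reproduce-table1`
PRINTED_SUMMARY = {
    "EC": {"VT": (0.97, 0.24), "K1": (1.71, 0.56), "K1_over_k2": (0.38, 0.09),
           "BPND": (1.53, 0.37), "vB": (0.16, 0.02)},
    "CIG": {"VT": (1.90, 1.60), "K1": (2.51, 0.60), "K1_over_k2": (1.13, 1.28),
            "BPND": (0.98, 0.36), "vB": (0.14, 0.02)},
    "CON": {"VT": (1.16, 0.23), "K1": (1.99, 0.70), "K1_over_k2": (0.55, 0.13),
            "BPND": (1.12, 0.11), "vB": (0.16, 0.02)},
    "All": {"VT": (1.34, 0.97), "K1": (2.07, 0.67), "K1_over_k2": (0.69, 0.77),
            "BPND": (1.21, 0.37), "vB": (0.15, 0.02)},
    "P": {"VT": 0.36, "K1": 0.09, "K1_over_k2": 0.03, "BPND": 0.02, "vB": 0.31},
}


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (display-precision rule)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortTable:
    """Per-subject kinetic-parameter records for a 3-group cohort."""

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        needed = {"subject_id", "group", *PARAM_COLUMNS}
        missing = needed - set(df.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns {sorted(missing)}")
        if df["subject_id"].duplicated().any():
            raise ValidationError("subject_ids must be unique")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.records["group"]))

    def group_values(self, column: str) -> list[np.ndarray]:
        return [self.records.loc[self.records["group"] == g, column].to_numpy(float)
                for g in self.groups]

    def checksum(self) -> str:
        payload = self.records.sort_values("subject_id").to_csv(index=False)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_table1() -> CohortTable:
    """The embedded 15-subject study table, values as printed."""
    df = pd.DataFrame(
        _TABLE1_ROWS,
        columns=["subject_id", "sex", "group", *PARAM_COLUMNS],
    )
    return CohortTable(df)


def load_cohort_csv(path) -> CohortTable:
    df = pd.read_csv(path)
    return CohortTable(df)


def write_cohort_csv(ct: CohortTable, path) -> None:
    ct.records.to_csv(path, index=False)


def reproduce_summary(ct: CohortTable) -> dict:
    """Group/pooled mean +/- SD and Kruskal-Wallis P per kinetic parameter.

    Returns ``{"groups": {label: {param: {"mean", "sd"}}}, "pooled": ...,
    "kruskal_p": {param: p}}`` with raw (unrounded) floats; round with
    :func:`round2` for display-precision comparison.
    """
    present = set(ct.groups)
    if len(present) < 2:
        raise ValidationError("cohort summary needs at least two groups")
    if present < set(GROUPS):  # partial standard layout: a group is missing
        raise ValidationError(
            f"cohort table missing group(s) {sorted(set(GROUPS) - present)}"
        )
    out = {"groups": {}, "pooled": {}, "kruskal_p": {}}
    for g in ct.groups:
        sub = ct.records[ct.records["group"] == g]
        out["groups"][g] = {}
        for col in PARAM_COLUMNS:
            s = stats.summarize_group(sub[col].to_numpy(float), label=g)
            out["groups"][g][col] = {"mean": s.mean, "sd": s.sd}
    for col in PARAM_COLUMNS:
        s = stats.summarize_group(ct.records[col].to_numpy(float), label="All")
        out["pooled"][col] = {"mean": s.mean, "sd": s.sd}
        out["kruskal_p"][col] = stats.kruskal_wallis(ct.group_values(col)).p_value
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline


DEFAULT_CONFIG = {
    "stage": "full",            # "full" (simulate+fit+stats) | "stats-only"
    "seed": 0,
    "n_per_group": 5,
    "noise": {"mode": "none", "alpha": 0.0},
    "framing": PAPER_FRAMING,
    "fit": {
        "t_max_min": 40.0,
        "vb_mode": ["floating", 0.05, 0.3],
        "t_star_min": 10.0,
        "n_starts": kinetics.DEFAULT_N_STARTS,
        "grid_dt_s": kinetics.DEFAULT_GRID_DT_S,
    },
    "cohort_csv": None,         # stats-only: path, or None for the embedded table
}


def _merged_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _fit_subject(lung, blood, bs, fit_cfg: dict, seed: int) -> dict:
    plasma = ifn.prepare_input(blood, bs)
    t_max_s = fit_cfg["t_max_min"] * 60.0
    vb_mode = tuple(fit_cfg["vb_mode"])
    common = dict(t_max_s=t_max_s, vb_mode=vb_mode, seed=seed,
                  n_starts=fit_cfg["n_starts"], grid_dt_s=fit_cfg["grid_dt_s"])
    fit1 = kinetics.fit_compartment(lung, plasma, blood, "1tc", **common)
    fit2 = kinetics.fit_compartment(lung, plasma, blood, "2tc", **common)
    selected = kinetics.select_model([fit1, fit2])
    logan = kinetics.logan_fit(lung, plasma, t_star_min=fit_cfg["t_star_min"])
    return {"1tc": fit1, "2tc": fit2, "selected": selected, "logan": logan}


def _fit_to_dict(fit: kinetics.KineticFit) -> dict:
    return {
        "model": fit.model_tag,
        "K1": fit.params.K1, "k2": fit.params.k2, "k3": fit.params.k3,
        "k4": fit.params.k4, "vB": fit.params.vB,
        "VT": fit.vt, "K1_over_k2": fit.k1_over_k2, "BPND": fit.bp_nd,
        "rss": fit.rss, "aic": fit.aic, "n_frames": fit.n_frames,
        "converged": fit.converged,
    }


def run_pipeline(config: dict | None = None) -> dict:
    """Run the configured analysis and return a JSON-serialisable report.

    ``stage: "stats-only"`` summarises an existing cohort table (the
    embedded study table by default).  ``stage: "full"`` simulates a
    cohort, prepares each subject's metabolite-corrected plasma input, fits
    1TC and 2TC models (AIC-selected) plus a Logan plot, and summarises the
    2TC macro-parameters with the nonparametric cohort statistics.
    Per-subject failures are reported and do not abort the run.
    """
    cfg = _merged_config(config)
    report: dict = {"config": cfg}

    if cfg["stage"] == "stats-only":
        ct = load_cohort_csv(cfg["cohort_csv"]) if cfg["cohort_csv"] else load_table1()
        report["summary"] = reproduce_summary(ct)
        return report
    if cfg["stage"] != "full":
        raise ValidationError(f"unknown stage {cfg['stage']!r}")

    schedule = make_frame_schedule([tuple(b) for b in cfg["framing"]])
    nm = synthetic.NoiseModel(alpha=cfg["noise"]["alpha"], mode=cfg["noise"]["mode"])
    truth, data = synthetic.simulate_cohort(
        n_per_group=cfg["n_per_group"], schedule=schedule, nm=nm,
        seed=cfg["seed"], grid_dt_s=cfg["fit"]["grid_dt_s"],
    )
    subjects, rows, failures = {}, [], {}
    for sid, (lung, blood, bs, kp) in data.items():
        try:
            fits = _fit_subject(lung, blood, bs, cfg["fit"], seed=cfg["seed"])
        except Exception as exc:
            failures[sid] = str(exc)
            continue
        fit2 = fits["2tc"]
        rows.append({
            "subject_id": sid,
            "group": sid.split("-")[0],
            "VT": fit2.vt, "K1": fit2.params.K1,
            "K1_over_k2": fit2.k1_over_k2, "BPND": fit2.bp_nd,
            "vB": fit2.params.vB,
        })
        subjects[sid] = {
            "fits": {tag: _fit_to_dict(fits[tag]) for tag in ("1tc", "2tc")},
            "selected_model": fits["selected"].model_tag,
            "logan": {"VT": fits["logan"].slope,
                      "r_squared": fits["logan"].r_squared,
                      "t_star_min": fits["logan"].t_star_min},
        }
    report["subjects"] = subjects
    report["failures"] = failures
    report["truth"] = truth.to_dict(orient="records")
    if rows:
        ct = CohortTable(pd.DataFrame(rows))
        report["cohort"] = rows
        report["summary"] = reproduce_summary(ct)
    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON encoding of a pipeline report."""
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=False,
                      default=float)
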