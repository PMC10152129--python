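"""Synthetic subjects and cohorts for the lung PET kinetic pipeline.

Nothing in the study's raw data is public, so end-to-end behaviour is
exercised on simulated subjects whose statistical structure matches what the
analysis assumes:

* a bolus arterial-like plasma input (Feng-style tri-exponential with onset
  delay);
* a monotonically declining parent fraction (single exponential to a floor),
  sampled at the venous draw times ~2, 5, 10, 15, 30, 45, 60 min;
* a linear plasma-to-whole-blood activity ratio (default constant 1.26);
* lung kinetics from the reversible 2TC model with fractional blood volume;
* the 50-frame/60-min framing schedule and frame-duration-weighted Gaussian
  measurement noise.

Continuous curves are evaluated on a fine uniform grid (default 0.5 s) and
averaged within frames, mirroring the forward model used for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    PAPER_FRAMING,
    BloodSeries,
    FrameSchedule,
    TimeActivityCurve,
    ValidationError,
    make_frame_schedule,
)
from .kinetics import DEFAULT_GRID_DT_S, KineticParams, _tissue_response

__all__ = [
    "InputModel",
    "NoiseModel",
    "GroupSpec",
    "plasma_input",
    "parent_fraction_curve",
    "pwb_ratio_curve",
    "simulate_subject",
    "simulate_cohort",
    "true_parent_plasma",
    "default_group_specs",
    "BLOOD_SAMPLE_TIMES_MIN",
]

#: venous draw times (minutes post-injection)
BLOOD_SAMPLE_TIMES_MIN = np.array([2.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0])


@dataclass(frozen=True)
class InputModel:
    """Plasma-input, parent-fraction and plasma/whole-blood ratio model.

    The plasma bolus is the Feng tri-exponential
    ``Cp(u) = (A1 u - A2 - A3) e^{-l1 u} + A2 e^{-l2 u} + A3 e^{-l3 u}``
    with ``u = t - delay`` (zero before the delay, continuous at onset).
    Amplitudes are kBq/mL (A1 kBq/mL/min), eigenvalues 1/min.  Defaults give
    a sharp peak well under 5 min (~55 kBq/mL) and a slow ~1.5 kBq/mL tail
    at 60 min, the shape expected of a venous-injected thoracic bolus.
    """

    A1: float = 600.0
    A2: float = 6.0
    A3: float = 2.5
    lambda1: float = 4.0
    lambda2: float = 0.5
    lambda3: float = 0.008
    delay_min: float = 0.3
    pf_floor: float = 0.15
    pf_tau_min: float = 20.0
    pwb0: float = 1.26
    pwb_slope: float = 0.0

    def __post_init__(self):
        if min(self.A1, self.A2, self.A3) < 0:
            raise ValidationError("input-model amplitudes must be non-negative")
        if not (self.lambda1 > self.lambda2 > self.lambda3 > 0):
            raise ValidationError("eigenvalues must satisfy lambda1 > lambda2 > lambda3 > 0")
        if not 0.0 <= self.pf_floor <= 1.0:
            raise ValidationError("pf_floor must lie in [0, 1]")
        if self.pf_tau_min <= 0:
            raise ValidationError("pf_tau_min must be positive")
        if self.delay_min < 0:
            raise ValidationError("delay must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Frame noise: sd_i = alpha * sqrt(value_i / duration_i) (durations in min)."""

    alpha: float = 0.0
    mode: str = "none"

    def __post_init__(self):
        if self.alpha < 0:
            raise ValidationError("noise scale alpha must be non-negative")
        if self.mode not in ("none", "frame_weighted"):
            raise ValidationError(f"unknown noise mode {self.mode!r}")


def plasma_input(model: InputModel, t_min) -> np.ndarray:
    """Total plasma activity (kBq/mL) at time(s) t (minutes)."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be non-negative")
    u = t - model.delay_min
    up = np.maximum(u, 0.0)
    val = ((model.A1 * up - model.A2 - model.A3) * np.exp(-model.lambda1 * up)
           + model.A2 * np.exp(-model.lambda2 * up)
           + model.A3 * np.exp(-model.lambda3 * up))
    return np.where(u <= 0, 0.0, np.maximum(val, 0.0))


def parent_fraction_curve(model: InputModel, t_min) -> np.ndarray:
    """Parent fraction pf(t) = floor + (1 - floor) e^{-t/tau}; pf(0) = 1."""
    t = np.asarray(t_min, dtype=float)
    return model.pf_floor + (1.0 - model.pf_floor) * np.exp(-t / model.pf_tau_min)


def pwb_ratio_curve(model: InputModel, t_min) -> np.ndarray:
    """Plasma-to-whole-blood activity ratio (clipped away from zero)."""
    t = np.asarray(t_min, dtype=float)
    return np.maximum(model.pwb0 + model.pwb_slope * t, 1e-6)


def true_parent_plasma(im: InputModel, t_end_min: float = 60.0,
                       dt_s: float = 0.5):
    """The generating parent-plasma input as a finely sampled PlasmaInput.

    Bypasses the framed-blood reconstruction entirely; used to exercise the
    fitting machinery against a perfectly known input.
    """
    from .input_function import PlasmaInput

    t_s = np.arange(0.0, t_end_min * 60.0 + dt_s / 2, dt_s)
    t_min = t_s / 60.0
    return PlasmaInput(t_s, plasma_input(im, t_min) * parent_fraction_curve(im, t_min),
                       provenance=("analytic",))


def simulate_subject(kp: KineticParams, im: InputModel,
                     schedule: FrameSchedule | None = None,
                     nm: NoiseModel = NoiseModel(),
                     seed: int = 0,
                     grid_dt_s: float = DEFAULT_GRID_DT_S,
                     ) -> tuple[TimeActivityCurve, TimeActivityCurve, BloodSeries]:
    """Forward-simulate one subject.

    Returns the lung TAC, the whole-blood (blood-pool) TAC, and the venous
    blood series.  The lung concentration is
    ``(1 - vB) * (h conv parent-plasma) + vB * C_wb`` frame-averaged on the
    schedule; all randomness is owned by ``seed``.
    """
    if schedule is None:
        schedule = make_frame_schedule(PAPER_FRAMING)
    t_end_s = schedule.total_duration_s
    n = int(round(t_end_s / grid_dt_s))
    grid_s = np.linspace(0.0, t_end_s, n + 1)
    grid_min = grid_s / 60.0
    dt_min = grid_dt_s / 60.0

    cp = plasma_input(im, grid_min)
    pf = parent_fraction_curve(im, grid_min)
    ratio = pwb_ratio_curve(im, grid_min)
    c_parent = cp * pf
    c_wb = cp / ratio

    if kp.K1 == 0.0:
        tissue = np.zeros_like(grid_min)
    else:
        tag = "2tc" if kp.is_two_tissue else "1tc"
        tissue = _tissue_response(kp, tag, dt_min, c_parent)
    lung_grid = (1.0 - kp.vB) * tissue + kp.vB * c_wb

    def frame_avg(curve):
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (curve[1:] + curve[:-1])
                                               * np.diff(grid_s))])
        hi = np.interp(schedule.end_s, grid_s, cum)
        lo = np.interp(schedule.start_s, grid_s, cum)
        return (hi - lo) / schedule.durations_s

    lung_vals = frame_avg(lung_grid)
    wb_vals = frame_avg(c_wb)

    noisy = nm.mode == "frame_weighted" and nm.alpha > 0
    if noisy:
        rng = np.random.default_rng(seed)
        dur_min = schedule.durations_s / 60.0
        sd = nm.alpha * np.sqrt(np.maximum(lung_vals, 0.0) / dur_min)
        lung_vals = lung_vals + rng.normal(0.0, 1.0, lung_vals.size) * sd

    lung = TimeActivityCurve(schedule, lung_vals, label="lung", noisy=noisy)
    blood = TimeActivityCurve(schedule, wb_vals, label="pulmonary_artery")

    ts = BLOOD_SAMPLE_TIMES_MIN
    bs = BloodSeries(
        sample_times_s=ts * 60.0,
        wholeblood=plasma_input(im, ts) / pwb_ratio_curve(im, ts),
        plasma=plasma_input(im, ts),
        parent_fraction=parent_fraction_curve(im, ts),
    )
    return lung, blood, bs


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Log-normal parameter distribution for one group.

    ``centers`` maps K1/k2/k3/k4/vB to group means (the log-normal is
    mean-parameterised, so E[X] equals the stated center); ``cv`` is the
    coefficient of variation of the draws.  vB is drawn normally with sd
    ``vb_sd`` and clipped to [0.05, 0.3], the physiologic lung blood-volume
    window the fit itself uses.
    """

    label: str
    centers: dict
    cv: float = 0.2
    vb_sd: float = 0.02

    def __post_init__(self):
        needed = {"K1", "k2", "k3", "k4", "vB"}
        if set(self.centers) != needed:
            raise ValidationError(f"group spec must give centers for {sorted(needed)}")
        if self.cv < 0 or self.vb_sd < 0:
            raise ValidationError("spread parameters must be non-negative")


def default_group_specs() -> list[GroupSpec]:
    """EC / CIG / CON group medians.

    K1, K1/k2 and BP_ND medians follow the study cohort's group means; k4 is
    set to 1.0/min (not separately reported for lung) so k3 = BP_ND * k4 and
    k2 = K1 / (K1/k2).
    """
    def centers(k1, k1k2, bp, vb):
        return {"K1": k1, "k2": k1 / k1k2, "k3": bp, "k4": 1.0, "vB": vb}

    return [
        GroupSpec("EC", centers(1.71, 0.38, 1.53, 0.16)),
        GroupSpec("CIG", centers(2.51, 1.13, 0.98, 0.14)),
        GroupSpec("CON", centers(1.99, 0.55, 1.12, 0.16)),
    ]


def _draw_params(spec: GroupSpec, rng: np.random.Generator) -> KineticParams:
    sigma = np.sqrt(np.log(1.0 + spec.cv ** 2))
    vals = {}
    for name in ("K1", "k2", "k3", "k4"):
        z = rng.standard_normal()
        vals[name] = float(spec.centers[name]
                           * np.exp(sigma * z - 0.5 * sigma ** 2))
    vb = float(np.clip(spec.centers["vB"] + spec.vb_sd * rng.standard_normal(),
                       0.05, 0.3))
    return KineticParams(vB=vb, **vals)


def simulate_cohort(group_specs: list[GroupSpec] | None = None,
                    n_per_group: int = 5,
                    im: InputModel = InputModel(),
                    schedule: FrameSchedule | None = None,
                    nm: NoiseModel = NoiseModel(),
                    seed: int = 0,
                    grid_dt_s: float = DEFAULT_GRID_DT_S):
    """Simulate a cohort; returns (truth table, per-subject data dict).

    The truth table is a DataFrame with columns subject_id, group, VT, K1,
    K1_over_k2, BPND, vB (the generating parameters and their macro
    combinations); the data dict maps subject_id to a
    ``(lung, blood, blood_series, params)`` tuple.  Deterministic given seed.
    """
    if group_specs is None:
        group_specs = default_group_specs()
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    rows, data = [], {}
    for spec in group_specs:
        for i in range(n_per_group):
            kp = _draw_params(spec, rng)
            subject_seed = int(rng.integers(0, 2 ** 31 - 1))
            sid = f"{spec.label}-{i + 1:02d}"
            lung, blood, bs = simulate_subject(kp, im, schedule, nm,
                                               seed=subject_seed,
                                               grid_dt_s=grid_dt_s)
            rows.append({
                "subject_id": sid, "group": spec.label, "VT": kp.vt,
                "K1": kp.K1, "K1_over_k2": kp.K1 / kp.k2, "BPND": kp.bp_nd,
                "vB": kp.vB,
            })
            data[sid] = (lung, blood, bs, kp)
    return pd.DataFrame(rows), data
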