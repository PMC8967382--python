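"""Trackball optomotor-behavior analysis.

From two-sensor ball displacement logs to the behavioral statistics:
yaw/forward velocity decomposition, mirror-symmetric trial aggregation,
baseline-referenced peak turning velocities, slow-walker rejection,
per-fly log-luminance slope fits, and the rescue-efficiency statistic with
its fly-shuffling permutation test.

Sign convention: positive yaw is turning in the direction of stimulus
motion.  Yaw is reported in rad/s, forward speed in mm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import fit_log_slope
from .stimuli import StimulusProtocol, michelson_contrast
from .synthetic_data import BallKinematics, SensorSample, VelocityTrace

__all__ = [
    "BallVelocities",
    "MeanTurn",
    "SlopeFit",
    "EfficiencyResult",
    "velocities_from_sensors",
    "aggregate_mirrored",
    "peak_velocity",
    "summarize_turning",
    "reject_slow_flies",
    "fit_turn_slope",
    "rescue_efficiency",
    "permutation_efficiency_test",
]


@dataclass
class BallVelocities:
    """Body rotation rates recovered from the ball sensors."""

    time: np.ndarray
    yaw: np.ndarray  # rad/s
    pitch: np.ndarray  # rad/s, about the left-right axis (forward translation)
    roll: np.ndarray  # rad/s, about the front-back axis

    @property
    def forward(self) -> np.ndarray:
        """Forward translation speed in mm/s (requires radius in mm)."""
        return self._radius * self.pitch

    _radius: float = 3.0


def velocities_from_sensors(
    samples: SensorSample, kin: BallKinematics | None = None
) -> BallVelocities:
    """Invert the two-sensor ball geometry into body rotation rates.

    The horizontal channels read yaw identically at any equatorial
    azimuth; the two vertical channels are a linear map of the horizontal
    rotation components (pitch, roll) that is inverted exactly whenever
    the sensors sit at distinct azimuths.
    """
    kin = kin or samples.kin
    r = kin.radius
    th1, th2 = np.deg2rad(kin.sensor_azimuths)
    det = np.sin(th2 - th1)
    if abs(det) < 1e-9:
        raise ValueError("degenerate sensor geometry: coincident azimuths")
    yaw = (samples.s1_h + samples.s2_h) / (2.0 * r)
    # [v1; v2]/R = [[sin th1, -cos th1], [sin th2, -cos th2]] @ [pitch; roll]
    v1 = samples.s1_v / r
    v2 = samples.s2_v / r
    pitch = (-np.cos(th2) * v1 + np.cos(th1) * v2) / det
    roll = (-np.sin(th2) * v1 + np.sin(th1) * v2) / det
    bv = BallVelocities(time=samples.time, yaw=yaw, pitch=pitch, roll=roll)
    bv._radius = r
    return bv


# ---------------------------------------------------------------------------
# trial aggregation and peak extraction
# ---------------------------------------------------------------------------


@dataclass
class MeanTurn:
    """Mirror-aggregated mean turning trace of one fly for one epoch."""

    fly_id: str
    epoch_label: str
    time: np.ndarray
    yaw: np.ndarray
    forward: np.ndarray
    n_trials: int
    genotype: str = ""


def aggregate_mirrored(trials: list[VelocityTrace]) -> list[MeanTurn]:
    """Average each fly's trials per epoch after mirroring leftward trials.

    Leftward (-1) trial yaw is negated before averaging with rightward
    trials, so a direction-independent turning bias cancels exactly when
    the two directions are presented equally often.  One-sided epochs are
    averaged as-is with a warning.
    """
    groups: dict[tuple[str, str], list[VelocityTrace]] = {}
    for tr in trials:
        groups.setdefault((tr.fly_id, tr.epoch_label), []).append(tr)
    out = []
    for (fly, label), g in groups.items():
        dirs = {tr.direction for tr in g}
        if dirs == {1} or dirs == {-1}:
            warnings.warn(
                f"epoch {label!r} of {fly} presented in one direction only",
                stacklevel=2,
            )
        yaw = np.mean([tr.direction * tr.yaw for tr in g], axis=0)
        fwd = np.mean([tr.forward for tr in g], axis=0)
        out.append(
            MeanTurn(
                fly_id=fly,
                epoch_label=label,
                time=g[0].time,
                yaw=yaw,
                forward=fwd,
                n_trials=len(g),
                genotype=g[0].genotype,
            )
        )
    return out


def peak_velocity(
    time: np.ndarray,
    yaw: np.ndarray,
    motion_duration: float = 0.75,
    response_delay: float = 0.1,
    baseline_window: float = 0.2,
) -> tuple[float, float]:
    """Baseline and peak turning velocity of a motion-onset-aligned trace.

    Baseline: mean yaw over the last 200 ms of the preceding inter-
    stimulus interval (time in ``[-baseline_window, 0)``).  Peak: maximum
    of (yaw - baseline) over the motion period shifted by the response
    delay, ``[delay, motion_duration + delay]``.  Returns
    ``(baseline, peak)``.
    """
    time = np.asarray(time, dtype=float)
    yaw = np.asarray(yaw, dtype=float)
    if time[0] > -baseline_window or time[-1] < motion_duration + response_delay:
        raise ValueError("trace does not cover the baseline and peak windows")
    base_sel = (time >= -baseline_window) & (time < 0)
    peak_sel = (time >= response_delay) & (time <= motion_duration + response_delay)
    baseline = float(yaw[base_sel].mean())
    peak = float((yaw[peak_sel] - baseline).max())
    return baseline, peak


def summarize_turning(
    trials: list[VelocityTrace],
    protocol: StimulusProtocol | None = None,
    motion_duration: float = 0.75,
) -> pd.DataFrame:
    """Per fly x epoch turning summary table.

    Columns: fly_id, genotype, epoch, baseline (rad/s), peak (rad/s),
    forward (mm/s, the fly's overall mean walking speed), n_trials, and —
    when a protocol is given — edge luminance and Michelson contrast.
    """
    means = aggregate_mirrored(trials)
    fwd_by_fly: dict[str, list[float]] = {}
    for tr in trials:
        fwd_by_fly.setdefault(tr.fly_id, []).append(float(np.mean(tr.forward)))
    rows = []
    for m in means:
        base, peak = peak_velocity(m.time, m.yaw, motion_duration=motion_duration)
        row = {
            "fly_id": m.fly_id,
            "genotype": m.genotype,
            "epoch": m.epoch_label,
            "baseline": base,
            "peak": peak,
            "forward": float(np.mean(fwd_by_fly[m.fly_id])),
            "n_trials": m.n_trials,
        }
        if protocol is not None:
            ep = protocol.occurrences(m.epoch_label)[0].epoch
            row["edge_luminance"] = ep.luminances["edge"]
            row["michelson_contrast"] = michelson_contrast(
                ep.luminances["edge"], ep.luminances["background"]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def reject_slow_flies(
    summary: pd.DataFrame, threshold: float = 2.0
) -> tuple[pd.DataFrame, dict]:
    """Discard flies whose baseline forward walking speed is below 2 mm/s.

    A fly walking at exactly the threshold is kept (the criterion is
    strictly "less than").  Returns the kept rows and a rejection report.
    """
    speed = summary.groupby("fly_id")["forward"].mean()
    slow = set(speed.index[speed < threshold])
    kept = summary[~summary["fly_id"].isin(slow)].reset_index(drop=True)
    report = {
        "n_flies": int(len(speed)),
        "n_rejected": int(len(slow)),
        "rejected_fraction": len(slow) / len(speed) if len(speed) else 0.0,
        "rejected_flies": sorted(slow),
    }
    return kept, report


# ---------------------------------------------------------------------------
# slopes and rescue efficiency
# ---------------------------------------------------------------------------


@dataclass
class SlopeFit:
    """Per-fly log-luminance slopes with their across-fly mean ± SEM."""

    per_fly: pd.DataFrame  # columns fly_id, a, b
    mean_a: float
    sem_a: float


def fit_turn_slope(summary: pd.DataFrame, normalize: bool = False) -> SlopeFit:
    """Fit ``V = a*log(luminance) + b`` to each fly's peak velocities.

    ``summary`` needs columns fly_id, edge_luminance, peak.  The slope is
    summarized as mean ± SEM across flies (the fly is the statistical
    unit).
    """
    rows = []
    for fly, g in summary.groupby("fly_id"):
        a, b = fit_log_slope(
            g["edge_luminance"].to_numpy(), g["peak"].to_numpy(), normalize=normalize
        )
        rows.append({"fly_id": fly, "a": a, "b": b})
    per_fly = pd.DataFrame(rows)
    slopes = per_fly["a"].to_numpy()
    sem = slopes.std(ddof=1) / np.sqrt(len(slopes)) if len(slopes) > 1 else np.nan
    return SlopeFit(per_fly=per_fly, mean_a=float(slopes.mean()), sem_a=float(sem))


def _peak_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Fly x luminance matrix of peak velocities."""
    return summary.pivot_table(index="fly_id", columns="edge_luminance", values="peak")


def rescue_efficiency(
    rescue: pd.DataFrame, ctrl_neg: pd.DataFrame, ctrl_pos: pd.DataFrame
) -> pd.Series:
    """Fractional rescue efficiency per edge luminance.

    ``E = (mean(rescue) - mean(negative control)) /
    (mean(positive control) - mean(negative control))`` on peak turning
    velocities; 0 means no rescue beyond the transmission-deficient
    negative control, 1 means full rescue to the heterozygous positive
    control.  Inputs are turning summaries with columns fly_id,
    edge_luminance, peak.
    """
    mr = _peak_matrix(rescue).mean()
    mn = _peak_matrix(ctrl_neg).mean()
    mp = _peak_matrix(ctrl_pos).mean()
    denom = mp - mn
    if (denom == 0).any():
        raise ZeroDivisionError("efficiency undefined: controls coincide")
    return (mr - mn) / denom


@dataclass
class EfficiencyResult:
    """Permutation comparison of two genotypes' rescue efficiencies."""

    luminances: np.ndarray
    e_a: np.ndarray
    e_b: np.ndarray
    observed_diff: np.ndarray
    null_diff: np.ndarray  # (n_perm, n_luminances)
    p_raw: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray
    n_perm: int
    alpha: float
    seed: int


def permutation_efficiency_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    ctrl_neg: pd.DataFrame,
    ctrl_pos: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> EfficiencyResult:
    """Fly-shuffling permutation test on rescue-efficiency differences.

    The flies of the two rescue genotypes are pooled and reassigned to the
    two groups ``n_perm`` times (group sizes preserved); each shuffle
    yields a per-luminance difference of rescue efficiencies, building the
    null distribution.  Two-tailed p-values use the add-one convention
    ``(b + 1)/(n + 1)`` and are Bonferroni-corrected across luminances.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    ma = _peak_matrix(group_a)
    mb = _peak_matrix(group_b)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("both groups need at least 2 flies")
    if not ma.columns.equals(mb.columns):
        raise ValueError("groups were measured at different luminances")
    mn = _peak_matrix(ctrl_neg).mean().to_numpy()
    mp = _peak_matrix(ctrl_pos).mean().to_numpy()
    denom = mp - mn
    if (denom == 0).any():
        raise ZeroDivisionError("efficiency undefined: controls coincide")

    def eff(mat: np.ndarray) -> np.ndarray:
        return (mat.mean(axis=0) - mn) / denom

    a_mat = ma.to_numpy()
    b_mat = mb.to_numpy()
    e_a = eff(a_mat)
    e_b = eff(b_mat)
    observed = e_a - e_b

    pooled = np.vstack([a_mat, b_mat])
    n_a = len(a_mat)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, pooled.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        null[i] = eff(pooled[perm[:n_a]]) - eff(pooled[perm[n_a:]])

    ge = (null >= observed).sum(axis=0)
    le = (null <= observed).sum(axis=0)
    p_raw = np.minimum(
        1.0, 2.0 * np.minimum(ge + 1, le + 1) / (n_perm + 1)
    )
    n_tests = pooled.shape[1]
    p_corr = np.minimum(1.0, p_raw * n_tests)
    return EfficiencyResult(
        luminances=ma.columns.to_numpy(dtype=float),
        e_a=e_a,
        e_b=e_b,
        observed_diff=observed,
        null_diff=null,
        p_raw=p_raw,
        p_corrected=p_corr,
        significant=p_corr < alpha,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
    )
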