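"""Two-photon calcium-imaging pipeline.

Turns raw image stacks (or raw ROI fluorescence traces) into trial-averaged
response metrics: translation registration, background-subtracted ROI
extraction, ΔF/F₀, 10 Hz interpolation + trial averaging, polarity-based
ROI filtering, and the per-protocol response quantifications (staircase OFF
steps, flash plateaus, A/B step peaks and sustained components, moving-edge
responses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.stats import spearmanr

from .stimuli import StimulusProtocol, staircase_down_steps

__all__ = [
    "save_stack",
    "load_stack",
    "ImageStack",
    "RoiMask",
    "RoiTrace",
    "RoiTraceSet",
    "EpochAverage",
    "TrialAverage",
    "register_stack",
    "extract_traces",
    "compute_dff",
    "trial_average",
    "filter_rois",
    "staircase_step_response",
    "plateau_responses",
    "ab_responses",
    "edge_response",
    "response_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """A T x H x W fluorescence movie with its frame rate (Hz)."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty T x H x W array")
        if not np.isfinite(self.frames).all():
            raise ValueError("frame intensities must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def save_stack(stack: ImageStack, path) -> None:
    """Write a stack to TIFF (float32), frame rate in the image description."""
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        description=f"frame_rate={stack.frame_rate}",
    )


def load_stack(path, frame_rate: float | None = None) -> ImageStack:
    """Read a TIFF movie; the frame rate comes from the file's description
    tag unless given explicitly."""
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        if frame_rate is None:
            desc = tf.pages[0].description or ""
            for token in desc.split():
                if token.startswith("frame_rate="):
                    frame_rate = float(token.split("=", 1)[1])
    if frame_rate is None:
        raise ValueError("frame rate not recorded in file; pass frame_rate=")
    return ImageStack(np.asarray(frames, dtype=float), frame_rate)


@dataclass
class RoiMask:
    """Manually selected ROI pixel sets plus one background pixel set.

    ``rois`` are boolean H x W arrays; they must be non-empty, disjoint and
    inside the frame.  ``background`` is a boolean array of pixels used for
    background subtraction.
    """

    rois: list[np.ndarray]
    background: np.ndarray

    def __post_init__(self) -> None:
        self.rois = [np.asarray(r, dtype=bool) for r in self.rois]
        self.background = np.asarray(self.background, dtype=bool)
        if not self.rois:
            raise ValueError("need at least one ROI")
        shape = self.rois[0].shape
        for r in self.rois:
            if r.shape != shape or not r.any():
                raise ValueError("ROIs must be non-empty masks of equal shape")
        if self.background.shape != shape or not self.background.any():
            raise ValueError("background mask must be non-empty and match ROI shape")
        stacked = np.sum(self.rois, axis=0)
        if (stacked > 1).any():
            raise ValueError("ROI masks overlap")

    def validate_frame(self, frame_shape: tuple[int, int]) -> None:
        if self.rois[0].shape != tuple(frame_shape):
            raise ValueError("mask shape does not match frame shape")


@dataclass
class RoiTrace:
    """Fluorescence time series of one ROI.

    ``dff`` is defined only after :func:`compute_dff`.
    """

    fly_id: str
    roi_id: str
    cell_type: str
    time: np.ndarray
    raw_f: np.ndarray
    sample_rate: float
    dff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.raw_f = np.asarray(self.raw_f, dtype=float)
        if self.time.shape != self.raw_f.shape:
            raise ValueError("time and raw_f must have equal length")
        if len(self.time) > 1 and not (np.diff(self.time) > 0).all():
            raise ValueError("time must be strictly increasing")

    @property
    def values(self) -> np.ndarray:
        """The ΔF/F₀ trace (preferred) or the raw trace."""
        return self.dff if self.dff is not None else self.raw_f


@dataclass
class RoiTraceSet:
    """A collection of ROI traces across flies, with CSV round-tripping."""

    traces: list[RoiTrace] = field(default_factory=list)

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def by_fly(self) -> dict[str, list[RoiTrace]]:
        out: dict[str, list[RoiTrace]] = {}
        for tr in self.traces:
            out.setdefault(tr.fly_id, []).append(tr)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (fly, roi, cell_type, time, raw_f[, dff])."""
        rows = []
        for tr in self.traces:
            df = pd.DataFrame(
                {
                    "fly_id": tr.fly_id,
                    "roi_id": tr.roi_id,
                    "cell_type": tr.cell_type,
                    "time": tr.time,
                    "raw_f": tr.raw_f,
                    "sample_rate": tr.sample_rate,
                }
            )
            if tr.dff is not None:
                df["dff"] = tr.dff
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RoiTraceSet":
        traces = []
        for (fly, roi, ct), g in df.groupby(["fly_id", "roi_id", "cell_type"], sort=False):
            g = g.sort_values("time")
            traces.append(
                RoiTrace(
                    fly_id=str(fly),
                    roi_id=str(roi),
                    cell_type=str(ct),
                    time=g["time"].to_numpy(),
                    raw_f=g["raw_f"].to_numpy(),
                    sample_rate=float(g["sample_rate"].iloc[0]),
                    dff=g["dff"].to_numpy() if "dff" in g else None,
                )
            )
        return cls(traces)


@dataclass
class EpochAverage:
    """Trial-averaged response of one epoch on its aligned 10 Hz grid."""

    label: str
    tau: np.ndarray
    mean: np.ndarray
    n_trials: int


@dataclass
class TrialAverage:
    """Per-epoch trial-averaged ΔF/F of one ROI at a fixed sample rate."""

    epochs: dict[str, EpochAverage]
    sample_rate: float
    fly_id: str = ""
    roi_id: str = ""
    cell_type: str = ""

    def __getitem__(self, label: str) -> EpochAverage:
        return self.epochs[label]

    def last_window(self, label: str, seconds: float) -> np.ndarray:
        """Samples of an epoch's trailing window ``[dur - seconds, dur)``."""
        ep = self.epochs[label]
        duration = len(ep.tau) / self.sample_rate
        if seconds > duration + 1e-9:
            raise ValueError(
                f"window of {seconds} s exceeds epoch {label!r} duration {duration} s"
            )
        return ep.mean[ep.tau >= duration - seconds - 1e-9]

    def normalized(self) -> "TrialAverage":
        """Min-max normalize all epoch means jointly to [0, 1]."""
        allv = np.concatenate([e.mean for e in self.epochs.values()])
        lo, hi = allv.min(), allv.max()
        if hi == lo:
            raise ValueError("cannot normalize a constant trial average")
        scaled = {
            lab: EpochAverage(lab, e.tau, (e.mean - lo) / (hi - lo), e.n_trials)
            for lab, e in self.epochs.items()
        }
        return TrialAverage(scaled, self.sample_rate, self.fly_id, self.roi_id, self.cell_type)


# ---------------------------------------------------------------------------
# registration & extraction
# ---------------------------------------------------------------------------


def register_stack(
    stack: ImageStack, max_shift: int = 10, n_reference_frames: int = 30
) -> tuple[ImageStack, np.ndarray]:
    """Rigid translation registration against an early-movie reference.

    The reference is the maximum-intensity projection of the first 30
    frames (all frames for shorter movies).  Each frame is translated by
    the integer shift, within ``±max_shift`` pixels, that maximizes its
    cross-correlation with the reference.  Returns the aligned stack and
    the detected per-frame (dy, dx) shifts.
    """
    frames = stack.frames
    n_ref = min(n_reference_frames, stack.n_frames)
    reference = frames[:n_ref].max(axis=0)
    ref0 = reference - reference.mean()
    fref = np.conj(np.fft.rfft2(ref0))

    h, w = reference.shape
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    aligned = np.empty_like(frames)
    for t in range(stack.n_frames):
        fr = frames[t] - frames[t].mean()
        # circular cross-correlation; peak index = shift of frame vs reference
        corr = np.fft.irfft2(np.fft.rfft2(fr) * fref, s=(h, w))
        dyc = np.r_[np.arange(0, max_shift + 1), np.arange(-max_shift, 0)]
        window = corr[np.ix_(dyc % h, dyc % w)]
        iy, ix = np.unravel_index(np.argmax(window), window.shape)
        dy, dx = int(dyc[iy]), int(dyc[ix])
        shifts[t] = (dy, dx)
        aligned[t] = np.roll(frames[t], (-dy, -dx), axis=(0, 1))
    return ImageStack(aligned, stack.frame_rate), shifts


def extract_traces(
    stack: ImageStack,
    masks: RoiMask,
    fly_id: str = "fly0",
    cell_type: str = "custom",
) -> RoiTraceSet:
    """Mean ROI intensity per frame, background subtracted."""
    masks.validate_frame(stack.frames.shape[1:])
    flat = stack.frames.reshape(stack.n_frames, -1)
    bg = flat[:, masks.background.ravel()].mean(axis=1)
    traces = []
    for k, roi in enumerate(masks.rois):
        f = flat[:, roi.ravel()].mean(axis=1) - bg
        traces.append(
            RoiTrace(
                fly_id=fly_id,
                roi_id=f"roi{k}",
                cell_type=cell_type,
                time=stack.times,
                raw_f=f,
                sample_rate=stack.frame_rate,
            )
        )
    return RoiTraceSet(traces)


# ---------------------------------------------------------------------------
# dF/F and trial averaging
# ---------------------------------------------------------------------------


def compute_dff(
    trace: RoiTrace,
    f0_mode: str = "whole_trace_mean",
    window: tuple[float, float] | None = None,
) -> RoiTrace:
    """ΔF/F₀ with a selectable baseline definition.

    ``"whole_trace_mean"`` uses the mean of the entire raw trace as F₀;
    ``"adaptation_mean"`` uses the mean over a stated time ``window``
    (e.g. the 30 s adapting period of an A/B protocol).
    """
    if f0_mode == "whole_trace_mean":
        f0 = trace.raw_f.mean()
    elif f0_mode == "adaptation_mean":
        if window is None:
            raise ValueError("adaptation_mean requires a (t0, t1) window")
        sel = (trace.time >= window[0]) & (trace.time < window[1])
        if not sel.any():
            raise ValueError("adaptation window contains no samples")
        f0 = trace.raw_f[sel].mean()
    else:
        raise ValueError(f"unknown F0 mode {f0_mode!r}")
    if f0 == 0:
        raise ZeroDivisionError("degenerate baseline: F0 is zero")
    return replace(trace, dff=(trace.raw_f - f0) / f0)


def trial_average(
    trace: RoiTrace,
    protocol: StimulusProtocol,
    target_rate: float = 10.0,
) -> TrialAverage:
    """Interpolate the ΔF/F trace to 10 Hz on each epoch's aligned time base
    and average repetitions of the same epoch label."""
    values = trace.values
    epochs: dict[str, EpochAverage] = {}
    for label in protocol.epoch_labels():
        occ = protocol.occurrences(label)
        if not occ:
            raise ValueError(f"epoch {label!r} has no presentations")
        duration = occ[0].epoch.duration
        tau = np.arange(0.0, duration - 1e-9, 1.0 / target_rate)
        reps = np.stack(
            [np.interp(s.t_start + tau, trace.time, values) for s in occ]
        )
        epochs[label] = EpochAverage(label, tau, reps.mean(axis=0), len(occ))
    return TrialAverage(
        epochs, target_rate, trace.fly_id, trace.roi_id, trace.cell_type
    )


def filter_rois(
    traces: RoiTraceSet | Iterable[RoiTrace],
    protocol: StimulusProtocol,
    rf_azimuth: float | None = None,
) -> tuple[RoiTraceSet, pd.DataFrame]:
    """Keep only ROIs anti-correlated with the stimulus.

    An ROI is kept iff the Spearman rank correlation between its ΔF/F trace
    and the frame-wise stimulus luminance is strictly negative; opposite-
    polarity ("off-screen") and constant/undefined-correlation ROIs are
    rejected.  Returns the kept subset plus a per-ROI report.
    """
    kept = []
    rows = []
    for tr in traces:
        t = tr.time[tr.time < protocol.total_duration]
        lum = protocol.luminance_at_times(t, rf_azimuth=rf_azimuth)
        vals = tr.values[: len(t)]
        if np.ptp(vals) == 0 or np.ptp(lum) == 0:
            rho = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearmanr(vals, lum).statistic
        keep = bool(np.isfinite(rho) and rho < 0)
        rows.append(
            {
                "fly_id": tr.fly_id,
                "roi_id": tr.roi_id,
                "cell_type": tr.cell_type,
                "spearman_rho": rho,
                "kept": keep,
            }
        )
        if keep:
            kept.append(tr)
    return RoiTraceSet(kept), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response metrics
# ---------------------------------------------------------------------------


def staircase_step_response(
    avg: TrialAverage,
    protocol: StimulusProtocol,
    normalize: bool = False,
    baseline_window: float = 2.0,
) -> pd.DataFrame:
    """OFF-step responses of a staircase: per down-step, the maximum response
    within the step epoch minus the mean over the last 2 s of the preceding
    luminance epoch.  With ``normalize`` the trial-averaged traces are first
    min-max scaled to [0, 1] (for cross-cell-type comparison)."""
    if normalize:
        avg = avg.normalized()
    rows = []
    for prev_label, step_label, contrast in staircase_down_steps(protocol):
        base = avg.last_window(prev_label, baseline_window).mean()
        resp = avg[step_label].mean.max() - base
        rows.append(
            {
                "step": step_label,
                "weber_contrast": contrast,
                "contrast_magnitude": abs(contrast),
                "response": resp,
            }
        )
    return pd.DataFrame(rows)


def plateau_responses(
    avg: TrialAverage,
    protocol: StimulusProtocol,
    subtract_highest: bool = False,
    window: float = 2.0,
) -> pd.DataFrame:
    """Plateau response per luminance: mean ΔF/F of the last 2 s of each
    flash epoch; optionally referenced to the highest-luminance plateau
    (which then becomes 0 by construction)."""
    rows = []
    for label in protocol.epoch_labels(kinds=("flash", "step")):
        level = protocol.occurrences(label)[0].epoch.level
        rows.append(
            {"epoch": label, "luminance": level, "plateau": avg.last_window(label, window).mean()}
        )
    df = pd.DataFrame(rows)
    if subtract_highest:
        ref = df.loc[df["luminance"].idxmax(), "plateau"]
        df["plateau"] = df["plateau"] - ref
    return df


def ab_responses(
    avg: TrialAverage,
    protocol: StimulusProtocol,
    baseline_window: float = 2.0,
    sustained_window: float = 0.5,
) -> pd.DataFrame:
    """Peak and sustained responses of A/B contrast steps.

    Peak: maximum within each step minus the mean baseline over the last
    2 s of the adapting period.  Sustained: mean over the last 500 ms of
    each step.
    """
    if "adapt" not in avg.epochs:
        raise ValueError("protocol has no adapting epoch")
    base = avg.last_window("adapt", baseline_window).mean()
    i_adapt = protocol.occurrences("adapt")[0].epoch.level
    rows = []
    for label in protocol.epoch_labels(kinds=("step",)):
        if label == "adapt":
            continue
        level = protocol.occurrences(label)[0].epoch.level
        rows.append(
            {
                "epoch": label,
                "step_kind": label[0],
                "luminance": level,
                "weber_vs_adapt": (level - i_adapt) / i_adapt,
                "peak": avg[label].mean.max() - base,
                "sustained": avg.last_window(label, sustained_window).mean(),
            }
        )
    return pd.DataFrame(rows)


def edge_response(avg: TrialAverage, protocol: StimulusProtocol) -> pd.DataFrame:
    """Moving-edge response per epoch: absolute difference between the mean
    of the dark inter-stimulus epoch and the minimum during the edge epoch
    (minima, because these neurons hyperpolarize to ON stimuli)."""
    interval_labels = [
        lab
        for lab in protocol.epoch_labels(kinds=("interval",))
        if protocol.occurrences(lab)[0].epoch.level == 0
    ]
    if not interval_labels:
        raise ValueError("protocol has no dark inter-stimulus epoch")
    dark_mean = np.mean(
        np.concatenate([avg[lab].mean for lab in interval_labels])
    )
    rows = []
    for label in protocol.epoch_labels(kinds=("edge_motion",)):
        lum = protocol.occurrences(label)[0].epoch.luminances["edge"]
        rows.append(
            {
                "epoch": label,
                "edge_luminance": lum,
                "response": abs(dark_mean - avg[label].mean.min()),
            }
        )
    return pd.DataFrame(rows)


def response_table(
    traces: RoiTraceSet | Sequence[RoiTrace],
    protocol: StimulusProtocol,
    metric: str,
    **kwargs,
) -> pd.DataFrame:
    """Run one response metric over every ROI and stack the results.

    ``metric`` is one of ``"staircase_step"``, ``"plateau"``, ``"ab"``,
    ``"edge"``.  Traces without ΔF/F get the whole-trace-mean baseline.
    Output rows carry fly/ROI/cell-type provenance for hierarchical stats.
    """
    fns = {
        "staircase_step": staircase_step_response,
        "plateau": plateau_responses,
        "ab": ab_responses,
        "edge": edge_response,
    }
    if metric not in fns:
        raise ValueError(f"unknown metric {metric!r}")
    out = []
    for tr in traces:
        if tr.dff is None:
            tr = compute_dff(tr)
        avg = trial_average(tr, protocol)
        df = fns[metric](avg, protocol, **kwargs)
        df.insert(0, "cell_type", tr.cell_type)
        df.insert(0, "roi_id", tr.roi_id)
        df.insert(0, "fly_id", tr.fly_id)
        out.append(df)
    return pd.concat(out, ignore_index=True)
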