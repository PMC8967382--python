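"""Visual stimulus protocols for an LED-arena / projector rig.

This module is the single source of truth for stimulus timing, luminance
and contrast semantics used by the rest of the package.  A protocol is an
ordered presentation of :class:`Epoch` objects (full-field flashes,
luminance steps, static patterns and moving-edge epochs), tied to a
photometric :class:`Calibration` that converts between measured luminance
(cd/m^2) and photon incidence per photoreceptor per second.

Conventions
-----------
* Luminance values are photon fluxes (photons s^-1 photoreceptor^-1).
* Time is continuous seconds from protocol start; epoch intervals are
  half-open ``[t_start, t_end)``.
* LED-arena luminances live on a grid of ``n_led_levels`` linearly spaced
  intensity levels; requested fractions are snapped to the nearest level.
* Moving-edge epochs contain several traversals of the per-edge sector:
  after each traversal the pattern resets to the pre-motion level and the
  next traversal follows immediately, so the edges virtually move
  continuously for the whole motion window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ContrastUndefinedError",
    "Calibration",
    "Epoch",
    "ScheduledEpoch",
    "StimulusProtocol",
    "michelson_contrast",
    "weber_contrast",
    "cd_to_photons",
    "quantize_fraction",
    "build_edge_protocol",
    "build_staircase",
    "build_random_flashes",
    "build_ab_protocol",
    "staircase_down_steps",
    "rf_luminance",
]


class ContrastUndefinedError(ValueError):
    """Raised when a contrast value is mathematically undefined."""


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

#: Measured luminance of the brightest native LED level (cd/m^2).
_CD_NATIVE_MAX = 51.34
#: Photon flux corresponding to the brightest native LED level.
_PHOTONS_NATIVE_MAX = 11.77e5
#: Effective maximum photon flux behind the ND-0.9 filter foil.
_PHOTONS_ND_MAX = 14.71e4


@dataclass(frozen=True)
class Calibration:
    """Photometric calibration of a display.

    Parameters
    ----------
    cd_at_native_max
        Luminance (cd/m^2) measured at the brightest native intensity level.
    photons_at_native_max
        Photon flux (photons s^-1 photoreceptor^-1) at that same level.
    nd_attenuation
        Dimensionless transmission of any neutral-density filter in the
        light path, in ``(0, 1]``.  The default is the *measured*
        attenuation of the 0.9 ND foil (14.71e4 / 11.77e5 ~ 1/8.0) rather
        than the nominal ``10**-0.9``; use :meth:`led_arena` with
        ``nominal_nd=True`` for the nominal value.
    n_led_levels
        Number of linearly spaced intensity levels the display can show.
    """

    cd_at_native_max: float = _CD_NATIVE_MAX
    photons_at_native_max: float = _PHOTONS_NATIVE_MAX
    nd_attenuation: float = _PHOTONS_ND_MAX / _PHOTONS_NATIVE_MAX
    n_led_levels: int = 16

    def __post_init__(self) -> None:
        if self.cd_at_native_max <= 0 or self.photons_at_native_max <= 0:
            raise ValueError("calibration anchors must be positive")
        if not 0 < self.nd_attenuation <= 1:
            raise ValueError("nd_attenuation must be in (0, 1]")
        if self.n_led_levels < 2:
            raise ValueError("need at least two intensity levels")

    @property
    def i_max(self) -> float:
        """Effective maximum photon flux after ND attenuation."""
        return self.photons_at_native_max * self.nd_attenuation

    @classmethod
    def led_arena(cls, nominal_nd: bool = False) -> "Calibration":
        """Calibration of the 16-level LED arena used for behavior."""
        nd = 10.0 ** -0.9 if nominal_nd else _PHOTONS_ND_MAX / _PHOTONS_NATIVE_MAX
        return cls(nd_attenuation=nd)

    @classmethod
    def projector(cls, photons_at_max: float, n_levels: int = 256) -> "Calibration":
        """Calibration of a projector-based imaging screen.

        The projector presents an effectively continuous intensity range;
        ``photons_at_max`` is the measured maximum photon flux at the fly
        position (e.g. 2.17e5 for the full-field stimuli, 2.4e5 for the
        moving-edge stimuli).
        """
        return cls(
            cd_at_native_max=1.0,
            photons_at_native_max=photons_at_max,
            nd_attenuation=1.0,
            n_led_levels=n_levels,
        )


def michelson_contrast(i_edge: float, i_background: float) -> float:
    """Michelson contrast ``(I_edge - I_background) / (I_edge + I_background)``.

    Defined for non-negative luminances, bounded in ``[-1, 1]``.
    """
    i_edge = float(i_edge)
    i_background = float(i_background)
    if i_edge < 0 or i_background < 0:
        raise ValueError("luminances must be non-negative")
    total = i_edge + i_background
    if total == 0:
        raise ContrastUndefinedError("Michelson contrast undefined for two zero luminances")
    return (i_edge - i_background) / total


def weber_contrast(i_b: float, i_a: float) -> float:
    """Weber contrast ``(I_B - I_A) / I_A`` of a step from level A to level B."""
    i_a = float(i_a)
    i_b = float(i_b)
    if i_a <= 0:
        raise ContrastUndefinedError("Weber contrast undefined for zero reference luminance")
    return (i_b - i_a) / i_a


def cd_to_photons(cd: float, cal: Calibration, attenuated: bool = True) -> float:
    """Convert measured luminance (cd/m^2) to photon flux.

    Linear scale anchored at the calibration's measured
    (cd, photons) pair; when ``attenuated`` the ND-filter transmission is
    applied on top.
    """
    cd = float(cd)
    if cd < 0:
        raise ValueError("luminance must be non-negative")
    photons = cd * cal.photons_at_native_max / cal.cd_at_native_max
    if attenuated:
        photons *= cal.nd_attenuation
    return photons


def quantize_fraction(fraction: float, n_levels: int) -> float:
    """Snap a requested intensity fraction onto the ``n_levels`` grid.

    The grid is ``k / (n_levels - 1)`` for integer ``k``; the largest
    quantization error is half a level.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"intensity fraction {fraction} outside [0, 1]")
    steps = n_levels - 1
    return round(fraction * steps) / steps


# ---------------------------------------------------------------------------
# epochs & protocols
# ---------------------------------------------------------------------------

_EPOCH_KINDS = ("static", "edge_motion", "flash", "step", "interval")


@dataclass(frozen=True)
class Epoch:
    """One presentable stimulus segment.

    ``luminances`` is a small named mapping: ``{"level": I}`` for uniform
    epochs (flash/step/interval), ``{"edge": I_e, "background": I_b}`` for
    static patterns and moving edges.  ``direction`` is +1 (rightward),
    -1 (leftward) or 0 (no motion).
    """

    label: str
    kind: str
    duration: float
    luminances: dict = field(default_factory=dict)
    direction: int = 0
    speed: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        for name, lum in self.luminances.items():
            if lum < 0:
                raise ValueError(f"luminance {name!r} is negative")
        if self.kind == "edge_motion":
            if self.direction not in (-1, 1):
                raise ValueError("edge_motion epochs need direction +1 or -1")
            if not self.speed or self.speed <= 0:
                raise ValueError("edge_motion epochs need a positive speed")

    @property
    def level(self) -> float:
        """Uniform luminance of a non-patterned epoch."""
        return self.luminances["level"]


@dataclass(frozen=True)
class ScheduledEpoch:
    """An epoch placed on the protocol time axis; interval ``[t_start, t_end)``."""

    epoch: Epoch
    t_start: float
    t_end: float


@dataclass
class StimulusProtocol:
    """Ordered stimulus presentation with calibration and arena geometry.

    ``presentation_order`` is the complete flat sequence of epoch indices
    actually shown, including static pre-motion patterns, inter-trial
    intervals, adapting backgrounds etc., so the protocol duration is the
    plain sum of presented epoch durations.
    """

    name: str
    epochs: list[Epoch]
    presentation_order: list[int]
    calibration: Calibration
    arena_span: float = 192.0
    n_edges: int = 4
    n_trials: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.epochs)
        if any(not 0 <= i < n for i in self.presentation_order):
            raise ValueError("presentation_order indexes nonexistent epochs")
        counts: dict[tuple, int] = {}
        for i in self.presentation_order:
            ep = self.epochs[i]
            if ep.kind == "edge_motion":
                counts[(ep.label, ep.direction)] = counts.get((ep.label, ep.direction), 0) + 1
        labels = {lab for lab, _ in counts}
        for lab in labels:
            if counts.get((lab, 1), 0) != counts.get((lab, -1), 0):
                # one-sided motion protocols (e.g. imaging) are permitted,
                # but a mirrored protocol must be balanced
                if counts.get((lab, 1), 0) and counts.get((lab, -1), 0):
                    raise ValueError(f"unbalanced mirrored presentation for epoch {lab!r}")

    # -- timing -------------------------------------------------------------

    @property
    def total_duration(self) -> float:
        return float(sum(self.epochs[i].duration for i in self.presentation_order))

    def schedule(self) -> list[ScheduledEpoch]:
        """Epochs on the global time axis, in presentation order."""
        out = []
        t = 0.0
        for i in self.presentation_order:
            ep = self.epochs[i]
            out.append(ScheduledEpoch(ep, t, t + ep.duration))
            t += ep.duration
        return out

    def occurrences(self, label: str) -> list[ScheduledEpoch]:
        return [s for s in self.schedule() if s.epoch.label == label]

    def epoch_labels(self, kinds: Iterable[str] | None = None) -> list[str]:
        """Distinct epoch labels in first-presentation order."""
        seen: list[str] = []
        for s in self.schedule():
            if kinds is not None and s.epoch.kind not in kinds:
                continue
            if s.epoch.label not in seen:
                seen.append(s.epoch.label)
        return seen

    # -- luminance ----------------------------------------------------------

    def luminance_at(self, t: float, rf_azimuth: float | None = None) -> float:
        """Luminance seen by a point receptive field at global time ``t``."""
        for s in self.schedule():
            if s.t_start <= t < s.t_end:
                return float(_epoch_luminance(s.epoch, t - s.t_start, self, rf_azimuth))
        raise ValueError(f"time {t} outside protocol [0, {self.total_duration})")

    def luminance_at_times(
        self, times: np.ndarray, rf_azimuth: float | None = None
    ) -> np.ndarray:
        """Vectorized :meth:`luminance_at` over an array of times."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, np.nan)
        for s in self.schedule():
            m = (times >= s.t_start) & (times < s.t_end)
            if m.any():
                out[m] = _epoch_luminance(s.epoch, times[m] - s.t_start, self, rf_azimuth)
        if np.isnan(out).any():
            raise ValueError("some times fall outside the protocol")
        return out

    def luminance_series(
        self, sample_rate: float, rf_azimuth: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Sampled luminance time series ``(t, I)`` over the whole protocol."""
        t = np.arange(0.0, self.total_duration, 1.0 / sample_rate)
        t = t[t < self.total_duration]
        return t, self.luminance_at_times(t, rf_azimuth=rf_azimuth)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "epochs": [asdict(e) for e in self.epochs],
            "presentation_order": list(map(int, self.presentation_order)),
            "calibration": asdict(self.calibration),
            "arena_span": self.arena_span,
            "n_edges": self.n_edges,
            "n_trials": self.n_trials,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        d = json.loads(text)
        return cls(
            name=d["name"],
            epochs=[Epoch(**e) for e in d["epochs"]],
            presentation_order=d["presentation_order"],
            calibration=Calibration(**d["calibration"]),
            arena_span=d["arena_span"],
            n_edges=d["n_edges"],
            n_trials=d["n_trials"],
            seed=d["seed"],
        )


def _epoch_luminance(epoch, tau, protocol, rf_azimuth):
    """Luminance of one epoch at epoch-local time(s) ``tau`` for a point RF."""
    tau = np.asarray(tau, dtype=float)
    if epoch.kind in ("flash", "step", "interval"):
        return np.broadcast_to(epoch.level, tau.shape).copy()
    if epoch.kind == "static":
        # first frame of the upcoming pattern: background everywhere except
        # the zero-width starting edge
        return np.broadcast_to(epoch.luminances["background"], tau.shape).copy()
    # edge motion with within-epoch resets
    if rf_azimuth is None:
        rf_azimuth = protocol.arena_span / (2 * protocol.n_edges)
    if not 0 <= rf_azimuth <= protocol.arena_span:
        raise ValueError("receptive-field azimuth outside arena span")
    sector = protocol.arena_span / protocol.n_edges
    traversal = sector / epoch.speed
    tau_in = tau % traversal
    d = rf_azimuth % sector
    crossing = d / epoch.speed if epoch.direction > 0 else (sector - d) / epoch.speed
    return np.where(
        tau_in >= crossing, epoch.luminances["edge"], epoch.luminances["background"]
    )


def rf_luminance(
    protocol: StimulusProtocol, rf_azimuth: float, sample_rate: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Local luminance time series seen by one receptive field.

    For uniform epochs this is simply the presented level; for moving-edge
    epochs the luminance switches from background to edge when the nearest
    edge crosses ``rf_azimuth`` (crossing time = angular distance / speed,
    respecting within-epoch pattern resets).
    """
    if not 0 <= rf_azimuth <= protocol.arena_span:
        raise ValueError("receptive-field azimuth outside arena span")
    return protocol.luminance_series(sample_rate, rf_azimuth=rf_azimuth)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

#: Level fractions (of the 16-level grid) of the five 100%-contrast edges.
ON_EDGE_FRACTIONS = (1 / 15, 2 / 15, 4 / 15, 8 / 15, 1.0)
#: Background fractions of the mixed-contrast edge set (edge held at 10/15).
MIXED_BG_FRACTIONS = (8 / 15, 6 / 15, 5 / 15, 4 / 15, 2 / 15, 1 / 15, 0.0)
MIXED_EDGE_FRACTION = 10 / 15


def _interleave_mirrored(
    rng: np.random.Generator, condition_indices: Sequence[tuple[int, ...]], n_trials: int
) -> list[tuple[int, ...]]:
    """Randomized trial list with each condition n_trials times, direction-balanced.

    ``condition_indices`` holds, per condition, the epoch-index tuples of the
    two mirrored variants (or a single tuple when not mirrored).
    """
    trials: list[tuple[int, ...]] = []
    for variants in condition_indices:
        if len(variants) == 2:
            if n_trials % 2:
                raise ValueError("mirrored presentation needs an even n_trials")
            trials += [variants[0]] * (n_trials // 2) + [variants[1]] * (n_trials // 2)
        else:
            trials += [variants[0]] * n_trials
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def build_edge_protocol(
    kind: str = "ON",
    cal: Calibration | None = None,
    level_fractions: Sequence[float] | None = None,
    edge_fraction: float | None = None,
    n_trials: int = 2,
    seed: int = 0,
    static_duration: float = 0.5,
    motion_duration: float = 0.75,
    iti_duration: float = 1.0,
    speed: float = 160.0,
    n_edges: int = 4,
    arena_span: float = 192.0,
    mirrored: bool = True,
    quantize: bool = True,
    luminances: Sequence[float] | None = None,
) -> StimulusProtocol:
    """Build a moving-edge protocol.

    Three stimulus sets are supported:

    ``"ON"``
        Bright edges of several luminances moving on a dark background
        (100% Michelson contrast each); dark inter-trial interval.
    ``"OFF"``
        A dark edge moving over several uniformly lit backgrounds
        (-100% Weber contrast); dark inter-trial interval.
    ``"mixed_contrast"``
        Edge luminance fixed, background varied, yielding a range of
        Michelson contrasts; the inter-trial screen is lit at the edge
        luminance.

    Each trial is static pattern (0.5 s) -> edge motion (0.75 s) -> inter-
    trial interval (1 s).  Edges cover ``arena_span / n_edges`` degrees
    each and the pattern resets after every sector traversal so motion
    fills the whole window.  Conditions are randomly interleaved and, when
    ``mirrored``, presented equally often in both directions.
    """
    cal = cal or Calibration.led_arena()
    rng = np.random.default_rng(seed)

    def lum(frac: float) -> float:
        if quantize:
            frac = quantize_fraction(frac, cal.n_led_levels)
        elif not 0 <= frac <= 1:
            raise ValueError(f"intensity fraction {frac} outside [0, 1]")
        return frac * cal.i_max

    if luminances is not None:
        pairs = [(float(l), 0.0) for l in luminances]  # (edge, background)
        labels = [f"ON_{l:.3g}" for l, _ in pairs]
        iti_level = 0.0
    elif kind == "ON":
        fr = level_fractions if level_fractions is not None else ON_EDGE_FRACTIONS
        pairs = [(lum(f), 0.0) for f in fr]
        labels = [f"ON_{e:.4g}" for e, _ in pairs]
        iti_level = 0.0
    elif kind == "OFF":
        fr = level_fractions if level_fractions is not None else ON_EDGE_FRACTIONS
        pairs = [(0.0, lum(f)) for f in fr]
        labels = [f"OFF_bg{b:.4g}" for _, b in pairs]
        iti_level = 0.0
    elif kind == "mixed_contrast":
        e_frac = edge_fraction if edge_fraction is not None else MIXED_EDGE_FRACTION
        fr = level_fractions if level_fractions is not None else MIXED_BG_FRACTIONS
        e_lum = lum(e_frac)
        pairs = [(e_lum, lum(f)) for f in fr]
        labels = [
            f"C{100 * michelson_contrast(e, b):.0f}" for e, b in pairs
        ]
        iti_level = e_lum
    else:
        raise ValueError(f"unknown edge-set kind {kind!r}")

    epochs: list[Epoch] = []
    condition_indices: list[tuple[int, ...]] = []
    iti = Epoch("iti", "interval", iti_duration, {"level": iti_level})
    for (edge, bg), label in zip(pairs, labels):
        lums = {"edge": edge, "background": bg}
        static = Epoch(f"{label}/static", "static", static_duration, lums)
        epochs.append(static)
        i_static = len(epochs) - 1
        variants = []
        directions = (1, -1) if mirrored else (1,)
        for direction in directions:
            epochs.append(
                Epoch(label, "edge_motion", motion_duration, lums, direction, speed)
            )
            variants.append(len(epochs) - 1)
        condition_indices.append(tuple(variants))
        # remember static index alongside: encode trial as (static, motion, iti)
        condition_indices[-1] = tuple((i_static, v) for v in variants)
    epochs.append(iti)
    i_iti = len(epochs) - 1

    trial_list = _interleave_mirrored(rng, condition_indices, n_trials)
    order: list[int] = []
    for i_static, i_motion in trial_list:
        order += [i_static, i_motion, i_iti]

    return StimulusProtocol(
        name=f"edges_{kind}",
        epochs=epochs,
        presentation_order=order,
        calibration=cal,
        arena_span=arena_span,
        n_edges=n_edges,
        n_trials=n_trials,
        seed=seed,
    )


STAIRCASE_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


def build_staircase(
    cal: Calibration | None = None,
    level_fractions: Sequence[float] = STAIRCASE_FRACTIONS,
    step_duration: float = 10.0,
    n_repeats: int = 3,
) -> StimulusProtocol:
    """Full-field luminance staircase: darkness up to I_max, then back down.

    One cycle presents the levels in increasing order and then, excluding
    the top level, in decreasing order (9 epochs for the default five
    levels); the cycle repeats ``n_repeats`` times.  Epochs are labelled by
    cycle position so each one has a well-defined predecessor.
    """
    cal = cal or Calibration.projector(2.17e5)
    fr = list(level_fractions)
    if fr != sorted(fr):
        raise ValueError("staircase levels must be sorted ascending")
    cycle_fracs = fr + fr[-2::-1]
    epochs = [
        Epoch(f"stair{i:02d}", "flash", step_duration, {"level": f * cal.i_max})
        for i, f in enumerate(cycle_fracs)
    ]
    order = list(range(len(epochs))) * n_repeats
    return StimulusProtocol(
        name="staircase",
        epochs=epochs,
        presentation_order=order,
        calibration=cal,
        n_trials=n_repeats,
    )


def staircase_down_steps(
    protocol: StimulusProtocol, convention: str = "weber"
) -> list[tuple[str, str, float]]:
    """(previous label, step label, contrast) for each down-step of a staircase.

    ``convention`` selects the contrast axis: Weber contrast of the step
    relative to the preceding level (default) or Michelson contrast of the
    two levels.
    """
    n = len(protocol.epochs)
    half = n // 2  # index of the brightest epoch
    out = []
    for i in range(half, n - 1):
        prev, step = protocol.epochs[i], protocol.epochs[i + 1]
        if convention == "weber":
            c = weber_contrast(step.level, prev.level)
        elif convention == "michelson":
            c = michelson_contrast(step.level, prev.level)
        else:
            raise ValueError(f"unknown contrast convention {convention!r}")
        out.append((prev.label, step.label, c))
    return out


def build_random_flashes(
    cal: Calibration | None = None,
    level_fractions: Sequence[float] = STAIRCASE_FRACTIONS,
    flash_duration: float = 10.0,
    total_duration: float = 300.0,
    seed: int = 0,
) -> StimulusProtocol:
    """Pseudo-randomized full-field flashes of several luminances.

    The sequence is built from seeded shuffles of complete level blocks, so
    levels occur near-uniformly and every level appears at least once
    whenever the protocol is long enough to hold one full block.
    """
    cal = cal or Calibration.projector(2.17e5)
    if total_duration < flash_duration:
        raise ValueError("total_duration must cover at least one flash")
    rng = np.random.default_rng(seed)
    epochs = [
        Epoch(f"flash{f:g}", "flash", flash_duration, {"level": f * cal.i_max})
        for f in level_fractions
    ]
    n_flashes = int(total_duration // flash_duration)
    order: list[int] = []
    while len(order) < n_flashes:
        order += [int(i) for i in rng.permutation(len(epochs))]
    order = order[:n_flashes]
    return StimulusProtocol(
        name="random_flashes",
        epochs=epochs,
        presentation_order=order,
        calibration=cal,
        seed=seed,
    )


AB_A_FRACTIONS = (0.8, 0.65, 0.5, 0.4, 0.3, 0.2, 0.1)


def build_ab_protocol(
    cal: Calibration | None = None,
    adapt_duration: float = 30.0,
    a_fractions: Sequence[float] = AB_A_FRACTIONS,
    b_weber: float = -0.25,
    step_duration: float = 3.0,
    seed: int = 0,
) -> StimulusProtocol:
    """Adapting background followed by two consecutive OFF steps (A then B).

    Each trial: 30 s bright adapting background, a 3 s A step to one of
    several decreasing luminances (varying Weber contrast relative to the
    adapting level), then a 3 s B step at ``I_B = I_A * (1 + b_weber)`` so
    every B step carries the same Weber contrast.  A/B pairs are presented
    in seeded random order.
    """
    cal = cal or Calibration.projector(2.17e5)
    rng = np.random.default_rng(seed)
    i_adapt = cal.i_max
    epochs = [Epoch("adapt", "step", adapt_duration, {"level": i_adapt})]
    pair_indices: list[tuple[int, int]] = []
    for j, f in enumerate(a_fractions):
        if not 0 <= f < 1:
            raise ValueError("A levels must lie strictly below the adapting luminance")
        i_a = f * cal.i_max
        if i_a == 0 and b_weber != 0:
            raise ContrastUndefinedError("B level undefined for a zero-luminance A step")
        i_b = i_a * (1.0 + b_weber)
        epochs.append(Epoch(f"A{j}", "step", step_duration, {"level": i_a}))
        epochs.append(Epoch(f"B{j}", "step", step_duration, {"level": i_b}))
        pair_indices.append((len(epochs) - 2, len(epochs) - 1))

    order: list[int] = []
    for j in rng.permutation(len(pair_indices)):
        ia, ib = pair_indices[j]
        order += [0, ia, ib]
    return StimulusProtocol(
        name="ab_steps",
        epochs=epochs,
        presentation_order=order,
        calibration=cal,
        seed=seed,
    )
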