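"""Discretization of MVCT delivery into beam plans.

Helical MVCT irradiation (continuous gantry rotation + couch travel) is
approximated as a sum of discrete 400 x 4 mm^2 beams placed at equally
spaced isocenters along the rotation axis, with gantry angles stepping
by 360/beams_per_rotation degrees (default eight beams per rotation, i.e.
45-degree intervals).  The unit's dose is prescribed in irradiation time;
plans convert it to monitor units via the model convention 40 MU per
60 s, so e.g. a 4.8-cm scan at normal pitch (0.8 cm couch travel per
10-s rotation) takes 60 s and 40 MU shared equally over 48 beams.

A static plan keeps the gantry fixed while the couch moves; it is used
for output calibration and beam-model adjustment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "PitchSetting",
    "PITCH_SETTINGS",
    "BeamInstance",
    "ScanPlan",
    "irradiation_time",
    "time_to_mu",
    "build_helical_plan",
    "build_static_plan",
    "save_plan_json",
    "load_plan_json",
    "plan_from_config",
]

DEFAULT_MU_PER_MINUTE = 40.0


@dataclass(frozen=True)
class PitchSetting:
    """Scan-pitch option of the tomotherapy unit.

    ``couch_travel_per_rotation`` (cm) with a 10-s gantry period sets the
    couch speed; ``isocenter_interval`` is the longitudinal spacing of the
    discretized beam isocenters (couch travel / 8 beams per rotation).
    """

    name: str
    couch_travel_per_rotation: float
    isocenter_interval: float
    period_per_rotation: float = 10.0

    def __post_init__(self) -> None:
        if self.period_per_rotation <= 0:
            raise ValueError("period_per_rotation must be > 0")
        if self.couch_travel_per_rotation <= 0 or self.isocenter_interval <= 0:
            raise ValueError("pitch distances must be > 0")

    @property
    def couch_speed(self) -> float:
        """cm/s."""
        return self.couch_travel_per_rotation / self.period_per_rotation


PITCH_SETTINGS: dict[str, PitchSetting] = {
    "fine": PitchSetting("fine", 0.4, 0.05),
    "normal": PitchSetting("normal", 0.8, 0.10),
    "coarse": PitchSetting("coarse", 1.2, 0.15),
}


@dataclass(frozen=True)
class BeamInstance:
    """One discrete 400 x 4 mm^2 beam: isocenter on the rotation axis,
    gantry angle (degrees, 0 = beam entering from above, normalized to
    [0, 360)) and monitor units."""

    isocenter: np.ndarray
    gantry_angle: float
    mu: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "isocenter", np.asarray(self.isocenter, dtype=float).reshape(3))
        object.__setattr__(self, "gantry_angle", float(self.gantry_angle) % 360.0)
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass(frozen=True)
class ScanPlan:
    mode: str  # "helical" | "static"
    beams: tuple[BeamInstance, ...]
    scan_length: float
    total_time: float
    total_mu: float
    pitch: PitchSetting | None = None
    couch_speed: float | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "beams", tuple(self.beams))
        if self.mode not in ("helical", "static"):
            raise ValueError("mode must be 'helical' or 'static'")
        if abs(sum(b.mu for b in self.beams) - self.total_mu) > 1e-9 * max(1.0, self.total_mu):
            raise ValueError("total_mu must equal the sum of beam MUs")

    @property
    def n_beams(self) -> int:
        return len(self.beams)


def irradiation_time(scan_length: float, pitch: PitchSetting) -> float:
    """Beam-on time (s) = scan_length / couch-travel-per-rotation * period."""
    if scan_length < 0:
        raise ValueError("scan_length must be >= 0")
    return scan_length / pitch.couch_travel_per_rotation * pitch.period_per_rotation


def time_to_mu(time_s: float, mu_per_minute: float = DEFAULT_MU_PER_MINUTE) -> float:
    """Convert irradiation time to monitor units (40 MU per 60 s by default)."""
    if time_s < 0:
        raise ValueError("time must be >= 0")
    return mu_per_minute * time_s / 60.0


def _isocenter_positions(scan_start: float, scan_length: float, interval: float) -> np.ndarray:
    n_exact = scan_length / interval
    n = int(round(n_exact))
    if n < 1:
        raise ValueError("scan_length smaller than one isocenter interval: degenerate plan")
    if abs(n_exact - n) > 1e-6:
        warnings.warn(
            f"scan length {scan_length} cm is not a multiple of the isocenter "
            f"interval {interval} cm; using n = {n} beams",
            stacklevel=3,
        )
    # cell-centered placement: first isocenter at scan_start + interval/2
    return scan_start + (np.arange(n) + 0.5) * interval


def build_helical_plan(
    scan_start: float,
    scan_length: float,
    pitch: PitchSetting | str,
    beams_per_rotation: int = 8,
    axis_xz: tuple[float, float] = (0.0, 0.0),
    start_angle: float = 0.0,
    rotation_sign: int = 1,
    mu_per_minute: float = DEFAULT_MU_PER_MINUTE,
) -> ScanPlan:
    """Discretize a helical scan into equally weighted beams.

    ``n = round(scan_length / isocenter_interval)`` beams are placed
    cell-centered on the rotation axis starting at ``scan_start`` (IEC-Y,
    cm), with gantry angles stepping by ``360 / beams_per_rotation``
    degrees from ``start_angle``; total MU (from the scan time) is shared
    equally.  ``rotation_sign`` selects the rotation sense (+1/-1).
    """
    if isinstance(pitch, str):
        pitch = PITCH_SETTINGS[pitch]
    if scan_length <= 0:
        raise ValueError("scan_length must be > 0")
    if beams_per_rotation < 1:
        raise ValueError("beams_per_rotation must be >= 1")
    if rotation_sign not in (1, -1):
        raise ValueError("rotation_sign must be +1 or -1")
    interval = pitch.couch_travel_per_rotation / beams_per_rotation
    y_positions = _isocenter_positions(scan_start, scan_length, interval)
    n = y_positions.size
    total_time = irradiation_time(scan_length, pitch)
    total_mu = time_to_mu(total_time, mu_per_minute)
    mu_each = total_mu / n
    step = 360.0 / beams_per_rotation
    beams = tuple(
        BeamInstance(
            isocenter=(axis_xz[0], y, axis_xz[1]),
            gantry_angle=(start_angle + rotation_sign * i * step) % 360.0,
            mu=mu_each,
        )
        for i, y in enumerate(y_positions)
    )
    return ScanPlan(
        mode="helical",
        beams=beams,
        scan_length=scan_length,
        total_time=total_time,
        total_mu=mu_each * n,
        pitch=pitch,
        settings={
            "scan_start": scan_start,
            "beams_per_rotation": beams_per_rotation,
            "start_angle": start_angle,
            "rotation_sign": rotation_sign,
            "mu_per_minute": mu_per_minute,
        },
    )


def build_static_plan(
    scan_start: float,
    scan_length: float,
    couch_speed: float,
    gantry_angle: float = 0.0,
    isocenter_interval: float = 0.2,
    axis_xz: tuple[float, float] = (0.0, 0.0),
    mu_per_minute: float = DEFAULT_MU_PER_MINUTE,
) -> ScanPlan:
    """Fixed-gantry scan: the couch moves at ``couch_speed`` (cm/s) while
    the gantry holds ``gantry_angle``.

    The reference calibration scan is 6 cm at 0.1 cm/s with 0.2-cm
    intervals: 30 beams of 2 s each, 40 MU total.
    """
    if couch_speed <= 0:
        raise ValueError("couch_speed must be > 0")
    if isocenter_interval <= 0:
        raise ValueError("isocenter_interval must be > 0")
    if scan_length <= 0:
        raise ValueError("scan_length must be > 0")
    y_positions = _isocenter_positions(scan_start, scan_length, isocenter_interval)
    per_beam_time = isocenter_interval / couch_speed
    mu_each = time_to_mu(per_beam_time, mu_per_minute)
    beams = tuple(
        BeamInstance(isocenter=(axis_xz[0], y, axis_xz[1]), gantry_angle=gantry_angle, mu=mu_each)
        for y in y_positions
    )
    return ScanPlan(
        mode="static",
        beams=beams,
        scan_length=scan_length,
        total_time=scan_length / couch_speed,
        total_mu=mu_each * y_positions.size,
        couch_speed=couch_speed,
        settings={
            "scan_start": scan_start,
            "gantry_angle": gantry_angle,
            "isocenter_interval": isocenter_interval,
            "mu_per_minute": mu_per_minute,
        },
    )


# -- serialization / config -------------------------------------------------

def save_plan_json(plan: ScanPlan, path) -> None:
    doc = {
        "mode": plan.mode,
        "scan_length": plan.scan_length,
        "total_time": plan.total_time,
        "total_mu": plan.total_mu,
        "pitch": plan.pitch.name if plan.pitch else None,
        "couch_speed": plan.couch_speed,
        "settings": plan.settings,
        "beams": [
            {"isocenter": b.isocenter.tolist(), "gantry_angle": b.gantry_angle, "mu": b.mu}
            for b in plan.beams
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_plan_json(path) -> ScanPlan:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    beams = tuple(
        BeamInstance(b["isocenter"], b["gantry_angle"], b["mu"]) for b in doc["beams"]
    )
    return ScanPlan(
        mode=doc["mode"],
        beams=beams,
        scan_length=doc["scan_length"],
        total_time=doc["total_time"],
        total_mu=doc["total_mu"],
        pitch=PITCH_SETTINGS.get(doc["pitch"]) if doc.get("pitch") else None,
        couch_speed=doc.get("couch_speed"),
        settings=doc.get("settings", {}),
    )


def plan_from_config(path) -> ScanPlan:
    """Build a plan from a YAML config.

    Keys: ``mode`` (helical|static), ``scan_start_cm``, ``scan_length_cm``,
    ``pitch`` (fine|normal|coarse, helical), ``couch_speed_cm_s`` (static),
    optional ``beams_per_rotation``, ``gantry_angle``, ``isocenter_interval_cm``,
    ``start_angle``, ``rotation_sign``.
    """
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    mode = cfg["mode"]
    if mode == "helical":
        return build_helical_plan(
            scan_start=float(cfg["scan_start_cm"]),
            scan_length=float(cfg["scan_length_cm"]),
            pitch=cfg["pitch"],
            beams_per_rotation=int(cfg.get("beams_per_rotation", 8)),
            start_angle=float(cfg.get("start_angle", 0.0)),
            rotation_sign=int(cfg.get("rotation_sign", 1)),
        )
    if mode == "static":
        return build_static_plan(
            scan_start=float(cfg["scan_start_cm"]),
            scan_length=float(cfg["scan_length_cm"]),
            couch_speed=float(cfg["couch_speed_cm_s"]),
            gantry_angle=float(cfg.get("gantry_angle", 0.0)),
            isocenter_interval=float(cfg.get("isocenter_interval_cm", 0.2)),
        )
    raise ValueError(f"unknown plan mode {mode!r}")
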