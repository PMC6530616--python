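"""Commissioned MVCT beam representation.

The imaging beam of a helical tomotherapy unit is a single 400 x 4 mm^2
fan beam (nominal 3.5 MV) delivered with all MLC leaves open.  Its
dosimetric behaviour is captured by three one-dimensional commissioning
curves:

* ``pdd``   -- percentage depth dose along the central axis,
* ``ocr_x`` -- off-center ratio across the 40-cm field width (IEC-X),
* ``ocr_y`` -- off-center ratio along the 0.4-cm field length (IEC-Y),

together with the machine geometry (SAD 85 cm), an absolute output
calibration factor (cGy per monitor unit at the reference condition) and
the time-to-MU convention of the unit (40 MU per minute of beam-on time).

Curves can be loaded from two-column CSV files of film measurements, or
generated analytically with :func:`synthesize_beam_model` so the package
is fully testable without machine data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

__all__ = [
    "ProfileCurve",
    "MVCTBeamModel",
    "load_profile_csv",
    "normalize_curve",
    "eval_pdd",
    "eval_ocr",
    "synthesize_beam_model",
    "within_tolerance",
    "save_beam_model",
    "load_beam_model",
]

AXIS_LABELS = ("depth", "x_offaxis", "y_offaxis")


@dataclass(frozen=True)
class ProfileCurve:
    """A sampled relative-dose curve over one spatial coordinate.

    Parameters
    ----------
    positions : array-like
        Strictly increasing coordinate values in cm (depth or off-axis
        distance).  At least two nodes.
    values : array-like
        Non-negative relative dose at each node (dimensionless).
    axis_label : {"depth", "x_offaxis", "y_offaxis"}
    """

    positions: np.ndarray
    values: np.ndarray
    axis_label: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)
        if self.axis_label not in AXIS_LABELS:
            raise ValueError(f"axis_label must be one of {AXIS_LABELS}, got {self.axis_label!r}")
        if pos.ndim != 1 or val.shape != pos.shape:
            raise ValueError("positions and values must be 1-D arrays of equal length")
        if pos.size < 2:
            raise ValueError("a profile curve needs at least 2 nodes")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(val)):
            raise ValueError("profile curve nodes must be finite")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(val < 0):
            raise ValueError("profile values must be >= 0")

    def __call__(self, x) -> np.ndarray | float:
        """Piecewise-linear interpolation with clamped extrapolation.

        Queries beyond the first/last node return the terminal node value
        (never extrapolated below zero); node queries reproduce node
        values exactly.
        """
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("curve evaluated at non-finite position")
        out = np.interp(x, self.positions, self.values)
        return float(out) if out.ndim == 0 else out

    @property
    def span(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])


@dataclass(frozen=True)
class MVCTBeamModel:
    """Beam data for the single 400 x 4 mm^2 MVCT field.

    ``output_cal`` is the dose per monitor unit at the reference
    condition (1.5 cm depth on the central axis at the isocenter plane);
    the sentinel value 1.0 denotes an uncalibrated model.
    ``mu_per_minute`` converts tomotherapy irradiation time into TPS
    monitor units (60 s of beam-on time corresponds to 40 MU).
    """

    pdd: ProfileCurve
    ocr_x: ProfileCurve
    ocr_y: ProfileCurve
    sad: float = 85.0
    field_x: float = 40.0
    field_y: float = 0.4
    profile_depth: float = 1.5
    reference_depth: float = 1.5
    output_cal: float = 1.0
    mu_per_minute: float = 40.0

    def __post_init__(self) -> None:
        for name in ("sad", "field_x", "field_y", "output_cal", "mu_per_minute"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pdd.axis_label != "depth":
            raise ValueError("pdd curve must have axis_label 'depth'")
        lo, hi = self.pdd.span
        if lo > 0.0 or hi < 30.0:
            raise ValueError("pdd must cover at least [0, 30] cm depth")
        xlo, xhi = self.ocr_x.span
        if xlo > -25.0 or xhi < 25.0:
            raise ValueError("ocr_x must cover at least [-25, 25] cm")

    @property
    def calibrated(self) -> bool:
        return self.output_cal != 1.0

    def with_output_cal(self, output_cal: float) -> "MVCTBeamModel":
        return replace(self, output_cal=float(output_cal))


def load_profile_csv(path, axis_label: str) -> ProfileCurve:
    """Read a two-column profile CSV (position_cm, value).

    A header row is optional; lines starting with ``#`` are comments.
    Rows are sorted by position and duplicate positions are collapsed by
    averaging their values.  Normalization is *not* applied here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"profile CSV not found: {path}")
    positions: list[float] = []
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            if len(cells) < 2:
                raise ValueError(f"{path}: row {lineno}: expected two columns, got {line!r}")
            try:
                p, v = float(cells[0]), float(cells[1])
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise ValueError(
                    f"{path}: row {lineno}: non-numeric cell in {line!r}"
                ) from None
            positions.append(p)
            values.append(v)
    if len(positions) < 2:
        raise ValueError(f"{path}: fewer than 2 valid data rows")
    pos = np.asarray(positions)
    val = np.asarray(values)
    order = np.argsort(pos, kind="stable")
    pos, val = pos[order], val[order]
    uniq, inverse = np.unique(pos, return_inverse=True)
    if uniq.size != pos.size:  # average duplicate positions
        val = np.bincount(inverse, weights=val) / np.bincount(inverse)
        pos = uniq
    return ProfileCurve(pos, val, axis_label)


def normalize_curve(curve: ProfileCurve, mode: str) -> ProfileCurve:
    """Normalize a curve so its maximum (``mode='max'``) or its value at
    position 0 (``mode='central'``) equals 1.0 exactly."""
    if mode == "max":
        ref = float(np.max(curve.values))
    elif mode == "central":
        lo, hi = curve.span
        if lo > 0.0 or hi < 0.0:
            raise ValueError("central normalization requires position 0 within the curve range")
        ref = float(curve(0.0))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref == 0.0:
        raise ValueError("cannot normalize a curve whose reference value is 0")
    return ProfileCurve(curve.positions, curve.values / ref, curve.axis_label)


def eval_pdd(model: MVCTBeamModel, depth) -> np.ndarray | float:
    """Relative dose of the depth-dose curve at ``depth`` (cm, >= 0)."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0")
    return model.pdd(d)


def eval_ocr(model: MVCTBeamModel, x_off, y_off) -> np.ndarray | float:
    """Off-center ratio at isocenter-plane offsets (cm): OCR_x(x) * OCR_y(y).

    The two profiles are measured independently and treated as separable;
    off-axis coordinates must already be back-projected to the isocenter
    plane by the caller.
    """
    return model.ocr_x(x_off) * model.ocr_y(y_off)


def _pdd_shape(d, k, buildup_depth, attenuation_coeff):
    return (1.0 - np.exp(-k * d / buildup_depth)) * np.exp(-attenuation_coeff * d)


def _buildup_rate(buildup_depth: float, attenuation_coeff: float) -> float:
    # k such that the analytic PDD peaks exactly at d = buildup_depth:
    # d/dd [(1-e^{-k d/b}) e^{-a d}] = 0 at d=b  =>  (k/b) e^{-k} = a (1 - e^{-k})
    a, b = attenuation_coeff, buildup_depth

    def g(k):
        return (k / b) * np.exp(-k) - a * (1.0 - np.exp(-k))

    return brentq(g, 1e-9, 60.0)


def _erf_profile(x, half_width, sigma):
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((half_width - x) / s) + erf((half_width + x) / s))


def synthesize_beam_model(
    buildup_depth: float = 0.8,
    attenuation_coeff: float = 0.045,
    penumbra_sigma_x: float = 0.3,
    penumbra_sigma_y: float = 0.1,
    output_cal: float = 1.0,
) -> MVCTBeamModel:
    """Generate a fully analytic beam model for the 400 x 4 mm^2 field.

    The depth-dose is ``(1 - exp(-k d / buildup_depth)) * exp(-attenuation_coeff d)``
    with the build-up rate ``k`` solved so the curve peaks exactly at
    ``buildup_depth``; it is sampled on a fixed 0-35 cm grid (the peak
    depth included as a node) and normalized to a maximum of exactly 1.0.
    Off-center ratios are flat-topped error-function profiles with
    half-widths ``field_x/2`` = 20 cm and ``field_y/2`` = 0.2 cm and
    penumbra scales ``penumbra_sigma_x`` / ``penumbra_sigma_y``; both are
    exactly 1.0 on the central axis and fall to (float) zero a few sigma
    outside the field edge, giving the beam finite lateral extent.

    Defaults emulate a ~3.5-MV imaging beam: build-up depth 0.8 cm,
    effective attenuation 0.045 /cm, film-scale penumbras of 3 mm (X)
    and 1 mm (Y).  The generator is deterministic.
    """
    for name, v in (
        ("buildup_depth", buildup_depth),
        ("attenuation_coeff", attenuation_coeff),
        ("penumbra_sigma_x", penumbra_sigma_x),
        ("penumbra_sigma_y", penumbra_sigma_y),
        ("output_cal", output_cal),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")

    k = _buildup_rate(buildup_depth, attenuation_coeff)
    depths = np.unique(np.concatenate([np.arange(0.0, 35.0 + 1e-12, 0.1), [buildup_depth, 35.0]]))
    pdd_vals = _pdd_shape(depths, k, buildup_depth, attenuation_coeff)
    pdd = normalize_curve(ProfileCurve(depths, pdd_vals, "depth"), mode="max")

    field_x, field_y = 40.0, 0.4
    # integer-scaled grids so position 0 is an exact node (exact central norm)
    xs = np.arange(-500, 501) * 0.05
    ocr_x = ProfileCurve(xs, _erf_profile(xs, field_x / 2.0, penumbra_sigma_x), "x_offaxis")
    ys = np.arange(-300, 301) * 0.01
    ocr_y = ProfileCurve(ys, _erf_profile(ys, field_y / 2.0, penumbra_sigma_y), "y_offaxis")
    ocr_x = normalize_curve(ocr_x, mode="central")
    ocr_y = normalize_curve(ocr_y, mode="central")

    return MVCTBeamModel(
        pdd=pdd,
        ocr_x=ocr_x,
        ocr_y=ocr_y,
        sad=85.0,
        field_x=field_x,
        field_y=field_y,
        profile_depth=1.5,
        reference_depth=1.5,
        output_cal=float(output_cal),
    )


def within_tolerance(differences, tol: float) -> tuple[bool, list[int]]:
    """Check point-dose differences (%) against a tolerance.

    Passes iff every ``|difference| < tol`` (strict).  Returns
    ``(passed, offending_indices)`` so a commissioning loop can perturb
    the profile curves and re-check until all points are within
    tolerance.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    diffs = np.asarray(differences, dtype=float)
    if diffs.size == 0:
        raise ValueError("differences must be non-empty")
    bad = np.nonzero(np.abs(diffs) >= tol)[0]
    return bad.size == 0, [int(i) for i in bad]


# -- serialization ----------------------------------------------------------

def _curve_to_dict(c: ProfileCurve) -> dict:
    return {
        "positions": c.positions.tolist(),
        "values": c.values.tolist(),
        "axis_label": c.axis_label,
    }


def save_beam_model(model: MVCTBeamModel, path) -> None:
    """Write the model (curves + scalar fields) as a single JSON document."""
    doc = {
        "pdd": _curve_to_dict(model.pdd),
        "ocr_x": _curve_to_dict(model.ocr_x),
        "ocr_y": _curve_to_dict(model.ocr_y),
        "sad": model.sad,
        "field_x": model.field_x,
        "field_y": model.field_y,
        "profile_depth": model.profile_depth,
        "reference_depth": model.reference_depth,
        "output_cal": model.output_cal,
        "mu_per_minute": model.mu_per_minute,
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_beam_model(path) -> MVCTBeamModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    curves = {
        key: ProfileCurve(
            np.asarray(doc[key]["positions"], dtype=float),
            np.asarray(doc[key]["values"], dtype=float),
            doc[key]["axis_label"],
        )
        for key in ("pdd", "ocr_x", "ocr_y")
    }
    scalars = {
        k: float(doc[k])
        for k in (
            "sad",
            "field_x",
            "field_y",
            "profile_depth",
            "reference_depth",
            "output_cal",
            "mu_per_minute",
        )
    }
    return MVCTBeamModel(**curves, **scalars)
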