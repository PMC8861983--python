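"""Shared configuration constants for RSA migration analysis.

Axis and sign conventions
-------------------------
The RSA coordinate frame follows the usual hip convention: x transverse
(medial-lateral), y longitudinal (proximal-distal), z sagittal
(anterior-posterior).  Translations are in millimetres, rotations in degrees.
Signs: +y is proximal, so femoral-stem *subsidence* (distal migration) is a
negative y-translation; +ry is internal rotation; +rz is varus tilt and -rz
valgus.  Euler angles use the intrinsic x->y->z sequence (``EULER_SEQ``); the
sequence only matters in the third decimal at clinical migration magnitudes,
but it is pinned here so every decomposition in the package agrees.
"""

from __future__ import annotations

# Migration axes, fixed order used throughout (translations then rotations).
AXES: tuple[str, ...] = ("tx", "ty", "tz", "rx", "ry", "rz")
TRANSLATION_AXES: tuple[str, ...] = ("tx", "ty", "tz")
ROTATION_AXES: tuple[str, ...] = ("rx", "ry", "rz")

AXIS_UNITS: dict[str, str] = {
    "tx": "mm", "ty": "mm", "tz": "mm",
    "rx": "deg", "ry": "deg", "rz": "deg",
}

#: Euler sequence for the 6-DOF decomposition of a rigid transform
#: (scipy convention: uppercase = intrinsic rotations, here x -> y -> z).
EULER_SEQ = "XYZ"

#: Follow-up visit schedule (weeks after surgery).
VISIT_WEEKS: tuple[int, ...] = (12, 22, 48)

# ---------------------------------------------------------------------------
# Measurement precision of the clinical RSA setup: half-width of the 95%
# confidence interval of double examinations, per axis (mm / degrees).
# ---------------------------------------------------------------------------
PRECISION_95: dict[str, float] = {
    "tx": 0.140, "ty": 0.110, "tz": 0.350,
    "rx": 0.50, "ry": 1.04, "rz": 0.18,
}

#: Divisor converting a 95% repeatability limit to a measurement SD.
PRECISION_TO_SD = 1.96

# ---------------------------------------------------------------------------
# Marker quality-control acceptability thresholds.  An examination is
# unacceptable when the mean error of rigid-body fitting exceeds ME_MAX or
# the marker condition number exceeds CN_MAX.  CN conventions differ between
# RSA platforms, so CN_SCALE_MM (numerator of the condition number) ships as
# a named constant rather than being buried in the formula.
# ---------------------------------------------------------------------------
ME_MAX_MM = 0.35
CN_MAX = 150.0
CN_SCALE_MM = 100.0

# ---------------------------------------------------------------------------
# Outlier cut-offs published for the trial cohort (quartile +/- 1.5 IQR on the
# two principal migration directions).  They cannot be re-derived without the
# patient-level data, so they ship as frozen constants: a subject is an
# outlier when subsidence exceeds 5.44 mm (ty < -5.44) and/or y-rotation
# exceeds 5.52 deg internal (ry > 5.52) or 4.32 deg external (ry < -4.32).
# ---------------------------------------------------------------------------
TRIAL_OUTLIER_CUTOFFS: dict[str, tuple[float, float]] = {
    "ty": (-5.44, float("inf")),
    "ry": (-4.32, 5.52),
}
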