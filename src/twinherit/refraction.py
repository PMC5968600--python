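"""Spherical equivalents, myopia classification and analysis-group assignment.

Refraction is summarised per eye by the spherical equivalent
``SE = sphere + cylinder/2`` (diopters, minus-cylinder convention).
Subjects are assigned to the *myopia* group when at least one eye has
SE <= -0.5 D, to the *emmetropia* group when both eyes lie within
+/-0.49 D, and are otherwise excluded (hyperopia, other refractive
errors). Myopia severity is graded mild / medium / high at the -3 D and
-6 D boundaries, with each boundary belonging to the more severe class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    IncompleteRecordError,
    InvalidMeasurementError,
)

#: Myopia threshold on the signed spherical-equivalent scale (diopters).
MYOPIA_THRESHOLD = -0.5
#: Emmetropia band half-width (diopters).
EMMETROPIA_BAND = 0.49
#: Degree boundaries (mild/medium and medium/high), diopters.
MILD_MEDIUM_BOUNDARY = -3.0
MEDIUM_HIGH_BOUNDARY = -6.0

GROUPS = ("myopia", "emmetropia", "excluded")
DEGREES = ("none", "mild", "medium", "high")

ANALYSIS_EYE_POLICIES = ("right_eye", "mean", "worse_eye")


@dataclass(frozen=True)
class EyeMeasurement:
    """One eye's refraction: sphere and cylinder in diopters.

    Cylinder is recorded in minus-cylinder convention (cylinder <= 0).
    A positive cylinder is rejected unless ``normalize_plus_cylinder``
    transposes it at construction via :func:`transpose_plus_cylinder`.
    """

    eye: str  # "OD" (right) or "OS" (left)
    sphere: float
    cylinder: float

    def __post_init__(self):
        if self.eye not in ("OD", "OS"):
            raise InvalidMeasurementError(f"unknown eye label {self.eye!r}")
        if not (math.isfinite(self.sphere) and math.isfinite(self.cylinder)):
            raise InvalidMeasurementError(
                f"non-finite refraction for eye {self.eye}: "
                f"sphere={self.sphere}, cylinder={self.cylinder}"
            )
        if self.cylinder > 0:
            raise InvalidMeasurementError(
                f"positive cylinder {self.cylinder} (minus-cylinder "
                "convention required; use transpose_plus_cylinder)"
            )

    @property
    def spherical_equivalent(self) -> float:
        return spherical_equivalent(self.sphere, self.cylinder)


def transpose_plus_cylinder(sphere: float, cylinder: float) -> tuple[float, float]:
    """Convert a plus-cylinder prescription to minus-cylinder form.

    The transposition ``sphere' = sphere + cylinder, cylinder' = -cylinder``
    describes the same lens; the spherical equivalent is unchanged.
    """
    if cylinder <= 0:
        return sphere, cylinder
    return sphere + cylinder, -cylinder


@dataclass(frozen=True)
class SubjectRecord:
    """One twin: identity, zygosity, demographics, refraction, genotypes."""

    subject_id: str
    pair_id: str
    zygosity: str  # "MZ" or "DZ"
    sex: str  # "M" or "F"
    age: float
    od: EyeMeasurement
    os: EyeMeasurement
    genotypes: Mapping[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.zygosity not in ("MZ", "DZ"):
            raise InvalidMeasurementError(
                f"unknown zygosity {self.zygosity!r} for {self.subject_id}"
            )
        if self.sex not in ("M", "F"):
            raise InvalidMeasurementError(
                f"unknown sex {self.sex!r} for {self.subject_id}"
            )


@dataclass(frozen=True)
class RefractiveStatus:
    """Group assignment and myopia degree for one subject."""

    group: str  # myopia | emmetropia | excluded
    degree: str  # none | mild | medium | high
    se_od: float
    se_os: float


def spherical_equivalent(sphere, cylinder):
    """Spherical equivalent ``sphere + cylinder/2`` in diopters.

    Accepts scalars or numpy arrays; exact arithmetic on the given
    values (no rounding).
    """
    sphere = np.asarray(sphere, dtype=float)
    cylinder = np.asarray(cylinder, dtype=float)
    if not (np.all(np.isfinite(sphere)) and np.all(np.isfinite(cylinder))):
        raise InvalidMeasurementError("non-finite sphere or cylinder")
    se = sphere + cylinder / 2.0
    return float(se) if se.ndim == 0 else se


def classify_degree(se) -> str | np.ndarray:
    """Grade myopia severity from a spherical equivalent.

    mild for -3 < SE <= -0.5, medium for -6 < SE <= -3, high for
    SE <= -6, ``"none"`` otherwise.  Each interval boundary belongs to
    the more severe class.  Vectorised over arrays.
    """
    arr = np.asarray(se, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidMeasurementError("non-finite spherical equivalent")
    out = np.full(arr.shape, "none", dtype=object)
    out[(arr <= MYOPIA_THRESHOLD) & (arr > MILD_MEDIUM_BOUNDARY)] = "mild"
    out[(arr <= MILD_MEDIUM_BOUNDARY) & (arr > MEDIUM_HIGH_BOUNDARY)] = "medium"
    out[arr <= MEDIUM_HIGH_BOUNDARY] = "high"
    if arr.ndim == 0:
        return str(out[()])
    return out


def analysis_eye_value(se_od: float, se_os: float, policy: str = "right_eye") -> float:
    """Single per-subject spherical equivalent under the chosen policy.

    ``right_eye`` returns the OD value (default, matching plotting of
    right-eye refraction); ``mean`` averages the two eyes; ``worse_eye``
    takes the more myopic (more negative) eye.
    """
    if policy == "right_eye":
        return se_od
    if policy == "mean":
        return (se_od + se_os) / 2.0
    if policy == "worse_eye":
        return min(se_od, se_os)
    raise ConfigurationError(
        f"unknown analysis-eye policy {policy!r}; "
        f"expected one of {ANALYSIS_EYE_POLICIES}"
    )


def assign_group(
    subject: SubjectRecord, policy: str = "right_eye"
) -> RefractiveStatus:
    """Assign a subject to the myopia/emmetropia/excluded group.

    Group assignment always uses both eyes: myopia if at least one eye
    has SE <= -0.5 D; emmetropia if both eyes lie within +/-0.49 D;
    excluded otherwise.  Degree is graded on the analysis-eye value; if
    the analysis eye is non-myopic while the subject is in the myopia
    group (discordant eyes), the worse eye is graded instead so every
    myopia-group subject carries a degree.
    """
    if subject.od is None or subject.os is None:
        raise IncompleteRecordError(
            f"subject {subject.subject_id} is missing an eye measurement"
        )
    se_od = subject.od.spherical_equivalent
    se_os = subject.os.spherical_equivalent
    group, degree = _group_and_degree(se_od, se_os, policy)
    return RefractiveStatus(group=group, degree=degree, se_od=se_od, se_os=se_os)


def _group_and_degree(se_od: float, se_os: float, policy: str) -> tuple[str, str]:
    myopic = se_od <= MYOPIA_THRESHOLD or se_os <= MYOPIA_THRESHOLD
    emmetropic = (
        abs(se_od) <= EMMETROPIA_BAND and abs(se_os) <= EMMETROPIA_BAND
    )
    if myopic:
        degree = classify_degree(analysis_eye_value(se_od, se_os, policy))
        if degree == "none":
            # analysis eye non-myopic; grade the worse eye
            degree = classify_degree(min(se_od, se_os))
        return "myopia", degree
    if emmetropic:
        return "emmetropia", "none"
    return "excluded", "none"


def classify_cohort(cohort: pd.DataFrame, policy: str = "right_eye") -> pd.DataFrame:
    """Classify every subject of a cohort table.

    Expects the cohort CSV schema columns ``od_sphere, od_cylinder,
    os_sphere, os_cylinder``; returns a copy with ``se_od, se_os,
    se_analysis, group, degree`` columns appended.
    """
    if policy not in ANALYSIS_EYE_POLICIES:
        raise ConfigurationError(f"unknown analysis-eye policy {policy!r}")
    out = cohort.copy()
    out["se_od"] = spherical_equivalent(
        out["od_sphere"].to_numpy(), out["od_cylinder"].to_numpy()
    )
    out["se_os"] = spherical_equivalent(
        out["os_sphere"].to_numpy(), out["os_cylinder"].to_numpy()
    )
    se_od = out["se_od"].to_numpy()
    se_os = out["se_os"].to_numpy()
    if policy == "right_eye":
        analysis = se_od
    elif policy == "mean":
        analysis = (se_od + se_os) / 2.0
    else:  # worse_eye
        analysis = np.minimum(se_od, se_os)
    myopic = (se_od <= MYOPIA_THRESHOLD) | (se_os <= MYOPIA_THRESHOLD)
    emmetropic = (np.abs(se_od) <= EMMETROPIA_BAND) & (
        np.abs(se_os) <= EMMETROPIA_BAND)
    group = np.where(myopic, "myopia",
                     np.where(emmetropic, "emmetropia", "excluded"))
    if len(out):
        degree = classify_degree(analysis)
        worse = classify_degree(np.minimum(se_od, se_os))
        degree = np.where(myopic & (degree == "none"), worse, degree)
        degree[~myopic] = "none"
    else:
        degree = np.array([], dtype=object)
    out["se_analysis"] = analysis
    out["group"] = group
    out["degree"] = degree
    return out
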