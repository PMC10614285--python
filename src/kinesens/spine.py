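"""Sagittal-plane vertebral spine representation and realignment.

A spine is an ordered stack of vertebrae, each carrying four corner
landmarks of the vertebral body (inferior/superior x posterior/anterior),
a measurement node at approximately the centre of gravity, and the pivot
of the intervertebral joint beneath it (instantaneous axis of rotation).

Coordinates are sagittal: x in mm, anterior positive; z in mm, superior
positive.  Positive rotation angles are counter-clockwise in the (x, z)
plane when viewed from the subject's left (i.e. extension of the segment
above the joint).

Realignment to target segment angles follows an iterative per-joint
procedure: the residual between target and current segment angle is
divided equally over the segment's joints, each joint is rotated in turn
from most inferior to most superior (everything above the joint moving
rigidly), and the sweep repeats until the residual is below tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VertebraLandmarks",
    "SpineModel",
    "SegmentSpec",
    "SpineMeasurements",
    "SEGMENTS",
    "LEVELS",
    "segment_angle",
    "rotate_about_joint",
    "align_segment",
    "rigid_rotate_to_distance",
    "align_spine",
    "default_template",
    "load_template_csv",
    "save_template_csv",
    "AlignmentError",
]

# Inferior-to-superior anatomical order: sacrum, lumbar, thoracic, cervical.
LEVELS: tuple[str, ...] = (
    ("S1",)
    + tuple(f"L{i}" for i in range(5, 0, -1))
    + tuple(f"T{i}" for i in range(12, 0, -1))
    + tuple(f"C{i}" for i in range(7, 1, -1))
)


class AlignmentError(RuntimeError):
    """Raised when an alignment operation cannot meet its contract."""


@dataclass(frozen=True)
class VertebraLandmarks:
    """Landmark set of one vertebral body in the sagittal plane.

    ``corners`` maps role -> (x, z) with roles ``inf_post``, ``inf_ant``,
    ``sup_post``, ``sup_ant``.  ``pivot`` is the instantaneous axis of
    rotation of the joint *beneath* this vertebra (``None`` for the most
    inferior vertebra).
    """

    level: str
    corners: dict[str, tuple[float, float]]
    measurement_point: tuple[float, float]
    pivot: tuple[float, float] | None = None

    def validate(self) -> None:
        for role in ("inf_post", "inf_ant", "sup_post", "sup_ant"):
            if role not in self.corners:
                raise ValueError(f"{self.level}: missing corner {role!r}")
        pts = list(self.corners.values()) + [self.measurement_point]
        if self.pivot is not None:
            pts.append(self.pivot)
        if not all(math.isfinite(v) for p in pts for v in p):
            raise ValueError(f"{self.level}: non-finite landmark")
        if not (
            self.corners["sup_post"][1] > self.corners["inf_post"][1]
            and self.corners["sup_ant"][1] > self.corners["inf_ant"][1]
        ):
            raise ValueError(f"{self.level}: superior corners must lie above inferior")
        if not (
            self.corners["inf_ant"][0] > self.corners["inf_post"][0]
            and self.corners["sup_ant"][0] > self.corners["sup_post"][0]
        ):
            raise ValueError(f"{self.level}: anterior corners must lie forward of posterior")

    def points(self) -> np.ndarray:
        """All landmarks as an array (corners, measurement point, pivot)."""
        pts = [self.corners[r] for r in ("inf_post", "inf_ant", "sup_post", "sup_ant")]
        pts.append(self.measurement_point)
        if self.pivot is not None:
            pts.append(self.pivot)
        return np.asarray(pts, dtype=float)

    def transformed(self, rot: np.ndarray, center: np.ndarray) -> "VertebraLandmarks":
        def _t(p: tuple[float, float]) -> tuple[float, float]:
            q = rot @ (np.asarray(p, dtype=float) - center) + center
            return (float(q[0]), float(q[1]))

        return replace(
            self,
            corners={k: _t(v) for k, v in self.corners.items()},
            measurement_point=_t(self.measurement_point),
            pivot=None if self.pivot is None else _t(self.pivot),
        )


@dataclass(frozen=True)
class SpineModel:
    """Ordered vertebral landmark sets from S1 (inferior) to C2 (superior)."""

    vertebrae: tuple[VertebraLandmarks, ...]
    frame: str = "sagittal_x_anterior_z_superior"

    def __post_init__(self) -> None:
        levels = [v.level for v in self.vertebrae]
        if levels.count("S1") != 1:
            raise ValueError("spine must contain exactly one S1")
        if levels[0] != "S1":
            raise ValueError("S1 must be the most inferior vertebra")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(v.level for v in self.vertebrae)

    def __getitem__(self, level: str) -> VertebraLandmarks:
        for v in self.vertebrae:
            if v.level == level:
                return v
        raise KeyError(f"vertebra {level!r} not present in spine")

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise KeyError(f"vertebra {level!r} not present in spine") from None

    def measurement_nodes(self, exclude: tuple[str, ...] = ()) -> np.ndarray:
        return np.asarray(
            [v.measurement_point for v in self.vertebrae if v.level not in exclude],
            dtype=float,
        )

    def joints(self) -> tuple[str, ...]:
        """Joint labels 'upper-lower', most inferior first."""
        lv = self.levels
        return tuple(f"{lv[i + 1]}-{lv[i]}" for i in range(len(lv) - 1))


@dataclass(frozen=True)
class SegmentSpec:
    """A named spinal segment: endplate references, joints and sign.

    ``orientation`` maps the raw counter-clockwise angle difference
    between the two endplate vectors (posterior -> anterior) onto the
    clinical convention: +1 gives positive lordosis (lumbar, cervical),
    -1 gives positive kyphosis (thoracic), so that positive values match
    positive literature means.
    """

    name: str
    upper_ref: tuple[str, str]  # (level, endplate in {"superior", "inferior"})
    lower_ref: tuple[str, str]
    joints: tuple[str, ...]  # most inferior first
    orientation: int = 1


SEGMENTS: dict[str, SegmentSpec] = {
    "lumbar_lordosis": SegmentSpec(
        name="lumbar_lordosis",
        upper_ref=("L1", "superior"),
        lower_ref=("L5", "inferior"),
        joints=("L4-L5", "L3-L4", "L2-L3", "L1-L2"),
        orientation=+1,
    ),
    "thoracic_kyphosis": SegmentSpec(
        name="thoracic_kyphosis",
        upper_ref=("T5", "superior"),
        lower_ref=("T12", "inferior"),
        joints=("T11-T12", "T10-T11", "T9-T10", "T8-T9", "T7-T8", "T6-T7", "T5-T6"),
        orientation=-1,
    ),
    "cervical_lordosis": SegmentSpec(
        name="cervical_lordosis",
        upper_ref=("C2", "inferior"),
        lower_ref=("C7", "inferior"),
        joints=("C6-C7", "C5-C6", "C4-C5", "C3-C4", "C2-C3"),
        orientation=+1,
    ),
}


@dataclass(frozen=True)
class SpineMeasurements:
    """Target segment angles (deg) and C7-sacrum horizontal distance (mm)."""

    lumbar_lordosis: float
    thoracic_kyphosis: float
    cervical_lordosis: float
    c7_sacrum_dx: float

    def validate(self) -> None:
        for name in ("lumbar_lordosis", "thoracic_kyphosis", "cervical_lordosis"):
            a = getattr(self, name)
            if not (-90.0 < a < 90.0):
                raise ValueError(f"{name}={a} outside (-90, 90) degrees")
        if not math.isfinite(self.c7_sacrum_dx):
            raise ValueError("c7_sacrum_dx must be finite")


def _endplate_vector(v: VertebraLandmarks, endplate: str) -> np.ndarray:
    """Posterior -> anterior vector of an endplate."""
    if endplate == "superior":
        a, b = v.corners["sup_post"], v.corners["sup_ant"]
    elif endplate == "inferior":
        a, b = v.corners["inf_post"], v.corners["inf_ant"]
    else:
        raise ValueError(f"unknown endplate {endplate!r}")
    return np.asarray(b, dtype=float) - np.asarray(a, dtype=float)


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def segment_angle(spine: SpineModel, seg: SegmentSpec) -> float:
    """Signed segment angle in degrees between the two endplate vectors.

    Positive values are lordotic for lumbar/cervical segments and
    kyphotic for the thoracic segment.
    """
    upper = _endplate_vector(spine[seg.upper_ref[0]], seg.upper_ref[1])
    lower = _endplate_vector(spine[seg.lower_ref[0]], seg.lower_ref[1])
    raw = math.degrees(
        math.atan2(upper[1], upper[0]) - math.atan2(lower[1], lower[0])
    )
    return seg.orientation * _wrap_deg(raw)


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


def rotate_about_joint(spine: SpineModel, joint: str, angle: float) -> SpineModel:
    """Rotate all vertebrae above ``joint`` rigidly about its pivot.

    ``joint`` is labelled 'upper-lower' (e.g. 'L4-L5'); the pivot is the
    one stored on the upper vertebra.  Vertebrae at or below the lower
    vertebra are returned bit-identical.
    """
    try:
        upper_level, lower_level = joint.split("-")
    except ValueError:
        raise KeyError(f"malformed joint label {joint!r}") from None
    iu, il = spine.index(upper_level), spine.index(lower_level)
    if iu != il + 1:
        raise KeyError(f"{joint!r} is not a joint between adjacent vertebrae")
    pivot = spine[upper_level].pivot
    if pivot is None:
        raise KeyError(f"upper vertebra of {joint!r} carries no pivot")
    rot = _rotation_matrix(angle)
    center = np.asarray(pivot, dtype=float)
    new = [
        v.transformed(rot, center) if i >= iu else v
        for i, v in enumerate(spine.vertebrae)
    ]
    return replace(spine, vertebrae=tuple(new))


def align_segment(
    spine: SpineModel,
    seg: SegmentSpec,
    target: float,
    tol: float = 0.01,
    max_iter: int = 100,
) -> SpineModel:
    """Drive a segment angle to ``target`` by iterative per-joint rotation.

    Each sweep rotates the segment's joints one at a time, most inferior
    first, each by (target - current) / n_joints (recomputed per sweep);
    everything above the moving joint rotates rigidly with it.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    n = len(seg.joints)
    current = segment_angle(spine, seg)
    for _ in range(max_iter):
        residual = _wrap_deg(target - current)
        if abs(residual) <= tol:
            return spine
        per_joint = seg.orientation * residual / n
        for joint in seg.joints:
            spine = rotate_about_joint(spine, joint, per_joint)
        current = segment_angle(spine, seg)
    residual = _wrap_deg(target - current)
    if abs(residual) <= tol:
        return spine
    raise AlignmentError(
        f"{seg.name}: residual {residual:.3g} deg after {max_iter} sweeps (tol {tol})"
    )


def first_sweep_rotation(spine: SpineModel, seg: SegmentSpec, target: float) -> float:
    """Per-joint rotation magnitude (deg) applied in the first sweep."""
    residual = _wrap_deg(target - segment_angle(spine, seg))
    return abs(residual) / len(seg.joints)


def rigid_rotate_to_distance(spine: SpineModel, target_dx: float) -> SpineModel:
    """Rotate the whole spine about the sacrum measurement point so that
    x(C7 meas) - x(S1 meas) equals ``target_dx`` (mm).

    Of the two candidate rotations the one with smaller magnitude is
    applied.  The sacrum measurement point is the fixed pivot.
    """
    s1 = np.asarray(spine["S1"].measurement_point, dtype=float)
    c7 = np.asarray(spine["C7"].measurement_point, dtype=float)
    rel = c7 - s1
    r = float(np.hypot(*rel))
    if abs(target_dx) > r:
        raise AlignmentError(
            f"target dx {target_dx:.3g} mm exceeds sacrum-C7 distance {r:.3g} mm"
        )
    alpha = math.atan2(rel[1], rel[0])  # current polar angle of C7 about S1
    beta = math.acos(target_dx / r)
    candidates = [_wrap_deg(math.degrees(b - alpha)) for b in (beta, -beta)]
    angle = min(candidates, key=abs)
    rot = _rotation_matrix(angle)
    new = [v.transformed(rot, s1) if abs(angle) > 0 else v for v in spine.vertebrae]
    return replace(spine, vertebrae=tuple(new))


def c7_sacrum_dx(spine: SpineModel) -> float:
    """Horizontal offset x(C7 measurement) - x(S1 measurement), mm."""
    return float(
        spine["C7"].measurement_point[0] - spine["S1"].measurement_point[0]
    )


def align_spine(
    spine: SpineModel, m: SpineMeasurements, tol: float = 0.01, max_iter: int = 100
) -> SpineModel:
    """Full realignment: lumbar, thoracic, cervical segments in order,
    then a rigid rotation about the sacrum to the target C7-sacrum
    horizontal distance."""
    m.validate()
    spine = align_segment(spine, SEGMENTS["lumbar_lordosis"], m.lumbar_lordosis, tol, max_iter)
    spine = align_segment(spine, SEGMENTS["thoracic_kyphosis"], m.thoracic_kyphosis, tol, max_iter)
    spine = align_segment(spine, SEGMENTS["cervical_lordosis"], m.cervical_lordosis, tol, max_iter)
    return rigid_rotate_to_distance(spine, m.c7_sacrum_dx)


# ---------------------------------------------------------------------------
# Template construction and CSV I/O


def _region_dims(level: str) -> tuple[float, float]:
    """(body height, body depth) in mm by spinal region."""
    if level == "S1":
        return 30.0, 45.0
    if level.startswith("L"):
        return 28.0, 33.0
    if level.startswith("T"):
        return 20.0, 26.0
    return 13.0, 16.0  # cervical


def _template_tilts() -> dict[str, float]:
    """Per-vertebra tilt (deg CCW from neutral) for a mildly curved stack.

    Gives the template a gentle S shape: slight sacral/lumbar extension,
    thoracic flexion, cervical extension.
    """
    tilts: dict[str, float] = {"S1": -12.0}
    for i, lv in enumerate(("L5", "L4", "L3", "L2", "L1")):
        tilts[lv] = -9.0 + 2.5 * i  # -9 .. +1
    for i, lv in enumerate((f"T{j}" for j in range(12, 0, -1))):
        tilts[lv] = 2.0 - 2.0 * i  # 2 .. -20
    for i, lv in enumerate(("C7", "C6", "C5", "C4", "C3", "C2")):
        tilts[lv] = -18.0 + 2.0 * i  # -18 .. -8
    return tilts


def default_template() -> SpineModel:
    """Construct a generic template spine (S1..C2) programmatically.

    Vertebral bodies are rectangles of region-typical size stacked with
    4 mm disc gaps, each tilted per a smooth sagittal curvature profile.
    Pivots default to the midpoint of the inferior endplate of the upper
    vertebra of each joint.
    """
    tilts = _template_tilts()
    vertebrae: list[VertebraLandmarks] = []
    top = np.zeros(2)  # superior endplate midpoint of previous vertebra
    for i, level in enumerate(LEVELS):
        h, d = _region_dims(level)
        tilt = _rotation_matrix(tilts[level])
        up = tilt @ np.array([0.0, 1.0])
        fwd = tilt @ np.array([1.0, 0.0])
        gap = 0.0 if i == 0 else 4.0
        center = top + up * (gap + h / 2.0)
        corners = {
            "inf_post": tuple(center - up * h / 2 - fwd * d / 2),
            "inf_ant": tuple(center - up * h / 2 + fwd * d / 2),
            "sup_post": tuple(center + up * h / 2 - fwd * d / 2),
            "sup_ant": tuple(center + up * h / 2 + fwd * d / 2),
        }
        corners = {k: (float(p[0]), float(p[1])) for k, p in corners.items()}
        inf_mid = center - up * h / 2
        v = VertebraLandmarks(
            level=level,
            corners=corners,
            measurement_point=(float(center[0]), float(center[1])),
            pivot=None if i == 0 else (float(inf_mid[0]), float(inf_mid[1])),
        )
        v.validate()
        vertebrae.append(v)
        top = center + up * h / 2
    return SpineModel(vertebrae=tuple(vertebrae))


_POINT_ROLES = ("inf_post", "inf_ant", "sup_post", "sup_ant", "meas", "pivot")


def save_template_csv(spine: SpineModel, path) -> None:
    rows = []
    for v in spine.vertebrae:
        for role in ("inf_post", "inf_ant", "sup_post", "sup_ant"):
            x, z = v.corners[role]
            rows.append((v.level, role, x, z))
        rows.append((v.level, "meas", *v.measurement_point))
        if v.pivot is not None:
            rows.append((v.level, "pivot", *v.pivot))
    pd.DataFrame(rows, columns=["level", "point_role", "x_mm", "z_mm"]).to_csv(
        path, index=False
    )


def load_template_csv(path) -> SpineModel:
    df = pd.read_csv(path)
    required = {"level", "point_role", "x_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"template CSV must have columns {sorted(required)}")
    vertebrae = []
    order = [lv for lv in LEVELS if lv in set(df["level"])]
    for level in order:
        sub = df[df["level"] == level].set_index("point_role")
        corners = {
            role: (float(sub.loc[role, "x_mm"]), float(sub.loc[role, "z_mm"]))
            for role in ("inf_post", "inf_ant", "sup_post", "sup_ant")
        }
        meas = (float(sub.loc["meas", "x_mm"]), float(sub.loc["meas", "z_mm"]))
        pivot = None
        if "pivot" in sub.index:
            pivot = (float(sub.loc["pivot", "x_mm"]), float(sub.loc["pivot", "z_mm"]))
        v = VertebraLandmarks(level, corners, meas, pivot)
        v.validate()
        vertebrae.append(v)
    return SpineModel(vertebrae=tuple(vertebrae))


def load_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {
        "subject_id",
        "lumbar_lordosis_deg",
        "thoracic_kyphosis_deg",
        "cervical_lordosis_deg",
        "c7_sacrum_dx_mm",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurements CSV missing columns {sorted(missing)}")
    return df


def measurements_from_row(row) -> SpineMeasurements:
    return SpineMeasurements(
        lumbar_lordosis=float(row["lumbar_lordosis_deg"]),
        thoracic_kyphosis=float(row["thoracic_kyphosis_deg"]),
        cervical_lordosis=float(row["cervical_lordosis_deg"]),
        c7_sacrum_dx=float(row["c7_sacrum_dx_mm"]),
    )
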