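"""Orthoptic scores: duction limitations, severity sum-score, affected EOM.

Monocular duction angles (synoptophore) are measured in eight cardinal
gaze directions up to a device cap: 40 deg for ab-/adduction, 30 deg for
elevation/depression, 35 deg (midpoint) for the diagonals.  A muscle is
"synoptophore-affected" when any duction limitation exists in its primary
direction of action, and "Hess-affected" when the Hess-chart deviation in
that direction exceeds 5 degrees (strictly; a deviation of exactly 5 deg
is not classified as affected).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import MUSCLES

__all__ = [
    "DIRECTIONS",
    "PRIMARY_DIRECTION",
    "default_caps",
    "OrthopticExam",
    "duction_limitation",
    "severity_sum_score",
    "classify_affected",
]

#: The eight cardinal gaze directions.
DIRECTIONS = (
    "abduction",
    "adduction",
    "elevation",
    "depression",
    "elevation_abduction",
    "elevation_adduction",
    "depression_abduction",
    "depression_adduction",
)

#: Primary direction of action per rectus muscle (total over MUSCLES).
PRIMARY_DIRECTION = {
    "LR": "abduction",
    "MR": "adduction",
    "SR_LPS": "elevation",
    "IR": "depression",
}


def default_caps(diagonal_deg: float = 35.0) -> dict[str, float]:
    """Measurement caps (degrees) per direction."""
    caps = {
        "abduction": 40.0,
        "adduction": 40.0,
        "elevation": 30.0,
        "depression": 30.0,
    }
    for d in DIRECTIONS[4:]:
        caps[d] = diagonal_deg
    return caps


@dataclass
class OrthopticExam:
    """One patient's duction angles and Hess-chart deviations.

    ``ductions[eye][direction]`` are measured angles in degrees (>= 0, at
    most the device cap); ``hess[eye][direction]`` are outer-field
    deviations in degrees (>= 0).
    """

    ductions: dict[str, dict[str, float]]
    hess: dict[str, dict[str, float]]
    ptosis: bool = False

    def eyes(self) -> tuple[str, ...]:
        return tuple(self.ductions)


def duction_limitation(
    exam: OrthopticExam,
    caps: dict[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-eye per-direction limitation: ``max(0, cap - measured)``.

    Angles above the device cap are rejected: the synoptophore cannot
    produce them.
    """
    if caps is None:
        caps = default_caps()
    if any(c <= 0 for c in caps.values()):
        raise ValueError("caps must be positive")
    out: dict[str, dict[str, float]] = {}
    for eye, angles in exam.ductions.items():
        out[eye] = {}
        for direction, angle in angles.items():
            cap = caps[direction]
            if angle < 0:
                raise ValueError(
                    f"negative duction angle {angle} ({eye}, {direction})"
                )
            if angle > cap + 1e-9:
                raise ValueError(
                    f"duction angle {angle} exceeds device cap {cap} "
                    f"({eye}, {direction})"
                )
            out[eye][direction] = max(0.0, cap - angle)
    return out


def severity_sum_score(
    exam: OrthopticExam,
    caps: dict[str, float] | None = None,
) -> float:
    """Severity of ophthalmoplegia: total duction limitation in degrees.

    Sum over all eight directions and both eyes; monotone non-decreasing
    in every individual limitation.  Missing directions are rejected by
    name rather than silently treated as full.
    """
    missing = [
        (eye, d)
        for eye, angles in exam.ductions.items()
        for d in DIRECTIONS
        if d not in angles
    ]
    if missing:
        raise ValueError(f"exam incomplete, missing directions: {missing}")
    lim = duction_limitation(exam, caps)
    return float(sum(sum(per_eye.values()) for per_eye in lim.values()))


def classify_affected(
    exam: OrthopticExam,
    mapping: dict[str, str] | None = None,
    hess_cutoff_deg: float = 5.0,
    caps: dict[str, float] | None = None,
) -> dict[str, dict[str, dict[str, bool]]]:
    """Affected / not-affected flags per eye and muscle.

    ``result[eye][muscle] = {"synoptophore": bool, "hess": bool}``:
    synoptophore-affected iff any duction limitation (> 0) in the
    muscle's primary direction; Hess-affected iff the deviation there is
    strictly above the cutoff.
    """
    if mapping is None:
        mapping = PRIMARY_DIRECTION
    missing = [m for m in MUSCLES if m not in mapping]
    if missing:
        raise ValueError(f"direction mapping incomplete for: {missing}")
    lim = duction_limitation(exam, caps)
    out: dict[str, dict[str, dict[str, bool]]] = {}
    for eye in exam.eyes():
        out[eye] = {}
        for muscle, direction in mapping.items():
            out[eye][muscle] = {
                "synoptophore": lim[eye].get(direction, 0.0) > 0.0,
                "hess": exam.hess.get(eye, {}).get(direction, 0.0)
                > hess_cutoff_deg,
            }
    return out
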