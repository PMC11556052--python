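"""The 0–6 point involution scale of the median atlantoaxial joint.

The scale grades age-related degenerative transformation of the joint
between the anterior arch of the atlas (C1) and the dens of the axis (C2):
progressive narrowing of the dens–atlas gap, accrual of bone exostoses at
the superior and inferior arch margins and the dens apex, and re-alignment
of the articular surfaces from an upward-open angle to full parallelism.
Each grade maps to a decade-scale age range (grade 0 → 14–20 years …
grade 6 → over 71 years).

The grader is a deterministic decision tree over :class:`GapGeometry`
evaluated from grade 6 downward; the first matching rule wins.  Verbal gap
descriptions are encoded as explicit numeric bands ("about 1 mm" →
[0.75, 1.25) mm), kept as named module constants.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import (
    Arrangement,
    ExostosisState,
    GapGeometry,
    PARALLEL_ARRANGEMENTS,
    exostosis_at_least,
)

#: Numeric reading of "about 1 mm".
ABOUT_1MM_LO = 0.75
ABOUT_1MM_HI = 1.25
#: "about 2–3 mm" band shared by the early grades.
BAND_2_3_LO = 2.0
BAND_2_3_HI = 3.0


@dataclass(frozen=True)
class InvolutionGrade:
    points: int

    def __post_init__(self) -> None:
        if not 0 <= self.points <= 6:
            raise ValueError(f"involution grade must be 0..6, got {self.points}")

    def __int__(self) -> int:
        return self.points


@dataclass(frozen=True)
class AgeRange:
    """Closed age interval in years; ``upper=None`` means open-ended."""

    lower: float
    upper: float | None

    def __post_init__(self) -> None:
        if self.upper is not None and self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    def contains(self, age: float) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)


_GRADE_AGE_RANGES: dict[int, AgeRange] = {
    0: AgeRange(14, 20),
    1: AgeRange(21, 30),
    2: AgeRange(31, 39),
    3: AgeRange(40, 49),
    4: AgeRange(50, 59),
    5: AgeRange(60, 70),
    6: AgeRange(71, None),
}


def grade_geometry(g: GapGeometry) -> InvolutionGrade:
    """Grade one joint geometry on the 0–6 involution scale.

    Rules are checked from grade 6 downward and the first match wins; the
    gap bands of adjacent grades overlap in the scale's verbal definitions,
    so exostosis state and surface arrangement act as the discriminators.
    """
    all_marked = all(s is ExostosisState.MARKED for s in g.exostoses)
    all_present = all(exostosis_at_least(s, ExostosisState.PRESENT) for s in g.exostoses)
    superior_present = exostosis_at_least(g.exostosis_superior, ExostosisState.PRESENT)
    parallel = g.arrangement in PARALLEL_ARRANGEMENTS
    no_exostoses = all(s is ExostosisState.ABSENT for s in g.exostoses)

    # Each rule carries only an upper gap bound: because evaluation runs
    # from grade 6 downward, a narrower gap can only promote the joint to a
    # higher grade, which keeps grading monotone in gap narrowing for any
    # fixed exostosis/arrangement state.
    if g.gap_mm < 1.0 and all_marked and parallel:
        return InvolutionGrade(6)
    if g.gap_mm < ABOUT_1MM_HI and all_marked and parallel:
        return InvolutionGrade(5)
    if g.gap_mm < ABOUT_1MM_HI and all_present:
        return InvolutionGrade(4)
    if g.gap_mm < 2.0 and superior_present:
        return InvolutionGrade(3)
    if g.gap_mm <= BAND_2_3_HI and superior_present:
        return InvolutionGrade(2)
    if (
        g.gap_mm <= BAND_2_3_HI
        and no_exostoses
        and g.arrangement is Arrangement.TENDENCY_PARALLEL
    ):
        return InvolutionGrade(1)
    return InvolutionGrade(0)


def grade_to_age_range(grade: InvolutionGrade | int) -> AgeRange:
    """Age range associated with an involution grade."""
    points = int(grade)
    if points not in _GRADE_AGE_RANGES:
        raise ValueError(f"involution grade must be 0..6, got {points}")
    return _GRADE_AGE_RANGES[points]


def age_to_modal_grade(age: float) -> InvolutionGrade:
    """The grade whose age range contains ``age`` (inverse of the lookup)."""
    if age < 14:
        raise ValueError("the involution scale starts at age 14")
    for points, rng in _GRADE_AGE_RANGES.items():
        if rng.contains(age):
            return InvolutionGrade(points)
    # integer ranges leave gaps like (20, 21); assign the nearer lower grade
    for points in range(6, -1, -1):
        if age >= _GRADE_AGE_RANGES[points].lower:
            return InvolutionGrade(points)
    return InvolutionGrade(0)


def template_geometry(grade: InvolutionGrade | int) -> GapGeometry:
    """Canonical noise-free geometry exemplifying each grade.

    Used for round-trip testing and as documentation of the scale: grading
    the template of grade g returns g for every g.
    """
    points = int(grade)
    A = ExostosisState.ABSENT
    P = ExostosisState.PRESENT
    M = ExostosisState.MARKED
    table = {
        0: (3.0, Arrangement.ANGLE_OPEN_UPWARD, A, A, A, True),
        1: (2.5, Arrangement.TENDENCY_PARALLEL, A, A, A, True),
        2: (2.5, Arrangement.LINEAR_ARCUATE, P, A, A, False),
        3: (1.5, Arrangement.PARALLEL_RECTILINEAR, P, P, A, False),
        4: (1.0, Arrangement.PARALLEL_RECTILINEAR, P, P, P, False),
        5: (1.0, Arrangement.PARALLEL_ARCUATE, M, M, M, False),
        6: (0.6, Arrangement.PARALLEL_RECTILINEAR, M, M, M, False),
    }
    if points not in table:
        raise ValueError(f"involution grade must be 0..6, got {points}")
    gap, arr, sup, inf, apex, above = table[points]
    return GapGeometry(
        gap_mm=gap,
        arrangement=arr,
        exostosis_superior=sup,
        exostosis_inferior=inf,
        exostosis_apex=apex,
        apex_above_arch=above,
    )
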