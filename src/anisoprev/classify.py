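"""Age-dependent refractive-state labels and anisometropia classification.

The screening criteria are age-dependent because physiological hyperopia is
normal in young children: below the age split (6 completed years) a child is
only called hyperopic from SE >= +1.25 D and astigmatic from |C| >= 1.00 D,
while from 6 years on the hyperopia threshold drops to +1.00 D and the
astigmatism threshold rises to 1.25 D.  Myopia is SE <= -1.00 D at any age.

Anisometropia is an interocular difference (IOD):

    SA = |SE_RE - SE_LE|     spherical anisometropia
    MA = |C_RE - C_LE|       meridional anisometropia (negative-form cylinders)

Total anisometropia (TA) is present when either IOD reaches the cutoff
(1.25 D for the instrument-specific profile).  MA without SA is "simple
meridional anisometropia" (sMA).  TA cases are typed from the per-eye
refractive states (myopic / hyperopic / antimetropic / sMA) and banded by
severity: low below 2.00 D, high from 2.00 through 6.00 D, very high above.

Person-level categories are mutually exclusive with precedence

    anisometrope > myope > hyperope > simple astigmat > emmetrope

so that the category counts partition any cohort; compound astigmatism
(an astigmatic eye that is also ametropic in SE) is carried as a flag, not a
category.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np
import pandas as pd

from .vectors import PowerVector

__all__ = [
    "RefractiveCriteria",
    "EyeState",
    "AnisoMetrics",
    "AnisoProfile",
    "PersonCategory",
    "IncompleteRecordError",
    "SeverityNotApplicableError",
    "classify_eye",
    "compute_aniso",
    "classify_aniso",
    "severity",
    "classify_person",
    "classify_frame",
]

SE_STATES = ("emmetrope", "myope", "hyperope")
ANISO_TYPES = ("none", "myopic", "hyperopic", "antimetropic", "sMA")
SEVERITIES = ("none", "low", "high", "very_high")
CATEGORIES = ("emmetrope", "myope", "hyperope", "simple_astigmat", "anisometrope")
PERSON_RULES = ("either_worse", "right_eye")


class IncompleteRecordError(ValueError):
    """A participant is missing the measurements an operation requires."""


class SeverityNotApplicableError(ValueError):
    """Severity was requested for an IOD below the anisometropia cutoff."""


@dataclass(frozen=True)
class RefractiveCriteria:
    """Threshold profile for refractive-state and anisometropia labels.

    The defaults are the screening criteria recommended for the PlusOptix
    pediatric autorefractometer.  All values are diopters except
    ``age_split`` (completed years) and ``person_rule``.

    Attributes
    ----------
    myope_se : SE at or below this is myopic (both age groups).
    hyperope_se_young, hyperope_se_old : SE at or above this is hyperopic,
        below / at-or-above ``age_split``.  The emmetrope band is the open
        interval between the myopia and hyperopia thresholds, so the
        partition has no gaps or overlaps by construction.
    astig_cyl_young, astig_cyl_old : |C| at or above this is astigmatic.
    aniso_cutoff : IOD (SE or C) at or above this is anisometropic.  1.25 D
        is the instrument recommendation; 1.00 D is the common literature
        convention and can be set here for comparisons.
    severity_low_high, severity_high_very : severity band edges; low is
        below the first, high runs from the first through the second
        (closed), very high is above the second.
    person_rule : ``"either_worse"`` labels a person myopic/hyperopic if
        either eye qualifies, the larger-|SE| eye deciding conflicts
        (myopia wins exact ties); ``"right_eye"`` uses the right eye alone.
    """

    myope_se: float = -1.00
    hyperope_se_young: float = 1.25
    hyperope_se_old: float = 1.00
    astig_cyl_young: float = 1.00
    astig_cyl_old: float = 1.25
    aniso_cutoff: float = 1.25
    age_split: float = 6.0
    severity_low_high: float = 2.00
    severity_high_very: float = 6.00
    person_rule: str = "either_worse"

    def __post_init__(self) -> None:
        if self.aniso_cutoff <= 0:
            raise ValueError("anisometropia cutoff must be positive")
        if not (self.aniso_cutoff <= self.severity_low_high < self.severity_high_very):
            raise ValueError("severity band edges must be strictly increasing "
                             "and start at or above the cutoff")
        if self.myope_se >= min(self.hyperope_se_young, self.hyperope_se_old):
            raise ValueError("myopia threshold must lie below hyperopia thresholds")
        if self.person_rule not in PERSON_RULES:
            raise ValueError(f"person_rule must be one of {PERSON_RULES}")

    @classmethod
    def plusoptix(cls, **overrides) -> "RefractiveCriteria":
        """The shipped instrument-recommended profile (the defaults)."""
        return cls(**overrides)

    def hyperope_threshold(self, age: float) -> float:
        return self.hyperope_se_young if age < self.age_split else self.hyperope_se_old

    def astig_threshold(self, age: float) -> float:
        return self.astig_cyl_young if age < self.age_split else self.astig_cyl_old

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RefractiveCriteria":
        return cls(**d)

    def with_cutoff(self, cutoff: float) -> "RefractiveCriteria":
        return replace(self, aniso_cutoff=cutoff)


@dataclass(frozen=True)
class EyeState:
    """Refractive state of one eye: SE label, astigmatism flag, and the SE."""

    se_state: str
    astigmatic: bool
    se: float = 0.0


@dataclass(frozen=True)
class AnisoMetrics:
    """Interocular differences: SA = |SE_RE - SE_LE|, MA = |C_RE - C_LE|."""

    sa: float
    ma: float


@dataclass(frozen=True)
class AnisoProfile:
    """Anisometropia flags, type and severity for one participant."""

    has_sa: bool
    has_ma: bool
    is_sma: bool
    is_ta: bool
    aniso_type: str
    severity: str


@dataclass(frozen=True)
class PersonCategory:
    """Mutually exclusive person-level refractive category plus the
    compound-astigmatism flag."""

    category: str
    compound_astigmat: bool


def classify_eye(
    pv: PowerVector, cylinder: float, age: float, criteria: RefractiveCriteria
) -> EyeState:
    """Label one eye from its (averaged) power vector and cylinder.

    ``cylinder`` is the negative-form cylinder implied by the averaged
    reading (``pv.cylinder`` when averaging was done in vector space).
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if pv.se <= criteria.myope_se:
        se_state = "myope"
    elif pv.se >= criteria.hyperope_threshold(age):
        se_state = "hyperope"
    else:
        se_state = "emmetrope"
    astigmatic = abs(cylinder) >= criteria.astig_threshold(age)
    return EyeState(se_state=se_state, astigmatic=astigmatic, se=pv.se)


def compute_aniso(re: Optional[PowerVector], le: Optional[PowerVector]) -> AnisoMetrics:
    """Interocular differences from both eyes' averaged power vectors."""
    if re is None or le is None:
        raise IncompleteRecordError("both eyes are required to compute anisometropia")
    return AnisoMetrics(sa=abs(re.se - le.se), ma=abs(re.cylinder - le.cylinder))


def _fallback_type(re_state: EyeState, le_state: EyeState) -> str:
    # SA at cutoff with both eyes inside the emmetrope band (the band is
    # wider than the cutoff): type by the sign of the more ametropic eye.
    worse = re_state if abs(re_state.se) >= abs(le_state.se) else le_state
    return "myopic" if worse.se < 0 else "hyperopic"


def classify_aniso(
    metrics: AnisoMetrics,
    re_state: EyeState,
    le_state: EyeState,
    criteria: RefractiveCriteria,
) -> AnisoProfile:
    """Type and grade a participant's anisometropia.

    Typing of TA cases: sMA when the IOD is meridional only; antimetropic
    when one eye is myopic and the other hyperopic; myopic when at least one
    eye is myopic and the other is myopic or emmetropic; hyperopic
    symmetrically.  Severity is banded on ``max(SA, MA)``.
    """
    cutoff = criteria.aniso_cutoff
    has_sa = metrics.sa >= cutoff
    has_ma = metrics.ma >= cutoff
    is_ta = has_sa or has_ma
    is_sma = has_ma and not has_sa
    if not is_ta:
        return AnisoProfile(False, False, False, False, "none", "none")

    states = {re_state.se_state, le_state.se_state}
    if is_sma:
        aniso_type = "sMA"
    elif "myope" in states and "hyperope" in states:
        aniso_type = "antimetropic"
    elif "myope" in states:
        aniso_type = "myopic"
    elif "hyperope" in states:
        aniso_type = "hyperopic"
    else:
        aniso_type = _fallback_type(re_state, le_state)
    sev = severity(max(metrics.sa, metrics.ma), criteria)
    return AnisoProfile(has_sa, has_ma, is_sma, True, aniso_type, sev)


def severity(d: float, criteria: RefractiveCriteria) -> str:
    """Severity band for an IOD magnitude ``d = max(SA, MA)`` of a TA case."""
    if d < criteria.aniso_cutoff:
        raise SeverityNotApplicableError(
            f"IOD {d} is below the anisometropia cutoff {criteria.aniso_cutoff}"
        )
    if d < criteria.severity_low_high:
        return "low"
    if d <= criteria.severity_high_very:
        return "high"
    return "very_high"


def _person_se_label(
    re_state: EyeState, le_state: EyeState, rule: str
) -> str:
    if rule == "right_eye":
        return re_state.se_state
    states = {re_state.se_state, le_state.se_state}
    if "myope" in states and "hyperope" in states:
        # conflicting eyes: larger |SE| decides, myopia wins exact ties
        if abs(re_state.se) == abs(le_state.se):
            return "myope"
        worse = re_state if abs(re_state.se) > abs(le_state.se) else le_state
        return worse.se_state
    if "myope" in states:
        return "myope"
    if "hyperope" in states:
        return "hyperope"
    return "emmetrope"


def classify_person(
    re_state: EyeState,
    le_state: EyeState,
    profile: AnisoProfile,
    criteria: RefractiveCriteria,
) -> PersonCategory:
    """Assign the mutually exclusive person-level category.

    Precedence: anisometrope > myope > hyperope > simple astigmat >
    emmetrope.  The compound-astigmatism flag is set whenever an astigmatic
    eye is also SE-ametropic, whatever the category.
    """
    compound = any(
        e.astigmatic and e.se_state != "emmetrope" for e in (re_state, le_state)
    )
    if profile.is_ta:
        return PersonCategory("anisometrope", compound)
    se_label = _person_se_label(re_state, le_state, criteria.person_rule)
    if se_label in ("myope", "hyperope"):
        return PersonCategory(se_label, compound)
    if criteria.person_rule == "right_eye":
        astig = re_state.astigmatic
    else:
        astig = re_state.astigmatic or le_state.astigmatic
    if astig:
        return PersonCategory("simple_astigmat", compound)
    return PersonCategory("emmetrope", compound)


# ---------------------------------------------------------------------------
# vectorized frame-level classification


def classify_frame(
    frame: pd.DataFrame, criteria: RefractiveCriteria
) -> pd.DataFrame:
    """Classify a whole cohort at once.

    ``frame`` must carry per-eye averaged refraction columns ``se_re``,
    ``c_re``, ``se_le``, ``c_le`` (diopters, negative-form cylinders) and
    ``age`` (completed years).  Returns a copy with the label columns
    appended: per-eye states, SA/MA, anisometropia flags/type/severity,
    the person ``category`` and the ``compound_astigmat`` flag.  Semantics
    are identical to the scalar operations.
    """
    out = frame.copy()
    age = out["age"].to_numpy(dtype=float)
    se_re = out["se_re"].to_numpy(dtype=float)
    se_le = out["se_le"].to_numpy(dtype=float)
    c_re = out["c_re"].to_numpy(dtype=float)
    c_le = out["c_le"].to_numpy(dtype=float)

    young = age < criteria.age_split
    hyp_thr = np.where(young, criteria.hyperope_se_young, criteria.hyperope_se_old)
    ast_thr = np.where(young, criteria.astig_cyl_young, criteria.astig_cyl_old)

    def se_states(se: np.ndarray) -> np.ndarray:
        st = np.full(se.shape, "emmetrope", dtype=object)
        st[se <= criteria.myope_se] = "myope"
        st[se >= hyp_thr] = "hyperope"
        return st

    st_re, st_le = se_states(se_re), se_states(se_le)
    astig_re = np.abs(c_re) >= ast_thr
    astig_le = np.abs(c_le) >= ast_thr

    sa = np.abs(se_re - se_le)
    ma = np.abs(c_re - c_le)
    has_sa = sa >= criteria.aniso_cutoff
    has_ma = ma >= criteria.aniso_cutoff
    is_ta = has_sa | has_ma
    is_sma = has_ma & ~has_sa

    any_myo = (st_re == "myope") | (st_le == "myope")
    any_hyp = (st_re == "hyperope") | (st_le == "hyperope")
    worse_neg = np.where(np.abs(se_re) >= np.abs(se_le), se_re, se_le) < 0

    aniso_type = np.full(len(out), "none", dtype=object)
    aniso_type[is_ta & worse_neg] = "myopic"          # fallback cases
    aniso_type[is_ta & ~worse_neg] = "hyperopic"
    aniso_type[is_ta & any_hyp] = "hyperopic"
    aniso_type[is_ta & any_myo] = "myopic"
    aniso_type[is_ta & any_myo & any_hyp] = "antimetropic"
    aniso_type[is_sma] = "sMA"

    d = np.maximum(sa, ma)
    sev = np.full(len(out), "none", dtype=object)
    sev[is_ta] = "low"
    sev[is_ta & (d >= criteria.severity_low_high)] = "high"
    sev[is_ta & (d > criteria.severity_high_very)] = "very_high"

    # person-level SE label
    if criteria.person_rule == "right_eye":
        se_label = st_re.copy()
        astig_any = astig_re
    else:
        se_label = np.full(len(out), "emmetrope", dtype=object)
        se_label[any_hyp] = "hyperope"
        se_label[any_myo] = "myope"
        conflict = any_myo & any_hyp
        re_worse = np.abs(se_re) > np.abs(se_le)
        tie = np.abs(se_re) == np.abs(se_le)
        se_label[conflict & re_worse] = st_re[conflict & re_worse]
        se_label[conflict & ~re_worse & ~tie] = st_le[conflict & ~re_worse & ~tie]
        se_label[conflict & tie] = "myope"
        astig_any = astig_re | astig_le

    category = np.full(len(out), "emmetrope", dtype=object)
    category[astig_any] = "simple_astigmat"
    category[se_label == "hyperope"] = "hyperope"
    category[se_label == "myope"] = "myope"
    category[is_ta] = "anisometrope"

    compound = (astig_re & (st_re != "emmetrope")) | (astig_le & (st_le != "emmetrope"))

    out["re_state"] = st_re
    out["le_state"] = st_le
    out["re_astig"] = astig_re
    out["le_astig"] = astig_le
    out["sa"] = sa
    out["ma"] = ma
    out["has_sa"] = has_sa
    out["has_ma"] = has_ma
    out["is_sma"] = is_sma
    out["is_ta"] = is_ta
    out["aniso_type"] = aniso_type
    out["severity"] = sev
    out["category"] = category
    out["compound_astigmat"] = compound
    return out
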