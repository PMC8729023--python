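"""Synthetic school-screening cohorts with known ground truth.

The generator emulates the statistical structure of a Portuguese school
vision-screening sample: stratum proportions over gender, rural/urban
residence and school cycle (preschool 3-6 y, 1st cycle 6-10, 2nd 10-12,
3rd 12-15); a per-cycle total-anisometropia rate rising from 2.9% in
preschool to 9.4% in the 3rd cycle; an anisometropia type mix dominated by
myopic cases (46%), then hyperopic (33%), simple meridional (19%) and
antimetropic (2%); and refractive-component distributions for the ametrope
groups (myopic SE -2.67 +/- 1.32 D, hyperopic SE +1.46 +/- 0.59 D,
simple-astigmat cylinder -1.50 +/- 0.33 D).  Every participant gets three
replicate readings per eye: the truth refraction plus independent Gaussian
noise in power-vector space.

Two design points matter for testing:

* Truth refractions are snapped to the 0.01 D / 1 degree grid that the
  cohort CSV uses, and every injected label is kept a safe margin (0.02 D)
  away from its classification boundary.  With replicate noise SD 0 the
  classifier therefore recovers the injected labels exactly, including
  after a CSV round trip.
* Ground-truth labels attached to the cohort are computed by running the
  classifier on the noise-free truth values, so truth and classifier share
  one set of semantics; the injected state/type/TA flags are stored
  alongside and are verified to coincide.

Values are never clamped to the instrument range (sphere and cylinder
-7.00 to +5.00 D), so range-exclusion filters can be exercised on noisy
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import RefractiveCriteria, classify_frame

__all__ = ["SimulationConfig", "CohortTable", "simulate_cohort", "make_fixture",
           "REPLICATE_COLUMNS", "DEMOGRAPHIC_COLUMNS"]

CYCLES = ("preschool", "cycle1", "cycle2", "cycle3")
AGE_RANGES = {"preschool": (3, 5), "cycle1": (6, 9), "cycle2": (10, 11),
              "cycle3": (12, 15)}
ANISO_TYPES_MIX = ("myopic", "hyperopic", "sMA", "antimetropic")
BASE_STATES = ("emmetrope", "hyperope", "myope", "simple_astigmat")

DEMOGRAPHIC_COLUMNS = ["id", "age", "gender", "residence", "cycle",
                       "wears_correction"]
REPLICATE_COLUMNS = [f"{eye}_{comp}{k}" for eye in ("re", "le")
                     for k in (1, 2, 3) for comp in ("s", "c", "a")]

_GRID = 0.01        # diopter grid of the cohort CSV
_MARGIN = 0.02      # distance injected truths keep from label boundaries


def _check_mix(name: str, mix: Dict[str, float], keys) -> None:
    if set(mix) != set(keys):
        raise ValueError(f"{name} must have keys {sorted(keys)}, got {sorted(mix)}")
    if any(not 0 <= v <= 1 for v in mix.values()):
        raise ValueError(f"{name} proportions must lie in [0, 1]")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions must sum to 1")


@dataclass
class SimulationConfig:
    """Study-shaped generator settings.

    Defaults reproduce the screening sample's structure: n = 749; cycle
    shares 13.8/30.8/24.2/31.2%; per-cycle TA rates 2.9/5.0/7.0/9.4%
    (the two intermediate rates are interpolated between the published
    end points); type mix 46/33/19/2%; component distributions as in the
    module docstring.  ``noise_sd`` is the replicate measurement noise SD
    in diopters per power-vector component.
    """

    n: int = 749
    gender_props: Dict[str, float] = field(
        default_factory=lambda: {"male": 0.533, "female": 0.467})
    residence_props: Dict[str, float] = field(
        default_factory=lambda: {"rural": 0.427, "urban": 0.565, "missing": 0.008})
    cycle_props: Dict[str, float] = field(
        default_factory=lambda: {"preschool": 0.138, "cycle1": 0.308,
                                 "cycle2": 0.242, "cycle3": 0.312})
    ta_rates: Dict[str, float] = field(
        default_factory=lambda: {"preschool": 0.029, "cycle1": 0.050,
                                 "cycle2": 0.070, "cycle3": 0.094})
    type_mix: Dict[str, float] = field(
        default_factory=lambda: {"myopic": 0.46, "hyperopic": 0.33,
                                 "sMA": 0.19, "antimetropic": 0.02})
    state_mix: Dict[str, float] = field(
        default_factory=lambda: {"emmetrope": 0.758, "hyperope": 0.155,
                                 "myope": 0.070, "simple_astigmat": 0.017})
    myopic_se: tuple = (-2.67, 1.32)
    hyperopic_se: tuple = (1.46, 0.59)
    emmetropic_se: tuple = (0.50, 0.50)
    astig_cyl: tuple = (-1.50, 0.33)
    cylinder_halfnormal_sd: float = 0.45
    noise_sd: float = 0.25
    low_severity_share: float = 0.67
    high_severity_max: float = 3.5
    wear_rates: Dict[str, float] = field(
        default_factory=lambda: {"emmetrope": 0.12, "myope": 0.90,
                                 "hyperope": 0.20, "simple_astigmat": 0.50,
                                 "anisometrope": 0.80})
    wear_missing_rate: float = 0.003
    criteria: RefractiveCriteria = field(default_factory=RefractiveCriteria)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        _check_mix("gender_props", self.gender_props,
                   self.gender_props.keys() | {"male", "female"})
        _check_mix("residence_props", self.residence_props,
                   self.residence_props.keys())
        _check_mix("cycle_props", self.cycle_props, CYCLES)
        _check_mix("type_mix", self.type_mix, ANISO_TYPES_MIX)
        _check_mix("state_mix", self.state_mix, BASE_STATES)
        if set(self.ta_rates) != set(CYCLES):
            raise ValueError(f"ta_rates must have keys {CYCLES}")
        if any(not 0 <= v <= 1 for v in self.ta_rates.values()):
            raise ValueError("ta_rates must lie in [0, 1]")
        for name, sd in (("noise_sd", self.noise_sd),
                         ("cylinder_halfnormal_sd", self.cylinder_halfnormal_sd),
                         ("myopic SE SD", self.myopic_se[1]),
                         ("hyperopic SE SD", self.hyperopic_se[1]),
                         ("emmetropic SE SD", self.emmetropic_se[1]),
                         ("astigmatic cylinder SD", self.astig_cyl[1])):
            if sd < 0:
                raise ValueError(f"{name} must be non-negative")
        cut = self.criteria.aniso_cutoff
        # an injectable low-severity IOD must exist below the low/high edge
        if cut + 2 * _MARGIN >= self.criteria.severity_low_high:
            raise ValueError(
                f"anisometropia cutoff {cut} leaves no room below the "
                f"low-severity edge {self.criteria.severity_low_high}; "
                "type mix is infeasible")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["criteria"] = self.criteria.to_dict()
        return d


@dataclass
class CohortTable:
    """A simulated cohort: the measurement table plus its truth sidecar.

    ``data`` is CSV-shaped (one row per participant, demographics plus
    ``re_s1..le_a3`` replicate columns); ``truth`` carries the noise-free
    per-eye refractions, classifier-derived truth labels, and the injected
    flags, keyed by the same ``id``.
    """

    data: pd.DataFrame
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)


def _snap(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float) / _GRID) * _GRID


def _truncnorm(rng, mean, sd, lo, hi, size):
    if size == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a = (np.asarray(lo, dtype=float) - mean) / sd
    b = (np.asarray(hi, dtype=float) - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_iod(rng, size, cutoff, low_share, high_max):
    """Severity-mixture IOD magnitudes on the diopter grid, >= cutoff."""
    low = rng.random(size) < low_share
    u = rng.random(size)
    lo_min = cutoff + _MARGIN
    lo_max = 2.0 - _MARGIN
    iod = np.where(low, lo_min + u * (lo_max - lo_min),
                   2.0 + u * (high_max - 2.0))
    return _snap(iod)


def simulate_cohort(config: SimulationConfig, seed: int) -> CohortTable:
    """Draw one cohort; deterministic given ``(config, seed)``."""
    rng = np.random.default_rng(seed)
    n = config.n
    crit = config.criteria
    if n == 0:
        empty = pd.DataFrame(columns=DEMOGRAPHIC_COLUMNS + REPLICATE_COLUMNS)
        return CohortTable(data=empty, truth=pd.DataFrame(columns=["id"]))

    cycle = rng.choice(CYCLES, size=n, p=[config.cycle_props[c] for c in CYCLES])
    age = np.empty(n, dtype=int)
    for c in CYCLES:
        m = cycle == c
        lo, hi = AGE_RANGES[c]
        age[m] = rng.integers(lo, hi + 1, size=int(m.sum()))

    g_levels = list(config.gender_props)
    gender = rng.choice(g_levels, size=n, p=[config.gender_props[g] for g in g_levels])
    r_levels = list(config.residence_props)
    residence = rng.choice(r_levels, size=n,
                           p=[config.residence_props[r] for r in r_levels])

    young = age < crit.age_split
    hyp_thr = np.where(young, crit.hyperope_se_young, crit.hyperope_se_old)
    ast_thr = np.where(young, crit.astig_cyl_young, crit.astig_cyl_old)

    ta_rate = np.array([config.ta_rates[c] for c in cycle])
    is_ta = rng.random(n) < ta_rate
    state = rng.choice(BASE_STATES, size=n,
                       p=[config.state_mix[s] for s in BASE_STATES])
    atype = rng.choice(ANISO_TYPES_MIX, size=n,
                       p=[config.type_mix[t] for t in ANISO_TYPES_MIX])

    # --- shared base refraction (both eyes identical) -------------------
    se = np.empty(n)
    for s_name, mean_sd, lo, hi in (
        ("emmetrope", config.emmetropic_se,
         crit.myope_se + _MARGIN, hyp_thr - _MARGIN),
        ("simple_astigmat", config.emmetropic_se,
         crit.myope_se + _MARGIN, hyp_thr - _MARGIN),
        ("myope", config.myopic_se, -6.0, crit.myope_se - _MARGIN),
        ("hyperope", config.hyperopic_se, hyp_thr + _MARGIN, 4.5),
    ):
        m = state == s_name
        k = int(m.sum())
        lo_m = lo[m] if isinstance(lo, np.ndarray) else lo
        hi_m = hi[m] if isinstance(hi, np.ndarray) else hi
        se[m] = _truncnorm(rng, mean_sd[0], mean_sd[1], lo_m, hi_m, k)

    cyl = -np.abs(rng.normal(0.0, config.cylinder_halfnormal_sd, size=n))
    cyl = np.maximum(cyl, -(ast_thr - _MARGIN))
    m_ast = state == "simple_astigmat"
    cyl[m_ast] = _truncnorm(rng, config.astig_cyl[0], config.astig_cyl[1],
                            -3.0, -ast_thr[m_ast], int(m_ast.sum()))
    axis = rng.integers(0, 180, size=n).astype(float)

    se_r, se_l = se.copy(), se.copy()
    c_r, c_l = cyl.copy(), cyl.copy()
    ax_r, ax_l = axis.copy(), axis.copy()

    # --- anisometropia injection (worse eye = right, swapped later) -----
    iod = _draw_iod(rng, n, crit.aniso_cutoff, config.low_severity_share,
                    config.high_severity_max)
    cut_min = np.ceil(crit.aniso_cutoff / _GRID) * _GRID

    m = is_ta & (atype == "myopic")
    k = int(m.sum())
    worse = _truncnorm(rng, *config.myopic_se, -6.0, crit.myope_se - _MARGIN, k)
    d = np.minimum(iod[m], _snap(hyp_thr[m] - _MARGIN - worse))
    se_r[m], se_l[m] = worse, worse + np.maximum(d, cut_min)

    m = is_ta & (atype == "hyperopic")
    k = int(m.sum())
    worse = _truncnorm(rng, *config.hyperopic_se, hyp_thr[m] + _MARGIN, 4.5, k)
    d = np.minimum(iod[m], _snap(worse - crit.myope_se - _MARGIN))
    se_r[m], se_l[m] = worse, worse - np.maximum(d, cut_min)

    m = is_ta & (atype == "antimetropic")
    k = int(m.sum())
    se_r[m] = _truncnorm(rng, *config.myopic_se, -6.0, crit.myope_se - _MARGIN, k)
    se_l[m] = _truncnorm(rng, *config.hyperopic_se, hyp_thr[m] + _MARGIN, 4.5, k)

    m = is_ta & (atype == "sMA")
    k = int(m.sum())
    base_c = -_snap(rng.uniform(0.0, 0.5, size=k))
    d = np.minimum(iod[m], _snap(4.0 + base_c))
    c_l[m] = base_c
    c_r[m] = base_c - np.maximum(d, cut_min)
    ax_r[m] = rng.integers(0, 180, size=k).astype(float)

    swap = is_ta & (rng.random(n) < 0.5)
    se_r[swap], se_l[swap] = se_l[swap].copy(), se_r[swap].copy()
    c_r[swap], c_l[swap] = c_l[swap].copy(), c_r[swap].copy()
    ax_r[swap], ax_l[swap] = ax_l[swap].copy(), ax_r[swap].copy()

    # --- snap truth to the CSV grid -------------------------------------
    c_r, c_l = _snap(c_r), _snap(c_l)
    s_r = _snap(se_r - c_r / 2.0)
    s_l = _snap(se_l - c_l / 2.0)
    se_r, se_l = s_r + c_r / 2.0, s_l + c_l / 2.0
    ax_r[c_r == 0] = 0.0
    ax_l[c_l == 0] = 0.0

    ids = np.array([f"P{i + 1:05d}" for i in range(n)])
    truth = pd.DataFrame({
        "id": ids, "age": age, "cycle": cycle,
        "se_re": se_r, "c_re": c_r, "axis_re": ax_r.astype(int),
        "se_le": se_l, "c_le": c_l, "axis_le": ax_l.astype(int),
    })
    truth = classify_frame(truth, crit)
    truth["injected_ta"] = is_ta
    truth["injected_type"] = np.where(is_ta, atype, "none")
    truth["injected_state"] = np.where(is_ta, "anisometrope", state)

    wear_p = truth["category"].map(config.wear_rates).to_numpy(dtype=float)
    wears = np.where(rng.random(n) < wear_p, "yes", "no").astype(object)
    wears[rng.random(n) < config.wear_missing_rate] = "missing"

    data = pd.DataFrame({
        "id": ids, "age": age, "gender": gender, "residence": residence,
        "cycle": cycle, "wears_correction": wears,
    })
    for eye, (se_t, c_t, ax_t) in (("re", (se_r, c_r, ax_r)),
                                   ("le", (se_l, c_l, ax_l))):
        two_alpha = np.radians(2.0 * ax_t)
        j0_t = -(c_t / 2.0) * np.cos(two_alpha)
        j45_t = -(c_t / 2.0) * np.sin(two_alpha)
        for k in (1, 2, 3):
            se_k = se_t + rng.normal(0.0, config.noise_sd, size=n)
            j0_k = j0_t + rng.normal(0.0, config.noise_sd, size=n)
            j45_k = j45_t + rng.normal(0.0, config.noise_sd, size=n)
            c_k = -2.0 * np.hypot(j0_k, j45_k)
            a_k = np.degrees(np.arctan2(j45_k, j0_k)) / 2.0 % 180.0
            a_k = np.round(a_k) % 180
            a_k[np.round(c_k, 2) == 0] = 0
            data[f"{eye}_s{k}"] = np.round(se_k - c_k / 2.0, 2)
            data[f"{eye}_c{k}"] = np.round(c_k, 2)
            data[f"{eye}_a{k}"] = a_k.astype(int)
    data = data[DEMOGRAPHIC_COLUMNS + REPLICATE_COLUMNS]
    return CohortTable(data=data, truth=truth)


# ---------------------------------------------------------------------------
# hand-built worked fixture


def make_fixture() -> CohortTable:
    """A 12-participant hand-built cohort with hand-derived labels.

    Covers every person-level category and hits each classification
    boundary exactly once: myopia at SE -1.00; hyperopia at +1.25 (under 6)
    and +1.00 (6 and over); astigmatism at |C| 1.00 (under 6) and 1.25
    (6 and over); the anisometropia cutoff at SA 1.25; and the low/high
    severity edge at SA 2.00.  Readings are noise-free (three identical
    replicates), so classification must reproduce the embedded truth
    exactly.
    """
    # id, age, cycle, (RE s, c, a), (LE s, c, a), expected labels
    rows = [
        ("emmetrope", 8, "cycle1", (0.50, 0.0, 0), (0.50, 0.0, 0),
         dict(category="emmetrope", compound=False, is_ta=False,
              aniso_type="none", severity="none",
              re_state="emmetrope", le_state="emmetrope")),
        ("myope-boundary", 7, "cycle1", (-1.00, 0.0, 0), (-1.00, 0.0, 0),
         dict(category="myope", compound=False, is_ta=False,
              aniso_type="none", severity="none",
              re_state="myope", le_state="myope")),
        ("hyperope-young-boundary", 5, "preschool",
         (1.25, 0.0, 0), (1.25, 0.0, 0),
         dict(category="hyperope", compound=False, is_ta=False,
              aniso_type="none", severity="none",
              re_state="hyperope", le_state="hyperope")),
        ("hyperope-old-boundary", 10, "cycle2", (1.00, 0.0, 0), (1.00, 0.0, 0),
         dict(category="hyperope", compound=False, is_ta=False,
              aniso_type="none", severity="none",
              re_state="hyperope", le_state="hyperope")),
        # SE = 1.70 - 0.50 = +1.20 < +1.25 -> emmetrope; |C| = 1.00 -> astigmat
        ("young-simple-astigmat", 5, "preschool",
         (1.70, -1.00, 90), (1.70, -1.00, 90),
         dict(category="simple_astigmat", compound=False, is_ta=False,
              aniso_type="none", severity="none",
              re_state="emmetrope", le_state="emmetrope")),
        # SE = 1.60 - 0.60 = +1.00 -> hyperope; |C| = 1.20 < 1.25 -> not astigmat
        ("old-hyperope-subthreshold-cyl", 10, "cycle2",
         (1.60, -1.20, 180), (1.60, -1.20, 180),
         dict(category="hyperope", compound=False, is_ta=False,
              aniso_type="none", severity="none",
              re_state="hyperope", le_state="hyperope")),
        # SE = -2.025 -> myope; |C| = 1.25 -> astigmat => compound flag
        ("compound-astigmat-myope", 12, "cycle3",
         (-1.40, -1.25, 20), (-1.40, -1.25, 20),
         dict(category="myope", compound=True, is_ta=False,
              aniso_type="none", severity="none",
              re_state="myope", le_state="myope")),
        # SA = 1.25 exactly at cutoff -> TA, both eyes myopic -> myopic, low
        ("myopic-aniso-boundary", 13, "cycle3",
         (-2.25, 0.0, 0), (-1.00, 0.0, 0),
         dict(category="anisometrope", compound=False, is_ta=True,
              aniso_type="myopic", severity="low",
              re_state="myope", le_state="myope")),
        # SA = 2.00 exactly at the low/high edge -> high
        ("hyperopic-aniso-severity-edge", 7, "cycle1",
         (2.50, 0.0, 0), (0.50, 0.0, 0),
         dict(category="anisometrope", compound=False, is_ta=True,
              aniso_type="hyperopic", severity="high",
              re_state="hyperope", le_state="emmetrope")),
        ("antimetrope", 9, "cycle1", (-1.50, 0.0, 0), (1.25, 0.0, 0),
         dict(category="anisometrope", compound=False, is_ta=True,
              aniso_type="antimetropic", severity="high",
              re_state="myope", le_state="hyperope")),
        # SE 0 in both eyes; MA = |-2.50 - (-1.00)| = 1.50 -> sMA, low
        ("sMA", 11, "cycle2", (1.25, -2.50, 45), (0.50, -1.00, 45),
         dict(category="anisometrope", compound=False, is_ta=True,
              aniso_type="sMA", severity="low",
              re_state="emmetrope", le_state="emmetrope")),
        # SA = 1.24 just under the cutoff -> not anisometropic, both myopic
        ("subthreshold-aniso", 14, "cycle3",
         (-2.24, 0.0, 0), (-1.00, 0.0, 0),
         dict(category="myope", compound=False, is_ta=False,
              aniso_type="none", severity="none",
              re_state="myope", le_state="myope")),
    ]
    genders = ["female", "male"] * 6
    residences = ["rural", "urban"] * 6
    wears = ["no"] * 7 + ["yes", "yes", "yes", "no", "yes"]
    data_rows, truth_rows = [], []
    for i, (pid, page, pcycle, re_r, le_r, exp) in enumerate(rows):
        row = {"id": pid, "age": page, "gender": genders[i],
               "residence": residences[i], "cycle": pcycle,
               "wears_correction": wears[i]}
        for eye, (s, c, a) in (("re", re_r), ("le", le_r)):
            for k in (1, 2, 3):
                row[f"{eye}_s{k}"] = s
                row[f"{eye}_c{k}"] = c
                row[f"{eye}_a{k}"] = a
        data_rows.append(row)
        truth_rows.append({
            "id": pid, "age": page, "cycle": pcycle,
            "se_re": re_r[0] + re_r[1] / 2.0, "c_re": re_r[1],
            "se_le": le_r[0] + le_r[1] / 2.0, "c_le": le_r[1],
            "category": exp["category"], "compound_astigmat": exp["compound"],
            "is_ta": exp["is_ta"], "aniso_type": exp["aniso_type"],
            "severity": exp["severity"], "re_state": exp["re_state"],
            "le_state": exp["le_state"],
        })
    data = pd.DataFrame(data_rows)[DEMOGRAPHIC_COLUMNS + REPLICATE_COLUMNS]
    return CohortTable(data=data, truth=pd.DataFrame(truth_rows))
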