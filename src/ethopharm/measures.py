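"""Per-animal behavioral outcome measures.

Eight measures are derived before surgery (thermal reflex latencies,
locomotion under vehicle and oxycodone, conditioned place preference and
its extinction) and six after sham/CCI surgery.  Each function implements
one measure's calculation rule; :func:`build_measure_table` assembles the
full animals x measures matrix from a tidy :class:`~ethopharm.synthetic.StudyDataset`.

Sign conventions: the reflex-pain, locomotor-habituation and CPP-extinction
rates are *inverted* regression slopes, so a decline over sessions yields a
positive value; the behavioral-sensitization rate is an uninverted slope,
so a rise yields a positive value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, InsufficientDataError
from . import synthetic as syn

__all__ = [
    "PRE_MEASURES", "POST_MEASURES", "ALL_MEASURES", "MeasureTable", "PlaceTest",
    "paw_latency", "session_latency", "ols_slope",
    "basal_reflex_pain", "rate_change_reflex_pain",
    "basal_loco", "raw_habituation_slope", "rate_loco_habituation",
    "acute_oxy_loco", "rate_behavioral_sensitization",
    "cpp_score", "cpp_at_first_test", "rate_cpp_extinction",
    "post_surgery_reflex_measures", "post_surgery_cpp_measures",
    "human_equivalent_dose", "signed_sqrt", "build_measure_table",
]

from .panels import ALL_MEASURES, POST_MEASURES, PRE_MEASURES  # noqa: F401

CPP_METHODS = ("pre_subtraction", "veh_subtraction", "proportion")


@dataclass
class PlaceTest:
    """Compartment-time triple for one place test."""

    day: int
    oxy_s: float
    veh_s: float
    center_s: float


@dataclass
class MeasureTable:
    """Animals x measures matrix plus per-column transform flags."""

    data: pd.DataFrame
    transform_flags: dict[str, bool] = field(default_factory=dict)


def paw_latency(trials: Sequence[float]) -> float:
    """Average of the two numerically closest withdrawal latencies.

    Two or more trials are taken per paw; the two with the smallest absolute
    difference are averaged.  Ties are broken by the earliest pair in
    acquisition order, which makes the rule deterministic.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise InsufficientDataError("paw_latency needs at least 2 trials")
    best = None
    for i in range(len(trials)):
        for j in range(i + 1, len(trials)):
            gap = abs(trials[i] - trials[j])
            if best is None or gap < best[0]:
                best = (gap, i, j)
    _, i, j = best
    return (trials[i] + trials[j]) / 2.0


def session_latency(paw_trials: Mapping[str, Sequence[float]]) -> float:
    """Session withdrawal latency: mean of the two per-paw values."""
    if len(paw_trials) != 2:
        raise InsufficientDataError("session_latency needs both paws")
    return float(np.mean([paw_latency(t) for t in paw_trials.values()]))


def ols_slope(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares fit; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y must have equal length")
    if x.size < 2 or np.ptp(x) == 0:
        raise InsufficientDataError("ols_slope needs >= 2 distinct x values")
    xc = x - x.mean()
    slope = float((xc @ (y - y.mean())) / (xc @ xc))
    return slope, float(y.mean() - slope * x.mean())


def _sorted_by_day(days: Sequence[float], values: Sequence[float]):
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(days, kind="stable")
    return days[order], values[order]


def basal_reflex_pain(days: Sequence[float], session_latencies: Sequence[float]) -> float:
    """Session latency of the earliest pre-surgery reflex test (day 6)."""
    if len(session_latencies) == 0:
        raise InsufficientDataError("no reflex sessions")
    _, lat = _sorted_by_day(days, session_latencies)
    return float(lat[0])


def rate_change_reflex_pain(days: Sequence[float], session_latencies: Sequence[float]) -> float:
    """Inverted OLS slope of session latencies over session index 1..k (s/session).

    Positive values mean latencies declined, i.e. sensitization to the
    repeated thermal stimulus.
    """
    if len(session_latencies) < 2:
        raise InsufficientDataError("need >= 2 reflex sessions")
    _, lat = _sorted_by_day(days, session_latencies)
    slope, _ = ols_slope(np.arange(1, lat.size + 1), lat)
    return -slope


def basal_loco(days: Sequence[float], veh_counts: Sequence[float]) -> float:
    """Beam-break counts after vehicle on the first conditioning day."""
    if len(veh_counts) == 0:
        raise InsufficientDataError("no VEH conditioning sessions")
    _, counts = _sorted_by_day(days, veh_counts)
    return float(counts[0])


def raw_habituation_slope(days: Sequence[float], veh_counts: Sequence[float]) -> float:
    """Untransformed inverted slope of VEH counts over session index (counts/session)."""
    if len(veh_counts) < 2:
        raise InsufficientDataError("need >= 2 VEH sessions")
    _, counts = _sorted_by_day(days, veh_counts)
    slope, _ = ols_slope(np.arange(1, counts.size + 1), counts)
    return -slope


def signed_sqrt(x: float) -> float:
    """sign(x) * sqrt(|x|); monotone extension of the square root to negatives."""
    return math.copysign(math.sqrt(abs(x)), x) if x != 0 else 0.0


def rate_loco_habituation(raw_slopes: pd.Series) -> tuple[pd.Series, bool]:
    """Cohort-level habituation measure with a normality-triggered transform.

    The raw per-animal inverted slopes are tested for normality
    (Shapiro-Wilk).  If p < 0.05 the signed square root is applied to every
    animal and the transform flag is set; otherwise the raw slopes are
    returned untouched.  The transform is applied to all animals or none so
    the column stays on a single scale.
    """
    raw = raw_slopes.astype(float)
    vals = raw.dropna().to_numpy()
    flag = False
    if vals.size >= 3 and np.ptp(vals) > 0:
        _, p = sps.shapiro(vals)
        flag = bool(p < 0.05)
    if flag:
        return raw.map(lambda v: signed_sqrt(v) if pd.notna(v) else v), True
    return raw, False


def acute_oxy_loco(day13_oxy: float, day13_veh: float) -> float:
    """First-day OXY counts normalized by subtracting same-day VEH counts."""
    return float(day13_oxy) - float(day13_veh)


def rate_behavioral_sensitization(days: Sequence[float], oxy_counts: Sequence[float],
                                  veh_counts: Sequence[float]) -> float:
    """OLS slope of VEH-normalized OXY locomotion over the conditioning
    sessions (counts/session).  Not inverted: a rise is positive.
    """
    if len(oxy_counts) != len(veh_counts):
        raise InsufficientDataError("unpaired OXY/VEH conditioning days")
    if len(oxy_counts) < 2:
        raise InsufficientDataError("need >= 2 paired conditioning days")
    _, oxy = _sorted_by_day(days, oxy_counts)
    _, veh = _sorted_by_day(days, veh_counts)
    slope, _ = ols_slope(np.arange(1, oxy.size + 1), oxy - veh)
    return slope


def cpp_score(test: PlaceTest, pretest: PlaceTest, method: str = "pre_subtraction") -> float:
    """Conditioned-place-preference score for one test.

    ``pre_subtraction`` (the primary scoring): OXY-compartment time minus
    the pre-test OXY-compartment time.  ``veh_subtraction``: OXY minus VEH
    time within the test.  ``proportion``: OXY / (OXY + VEH) within the
    test.
    """
    if method == "pre_subtraction":
        return test.oxy_s - pretest.oxy_s
    if method == "veh_subtraction":
        return test.oxy_s - test.veh_s
    if method == "proportion":
        denom = test.oxy_s + test.veh_s
        if denom == 0:
            raise InsufficientDataError("proportion undefined: no time outside center")
        return test.oxy_s / denom
    raise ConfigError(f"unknown CPP scoring method {method!r}; "
                      f"expected one of {CPP_METHODS}")


def cpp_at_first_test(pretest: PlaceTest, tests: Sequence[PlaceTest]) -> float:
    """Pre-test-subtracted CPP at the first post-conditioning test (day 17)."""
    if not tests:
        raise InsufficientDataError("no post-conditioning place tests")
    first = min(tests, key=lambda t: t.day)
    return cpp_score(first, pretest, "pre_subtraction")


def rate_cpp_extinction(pretest: PlaceTest, tests: Sequence[PlaceTest]) -> float:
    """Inverted OLS slope of CPP scores against *calendar day* (s/day).

    The abscissa is the actual test day (17, 24, ... 51), not the test
    index: the printed unit of this measure is seconds per day and the
    extinction tests are unevenly spaced.
    """
    if len(tests) < 2:
        raise InsufficientDataError("need >= 2 post-conditioning tests")
    tests = sorted(tests, key=lambda t: t.day)
    days = [t.day for t in tests]
    scores = [cpp_score(t, pretest, "pre_subtraction") for t in tests]
    slope, _ = ols_slope(days, scores)
    return -slope


def post_surgery_reflex_measures(
    day6_surg_paw_latency: float,
    post_sessions: Sequence[Mapping[str, Sequence[float]]],
    surgeried_paw: str,
) -> tuple[float, float, float]:
    """The three post-surgery reflex measures.

    Returns (a) mean surgeried-paw latency over the three post-surgery
    sessions, (b) the same expressed as a percentage of the non-surgeried
    paw, and (c) the change of (a) from the day-6 surgeried-paw latency
    (negative = sensitized).
    """
    if not post_sessions:
        raise InsufficientDataError("no post-surgery reflex sessions")
    surg, nonsurg = [], []
    for session in post_sessions:
        if surgeried_paw not in session or len(session) != 2:
            raise InsufficientDataError("both paws required in each session")
        for paw, trials in session.items():
            (surg if paw == surgeried_paw else nonsurg).append(paw_latency(trials))
    mean_surg = float(np.mean(surg))
    mean_nonsurg = float(np.mean(nonsurg))
    return (mean_surg,
            100.0 * mean_surg / mean_nonsurg,
            mean_surg - day6_surg_paw_latency)


def post_surgery_cpp_measures(tests_by_day: Mapping[int, PlaceTest]) -> tuple[float, float, float]:
    """Day-66 OXY-compartment time minus the day-10, day-17 and day-51 times.

    These quantify post-surgery CPP relative to the pre-test, to the CPP
    expressed immediately after conditioning, and to the end of extinction.
    """
    required = (syn.PRETEST_DAY, syn.CPP_TEST_DAYS[0], syn.CPP_TEST_DAYS[-1],
                syn.POST_TEST_DAY)
    for day in required:
        if day not in tests_by_day:
            raise InsufficientDataError(f"missing place test on day {day}")
    final = tests_by_day[syn.POST_TEST_DAY].oxy_s
    return (final - tests_by_day[syn.PRETEST_DAY].oxy_s,
            final - tests_by_day[syn.CPP_TEST_DAYS[0]].oxy_s,
            final - tests_by_day[syn.CPP_TEST_DAYS[-1]].oxy_s)


def human_equivalent_dose(animal_dose_mg_per_kg: float,
                          species_divisor: float = 6.2,
                          human_mass_kg: float = 70.0) -> float:
    """Body-surface-area dose translation, reported to 1 decimal place (mg).

    The rat-to-human conversion divides the animal dose by the
    species-specific factor (6.2 for rat) and scales by the reference human
    mass: 0.56 mg/kg in the rat corresponds to 6.3 mg in a 70 kg human.
    """
    if species_divisor <= 0 or human_mass_kg <= 0:
        raise ConfigError("divisor and mass must be positive")
    return round(animal_dose_mg_per_kg / species_divisor * human_mass_kg, 1)


# ---------------------------------------------------------------------------
# table assembly


def _reflex_sessions(rx: pd.DataFrame) -> dict[int, dict[str, list[float]]]:
    """day -> paw -> trial latencies, in acquisition order."""
    out: dict[int, dict[str, list[float]]] = {}
    rx = rx.sort_values(["day", "paw", "trial_index"], kind="stable")
    for day, paw, lat in zip(rx["day"].to_numpy(), rx["paw"].to_numpy(),
                             rx["latency_s"].to_numpy()):
        out.setdefault(int(day), {}).setdefault(paw, []).append(float(lat))
    return out


def _place_tests_of(pt: pd.DataFrame) -> dict[int, PlaceTest]:
    out: dict[int, dict[str, float]] = {}
    for day, comp, t in zip(pt["day"].to_numpy(), pt["compartment"].to_numpy(),
                            pt["time_s"].to_numpy()):
        out.setdefault(int(day), {})[comp] = float(t)
    return {d: PlaceTest(day=d, oxy_s=v["OXY"], veh_s=v["VEH"], center_s=v["CENTER"])
            for d, v in out.items() if {"OXY", "VEH", "CENTER"} <= set(v)}


def _by_animal(df: pd.DataFrame) -> dict:
    return {a: g for a, g in df.groupby("animal", sort=False)}


def build_measure_table(dataset: syn.StudyDataset) -> MeasureTable:
    """Derive all 14 measures for every animal in the dataset.

    Animals missing a phase get missing values in that phase's columns only;
    nothing is imputed.  The habituation transform decision is made once at
    cohort level (see :func:`rate_loco_habituation`) and recorded in
    ``transform_flags``.
    """
    if dataset.animals.empty:
        raise InsufficientDataError("dataset contains no animals")
    animals = dataset.animals.set_index("animal")
    table = pd.DataFrame(index=animals.index.copy(), columns=list(ALL_MEASURES),
                         dtype=float)
    if table.index.has_duplicates:
        raise InsufficientDataError("duplicated animal ids")

    rx_by = _by_animal(dataset.reflex_trials)
    cond_by = _by_animal(dataset.conditioning)
    pt_by = _by_animal(dataset.place_tests)
    empty = dataset.reflex_trials.iloc[0:0]

    raw_hab = pd.Series(np.nan, index=table.index)
    values: dict[str, dict] = {m: {} for m in ALL_MEASURES}

    for animal in table.index:
        rx = rx_by.get(animal, empty)
        sessions = _reflex_sessions(rx)
        pre_sessions = {d: v for d, v in sessions.items() if d < syn.SURGERY_DAY}
        post_sessions = {d: v for d, v in sessions.items() if d >= syn.SURGERY_DAY}
        surg_paw = animals.loc[animal, "surgeried_paw"]

        # reflex phase
        day6_surg = None
        try:
            days = sorted(pre_sessions)
            lats = [session_latency(pre_sessions[d]) for d in days]
            values["Basal reflex pain"][animal] = basal_reflex_pain(days, lats)
            values["Rate of change in reflex pain"][animal] = \
                rate_change_reflex_pain(days, lats)
            day6_surg = paw_latency(pre_sessions[days[0]][surg_paw])
        except (InsufficientDataError, KeyError, IndexError):
            pass

        # conditioning phase
        cond = cond_by.get(animal)
        if cond is not None:
            try:
                cond = cond.sort_values("day", kind="stable")
                veh = cond[cond["drug"] == "VEH"]
                oxy = cond[cond["drug"] == "OXY"]
                if len(veh) and len(veh) == len(oxy):
                    vdays = veh["day"].to_numpy()
                    vcounts = veh["counts"].to_numpy()
                    ocounts = oxy["counts"].to_numpy()
                    values["Basal loco"][animal] = basal_loco(vdays, vcounts)
                    raw_hab[animal] = raw_habituation_slope(vdays, vcounts)
                    values["Acute OXY loco"][animal] = acute_oxy_loco(
                        ocounts[0], vcounts[0])
                    values["Rate of behavioral sensitization"][animal] = \
                        rate_behavioral_sensitization(vdays, ocounts, vcounts)
            except InsufficientDataError:
                pass

        # place-preference phases
        tests = _place_tests_of(pt_by.get(animal, dataset.place_tests.iloc[0:0]))
        pre = tests.get(syn.PRETEST_DAY)
        ext_tests = [t for d, t in tests.items()
                     if syn.PRETEST_DAY < d < syn.SURGERY_DAY]
        if pre is not None and ext_tests:
            try:
                values["CPP at first test"][animal] = cpp_at_first_test(pre, ext_tests)
                values["Rate of CPP extinction"][animal] = \
                    rate_cpp_extinction(pre, ext_tests)
            except InsufficientDataError:
                pass

        # post-surgery phase
        if post_sessions and day6_surg is not None:
            try:
                a, b, c = post_surgery_reflex_measures(
                    day6_surg, [post_sessions[d] for d in sorted(post_sessions)],
                    surg_paw)
                values["Reflex pain–surg. paw"][animal] = a
                values["Reflex pain–surg. paw vs. non-surg. paw"][animal] = b
                values["Reflex pain–Δ surg. paw"][animal] = c
            except InsufficientDataError:
                pass
        try:
            d1, d2, d3 = post_surgery_cpp_measures(tests)
            values["CPP–Δ pre-test CPP"][animal] = d1
            values["CPP–Δ post-cond. CPP"][animal] = d2
            values["CPP–Δ pre-surg. CPP"][animal] = d3
        except InsufficientDataError:
            pass

    for measure, vals in values.items():
        if vals:
            table[measure] = pd.Series(vals)
    hab, flag = rate_loco_habituation(raw_hab)
    table["Rate of loco habituation"] = hab
    flags = {m: False for m in ALL_MEASURES}
    flags["Rate of loco habituation"] = flag
    return MeasureTable(data=table, transform_flags=flags)
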