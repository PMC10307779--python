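"""Synthetic behavioral cohorts with controllable latent trait structure.

The study this package analyses follows each rat through five phases:
repeated thermal hindpaw reflex testing, conditioned-place-preference (CPP)
induction with vehicle/oxycodone (VEH/OXY) conditioning sessions, extinction
testing, sham or chronic-constriction-injury (CCI) surgery, and post-surgery
re-testing.  No per-animal data are deposited, so every downstream stage of
the pipeline is validated against cohorts generated here.

Each animal carries eight latent traits (one per pre-surgery outcome
measure).  Traits are jointly Gaussian with a configurable correlation
matrix and are mapped *linearly* onto the session-level observables, so the
measure-derivation pipeline can be checked by round-trip: with measurement
noise switched off it must recover every planted trait exactly, and at large
n the Pearson correlations between derived measures must approach the
planted latent correlations.

The locomotor-habituation trait is planted on the square-root scale (the
vehicle locomotion decline per session equals the trait squared) so that the
square-root transform applied downstream maps the derived slope back onto
the trait itself.

Randomness: one global seed drives a per-animal, per-phase stream-split RNG
(``numpy.random.SeedSequence.spawn``), so enlarging the cohort never
perturbs the data of existing animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "TRAITS",
    "GeneratorConfig",
    "StudyDataset",
    "default_config",
    "validation_config",
    "block_latent_corr",
    "three_block_config",
    "three_block_membership",
    "TRAIT_MEASURE",
    "four_block_measure_frame",
    "four_block_membership",
    "sample_latent_traits",
    "generate_study",
]

#: Latent trait names, in canonical order.  Units match the downstream
#: outcome measure each trait is planted into.
TRAITS = (
    "basal_latency",        # s      -> Basal reflex pain
    "latency_decline",      # s/sess -> Rate of change in reflex pain
    "basal_loco",           # counts -> Basal loco
    "loco_habituation",     # sqrt(counts/sess) -> Rate of loco habituation
    "oxy_loco_boost",       # counts -> Acute OXY loco
    "sensitization_slope",  # counts/sess -> Rate of behavioral sensitization
    "cpp_strength",         # s      -> CPP at first test
    "extinction_rate",      # s/day  -> Rate of CPP extinction
)

#: Latency bounds enforced by the thermal apparatus (cutoff to prevent
#: tissue damage; minimum accepted withdrawal).
LATENCY_MIN_S = 5.0
LATENCY_MAX_S = 20.0

#: Study-day layout of the five phases.
REFLEX_DAYS = (6, 7, 8, 9)
CONDITIONING_DAYS = (13, 14, 15, 16)
PRETEST_DAY = 10
CPP_TEST_DAYS = (17, 24, 28, 38, 45, 49, 51)
POST_REFLEX_DAYS = (63, 64, 65)
POST_TEST_DAY = 66
SURGERY_DAY = 56


@dataclass
class GeneratorConfig:
    """Full parameterisation of a synthetic cohort.

    ``latent_corr`` must be symmetric positive semidefinite with unit
    diagonal; ``trait_means`` / ``trait_sds`` are in the units of the
    downstream measures (see :data:`TRAITS`).
    """

    n_animals: int = 15
    seed: int = 0
    latent_corr: np.ndarray = field(default_factory=lambda: np.eye(len(TRAITS)))
    trait_means: np.ndarray = field(default_factory=lambda: np.zeros(len(TRAITS)))
    trait_sds: np.ndarray = field(default_factory=lambda: np.zeros(len(TRAITS)))
    trial_noise_sd: float = 0.4          # s, per reflex trial
    count_dispersion: float = 0.002      # NegBin: var = mu + d * mu^2
    cpp_noise_sd: float = 15.0           # s, per place test
    test_length_s: float = 1200.0
    n_reflex_sessions: int = 4
    n_trials_per_paw: int = 3
    conditioning_days: int = 4
    cpp_test_days: Sequence[int] = CPP_TEST_DAYS
    pretest_oxy_mean_s: float = 393.4
    pretest_oxy_sd_s: float = 92.2
    pretest_center_s: float = 413.2
    center_drift_s_per_test: float = 10.0
    cci_effect_s: float = 8.0            # surgeried-paw latency reduction (CCI only)
    cci_cpp_effect_s: float = -60.0      # shift of day-66 OXY-compartment time (CCI only)

    def __post_init__(self) -> None:
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        self.trait_sds = np.asarray(self.trait_sds, dtype=float)

    def validate(self) -> "GeneratorConfig":
        k = len(TRAITS)
        if self.n_animals < 3:
            raise ConfigError("n_animals must be >= 3")
        if self.latent_corr.shape != (k, k):
            raise ConfigError(f"latent_corr must be {k}x{k}")
        if not np.allclose(self.latent_corr, self.latent_corr.T, atol=1e-12):
            raise ConfigError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0, atol=1e-12):
            raise ConfigError("latent_corr must have unit diagonal")
        if np.any(np.abs(self.latent_corr) > 1 + 1e-12):
            raise ConfigError("latent_corr entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(self.latent_corr).min() < -1e-8:
            raise ConfigError("latent_corr is not positive semidefinite")
        if self.trait_means.shape != (k,) or self.trait_sds.shape != (k,):
            raise ConfigError(f"trait_means and trait_sds must have length {k}")
        for name in ("trait_sds",):
            if np.any(getattr(self, name) < 0):
                raise ConfigError(f"{name} must be non-negative")
        for name in ("trial_noise_sd", "count_dispersion", "cpp_noise_sd",
                     "pretest_oxy_sd_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.test_length_s <= 0:
            raise ConfigError("test_length_s must be positive")
        if self.n_reflex_sessions < 1 or self.conditioning_days < 1:
            raise ConfigError("need at least one session per phase")
        if self.n_trials_per_paw < 2:
            raise ConfigError("need at least two trials per paw")
        if len(self.cpp_test_days) < 2:
            raise ConfigError("need at least two CPP test days")
        return self

    def trait_mean(self, name: str) -> float:
        return float(self.trait_means[TRAITS.index(name)])


@dataclass
class StudyDataset:
    """Tidy session-level records for one cohort.

    ``reflex_trials``: animal, day, session, paw, trial_index, latency_s
    ``conditioning``:  animal, day, drug, counts
    ``place_tests``:   animal, day, compartment, time_s
    ``animals``:       animal, sex, surgery_arm, surgeried_paw
    """

    reflex_trials: pd.DataFrame
    conditioning: pd.DataFrame
    place_tests: pd.DataFrame
    animals: pd.DataFrame


def _corr(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    m = np.eye(len(TRAITS))
    for (a, b), r in pairs.items():
        i, j = TRAITS.index(a), TRAITS.index(b)
        m[i, j] = m[j, i] = r
    return m


def default_config(n_animals: int = 15, seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults anchored to the source cohort's group values.

    Means follow the printed group means (initial withdrawal latency 18.7 s
    declining to 16.7 s over four sessions; first-day vehicle locomotion
    675.3 counts; acute OXY-stimulated locomotion 441.7 counts;
    sensitization slope 104.0 counts/session; habituation slope 8.7 on the
    square-root scale; extinction slope 4.4 s/day; pre-test time in the
    to-be-OXY-paired compartment 393.4 s with SD 92.2 s).  Between-animal
    SDs are the printed SEMs scaled by sqrt(15).  The latent correlation
    plants the two headline associations: basal reflex latency vs.
    behavioral sensitization at -0.7, and basal locomotion vs. locomotor
    habituation at +0.6.
    """
    cfg = GeneratorConfig(
        n_animals=n_animals,
        seed=seed,
        latent_corr=_corr({
            ("basal_latency", "sensitization_slope"): -0.7,
            ("basal_loco", "loco_habituation"): 0.6,
        }),
        trait_means=np.array([18.7, 2.0 / 3.0, 675.3, 8.7, 441.7, 104.0, 100.0, 4.4]),
        trait_sds=np.array([0.9, 0.55, 218.0, 2.7, 594.0, 168.0, 125.0, 3.5]),
    )
    return cfg.validate()


def validation_config(
    n_animals: int = 200, seed: int = 0, noiseless: bool = False
) -> GeneratorConfig:
    """Recovery-validation regime: traits in the interior of the dynamic range.

    The study-condition defaults put basal latency within ~1.5 SD of the 20 s
    apparatus cutoff and low-locomotion animals near the zero-count floor,
    so censoring — not the pipeline — limits round-trip recovery there.
    This config keeps every planted trajectory linear with overwhelming
    probability, which is the regime in which exact (noiseless) and
    statistical (noisy) parameter recovery are well-posed.  Between-animal
    SDs deliberately dominate measurement noise, mirroring the high
    test-retest reliability these assays are designed for.
    """
    cfg = GeneratorConfig(
        n_animals=n_animals,
        seed=seed,
        latent_corr=_corr({
            ("basal_latency", "sensitization_slope"): -0.7,
            ("basal_loco", "loco_habituation"): 0.6,
        }),
        trait_means=np.array([15.0, 1.0, 1500.0, 14.0, 1500.0, 100.0, 100.0, 3.0]),
        trait_sds=np.array([1.5, 0.5, 200.0, 3.0, 400.0, 150.0, 50.0, 2.0]),
        pretest_oxy_sd_s=40.0,
        count_dispersion=0.0002,
    )
    if noiseless:
        cfg = replace(cfg, trial_noise_sd=0.0, count_dispersion=0.0, cpp_noise_sd=0.0)
    return cfg.validate()


def block_latent_corr(
    blocks: Sequence[Sequence[str]],
    rho: float = 0.8,
    signs: dict[str, int] | None = None,
) -> np.ndarray:
    """Block-structured latent correlation: |r| = ``rho`` within each block,
    0 across blocks.  ``signs`` maps trait -> +/-1; within a block,
    corr(a, b) = sign(a) * sign(b) * rho, which keeps the matrix positive
    semidefinite for any sign pattern (compound symmetry up to sign flips).
    """
    signs = signs or {}
    m = np.eye(len(TRAITS))
    for block in blocks:
        for a in block:
            for b in block:
                if a == b:
                    continue
                s = signs.get(a, 1) * signs.get(b, 1)
                i, j = TRAITS.index(a), TRAITS.index(b)
                m[i, j] = m[j, i] = s * rho
    return m


#: Cluster membership of the pre-surgery measures reported by the source
#: analysis: {reflex pain, sensitization, extinction}, {locomotion,
#: habituation, acute drug locomotion, rate of change in reflex pain}, and
#: CPP magnitude on its own.
THREE_BLOCKS = (
    ("basal_latency", "sensitization_slope", "extinction_rate"),
    ("basal_loco", "loco_habituation", "oxy_loco_boost", "latency_decline"),
    ("cpp_strength",),
)


#: Outcome measure each latent trait is planted into.
TRAIT_MEASURE = {
    "basal_latency": "Basal reflex pain",
    "latency_decline": "Rate of change in reflex pain",
    "basal_loco": "Basal loco",
    "loco_habituation": "Rate of loco habituation",
    "oxy_loco_boost": "Acute OXY loco",
    "sensitization_slope": "Rate of behavioral sensitization",
    "cpp_strength": "CPP at first test",
    "extinction_rate": "Rate of CPP extinction",
}


def three_block_membership() -> list[frozenset]:
    """The planted pre-surgery block partition, as measure names."""
    return [frozenset(TRAIT_MEASURE[t] for t in block) for block in THREE_BLOCKS]


def three_block_config(
    n_animals: int = 200, seed: int = 0, rho: float = 0.8
) -> GeneratorConfig:
    """Validation regime with the three-cluster latent structure planted.

    Basal latency enters its block negatively (shorter latency, i.e. higher
    pain sensitivity, goes with faster sensitization and extinction).
    """
    cfg = validation_config(n_animals=n_animals, seed=seed)
    cfg = replace(
        cfg,
        latent_corr=block_latent_corr(
            THREE_BLOCKS, rho=rho, signs={"basal_latency": -1}
        ),
    )
    return cfg.validate()


#: Planar blob centers for the combined-panel clustering fixture, in the
#: 1-|r| metric.  Because that metric caps distances at 1, four *mutually*
#: equidistant measure blocks are tetrahedral and cannot embed in the plane;
#: these centers instead fix every between-block correlation to
#: 1 - ||c_a - c_b||, giving a geometry that 2-D classical scaling
#: reproduces faithfully.
FOUR_BLOCK_CENTERS = np.array([[0.0, 0.0], [0.5, 0.0], [1.0, 0.0], [0.5, 0.45]])
FOUR_BLOCK_SIZES = (4, 4, 3, 3)


def four_block_measure_frame(n_animals: int = 200, seed: int = 0,
                             rho: float = 0.9) -> pd.DataFrame:
    """Combined-panel (14-measure) fixture with four planted blocks.

    Draws a multivariate-normal animals x measures table whose correlation
    is ``rho`` within each block and ``1 - distance`` between the planted
    planar block centers otherwise.  Used to validate that the full
    clustering pipeline recovers a four-cluster structure on the combined
    pre+post-surgery panel.
    """
    from .panels import ALL_MEASURES

    names = list(ALL_MEASURES)
    k = len(names)
    corr = np.eye(k)
    idx, i0 = [], 0
    for sz in FOUR_BLOCK_SIZES:
        idx.append(list(range(i0, i0 + sz)))
        i0 += sz
    for a in range(len(idx)):
        for b in range(len(idx)):
            d = float(np.linalg.norm(FOUR_BLOCK_CENTERS[a] - FOUR_BLOCK_CENTERS[b]))
            r = rho if a == b else max(1.0 - d, 0.0)
            for i in idx[a]:
                for j in idx[b]:
                    if i != j:
                        corr[i, j] = r
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_animals, k)) @ np.linalg.cholesky(corr).T
    return pd.DataFrame(data, columns=names,
                        index=pd.RangeIndex(1, n_animals + 1, name="animal"))


def four_block_membership() -> list[frozenset]:
    """The planted block partition of the combined panel, as measure names."""
    from .panels import ALL_MEASURES

    names = list(ALL_MEASURES)
    out, i0 = [], 0
    for sz in FOUR_BLOCK_SIZES:
        out.append(frozenset(names[i0:i0 + sz]))
        i0 += sz
    return out


def _sqrt_factor(corr: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root of a correlation matrix."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-8:
        raise ConfigError("latent_corr is not positive semidefinite")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def _animal_streams(config: GeneratorConfig) -> list[list[np.random.SeedSequence]]:
    root = np.random.SeedSequence(config.seed)
    return [child.spawn(5) for child in root.spawn(config.n_animals)]


def sample_latent_traits(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one row of latent traits per animal (multivariate normal).

    Deterministic for a fixed seed; each animal consumes an independent
    sub-stream, so traits of animal *i* do not depend on ``n_animals``.
    """
    config.validate()
    factor = _sqrt_factor(config.latent_corr)
    rows = []
    for streams in _animal_streams(config):
        rng = np.random.Generator(np.random.PCG64(streams[0]))
        z = rng.standard_normal(len(TRAITS))
        rows.append(config.trait_means + config.trait_sds * (factor @ z))
    return pd.DataFrame(rows, columns=list(TRAITS),
                        index=pd.RangeIndex(1, config.n_animals + 1, name="animal"))


def _negbin(rng: np.random.Generator, mu: float, dispersion: float) -> float:
    """Count observation with mean ``mu`` and variance mu + d*mu^2.

    dispersion == 0 is the deterministic limit (returns the mean itself so
    that noiseless cohorts are exactly linear); dispersion > 0 draws an
    integer negative-binomial count.
    """
    mu = max(mu, 0.0)
    if dispersion == 0.0:
        return mu
    if mu == 0.0:
        return 0.0
    r = 1.0 / dispersion
    p = r / (r + mu)
    return float(rng.negative_binomial(r, p))


def _compose_place_test(oxy: float, veh: float, center: float,
                        total: float) -> tuple[float, float, float]:
    """Clip negative compartment times to zero and rescale to the test length."""
    t = np.clip(np.array([oxy, veh, center]), 0.0, None)
    s = t.sum()
    if s == 0.0:
        t = np.array([total / 3] * 3)
    else:
        t = t * (total / s)
    return float(t[0]), float(t[1]), float(t[2])


def generate_study(config: GeneratorConfig) -> StudyDataset:
    """Simulate the full five-phase study for one cohort.

    Per animal: reflex trials declining linearly by ``latency_decline`` per
    session (clipped to the 5-20 s apparatus window trial by trial); paired
    VEH/OXY conditioning counts, with the VEH mean falling by
    ``loco_habituation**2`` per session and the OXY mean exceeding same-day
    VEH by ``oxy_loco_boost + sensitization_slope * (session-1)``; a
    pre-test and seven extinction place tests whose OXY-compartment time
    rises by ``cpp_strength`` then falls by ``extinction_rate`` s/day while
    center time drifts upward; a balanced sham/CCI assignment; three
    post-surgery reflex sessions with the surgeried paw reduced by
    ``cci_effect_s`` in CCI animals; and one post-surgery place test.
    """
    config.validate()
    traits = sample_latent_traits(config)
    streams = _animal_streams(config)
    n_sessions = config.n_reflex_sessions
    n_cond = config.conditioning_days
    test_days = list(config.cpp_test_days)

    reflex_rows, cond_rows, place_rows, animal_rows = [], [], [], []

    for idx, (animal, tr) in enumerate(traits.iterrows()):
        _, s_reflex, s_cond, s_cpp, s_post = streams[idx]
        rng_reflex = np.random.Generator(np.random.PCG64(s_reflex))
        rng_cond = np.random.Generator(np.random.PCG64(s_cond))
        rng_cpp = np.random.Generator(np.random.PCG64(s_cpp))
        rng_post = np.random.Generator(np.random.PCG64(s_post))

        arm = "sham" if idx % 2 == 0 else "cci"
        sex = "M" if idx % 2 == 0 else "F"
        animal_rows.append({"animal": animal, "sex": sex, "surgery_arm": arm,
                            "surgeried_paw": "right"})

        # --- phase 1: pre-surgery reflex testing (days 6..9) -------------
        noise = rng_reflex.standard_normal((n_sessions, 2, config.n_trials_per_paw))
        for s in range(n_sessions):
            base = tr["basal_latency"] - tr["latency_decline"] * s
            for ip, paw in enumerate(("left", "right")):
                for t in range(config.n_trials_per_paw):
                    lat = np.clip(base + config.trial_noise_sd * noise[s, ip, t],
                                  LATENCY_MIN_S, LATENCY_MAX_S)
                    reflex_rows.append({
                        "animal": animal, "day": REFLEX_DAYS[0] + s,
                        "session": s + 1, "paw": paw, "trial_index": t + 1,
                        "latency_s": float(lat),
                    })

        # --- phase 2: conditioning (days 13..16) --------------------------
        for d in range(n_cond):
            veh_mu = tr["basal_loco"] - tr["loco_habituation"] ** 2 * d
            oxy_mu = max(veh_mu, 0.0) + tr["oxy_loco_boost"] + tr["sensitization_slope"] * d
            day = CONDITIONING_DAYS[0] + d
            cond_rows.append({"animal": animal, "day": day, "drug": "VEH",
                              "counts": _negbin(rng_cond, veh_mu, config.count_dispersion)})
            cond_rows.append({"animal": animal, "day": day, "drug": "OXY",
                              "counts": _negbin(rng_cond, oxy_mu, config.count_dispersion)})

        # --- phases 2-3: pre-test, CPP test and extinction tests ----------
        pre_center = config.pretest_center_s
        pre_oxy = float(np.clip(
            config.pretest_oxy_mean_s
            + config.pretest_oxy_sd_s * rng_cpp.standard_normal(),
            0.0, config.test_length_s - pre_center))
        oxy, veh, center = _compose_place_test(
            pre_oxy, config.test_length_s - pre_oxy - pre_center, pre_center,
            config.test_length_s)
        for comp, t in (("OXY", oxy), ("VEH", veh), ("CENTER", center)):
            place_rows.append({"animal": animal, "day": PRETEST_DAY,
                               "compartment": comp, "time_s": t})

        eps = rng_cpp.standard_normal(len(test_days)) * config.cpp_noise_sd
        for i, day in enumerate(test_days):
            oxy_t = (pre_oxy + tr["cpp_strength"]
                     - tr["extinction_rate"] * (day - test_days[0]) + eps[i])
            center_t = pre_center + config.center_drift_s_per_test * (i + 1)
            veh_t = config.test_length_s - oxy_t - center_t
            oxy, veh, center = _compose_place_test(oxy_t, veh_t, center_t,
                                                   config.test_length_s)
            for comp, t in (("OXY", oxy), ("VEH", veh), ("CENTER", center)):
                place_rows.append({"animal": animal, "day": day,
                                   "compartment": comp, "time_s": t})

        # --- phase 4: post-surgery reflex testing (days 63..65) -----------
        post_noise = rng_post.standard_normal((len(POST_REFLEX_DAYS), 2,
                                               config.n_trials_per_paw))
        for s, day in enumerate(POST_REFLEX_DAYS):
            for ip, paw in enumerate(("left", "right")):
                base = tr["basal_latency"]
                if paw == "right" and arm == "cci":
                    base -= config.cci_effect_s
                for t in range(config.n_trials_per_paw):
                    lat = np.clip(base + config.trial_noise_sd * post_noise[s, ip, t],
                                  LATENCY_MIN_S, LATENCY_MAX_S)
                    reflex_rows.append({
                        "animal": animal, "day": day, "session": s + 1,
                        "paw": paw, "trial_index": t + 1, "latency_s": float(lat),
                    })

        # --- phase 5: post-surgery place test (day 66) --------------------
        # Extinction is complete by the last pre-surgery test; the day-66
        # trajectory plateaus at the day-51 value, shifted for CCI animals.
        oxy_t = (pre_oxy + tr["cpp_strength"]
                 - tr["extinction_rate"] * (test_days[-1] - test_days[0]))
        if arm == "cci":
            oxy_t += config.cci_cpp_effect_s
        oxy_t += rng_post.standard_normal() * config.cpp_noise_sd
        center_t = pre_center + config.center_drift_s_per_test * (len(test_days) + 1)
        veh_t = config.test_length_s - oxy_t - center_t
        oxy, veh, center = _compose_place_test(oxy_t, veh_t, center_t,
                                               config.test_length_s)
        for comp, t in (("OXY", oxy), ("VEH", veh), ("CENTER", center)):
            place_rows.append({"animal": animal, "day": POST_TEST_DAY,
                               "compartment": comp, "time_s": t})

    return StudyDataset(
        reflex_trials=pd.DataFrame(reflex_rows),
        conditioning=pd.DataFrame(cond_rows),
        place_tests=pd.DataFrame(place_rows),
        animals=pd.DataFrame(animal_rows),
    )
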