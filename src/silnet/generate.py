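"""Synthetic multi-school cohort generator.

Emulates the structure of a six-country school sociometric survey: each
school contributes two grades of adolescents aged 13-18, every respondent
nominates up to five best friends inside the school, and smoking behaviour
carries a socio-economic gradient, a household-smoking gradient and a peer
effect on first-degree exposure.

Mechanism overview
------------------
1. Each student draws a deprivation count (number of lowest SES
   categories, 0-5) from a school-tilted categorical distribution; the
   count is then realised as concrete indicator values by choosing that
   many of the seven indicators (weighted by their population lowest-band
   shares) to sit in their lowest band.
2. Friendship nominations are drawn per ego without replacement with
   weights exp(homophily_strength x 1[same parental-education group] +
   ses_homophily_strength x 1[same deprivation band]), giving a tunable
   Coleman homophily level and a tunable SES gradient in peer exposure.
3. Smoking is assigned by a logistic mechanism whose linear predictor is
   intercept + SES + household + age/sex + country effect +
   peer_effect_beta x (first-degree exposure / 10%), iterated synchronously
   to a fixed point with one fixed uniform draw per student; the intercept
   is re-calibrated each sweep so prevalence stays at its target.  Holding
   the uniform draws fixed makes the realised configuration exactly
   self-consistent with the conditional logistic model, so a regression of
   smoking on realised peer exposure estimates ``peer_effect_beta``.
4. Missing SES values are finally injected at the survey's item
   non-response rates to exercise the imputation rules downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .metrics import build_school_networks, coleman_index
from .types import NominationEdge, StudentRecord

COUNTRIES = ("BE", "FI", "DE", "IT", "NL", "PT")

#: Population share of each indicator's lowest band (used to decide which
#: indicators realise a student's drawn deprivation count).
_LOWEST_SHARES = {
    "father_edu": 0.215,
    "mother_edu": 0.179,
    "subjective_rank": 0.228,
    "father_working": 0.095,
    "mother_working": 0.194,
    "fas_ratio": 0.075,
    "housing": 0.183,
}
_INDICATORS = tuple(_LOWEST_SHARES)

# Education shares above the lowest band (medium, high), renormalised when
# the student is not lowest on that indicator.
_FATHER_EDU_UPPER = (0.319, 0.291)
_MOTHER_EDU_UPPER = (0.357, 0.315)
_RANK_UPPER = ((6, 7, 8, 9, 10), (0.187, 0.275, 0.211, 0.049, 0.049))
_FAS_UPPER = ((0.289, (0.61, 0.90)), (0.345, (0.91, 1.20)), (0.291, (1.21, 2.00)))


@dataclass
class GeneratorConfig:
    """Tunable study conditions for the synthetic cohort.

    Defaults reproduce the survey's marginals: ~17% regular smoking,
    deprivation-count distribution (0.326, ..., 0.021), household smoker
    means rising from ~1.2 (count 0) to ~1.8 (count 5), a peer effect of
    log(1.26) per 10 percentage points of first-degree smoking exposure,
    and friendship homophily tuned so the mean individual Coleman index on
    parental education is about 0.3.
    """

    n_schools: int = 12
    roster_size_range: Tuple[int, int] = (150, 250)
    target_smoking_prev: float = 0.169
    homophily_strength: float = 1.70
    peer_effect_beta: float = math.log(1.26)   # per 10% degree-1 exposure
    ses_category_probs: Tuple[float, ...] = (0.326, 0.289, 0.193, 0.116, 0.055, 0.021)
    household_smoker_gradient: float = 0.12    # extra household smokers per count
    seed: int = 0

    # secondary mechanism knobs
    ses_homophily_strength: float = 1.0        # log-odds penalty per unit count gap
    ses_effect: float = 0.06                   # direct log-OR per deprivation count
    household_effect: float = math.log(1.50)   # log-OR per household smoker
    household_base: float = 1.2                # household smoker mean at count 0
    age_effect: float = 0.45                   # log-OR per year of age above 15
    sex_effect: float = math.log(1.13)         # log-OR male vs female
    country_sd: float = 0.2                    # sd of country intercepts
    school_ses_sd: float = 0.35                # sd of the school deprivation tilt
    interaction_beta: float = 0.0              # log-OR per (Coleman x count)
    target_tried_prev: float = 0.466
    out_degree_probs: Tuple[float, ...] = (0.04, 0.04, 0.07, 0.12, 0.23, 0.50)
    n_sweeps: int = 10
    missing_rates: dict = field(default_factory=lambda: {
        "father_edu": 0.175, "mother_edu": 0.148, "subjective_rank": 0.035,
        "fas_ratio": 0.03, "father_working": 0.017, "mother_working": 0.017,
    })
    dependence_mean_regular: float = 11.0
    dependence_mean_tried: float = 1.0
    dependence_alpha: float = 0.8              # NB2 dispersion

    def validate(self) -> None:
        if self.n_schools < 1:
            raise ValueError("n_schools must be >= 1")
        lo, hi = self.roster_size_range
        if lo < 10 or hi < lo:
            raise ValueError("roster sizes must be >= 10 and lo <= hi")
        if lo <= len(self.out_degree_probs) - 1:
            raise ValueError(
                "roster too small to satisfy the nomination request"
            )
        p = np.asarray(self.ses_category_probs, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("ses_category_probs must be in [0,1] and sum to 1")
        q = np.asarray(self.out_degree_probs, dtype=float)
        if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("out_degree_probs must be a distribution")
        if not 0 < self.target_smoking_prev < 1:
            raise ValueError("target_smoking_prev must be in (0,1)")
        if self.homophily_strength < 0:
            raise ValueError("homophily_strength must be >= 0")
        for k, v in self.missing_rates.items():
            if not 0 <= v < 1:
                raise ValueError(f"missing rate for {k} outside [0,1)")


def _draw_indicators(rng: np.random.Generator, count: int):
    """Pick which of the seven indicators are in their lowest band."""
    w = np.array([_LOWEST_SHARES[k] for k in _INDICATORS])
    idx = rng.choice(len(_INDICATORS), size=count, replace=False, p=w / w.sum())
    return frozenset(_INDICATORS[i] for i in idx)


def _draw_from(rng, values, probs):
    probs = np.asarray(probs, dtype=float)
    return values[rng.choice(len(values), p=probs / probs.sum())]


def _student_attributes(rng, sid, school_id, country, grade, count):
    low = _draw_indicators(rng, count)
    father_edu = "low" if "father_edu" in low else \
        _draw_from(rng, ("medium", "high"), _FATHER_EDU_UPPER)
    mother_edu = "low" if "mother_edu" in low else \
        _draw_from(rng, ("medium", "high"), _MOTHER_EDU_UPPER)
    if "subjective_rank" in low:
        rank = int(rng.integers(1, 6))
    else:
        rank = int(_draw_from(rng, _RANK_UPPER[0], _RANK_UPPER[1]))
    if "fas_ratio" in low:
        fas = float(rng.uniform(0.30, 0.60))
    else:
        probs = [b[0] for b in _FAS_UPPER]
        band = _FAS_UPPER[rng.choice(3, p=np.asarray(probs) / sum(probs))][1]
        fas = float(rng.uniform(*band))
    age = int(np.clip(round(rng.normal(13.7 + grade, 0.8)), 13, 18))
    return StudentRecord(
        student_id=sid,
        school_id=school_id,
        country=country,
        grade=grade,
        sex="male" if rng.random() < 0.478 else "female",
        age=age,
        father_edu=father_edu,
        mother_edu=mother_edu,
        subjective_rank=rank,
        father_working="father_working" not in low,
        mother_working="mother_working" not in low,
        fas_ratio=fas,
        housing="tenant" if "housing" in low else "owner",
        tried_smoking=False,
        regular_smoker=False,
        dependence_score=0,
        household_smokers=0,
    )


def _draw_edges(rng, records, homophily_strength, ses_homophily_strength,
                out_degree_probs):
    """Per-ego weighted sampling of alters without replacement.

    Tie log-weight is homophily_strength for a same parental-education
    (father) alter minus ses_homophily_strength per unit of difference in
    the deprivation count (a distance kernel, so SES assortativity decays
    smoothly); sampling uses the Gumbel top-k trick.
    """
    edges = []
    by_school: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_school.setdefault(r.school_id, []).append(i)
    for school_idx in by_school.values():
        n = len(school_idx)
        groups = np.array([records[i].father_edu for i in school_idx])
        bands = np.array([_deprivation_count(records[i]) for i in school_idx])
        same = groups[:, None] == groups[None, :]
        band_gap = np.abs(bands[:, None] - bands[None, :]).astype(float)
        logw = (homophily_strength * same.astype(float)
                - ses_homophily_strength * band_gap)
        np.fill_diagonal(logw, -np.inf)
        degrees = rng.choice(len(out_degree_probs), size=n, p=out_degree_probs)
        gumbel = rng.gumbel(size=(n, n))
        order = np.argsort(-(logw + gumbel), axis=1)
        for row, d in enumerate(degrees):
            ego = records[school_idx[row]].student_id
            for col in order[row, :d]:
                edges.append(NominationEdge(ego, records[school_idx[col]].student_id))
    return edges


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + eta)) = target."""
    def gap(c):
        return float(np.mean(expit(c + eta)) - target)
    lo, hi = -30.0, 30.0
    return brentq(gap, lo, hi, xtol=1e-10)


def _smoking_fixed_point(rng, records, edges, cfg, country_eff):
    """Assign regular smoking by the calibrated logistic fixed point."""
    n = len(records)
    index = {r.student_id: i for i, r in enumerate(records)}
    nbrs = [[] for _ in range(n)]
    for e in edges:
        nbrs[index[e.ego_id]].append(index[e.alter_id])
    nbr_arr = [np.array(v, dtype=int) for v in nbrs]

    counts = np.array([_deprivation_count(r) for r in records], dtype=float)
    household = np.array([r.household_smokers for r in records], dtype=float)
    age = np.array([r.age for r in records], dtype=float)
    male = np.array([r.sex == "male" for r in records], dtype=float)
    ctry = np.array([country_eff[r.country] for r in records])

    eta_exo = (cfg.ses_effect * counts
               + cfg.household_effect * household
               + cfg.age_effect * (age - 15.0)
               + cfg.sex_effect * male
               + ctry)
    if cfg.interaction_beta != 0.0:
        nets = build_school_networks(records, edges)
        col = np.array([
            coleman_index(nets[r.school_id], r.student_id) or 0.0
            for r in records
        ])
        eta_exo = eta_exo + cfg.interaction_beta * col * counts

    u = rng.random(n)
    y = (u < cfg.target_smoking_prev).astype(float)
    for _ in range(cfg.n_sweeps):
        exposure = np.array([
            y[a].mean() if a.size else 0.0 for a in nbr_arr
        ])
        eta = eta_exo + cfg.peer_effect_beta * 10.0 * exposure
        c = _calibrate_intercept(eta, cfg.target_smoking_prev)
        y_new = (u < expit(c + eta)).astype(float)
        if np.array_equal(y_new, y):
            y = y_new
            break
        y = y_new
    return y.astype(bool), eta_exo, u


def _deprivation_count(r: StudentRecord) -> int:
    return int(
        (r.father_edu == "low") + (r.mother_edu == "low")
        + (r.subjective_rank <= 5) + (not r.father_working)
        + (not r.mother_working) + (r.fas_ratio <= 0.60)
        + (r.housing == "tenant")
    )


def _negbin(rng, mean: float, alpha: float, size: int) -> np.ndarray:
    """NB2 draws: var = mean + alpha * mean^2 (numpy (n, p) parametrisation)."""
    nshape = 1.0 / alpha
    p = nshape / (nshape + mean)
    return rng.negative_binomial(nshape, p, size=size)


def generate_cohort(config: GeneratorConfig):
    """Generate (records, edges) with the configured study conditions.

    Deterministic given ``config.seed``: the same config yields a
    bit-identical cohort.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    country_eff = {c: rng.normal(0.0, cfg.country_sd) for c in COUNTRIES}
    probs = np.asarray(cfg.ses_category_probs, dtype=float)
    ks = np.arange(len(probs))

    records: list[StudentRecord] = []
    for s in range(cfg.n_schools):
        country = COUNTRIES[s % len(COUNTRIES)]
        school_id = f"{country}-S{s:03d}"
        size = int(rng.integers(cfg.roster_size_range[0],
                                cfg.roster_size_range[1] + 1))
        tilt = rng.normal(0.0, cfg.school_ses_sd)
        p_school = probs * np.exp(tilt * ks)
        p_school = p_school / p_school.sum()
        for j in range(size):
            grade = 1 if j < size // 2 else 2
            count = int(rng.choice(ks, p=p_school))
            sid = f"{school_id}-{j:04d}"
            records.append(
                _student_attributes(rng, sid, school_id, country, grade, count))

    # household smokers: Poisson with a deprivation gradient
    counts = np.array([_deprivation_count(r) for r in records])
    hh = rng.poisson(cfg.household_base
                     + cfg.household_smoker_gradient * counts)
    for r, h in zip(records, hh):
        r.household_smokers = int(h)

    edges = _draw_edges(rng, records, cfg.homophily_strength,
                        cfg.ses_homophily_strength,
                        np.asarray(cfg.out_degree_probs, dtype=float))

    smoking, eta_exo, _u = _smoking_fixed_point(rng, records, edges, cfg,
                                                country_eff)

    # tried smoking: every regular smoker tried; non-smokers try with a
    # milder version of the same gradient, calibrated to the target.
    u2 = rng.random(len(records))
    def tried_gap(c):
        p_extra = expit(c + 0.5 * eta_exo)
        return float(np.mean(smoking + (1 - smoking) * p_extra)
                     - cfg.target_tried_prev)
    if tried_gap(-30.0) > 0:      # target below smoking prevalence
        tried = smoking.copy()
    else:
        c2 = brentq(tried_gap, -30.0, 30.0, xtol=1e-10)
        tried = smoking | (u2 < expit(c2 + 0.5 * eta_exo))

    dep = np.zeros(len(records), dtype=int)
    reg = np.flatnonzero(smoking)
    tri = np.flatnonzero(tried & ~smoking)
    dep[reg] = np.clip(_negbin(rng, cfg.dependence_mean_regular,
                               cfg.dependence_alpha, reg.size), 0, 25)
    dep[tri] = np.clip(_negbin(rng, cfg.dependence_mean_tried,
                               cfg.dependence_alpha, tri.size), 0, 25)

    for i, r in enumerate(records):
        r.regular_smoker = bool(smoking[i])
        r.tried_smoking = bool(tried[i])
        r.dependence_score = int(dep[i])

    # item non-response, injected last so the network and smoking mechanism
    # operate on true values while downstream sees survey-like missingness
    for fld, rate in cfg.missing_rates.items():
        if rate <= 0:
            continue
        mask = rng.random(len(records)) < rate
        for i in np.flatnonzero(mask):
            records[i] = replace(records[i], **{fld: None})

    return records, edges
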