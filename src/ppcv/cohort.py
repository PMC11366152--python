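"""Synthetic study cohorts with the statistical structure of the PPCV study.

The generative model for a quadrant-level PPCV record is

    PPCV = β₀ + β_age·age + β_nasal·1{nasal quadrant} + β_DR·1{DR}
           + offset(group, timepoint) + b_subject + b_eye + ε

with ε ~ N(0, σ_ε²) per record, and eye-level random effects split so that
two eyes of one subject correlate at ρ:  b_subject ~ N(0, ρ σ_u²),
b_eye ~ N(0, (1 − ρ) σ_u²).  At the 3-month visit each treated eye's
change score is coupled to its visual-acuity change:

    ΔPPCV(m3) = offset(group, m3) + slope_group · ΔlogMAR + η .

Healthy subjects contribute one randomly chosen eye (four quadrant
records at baseline); DR eyes contribute records at six timepoints.
Default group sizes, age moments and effect sizes are the study's:
101 healthy subjects (age 46.79 ± 19.30), 62 anti-VEGF / 74 PRP /
51 surgery eyes, β_age = −20790.03, β_nasal = −1.129 × 10⁶ (PPCV in μm³),
and Fig.-6-style slopes −9.67 × 10⁵ (PRP), −6.83 × 10⁵ (surgery), 0
(anti-VEGF).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .geometry import QUADRANTS, NASAL_QUADRANTS

TIMEPOINTS = ("baseline", "w1", "w2", "m1", "m2", "m3")
GROUPS = ("healthy", "anti_vegf", "prp", "surgery")

#: qualitative post-treatment time courses (PPCV units):
#: anti-VEGF dips at weeks 1–2 and returns by month 1; PRP is flat through
#: month 1 then rises; surgery dips at week 1, recovers, and rises by month 3.
DEFAULT_TREATMENT_OFFSETS = {
    "anti_vegf": {"baseline": 0.0, "w1": -8.0e5, "w2": -7.0e5,
                  "m1": -1.0e5, "m2": 0.0, "m3": 0.0},
    "prp": {"baseline": 0.0, "w1": 0.0, "w2": 0.0,
            "m1": 0.5e5, "m2": 6.0e5, "m3": 9.0e5},
    "surgery": {"baseline": 0.0, "w1": -9.0e5, "w2": -2.0e5,
                "m1": 0.0, "m2": 2.0e5, "m3": 7.0e5},
}

DEFAULT_DELTA_LOGMAR_SLOPES = {"anti_vegf": 0.0, "prp": -9.67e5, "surgery": -6.83e5}


@dataclass(frozen=True)
class CohortDesign:
    """Generative design of a synthetic cohort (PPCV in μm³, age in years)."""

    n_healthy: int = 101
    n_antivegf_eyes: int = 62
    n_prp_eyes: int = 74
    n_surgery_eyes: int = 51

    healthy_age_mean: float = 46.79
    healthy_age_sd: float = 19.30
    healthy_age_range: tuple[float, float] = (18.0, 90.0)
    dr_age_mean: float = 58.34
    dr_age_sd: float = 15.78
    dr_age_range: tuple[float, float] = (31.0, 90.0)

    beta0: float = 5.5e6
    beta_age: float = -20790.03
    beta_nasal: float = -1.129e6
    beta_dr: float = -1.5e6
    treatment_offsets: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_TREATMENT_OFFSETS.items()})
    delta_logmar_slopes: dict = field(
        default_factory=lambda: dict(DEFAULT_DELTA_LOGMAR_SLOPES))
    delta_logmar_mean: float = -0.3
    delta_logmar_sd: float = 0.25
    delta_ppcv_noise_sd: float = 3.0e5

    sigma_eps: float = 5.0e5      # per-record residual SD
    sigma_random: float = 4.0e5   # eye-level random-effect SD (subject + eye)
    rho_intereye: float = 0.6     # correlation between two eyes of a subject
    bilateral_fraction: float = 0.34  # DR eyes in bilateral subjects (47/140 patients)
    icc_target: float = 0.937

    def __post_init__(self):
        if self.sigma_eps <= 0:
            raise ConfigurationError("sigma_eps must be positive")
        if self.sigma_random < 0:
            raise ConfigurationError("sigma_random must be >= 0")
        if not 0.0 <= self.rho_intereye < 1.0:
            raise ConfigurationError("rho_intereye must be in [0, 1)")
        if not 0.0 < self.icc_target <= 1.0:
            raise ConfigurationError("icc_target must be in (0, 1]")
        for n in (self.n_healthy, self.n_antivegf_eyes, self.n_prp_eyes,
                  self.n_surgery_eyes):
            if n < 0:
                raise ConfigurationError("group sizes must be >= 0")
        if not 0.0 <= self.bilateral_fraction <= 1.0:
            raise ConfigurationError("bilateral_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        d = dict(d)
        for k in ("healthy_age_range", "dr_age_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _truncnorm_latent(mean, sd, lo, hi):
    """Latent (μ, σ) of a truncated normal whose *realized* mean and SD on
    [lo, hi] equal the requested values (so generated ages reproduce the
    design moments, not the pre-truncation ones)."""
    from scipy.optimize import fsolve

    def moments(p):
        mu, sig = p
        sig = abs(sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    mu, sig = fsolve(moments, [mean, sd], full_output=False)
    return float(mu), float(abs(sig))


@lru_cache(maxsize=32)
def _truncnorm_frozen(mean, sd, lo, hi):
    mu, sig = _truncnorm_latent(mean, sd, lo, hi)
    a, b = (lo - mu) / sig, (hi - mu) / sig
    return stats.truncnorm(a, b, loc=mu, scale=sig)


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    dist = _truncnorm_frozen(float(mean), float(sd), float(lo), float(hi))
    return dist.ppf(rng.uniform(size=size))


def generate_cohort(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Simulate a cohort table; deterministic for fixed (design, seed).

    Columns: subject_id, eye, age_years, sex, group, quadrant, timepoint,
    ppcv_um3, logmar_bcva.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    sig_subj = np.sqrt(design.rho_intereye) * design.sigma_random
    sig_eye = np.sqrt(1.0 - design.rho_intereye) * design.sigma_random

    # ---- healthy: one random eye, four quadrants, baseline only ----------
    ages = _truncnorm(rng, design.healthy_age_mean, design.healthy_age_sd,
                      *design.healthy_age_range, size=design.n_healthy)
    for s in range(design.n_healthy):
        sid = f"H{s + 1:04d}"
        sex = "F" if rng.uniform() < 0.5 else "M"
        eye = rng.choice(["OD", "OS"])
        b = rng.normal(0.0, sig_subj) + rng.normal(0.0, sig_eye)
        logmar = rng.normal(0.0, 0.02)
        for q in QUADRANTS:
            mu = (design.beta0 + design.beta_age * ages[s]
                  + (design.beta_nasal if q in NASAL_QUADRANTS else 0.0))
            rows.append(dict(
                subject_id=sid, eye=eye, age_years=float(ages[s]), sex=sex,
                group="healthy", quadrant=q, timepoint="baseline",
                ppcv_um3=max(1.0, mu + b + rng.normal(0.0, design.sigma_eps)),
                logmar_bcva=float(logmar)))

    # ---- DR treatment groups ---------------------------------------------
    def add_group(group: str, n_eyes: int, subj_prefix: str):
        offsets = design.treatment_offsets[group]
        slope = design.delta_logmar_slopes[group]
        # allocate eyes to subjects; ~bilateral_fraction of eyes are the
        # second eye of an already enrolled subject
        subj_of_eye, subj_effects, subj_age, subj_sex = [], {}, {}, {}
        s_counter = 0
        for e in range(n_eyes):
            open_subjects = [sid for sid in subj_effects
                             if sum(x == sid for x in subj_of_eye) == 1]
            if open_subjects and rng.uniform() < design.bilateral_fraction:
                sid = open_subjects[int(rng.integers(len(open_subjects)))]
            else:
                s_counter += 1
                sid = f"{subj_prefix}{s_counter:04d}"
                subj_effects[sid] = rng.normal(0.0, sig_subj)
                subj_age[sid] = float(_truncnorm(
                    rng, design.dr_age_mean, design.dr_age_sd,
                    *design.dr_age_range, size=1)[0])
                subj_sex[sid] = "F" if rng.uniform() < 0.47 else "M"
            subj_of_eye.append(sid)

        used_eyes: dict[str, str] = {}
        for e, sid in enumerate(subj_of_eye):
            if sid not in used_eyes:
                eye = str(rng.choice(["OD", "OS"]))
            else:  # fellow eye of a bilateral subject
                eye = "OS" if used_eyes[sid] == "OD" else "OD"
            used_eyes[sid] = eye
            b = subj_effects[sid] + rng.normal(0.0, sig_eye)
            age = subj_age[sid]
            logmar0 = max(0.0, rng.normal(0.7, 0.2))
            dlogmar = rng.normal(design.delta_logmar_mean, design.delta_logmar_sd)
            dlogmar = max(dlogmar, -logmar0)  # BCVA cannot improve past 0
            eta = rng.normal(0.0, design.delta_ppcv_noise_sd)
            for t in TIMEPOINTS:
                extra = slope * dlogmar + eta if t == "m3" else 0.0
                frac = {"baseline": 0.0, "w1": 0.15, "w2": 0.3,
                        "m1": 0.55, "m2": 0.8, "m3": 1.0}[t]
                logmar_t = logmar0 + frac * dlogmar
                for q in QUADRANTS:
                    mu = (design.beta0 + design.beta_age * age + design.beta_dr
                          + (design.beta_nasal if q in NASAL_QUADRANTS else 0.0)
                          + offsets[t] + extra)
                    rows.append(dict(
                        subject_id=sid, eye=eye, age_years=age,
                        sex=subj_sex[sid], group=group, quadrant=q,
                        timepoint=t,
                        ppcv_um3=max(1.0, mu + b + rng.normal(0.0, design.sigma_eps)),
                        logmar_bcva=float(logmar_t)))

    add_group("anti_vegf", design.n_antivegf_eyes, "A")
    add_group("prp", design.n_prp_eyes, "P")
    add_group("surgery", design.n_surgery_eyes, "S")

    return pd.DataFrame(rows)


def eye_change_scores(cohort: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-eye quadrant-averaged ΔPPCV (month 3 − baseline) and ΔlogMAR.

    This is the change-score table behind the ΔPPCV-vs-ΔlogMAR regressions;
    one row per treated eye.
    """
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise InputError(f"no records for group {group!r}")
    out = []
    for (sid, eye), g in sub.groupby(["subject_id", "eye"]):
        base = g[g["timepoint"] == "baseline"]
        m3 = g[g["timepoint"] == "m3"]
        if base.empty or m3.empty:
            continue
        out.append(dict(
            subject_id=sid, eye=eye,
            delta_ppcv_um3=m3["ppcv_um3"].mean() - base["ppcv_um3"].mean(),
            delta_logmar=m3["logmar_bcva"].mean() - base["logmar_bcva"].mean()))
    return pd.DataFrame(out)


def generate_rater_pairs(
    truth,
    icc_target: float,
    sigma_between: float,
    seed: int,
) -> pd.DataFrame:
    """Two independent raters measuring the same quantities.

    ``truth`` is a 1-D array of true values (or a CohortTable DataFrame,
    whose ``ppcv_um3`` column is used).  Each rater observes
    truth + N(0, σ_e²) independently with σ_e² = σ_b²·(1 − ICC)/ICC, the
    variance-component identity that makes the *population* ICC(2,1) equal
    ``icc_target`` when the between-subject SD is ``sigma_between``.
    """
    if not 0.0 < icc_target <= 1.0:
        raise ConfigurationError("icc_target must be in (0, 1]")
    if sigma_between <= 0:
        raise ConfigurationError("sigma_between must be positive "
                                 "(a zero between-subject SD makes ICC degenerate)")
    if isinstance(truth, pd.DataFrame):
        truth = truth["ppcv_um3"].to_numpy()
    truth = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(seed)
    sigma_e = sigma_between * np.sqrt((1.0 - icc_target) / icc_target)
    r1 = truth + rng.normal(0.0, sigma_e, size=truth.shape)
    r2 = truth + rng.normal(0.0, sigma_e, size=truth.shape)
    return pd.DataFrame({"truth": truth, "rater1": r1, "rater2": r2})
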