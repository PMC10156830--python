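"""Synthetic health-insurance populations with known ground truth.

The real calibration data for risk-equalization models (national claims
registries) are confidential, so every pipeline stage here is exercised
on generated populations that emulate their salient features:

* an exhaustive age-gender structure with realistic band frequencies;
* exclusive morbidity adjusters (pharmacy-based cost groups and friends)
  with configurable prevalences;
* a catalogue of rare, correlated hospital diagnosis groups (dxgroups)
  whose co-occurrence is driven by a person-level log-normal frailty, so
  that a small share of people accumulates many dxgroups (the
  multimorbidity mass the multi-qualification DCG design targets);
* spending equal to a known linear combination of the person's risk
  classes plus right-skewed, heteroskedastic two-part (zero-mass +
  gamma) noise;
* GP-style chronic-condition flags that only partially overlap the
  morbidity adjusters (roughly 55% chronic versus 25% flagged);
* a morbidity-enriched subsample standing in for GP-practice data, and a
  two-year claims history for dxgroup screening.

Everything is deterministic under ``GeneratorConfig.seed``; the true
coefficients are returned alongside the population so calibration can be
checked by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import (
    AGE_GENDER,
    NONE_CLASS,
    Classification,
    PersonRecord,
    RiskAdjusterScheme,
    ValidationError,
)

__all__ = [
    "MorbidityBlock",
    "GeneratorConfig",
    "DiagnosisClaims",
    "ClaimsHistory",
    "generate_population",
    "generate_subsample",
    "generate_claims_history",
]

_EMPTY: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MorbidityBlock:
    """One exclusive morbidity classification in the generator.

    ``prevalence`` is the target share of insured-years flagged by any
    class of the block; flagged persons are split over ``labels`` with
    probabilities ``class_shares``; ``coefficients`` are the true euros
    per person-year each class adds to expected spending.
    ``frailty_power`` couples the flag probability to the person-level
    frailty (0 = independent of health status, 1 = proportional).
    """

    name: str
    prevalence: float
    labels: tuple[str, ...]
    class_shares: tuple[float, ...]
    coefficients: tuple[float, ...]
    frailty_power: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError(f"block {self.name}: prevalence outside [0,1]")
        if abs(sum(self.class_shares) - 1.0) > 1e-9:
            raise ValidationError(f"block {self.name}: class shares must sum to 1")
        if not (len(self.labels) == len(self.class_shares) == len(self.coefficients)):
            raise ValidationError(f"block {self.name}: ragged class definition")


_AGE_BANDS = ("1-17", "18-34", "35-44", "45-54", "55-64", "65+")
_GENDERS = ("M", "F")

# Insured-year shares per gender x band (men first), national-registry-like.
_AGE_GENDER_SHARES = (
    0.098, 0.105, 0.060, 0.076, 0.068, 0.088,
    0.094, 0.103, 0.062, 0.076, 0.068, 0.104,
)

# True euros/person-year per age-gender cell, rising with age.
_AGE_GENDER_COEFS = (
    300.0, 420.0, 600.0, 850.0, 1350.0, 2800.0,
    400.0, 780.0, 950.0, 1050.0, 1450.0, 2700.0,
)

_DEFAULT_BLOCKS = (
    MorbidityBlock(
        "pcg", 0.169,
        ("mild", "moderate", "severe", "very_severe"),
        (0.50, 0.30, 0.15, 0.05),
        (900.0, 2200.0, 4500.0, 9000.0),
    ),
    MorbidityBlock(
        "mhc", 0.061,
        ("2of3yrs", "3of3yrs", "top"),
        (0.60, 0.30, 0.10),
        (1800.0, 4200.0, 8000.0),
    ),
    MorbidityBlock(
        "dme", 0.038,
        ("standard", "intensive"),
        (0.70, 0.30),
        (800.0, 2200.0),
    ),
    MorbidityBlock("hcs", 0.024, ("prior_homecare",), (1.0,), (2800.0,)),
    MorbidityBlock("phy", 0.019, ("chronic_physio",), (1.0,), (700.0,)),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the population generator (seed-deterministic).

    Defaults describe the emulated calibration dataset: 16.9% pharmacy
    cost groups, roughly 11% of persons in at least one of 209 dxgroups,
    overall mean spending near EUR 2,333 per person-year, and a chronic
    share of about 55% against ~25% flagged by any morbidity adjuster.
    """

    n_persons: int = 200_000
    seed: int = 0
    age_gender_shares: tuple[float, ...] = _AGE_GENDER_SHARES
    age_gender_coefficients: tuple[float, ...] = _AGE_GENDER_COEFS
    morbidity_blocks: tuple[MorbidityBlock, ...] = _DEFAULT_BLOCKS
    # dxgroups
    n_dxgroups: int = 209
    any_dxgroup_target: float = 0.114
    frailty_sigma: float = 3.0
    frailty_cap: float = 80.0
    dx_rate_log_sigma: float = 1.0
    dx_rate_floor: float = 3e-4
    dx_rate_cap: float = 8e-3
    n_severe_dxgroups: int = 12
    dx_coef_shape: float = 1.2
    dx_coef_scale: float = 620.0
    dx_coef_max: float = 13_000.0
    severe_coef_range: tuple[float, float] = (6000.0, 13_000.0)
    # spending noise
    noise_scale: float = 1.0
    gamma_shape: float = 8.0
    zero_prob_max: float = 0.25
    zero_prob_decay: float = 1500.0
    # enrollment
    full_year_share: float = 0.9
    # chronic conditions
    n_conditions: int = 109
    chronic_target: float = 0.55
    chronic_given_morbid: float = 0.90
    extra_conditions_rate: float = 0.8
    # GP-style subsample
    subsample_fraction: float = 0.077
    enrichment_factor: float = 1.1
    # claims history for dxgroup screening
    n_candidate_diagnoses: int = 40
    persistence_range: tuple[float, float] = (0.10, 0.90)
    candidate_prevalence_range: tuple[float, float] = (0.002, 0.02)

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        shares = np.asarray(self.age_gender_shares, dtype=float)
        if shares.min() < 0:
            raise ValidationError("age-gender shares must be non-negative")
        for p in (self.any_dxgroup_target, self.chronic_target,
                  self.chronic_given_morbid, self.full_year_share,
                  self.zero_prob_max, self.subsample_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0,1]")
        if not 0.0 <= self.noise_scale <= 1.0:
            raise ValidationError("noise_scale must lie in [0,1]")
        if self.enrichment_factor < 1.0:
            raise ValidationError("enrichment_factor must be >= 1")

    @property
    def age_gender_labels(self) -> tuple[str, ...]:
        return tuple(f"{g}|{b}" for g in _GENDERS for b in _AGE_BANDS)

    @property
    def dxgroup_catalogue(self) -> tuple[str, ...]:
        return tuple(f"dx{j + 1:03d}" for j in range(self.n_dxgroups))

    @property
    def condition_catalogue(self) -> tuple[str, ...]:
        return tuple(f"icpc{j + 1:03d}" for j in range(self.n_conditions))

    def scheme(self) -> RiskAdjusterScheme:
        """The risk-adjuster scheme matching generated populations."""
        classifications = [
            Classification(AGE_GENDER, self.age_gender_labels, reference=None)
        ] + [
            Classification(b.name, b.labels, reference=NONE_CLASS)
            for b in self.morbidity_blocks
        ]
        return RiskAdjusterScheme(tuple(classifications), self.dxgroup_catalogue)


# ---------------------------------------------------------------------------
# Frailty calibration helpers
# ---------------------------------------------------------------------------

# Fixed quadrature over the standard normal: deterministic expectations of
# clipped frailty functionals, independent of the simulation seed.
_Z_GRID = np.linspace(-8.0, 8.0, 1601)
_Z_W = np.exp(-0.5 * _Z_GRID**2)
_Z_W = _Z_W / _Z_W.sum()


def _frailty_grid(sigma: float, cap: float, power: float = 1.0) -> np.ndarray:
    """Values of min(frailty, cap)**power on the quadrature grid.

    Frailty is log-normal with unit mean before capping; the cap bounds
    a person's morbidity burden (and hence expected dxgroup count), as
    real multimorbidity is bounded.
    """
    f = np.minimum(np.exp(sigma * _Z_GRID - 0.5 * sigma**2), cap)
    return f**power


def _calibrate_scale(target: float, grid_values: np.ndarray, cap: float) -> float:
    """Solve E[min(scale * g, cap)] = target by bisection (monotone)."""
    def expect(scale: float) -> float:
        return float(_Z_W @ np.minimum(scale * grid_values, cap))

    lo, hi = 0.0, 1.0
    while expect(hi) < target:
        hi *= 2.0
        if hi > 1e9:
            raise ValidationError(f"cannot reach target prevalence {target}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expect(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _calibrate_dx_rates(base: np.ndarray, sigma: float, frailty_cap: float,
                        target: float, cap: float) -> np.ndarray:
    """Scale per-dxgroup base rates so E[P(any dxgroup)] hits target.

    Membership is Bernoulli(min(rate_j * frailty, cap)) independently
    across dxgroups given the frailty, so P(any | f) = 1 - prod(1 - p_j).
    """
    f = _frailty_grid(sigma, frailty_cap)

    def any_share(scale: float) -> float:
        p = np.minimum(np.outer(f, scale * base), cap)
        return float(_Z_W @ (1.0 - np.exp(np.log1p(-p).sum(axis=1))))

    lo, hi = 0.0, 1.0
    while any_share(hi) < target:
        hi *= 2.0
        if hi > 1e6:
            raise ValidationError("cannot reach any-dxgroup target")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if any_share(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) * base


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------


def _draw_truth(config: GeneratorConfig, rng: np.random.Generator):
    """Per-dxgroup base membership rates and true coefficients."""
    n = config.n_dxgroups
    base = np.exp(rng.normal(np.log(5e-4), config.dx_rate_log_sigma, size=n))
    base = np.clip(base, config.dx_rate_floor, config.dx_rate_cap)
    base = _calibrate_dx_rates(base, config.frailty_sigma, config.frailty_cap,
                               config.any_dxgroup_target, cap=0.5)
    coefs = rng.gamma(config.dx_coef_shape, config.dx_coef_scale, size=n)
    coefs = np.clip(coefs, 50.0, config.dx_coef_max)
    n_severe = min(config.n_severe_dxgroups, n)
    if n_severe:
        # severe (very expensive) diagnosis groups are the rarest ones
        severe = np.argsort(base)[:n_severe]
        lo, hi = config.severe_coef_range
        coefs[severe] = rng.uniform(lo, hi, size=n_severe)
    return base, coefs


def generate_population(
    config: GeneratorConfig,
) -> tuple[list[PersonRecord], dict[str, float]]:
    """Draw a population and return it with the true coefficient table.

    The truth table maps design-matrix column labels (``"age_gender:M|65+"``,
    ``"pcg:severe"``, ``"dx:dx001"``, ...) to euros per person-year;
    expected spending per person is the matching design row times these
    coefficients.  With ``noise_scale == 0`` realized spending equals its
    expectation exactly.
    """
    ss = np.random.SeedSequence(config.seed)
    truth_rng, person_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    n = config.n_persons

    dx_rates, dx_coefs = _draw_truth(config, truth_rng)
    ag_labels = config.age_gender_labels
    ag_shares = np.asarray(config.age_gender_shares, dtype=float)
    ag_shares = ag_shares / ag_shares.sum()
    ag_coefs = np.asarray(config.age_gender_coefficients, dtype=float)

    ag_idx = person_rng.choice(len(ag_labels), size=n, p=ag_shares)
    frailty = np.minimum(
        np.exp(config.frailty_sigma * person_rng.standard_normal(n)
               - 0.5 * config.frailty_sigma**2),
        config.frailty_cap,
    )

    # enrollment: most people insured the full year, the rest a uniform
    # number of whole months
    full = person_rng.random(n) < config.full_year_share
    months = person_rng.integers(1, 12, size=n)
    fraction = np.where(full, 1.0, months / 12.0)

    mu = ag_coefs[ag_idx].astype(float)

    # exclusive morbidity blocks
    block_labels: dict[str, np.ndarray] = {}
    any_morbid = np.zeros(n, dtype=bool)
    for block in config.morbidity_blocks:
        grid = _frailty_grid(config.frailty_sigma, config.frailty_cap,
                             block.frailty_power)
        scale = _calibrate_scale(block.prevalence, grid, cap=0.95)
        p = np.minimum(scale * frailty**block.frailty_power, 0.95)
        flagged = person_rng.random(n) < p
        cls = person_rng.choice(len(block.labels), size=n,
                                p=np.asarray(block.class_shares))
        labels = np.full(n, NONE_CLASS, dtype=object)
        labels[flagged] = np.asarray(block.labels, dtype=object)[cls[flagged]]
        block_labels[block.name] = labels
        any_morbid |= flagged
        mu[flagged] += np.asarray(block.coefficients)[cls[flagged]]

    # correlated dxgroup membership via the shared frailty
    dx_sets: list[list[str]] = [[] for _ in range(n)]
    catalogue = config.dxgroup_catalogue
    for j, (rate, coef) in enumerate(zip(dx_rates, dx_coefs)):
        p = np.minimum(rate * frailty, 0.5)
        members = np.nonzero(person_rng.random(n) < p)[0]
        mu[members] += coef
        gid = catalogue[j]
        for i in members:
            dx_sets[i].append(gid)
    any_morbid |= np.fromiter((len(s) > 0 for s in dx_sets), bool, n)

    # two-part spending noise around the linear expectation
    if config.noise_scale > 0.0:
        pi = config.zero_prob_max * np.exp(
            -(mu - mu.min()) / config.zero_prob_decay
        )
        zero = person_rng.random(n) < pi
        k = config.gamma_shape
        positive_mean = mu / (1.0 - pi)
        draw = person_rng.gamma(k, positive_mean / k)
        draw[zero] = 0.0
        y = (1.0 - config.noise_scale) * mu + config.noise_scale * draw
    else:
        y = mu.copy()

    # GP-style chronic conditions: near-superset of the morbidity flags
    # plus an independent chronic mass among unflagged persons
    morbid_share = float(any_morbid.mean())
    if morbid_share < 1.0:
        q = (config.chronic_target
             - config.chronic_given_morbid * morbid_share) / (1.0 - morbid_share)
        q = float(np.clip(q, 0.0, 1.0))
    else:
        q = 0.0
    p_chronic = np.where(any_morbid, config.chronic_given_morbid, q)
    chronic = person_rng.random(n) < p_chronic
    n_cond = np.zeros(n, dtype=int)
    n_cond[chronic] = 1 + person_rng.poisson(config.extra_conditions_rate,
                                             size=int(chronic.sum()))
    n_cond = np.minimum(n_cond, config.n_conditions)
    popularity = 1.0 / (np.arange(config.n_conditions) + 4.0)
    popularity /= popularity.sum()
    flat = person_rng.choice(config.n_conditions, size=int(n_cond.sum()),
                             p=popularity)
    cond_cat = config.condition_catalogue
    offsets = np.concatenate(([0], np.cumsum(n_cond)))

    records: list[PersonRecord] = []
    morb_names = [b.name for b in config.morbidity_blocks]
    width = len(str(n))
    for i in range(n):
        label = ag_labels[ag_idx[i]]
        gender, band = label.split("|")
        lo, hi = offsets[i], offsets[i + 1]
        conditions = (
            frozenset(cond_cat[c] for c in flat[lo:hi]) if hi > lo else _EMPTY
        )
        records.append(
            PersonRecord(
                person_id=f"p{i:0{width}d}",
                insured_fraction=float(fraction[i]),
                spending_annualized=float(y[i]),
                age_band=band,
                gender=gender,
                adjuster_flags={
                    name: str(block_labels[name][i]) for name in morb_names
                },
                dxgroups=frozenset(dx_sets[i]) if dx_sets[i] else _EMPTY,
                conditions=conditions,
            )
        )

    truth: dict[str, float] = {}
    for label, coef in zip(ag_labels, ag_coefs):
        truth[f"{AGE_GENDER}:{label}"] = float(coef)
    for block in config.morbidity_blocks:
        for label, coef in zip(block.labels, block.coefficients):
            truth[f"{block.name}:{label}"] = float(coef)
    for gid, coef in zip(catalogue, dx_coefs):
        truth[f"dx:{gid}"] = float(coef)
    return records, truth


# ---------------------------------------------------------------------------
# Subsample
# ---------------------------------------------------------------------------


def generate_subsample(
    records: list[PersonRecord],
    config: GeneratorConfig,
) -> list[PersonRecord]:
    """Draw a morbidity-enriched subsample emulating GP-practice data.

    Persons flagged by any morbidity adjuster or dxgroup are
    over-represented by ``config.enrichment_factor`` (1.0 = plain random
    subsample), so the subsample's weighted mean spending exceeds the
    population's, as in registry-versus-GP comparisons.
    """
    if config.subsample_fraction > 1.0:
        raise ValidationError("subsample cannot exceed the population")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(3)[2]
    )
    morbid = np.array(
        [bool(r.dxgroups) or any(v != NONE_CLASS
                                 for v in r.adjuster_flags.values())
         for r in records]
    )
    factor = np.where(morbid, config.enrichment_factor, 1.0)
    target = config.subsample_fraction * len(records)
    p = np.minimum(target * factor / factor.sum(), 1.0)
    keep = rng.random(len(records)) < p
    return [records[i] for i in np.nonzero(keep)[0]]


# ---------------------------------------------------------------------------
# Claims history (dxgroup screening input)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosisClaims:
    """Two consecutive claim years for one candidate diagnosis."""

    diagnosis_id: str
    year1: frozenset[int]
    year2: frozenset[int]
    spending: dict[int, float]  # per year-1 patient, euros


@dataclass(frozen=True)
class ClaimsHistory:
    n_persons: int
    diagnoses: tuple[DiagnosisClaims, ...]


def generate_claims_history(
    config: GeneratorConfig,
    persistence: np.ndarray | None = None,
    prevalence: np.ndarray | None = None,
    mean_spending: np.ndarray | None = None,
) -> ClaimsHistory:
    """Two-year patient sets per candidate diagnosis.

    ``persistence`` is the probability that a year-1 patient is diagnosed
    again in year 2; the year-2 set is topped up with new patients so its
    size matches year 1, hence a persistence target of 1 makes the sets
    identical.  Per-diagnosis parameters default to random draws from the
    configured ranges (recorded through the seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    m = config.n_candidate_diagnoses
    if persistence is None:
        persistence = rng.uniform(*config.persistence_range, size=m)
    persistence = np.asarray(persistence, dtype=float)
    m = len(persistence)
    if np.any((persistence < 0) | (persistence > 1)):
        raise ValidationError("persistence targets must lie in [0,1]")
    if prevalence is None:
        prevalence = rng.uniform(*config.candidate_prevalence_range, size=m)
    prevalence = np.asarray(prevalence, dtype=float)
    if mean_spending is None:
        mean_spending = np.exp(rng.normal(7.2, 0.6, size=m))
    mean_spending = np.asarray(mean_spending, dtype=float)

    n = config.n_persons
    out: list[DiagnosisClaims] = []
    for d in range(m):
        size = int(round(prevalence[d] * n))
        year1 = rng.choice(n, size=size, replace=False) if size else np.array([], int)
        survive = rng.random(size) < persistence[d] if size else np.array([], bool)
        survivors = year1[survive]
        n_new = size - len(survivors)
        pool = np.setdiff1d(np.arange(n), year1, assume_unique=False)
        new = rng.choice(pool, size=min(n_new, len(pool)), replace=False)
        year2 = np.concatenate([survivors, new])
        spend = rng.gamma(1.0, mean_spending[d], size=size) if size else np.array([])
        out.append(
            DiagnosisClaims(
                diagnosis_id=f"cand{d + 1:03d}",
                year1=frozenset(int(i) for i in year1),
                year2=frozenset(int(i) for i in year2),
                spending={int(i): float(s) for i, s in zip(year1, spend)},
            )
        )
    return ClaimsHistory(n_persons=n, diagnoses=tuple(out))
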