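"""Synthetic stress-strain record generator.

Stands in for the digitized literature curves behind the 15-study
compilation: for each study and strain-rate regime it emits monotone true
stress / true strain curves whose stiffness responds to the study's
testing conditions in the directions the experimental literature reports
— stiffer at higher loading rate, with donor age, at physiological
temperatures, with post-mortem preservation time, and differing between
white, gray and mixed tissue.

The curve shape is a one-term exponential hyperelastic form

    sigma(eps) = k * (exp(alpha * eps) - 1)

with the stiffness scale ``k`` a product of monotone modifier functions of
the testing conditions, times multiplicative lognormal noise.  This is a
deliberately simple toy constitutive law: positive, monotone, and letting
every input parameter leave a recoverable trace in the outputs — no claim
of biofidelity is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .studies import (REGIME_RATE_BANDS, StudyConfig, default_study_table,
                      study_points, validate_allocation, default_regime_allocation)

#: Column schema of a raw record table (SI units; temperatures in degC).
RECORD_COLUMNS = [
    "study_id", "stress_state", "rate_regime",
    "age_months", "strain_rate_per_s", "diameter_m", "thickness_m",
    "composition", "testing_temp_C", "storage_temp_C", "postmortem_s",
    "true_strain", "true_stress_Pa",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic constitutive law.

    Defaults encode the qualitative dependencies reported across the
    source studies: positive rate sensitivity, age stiffening past
    infancy, stiffer response at physiological temperature, slow
    stiffening with post-mortem time, and gray matter slightly stiffer
    than white with mixed tissue in between.
    """

    seed: int = 0
    points_per_curve: int = 30
    noise_cv: float = 0.05              # CV of multiplicative lognormal noise
    base_stiffness_pa: float = 1000.0   # k at reference conditions
    strain_nonlinearity: float = 2.0    # alpha in sigma = k*(exp(alpha*eps)-1)
    rate_exponent: float = 0.15         # k ~ rate^exponent  (must be > 0)
    age_slope: float = 0.3              # k ~ (age/6mo)^slope
    temp_slope: float = 0.01            # k ~ exp(slope * (T - 22degC)), both temps
    pmt_slope: float = 0.01             # k ~ 1 + slope * hours post mortem
    geom_exponent: float = 0.1          # k ~ (diameter/thickness)^exponent
    composition_factors: dict = field(default_factory=lambda: {
        "white": 0.8, "gray": 1.0, "mixed": 0.9})
    max_strain_tension: float = 0.5     # true strain span of a tension curve
    max_strain_compression: float = 0.5

    def __post_init__(self):
        if self.rate_exponent <= 0:
            raise ValueError("rate_exponent must be > 0 (tissue stiffens with rate)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.points_per_curve < 1:
            raise ValueError("points_per_curve must be >= 1")
        if min(self.max_strain_tension, self.max_strain_compression) <= 0:
            raise ValueError("max strains must be positive")


def stiffness_scale(params: GeneratorParams, *, strain_rate: float, age_months: float,
                    testing_temp_C: float, storage_temp_C: float, postmortem_h: float,
                    composition: str, diameter_mm: float, thickness_mm: float) -> float:
    """Deterministic stiffness k for one curve (noise excluded)."""
    k = params.base_stiffness_pa
    k *= strain_rate ** params.rate_exponent
    k *= (age_months / 6.0) ** params.age_slope
    k *= math.exp(params.temp_slope * (testing_temp_C - 22.0))
    k *= math.exp(params.temp_slope * (storage_temp_C - 22.0))
    k *= 1.0 + params.pmt_slope * postmortem_h
    k *= params.composition_factors[composition]
    k *= (diameter_mm / thickness_mm) ** params.geom_exponent
    return k


def generate_curve(config: StudyConfig, regime: str, n: int, rng: np.random.Generator,
                   params: GeneratorParams | None = None,
                   strain_rate: float | None = None) -> pd.DataFrame:
    """Generate one monotone stress-strain curve of ``n`` records.

    Per-curve attribute values (age, thickness, composition, ...) are
    sampled uniformly from the study's value sets; the strain rate is
    sampled log-uniformly from the regime's band unless given explicitly.
    Strains are evenly spread over (0, max_strain].
    """
    params = params or GeneratorParams()
    if regime not in config.rate_regimes:
        raise ValueError(f"study {config.study_id} has no {regime!r} regime "
                         f"(regimes: {config.rate_regimes})")
    if n < 1:
        raise ValueError("n must be >= 1")

    def pick(values):
        return values[rng.integers(len(values))]

    age = pick(config.age_months)
    dia = pick(config.diameter_mm)
    thick = pick(config.thickness_mm)
    comp = pick(config.composition)
    t_test = pick(config.testing_temp_C)
    t_store = pick(config.storage_temp_C)
    pmt = pick(config.postmortem_h)
    if strain_rate is None:
        lo, hi = REGIME_RATE_BANDS[regime]
        strain_rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    max_strain = (params.max_strain_tension if config.stress_state == "tension"
                  else params.max_strain_compression)
    eps = np.linspace(max_strain / n, max_strain, n)
    k = stiffness_scale(params, strain_rate=strain_rate, age_months=age,
                        testing_temp_C=t_test, storage_temp_C=t_store,
                        postmortem_h=pmt, composition=comp,
                        diameter_mm=dia, thickness_mm=thick)
    sigma = k * np.expm1(params.strain_nonlinearity * eps)
    if params.noise_cv > 0:
        s = math.sqrt(math.log1p(params.noise_cv ** 2))
        sigma = sigma * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)

    return pd.DataFrame({
        "study_id": config.study_id,
        "stress_state": config.stress_state,
        "rate_regime": regime,
        "age_months": float(age),
        "strain_rate_per_s": float(strain_rate),
        "diameter_m": dia * 1e-3,
        "thickness_m": thick * 1e-3,
        "composition": comp,
        "testing_temp_C": float(t_test),
        "storage_temp_C": float(t_store),
        "postmortem_s": pmt * 3600.0,
        "true_strain": eps,
        "true_stress_Pa": sigma,
    }, columns=RECORD_COLUMNS)


def generate_dataset(table: list[StudyConfig] | None = None,
                     params: GeneratorParams | None = None,
                     allocation: dict | None = None) -> pd.DataFrame:
    """Generate the full synthetic compilation (default: 5579 records).

    Per-study record counts equal the study table's n_points; within
    two-regime studies the split follows the packaged default allocation
    so the five state-by-regime subsets land on their documented sizes.
    Identical seed and parameters give a bit-identical table.
    """
    if table is None:
        table = default_study_table()
    if not table:
        raise ValueError("study table is empty")
    params = params or GeneratorParams()
    needs_alloc = any(len(c.rate_regimes) > 1 for c in table)
    if allocation is None and needs_alloc:
        allocation = default_regime_allocation()
    if allocation is not None:
        validate_allocation(table, allocation)

    root = np.random.SeedSequence(params.seed)
    children = root.spawn(len(table))
    frames = []
    for cfg, child in zip(table, children):
        rng = np.random.default_rng(child)
        counts = study_points(cfg, allocation)
        for regime in cfg.rate_regimes:  # fixed order for determinism
            remaining = counts[regime]
            while remaining > 0:
                n = min(params.points_per_curve, remaining)
                frames.append(generate_curve(cfg, regime, n, rng, params))
                remaining -= n
    out = pd.concat(frames, ignore_index=True)
    return out


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record CSV missing columns: {sorted(missing)}")
    return df[RECORD_COLUMNS]
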