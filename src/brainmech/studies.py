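"""Source-study metadata for the brain stress-strain compilation.

The compiled dataset emulated by this package aggregates uniaxial tension
and compression tests on cylindrical brain specimens from 15 published
studies.  Each study is described by a :class:`StudyConfig`: the specimen
properties (donor age, diameter, thickness, white/gray/mixed composition)
and testing conditions (strain-rate regime(s), testing and storage
temperature, post-mortem preservation time) under which its stress-strain
points were recorded, plus the number of digitized data points it
contributes.

Several studies report a *set* of values for a field (e.g. multiple
specimen thicknesses, or white and gray matter tested separately); such
fields are stored as tuples and the synthetic generator samples from them
curve by curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

STRESS_STATES = ("tension", "compression")
RATE_REGIMES = ("quasi-static", "intermediate", "high")
COMPOSITIONS = ("white", "gray", "mixed")

#: Strain-rate bands (1/s) per regime used when sampling rates.  The
#: quasi-static band follows the rates quoted for quasi-static tension
#: (0.0064-0.64 1/s); the intermediate and high bands extend it up to
#: split-Hopkinson-bar territory.  Regime *labels* always come from the
#: study table, never from the sampled rate.
REGIME_RATE_BANDS = {
    "quasi-static": (0.0064, 0.64),
    "intermediate": (0.64, 90.0),
    "high": (90.0, 3000.0),
}


def _as_tuple(x) -> tuple:
    if isinstance(x, (tuple, list, set, frozenset)):
        return tuple(x)
    return (x,)


@dataclass(frozen=True)
class StudyConfig:
    """Metadata for one source study (one row of the compilation table).

    Fields that can take several values in one study (ages, thicknesses,
    compositions, temperatures) accept a scalar or a sequence; they are
    normalized to tuples.
    """

    study_id: str
    age_months: tuple  # months
    stress_state: str  # "tension" | "compression"
    rate_regimes: tuple  # subset of RATE_REGIMES
    diameter_mm: tuple
    thickness_mm: tuple
    composition: tuple  # subset of COMPOSITIONS
    testing_temp_C: tuple
    storage_temp_C: tuple
    postmortem_h: tuple  # hours
    n_points: int

    def __post_init__(self):
        for name in ("age_months", "rate_regimes", "diameter_mm", "thickness_mm",
                     "composition", "testing_temp_C", "storage_temp_C", "postmortem_h"):
            object.__setattr__(self, name, _as_tuple(getattr(self, name)))
        if self.stress_state not in STRESS_STATES:
            raise ValueError(f"stress_state must be one of {STRESS_STATES}, got {self.stress_state!r}")
        bad = set(self.rate_regimes) - set(RATE_REGIMES)
        if bad:
            raise ValueError(f"unknown rate regimes {sorted(bad)}")
        bad = set(self.composition) - set(COMPOSITIONS)
        if bad:
            raise ValueError(f"unknown compositions {sorted(bad)}")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        for name in ("age_months", "diameter_mm", "thickness_mm", "postmortem_h"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} values must be positive")
        if any(v < 0 for v in self.testing_temp_C) or any(v < 0 for v in self.storage_temp_C):
            # 0 degC (ice-cold storage/testing) is legitimate; below is not used here
            raise ValueError("temperatures below 0 degC are not supported")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def default_study_table() -> list[StudyConfig]:
    """The 15-study compilation: 903 tension + 4676 compression = 5579 points.

    Transcribed from the source-summary table of the compilation; every
    study is tension-only or compression-only, at one to two strain-rate
    regimes.
    """
    S = StudyConfig
    return [
        S("miller_chinzei_1997", 6, "compression", ("quasi-static",), 30, 13,
          "gray", 5, 22, 12, 111),
        S("pervin_chen_2009", 18, "compression", ("quasi-static", "high"), 4.7, 1.7,
          ("white", "gray"), 37, 25, 4, 996),
        S("pervin_chen_2011", (6, 12, 18), "compression", ("quasi-static", "high"), 4.7, 1.7,
          ("white", "gray"), 37, 25, 4, 1900),
        S("zhang_2011", 6, "compression", ("high",), 13, 3,
          "mixed", (0, 37), 37, 4, 133),
        S("rashid_2012_comp", 6, "compression", ("intermediate",), 15, 5,
          "mixed", 5, 22, 8, 219),
        S("miller_chinzei_2002", 6, "tension", ("quasi-static",), 30, 10,
          "gray", 5, 22, 12, 185),
        S("shen_2006", 6, "compression", ("quasi-static",), 24, 9,
          "mixed", 4, 37, 24, 85),
        S("rashid_2012_tens", 6, "tension", ("intermediate",), 15, 10,
          "mixed", 5, 22, 4, 116),
        S("rashid_2013_tens", 6, "tension", ("intermediate",), 15, (4, 7, 10),
          "mixed", 4, 22, 3, 151),
        S("tamura_2007", 6, "tension", ("quasi-static", "intermediate"), 14, 14,
          "white", 4, 22, 4, 190),
        S("rashid_2014_tens", 6, "tension", ("quasi-static", "intermediate"), 15, (3, 4, 5, 6, 8),
          "mixed", 4.5, 22, 16.5, 261),
        S("rashid_2014_comp_a", 6, "compression", ("intermediate",), 15, 6.1,
          "mixed", 4.5, 22, 3, 204),
        S("rashid_2014_comp_b", 6, "compression", ("quasi-static", "intermediate"), 15, 5.1,
          "mixed", 4.5, 22, 3, 170),
        S("li_2019", 1, "compression", ("quasi-static", "intermediate"), 9, 5,
          "mixed", 4.5, 22, 6, 158),
        S("li_2020", 2, "compression", ("quasi-static", "intermediate"), 8, 5,
          ("white", "mixed"), 4, 25, 7, 700),
    ]


def default_regime_allocation() -> dict[str, dict[str, int]]:
    """Per-study split of n_points across rate regimes.

    The compilation table gives only per-study totals; the split across
    regimes within two-regime studies is a free choice constrained so the
    five state-by-regime subset totals come out at 370/533/1686/755
    (quasi-static tension / intermediate tension / quasi-static compression
    / intermediate compression) with the one leftover record landing in
    high-rate compression.  The default split is recorded in a packaged
    JSON fixture so every run reproduces it.
    """
    with resources.files("brainmech.data").joinpath("regime_allocation.json").open() as fh:
        return json.load(fh)


def validate_allocation(table: Iterable[StudyConfig],
                        allocation: dict[str, dict[str, int]]) -> None:
    """Check an allocation covers each study's regimes and sums to n_points."""
    for cfg in table:
        alloc = allocation.get(cfg.study_id)
        if len(cfg.rate_regimes) == 1:
            if alloc is not None and set(alloc) != set(cfg.rate_regimes):
                raise ValueError(f"{cfg.study_id}: allocation names wrong regimes")
            continue
        if alloc is None:
            raise ValueError(f"{cfg.study_id}: multi-regime study needs an allocation")
        if set(alloc) != set(cfg.rate_regimes):
            raise ValueError(f"{cfg.study_id}: allocation regimes {sorted(alloc)} "
                             f"!= study regimes {sorted(cfg.rate_regimes)}")
        if any(n < 1 for n in alloc.values()):
            raise ValueError(f"{cfg.study_id}: allocation counts must be >= 1")
        if sum(alloc.values()) != cfg.n_points:
            raise ValueError(f"{cfg.study_id}: allocation sums to {sum(alloc.values())}, "
                             f"expected {cfg.n_points}")


def study_points(cfg: StudyConfig,
                 allocation: dict[str, dict[str, int]] | None = None) -> dict[str, int]:
    """Number of points per regime for one study under an allocation."""
    if len(cfg.rate_regimes) == 1:
        return {cfg.rate_regimes[0]: cfg.n_points}
    if allocation is None:
        allocation = default_regime_allocation()
    validate_allocation([cfg], allocation)
    return dict(allocation[cfg.study_id])


def save_study_table(table: Iterable[StudyConfig], path: str | Path) -> None:
    path = Path(path)
    payload = [cfg.to_dict() for cfg in table]
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_study_table(path: str | Path) -> list[StudyConfig]:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return [StudyConfig(**entry) for entry in payload]
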