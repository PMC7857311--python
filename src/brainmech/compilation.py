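"""Compile raw stress-strain records into normalized analysis matrices.

Raw records (one row per digitized stress-strain point, SI units) become
a :class:`CompiledDataset`: a numeric matrix with every column divided by
its peak (maximum absolute) value so all entries lie in [0, 1], the
categorical white/gray/mixed composition encoded numerically, and peaks
retained for the inverse transform.  The full compilation splits into
seven analysis subsets — tension, compression, and the five stress-state
by rate-regime combinations — each carrying only the input parameters
that actually vary there and each normalized on its own rows.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Categorical encoding of brain-matter composition.
COMPOSITION_CODES = {"white": 0.33, "gray": 0.66, "mixed": 1.00}

#: Analysis-column name -> raw record column.
ANALYSIS_COLUMNS = {
    "age": "age_months",
    "strain_rate": "strain_rate_per_s",
    "diameter": "diameter_m",
    "thickness": "thickness_m",
    "composition": "composition",
    "storage_temp": "storage_temp_C",
    "testing_temp": "testing_temp_C",
    "postmortem_time": "postmortem_s",
}
OUTPUT_COLUMNS = {"true_strain": "true_strain", "true_stress": "true_stress_Pa"}

_ALL_INPUTS = list(ANALYSIS_COLUMNS)
_TENSION_INPUTS = ["strain_rate", "diameter", "thickness", "composition",
                   "storage_temp", "postmortem_time"]

#: Input-parameter sets of the seven analysis subsets.  Tension subsets
#: carry no age or testing-temperature column and high-rate compression
#: no post-mortem column (those parameters do not discriminate there).
SUBSET_INPUTS = {
    "tension": _TENSION_INPUTS,
    "compression": _ALL_INPUTS,
    "quasi_static_tension": _TENSION_INPUTS,
    "intermediate_tension": _TENSION_INPUTS,
    "quasi_static_compression": _ALL_INPUTS,
    "intermediate_compression": _ALL_INPUTS,
    "high_compression": [c for c in _ALL_INPUTS if c != "postmortem_time"],
}

_SUBSET_OF = {
    ("tension", "quasi-static"): "quasi_static_tension",
    ("tension", "intermediate"): "intermediate_tension",
    ("compression", "quasi-static"): "quasi_static_compression",
    ("compression", "intermediate"): "intermediate_compression",
    ("compression", "high"): "high_compression",
}

#: Source-unit converters accepted by :func:`convert_units`.
_UNIT_FACTORS = {
    "m": 1.0, "mm": 1e-3, "cm": 1e-2,
    "s": 1.0, "h": 3600.0, "min": 60.0,
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6,
    "degC": 1.0, "months": 1.0, "1/s": 1.0, "": 1.0,
}


def to_true(eng_strain, eng_stress):
    """Engineering -> true (logarithmic strain, current-area stress).

    true_strain = ln(1 + e), true_stress = s * (1 + e).  Accepts scalars
    or arrays; engineering strain must exceed -1.
    """
    e = np.asarray(eng_strain, dtype=float)
    s = np.asarray(eng_stress, dtype=float)
    if np.any(e <= -1):
        raise ValueError("engineering strain must be > -1")
    t_eps = np.log1p(e)
    t_sig = s * (1.0 + e)
    if np.isscalar(eng_strain) or e.ndim == 0:
        return float(t_eps), float(t_sig)
    return t_eps, t_sig


def encode_composition(label: str) -> float:
    """white -> 0.33, gray -> 0.66, mixed -> 1.00."""
    try:
        return COMPOSITION_CODES[label]
    except KeyError:
        raise ValueError(f"unknown composition {label!r}; "
                         f"expected one of {sorted(COMPOSITION_CODES)}") from None


def convert_units(values, unit: str):
    """Convert values in a declared source unit to SI (temperatures stay degC)."""
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown source unit {unit!r}")
    factor = _UNIT_FACTORS[unit]
    arr = np.asarray(values, dtype=float) * factor
    return float(arr) if arr.ndim == 0 else arr


@dataclass
class CompiledDataset:
    """Peak-normalized numeric matrix plus the metadata to undo it."""

    matrix: np.ndarray           # N x p, entries in [0, 1]
    column_names: list[str]
    peaks: np.ndarray            # per-column divisor (1.0 where unscaled)
    subset_label: str = "full"

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def input_names(self) -> list[str]:
        return [c for c in self.column_names if c not in OUTPUT_COLUMNS]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names)

    def denormalized(self) -> pd.DataFrame:
        """Inverse transform: multiply each column by its stored peak."""
        return pd.DataFrame(self.matrix * self.peaks, columns=self.column_names)

    def write(self, directory: str | Path) -> None:
        """Write ``<subset>.csv`` plus a JSON sidecar with peaks and counts."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / f"{self.subset_label}.csv", index=False)
        sidecar = {
            "subset": self.subset_label,
            "n_rows": int(self.n_rows),
            "columns": self.column_names,
            "peaks": [float(p) for p in self.peaks],
        }
        (directory / f"{self.subset_label}.json").write_text(
            json.dumps(sidecar, indent=2))


def normalize(records: pd.DataFrame, columns: list[str] | None = None,
              subset_label: str = "full") -> CompiledDataset:
    """Build the peak-normalized matrix for the requested analysis columns.

    Each numeric column is divided by its maximum absolute value over the
    rows being normalized; the composition column is the categorical
    encoding (already on [0, 1]) and is not rescaled.  All-zero columns
    are left unscaled with a warning.
    """
    if len(records) == 0:
        raise ValueError("no records to normalize")
    if columns is None:
        columns = _ALL_INPUTS + list(OUTPUT_COLUMNS)
    cols, peaks = [], []
    raw_names = {**ANALYSIS_COLUMNS, **OUTPUT_COLUMNS}
    for name in columns:
        raw = raw_names.get(name, name)
        if raw not in records.columns:
            raw = name
        if name == "composition" and records[raw].dtype == object:
            vals = records[raw].map(encode_composition).to_numpy(dtype=float)
            peak = 1.0
        else:
            vals = records[raw].to_numpy(dtype=float)
            peak = float(np.max(np.abs(vals)))
            if peak == 0.0:
                warnings.warn(f"column {name!r} is all zero; left unscaled")
                peak = 1.0
            else:
                vals = vals / peak
        cols.append(vals)
        peaks.append(peak)
    matrix = np.column_stack(cols)
    return CompiledDataset(matrix=matrix, column_names=list(columns),
                           peaks=np.asarray(peaks), subset_label=subset_label)


def split_subsets(records: pd.DataFrame,
                  include_stress_state_sets: bool = True) -> dict[str, CompiledDataset]:
    """Partition records into the seven analysis subsets and normalize each.

    Returns tension, compression, and the five state-by-regime subsets,
    each restricted to its documented input-parameter set and normalized
    on its own rows.  Records with a stress-state/regime pair outside the
    schema (e.g. high-rate tension) are rejected.
    """
    pairs = set(zip(records["stress_state"], records["rate_regime"]))
    bad = sorted(p for p in pairs if p not in _SUBSET_OF)
    if bad:
        raise ValueError(f"records carry state/regime pairs with no subset: {bad}")

    out: dict[str, CompiledDataset] = {}
    for state in ("tension", "compression"):
        if not include_stress_state_sets:
            break
        mask = records["stress_state"] == state
        out[state] = _subset(records[mask], state)
    for (state, regime), name in _SUBSET_OF.items():
        mask = (records["stress_state"] == state) & (records["rate_regime"] == regime)
        out[name] = _subset(records[mask], name)
    return out


def _subset(rows: pd.DataFrame, name: str) -> CompiledDataset:
    columns = SUBSET_INPUTS[name] + list(OUTPUT_COLUMNS)
    if len(rows) == 0:
        warnings.warn(f"subset {name!r} is empty")
        p = len(columns)
        return CompiledDataset(matrix=np.empty((0, p)), column_names=columns,
                               peaks=np.ones(p), subset_label=name)
    return normalize(rows, columns, subset_label=name)
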