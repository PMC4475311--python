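"""CSV schema validation and run configuration.

One unambiguous CSV dialect throughout: UTF-8, comma-separated, '.' decimal
separator, mandatory header row.  Validation never partially succeeds
silently: a file either parses into typed records or yields a report
listing every violation with its row number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .carbon_balance import BalanceConstants, CultureObservation
from .isotope_flux import DEFAULT_ALPHA, IsotopologueMeasurement


@dataclass
class RunConfig:
    """Defaults reproducing the study parameterization.

    alpha = 0.0345 (basal labeling ratio), recovery fraction f = 0.96,
    carbonate pKa = 6.35, OD600-to-DCW factor 0.35 g/L per OD unit.
    """

    alpha: float = DEFAULT_ALPHA
    mode: str = "exact"
    constants: BalanceConstants = field(default_factory=BalanceConstants)
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        const_keys = {
            "carbons_per_xylose",
            "co2_molar_mass_mg_per_mmol",
            "carbon_recovery_fraction",
            "biomass_carbon_fraction_gC_per_gDCW",
            "specific_co2_secretion_mmol_per_gDCW_h",
        }
        const = {k: v for k, v in data.items() if k in const_keys}
        rest = {k: v for k, v in data.items() if k not in const_keys}
        return cls(constants=BalanceConstants(**const), **rest)


class SchemaError(ValueError):
    """Raised when a CSV fails validation; carries the full report."""

    def __init__(self, path: str | Path, errors: list[str]):
        self.path = str(path)
        self.errors = list(errors)
        lines = "\n".join(f"  - {e}" for e in self.errors)
        super().__init__(f"{path}: {len(self.errors)} schema violation(s):\n{lines}")


SCHEMAS: dict[str, dict[str, list[str]]] = {
    "isotopologues": {
        "required": ["sample_id", "strain", "time_h", "x_unlabeled", "y_labeled"],
        "numeric": ["time_h", "x_unlabeled", "y_labeled"],
    },
    "cultures": {
        "required": [
            "strain",
            "role",
            "consumed_xylose_mmol_L",
            "biomass_gDCW_L",
            "duration_h",
            "initial_pH",
            "final_pH",
        ],
        "numeric": [
            "consumed_xylose_mmol_L",
            "biomass_gDCW_L",
            "duration_h",
            "initial_pH",
            "final_pH",
            "sd_xylose",
            "sd_biomass",
        ],
    },
    "replicates": {
        "required": ["strain", "replicate_id", "consumed_xylose_mmol_L", "biomass_gDCW_L"],
        "numeric": ["consumed_xylose_mmol_L", "biomass_gDCW_L"],
    },
}

# per-cell invariants: (column, predicate on value, message)
_INVARIANTS: dict[str, list[tuple[str, str]]] = {
    "isotopologues": [
        ("x_unlabeled", "x_unlabeled must be > 0"),
        ("y_labeled", "y_labeled must be >= 0"),
        ("time_h", "time_h must be >= 0"),
    ],
    "cultures": [
        ("consumed_xylose_mmol_L", "consumed_xylose_mmol_L must be > 0"),
        ("biomass_gDCW_L", "biomass_gDCW_L must be > 0"),
        ("duration_h", "duration_h must be > 0"),
    ],
    "replicates": [
        ("consumed_xylose_mmol_L", "consumed_xylose_mmol_L must be > 0"),
        ("biomass_gDCW_L", "biomass_gDCW_L must be > 0"),
    ],
}

_STRICTLY_POSITIVE = {
    "x_unlabeled",
    "consumed_xylose_mmol_L",
    "biomass_gDCW_L",
    "duration_h",
}


def validate_csv(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Parse and validate a CSV against a named schema.

    Returns the typed frame on success; raises :class:`SchemaError` with a
    report of every violation (missing columns, non-numeric cells, broken
    invariants) otherwise.  Row numbers in the report are 1-based data
    rows (the header is row 0).
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such file: {path}")
    schema = SCHEMAS[schema_name]
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:
        raise SchemaError(path, [f"unparseable CSV: {exc}"]) from exc

    errors: list[str] = []
    missing = [c for c in schema["required"] if c not in frame.columns]
    for col in missing:
        errors.append(f"missing required column '{col}'")
    if missing:
        raise SchemaError(path, errors)

    for col in schema["numeric"]:
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        for i in bad:
            errors.append(f"row {i + 1}: non-numeric value {frame.at[i, col]!r} in '{col}'")
        frame[col] = coerced

    for col, message in _INVARIANTS.get(schema_name, []):
        values = frame[col]
        if col in _STRICTLY_POSITIVE:
            bad = frame.index[values.notna() & (values <= 0)]
        else:
            bad = frame.index[values.notna() & (values < 0)]
        for i in bad:
            errors.append(f"row {i + 1}: {message} (got {values[i]!r})")

    if errors:
        raise SchemaError(path, errors)
    return frame


def read_isotopologues(path: str | Path) -> list[IsotopologueMeasurement]:
    frame = validate_csv(path, "isotopologues")
    return [
        IsotopologueMeasurement(
            sample_id=str(r.sample_id),
            strain=str(r.strain),
            time_h=float(r.time_h),
            x_unlabeled=float(r.x_unlabeled),
            y_labeled=float(r.y_labeled),
        )
        for r in frame.itertuples(index=False)
    ]


def read_cultures(
    path: str | Path, replicates_path: str | Path | None = None
) -> dict[str, CultureObservation]:
    """Read culture observations keyed by role ('test'/'control').

    An optional long-format replicates file attaches per-replicate
    (xylose, biomass) pairs to matching strains.
    """
    frame = validate_csv(path, "cultures")
    reps_by_strain: dict[str, list[tuple[float, float]]] = {}
    if replicates_path is not None:
        reps = validate_csv(replicates_path, "replicates")
        for r in reps.itertuples(index=False):
            reps_by_strain.setdefault(str(r.strain), []).append(
                (float(r.consumed_xylose_mmol_L), float(r.biomass_gDCW_L))
            )
    out: dict[str, CultureObservation] = {}
    for r in frame.itertuples(index=False):
        role = str(r.role).strip().lower()
        if role not in ("test", "control"):
            raise SchemaError(path, [f"role must be 'test' or 'control', got {r.role!r}"])
        reps = reps_by_strain.get(str(r.strain))
        sd_x = getattr(r, "sd_xylose", None)
        sd_b = getattr(r, "sd_biomass", None)
        out[role] = CultureObservation(
            strain=str(r.strain),
            consumed_xylose_mmol_per_L=float(r.consumed_xylose_mmol_L),
            biomass_gDCW_per_L=float(r.biomass_gDCW_L),
            duration_h=float(r.duration_h),
            initial_pH=float(r.initial_pH),
            final_pH=float(r.final_pH),
            replicates=tuple(reps) if reps else None,
            sd_xylose=None if sd_x is None or pd.isna(sd_x) else float(sd_x),
            sd_biomass=None if sd_b is None or pd.isna(sd_b) else float(sd_b),
        )
    if "test" not in out or "control" not in out:
        raise SchemaError(path, ["need one 'test' and one 'control' row"])
    return out
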