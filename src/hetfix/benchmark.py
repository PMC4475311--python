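"""Benchmark of autotrophic vs heterotrophic CO2-fixation rates.

Ships a transcription of published volumetric rates (mg CO2 L^-1 h^-1),
biomass concentrations and specific rates for 14 autotrophic microbes
(microalgae, cyanobacteria, non-green algae) and 3 engineered heterotrophic
bacteria, and recomputes the derived columns so user strains can be placed
in context.  Printed specific rates are preserved alongside recomputed
ones; rows whose printed value differs from 1-decimal rounding of
rate/biomass are flagged, not corrected.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

GROUPS = ("microalgae", "cyanobacteria", "non-green algae", "bacteria")
AUTOTROPH_GROUPS = ("microalgae", "cyanobacteria", "non-green algae")
HETEROTROPH_GROUPS = ("bacteria",)

_COLUMNS = [
    "species",
    "group",
    "volumetric_rate_mg_L_h",
    "biomass_gDCW_L",
    "specific_rate_printed_mg_gDCW_h",
    "co2_percent",
    "culture_condition",
    "source",
]


@dataclass(frozen=True)
class FixationRecord:
    """One benchmark row: a species and its published fixation figures."""

    species: str
    group: str
    volumetric_rate_mg_L_h: float
    biomass_gDCW_L: float
    specific_rate_printed_mg_gDCW_h: float | None = None
    co2_percent: float = float("nan")
    culture_condition: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.species}: unknown group {self.group!r}")
        if self.volumetric_rate_mg_L_h <= 0:
            raise ValueError(f"{self.species}: volumetric rate must be > 0")
        if self.biomass_gDCW_L <= 0:
            raise ValueError(f"{self.species}: biomass must be > 0")

    @property
    def specific_rate_computed(self) -> float:
        return self.volumetric_rate_mg_L_h / self.biomass_gDCW_L

    @property
    def specific_rate(self) -> float:
        """Printed specific rate when available, else computed."""
        if self.specific_rate_printed_mg_gDCW_h is not None:
            return self.specific_rate_printed_mg_gDCW_h
        return self.specific_rate_computed


def _records_from_frame(frame: pd.DataFrame) -> list[FixationRecord]:
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"benchmark table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        printed = getattr(row, "specific_rate_printed_mg_gDCW_h")
        printed = None if printed is None or (isinstance(printed, float) and math.isnan(printed)) else float(printed)
        records.append(
            FixationRecord(
                species=str(row.species),
                group=str(row.group),
                volumetric_rate_mg_L_h=float(row.volumetric_rate_mg_L_h),
                biomass_gDCW_L=float(row.biomass_gDCW_L),
                specific_rate_printed_mg_gDCW_h=printed,
                co2_percent=float(row.co2_percent),
                culture_condition=str(row.culture_condition),
                source=str(row.source),
            )
        )
    return records


def parse_benchmark_csv(text: str) -> list[FixationRecord]:
    """Parse benchmark records from CSV text ('#' lines are comments)."""
    frame = pd.read_csv(io.StringIO(text), comment="#")
    return _records_from_frame(frame)


def load_benchmark() -> list[FixationRecord]:
    """Load the packaged benchmark table (17 rows: 14 autotrophs, 3 bacteria)."""
    ref = resources.files("hetfix").joinpath("data/table2_benchmark.csv")
    try:
        text = ref.read_text(encoding="utf-8")
    except (FileNotFoundError, OSError) as exc:
        raise RuntimeError("packaged benchmark table is missing or unreadable") from exc
    records = parse_benchmark_csv(text)
    n_auto = sum(r.group in AUTOTROPH_GROUPS for r in records)
    if n_auto != 14:
        raise RuntimeError(
            f"packaged benchmark table is corrupted: {n_auto} autotroph rows, expected 14"
        )
    return records


def recompute_specific_rates(records: Sequence[FixationRecord]) -> pd.DataFrame:
    """Recompute specific rates and flag rows that disagree with print.

    A discrepancy flag marks rows where 1-decimal rounding of
    rate/biomass differs from the printed specific rate (those printed
    values were evidently derived from unrounded source data); the printed
    value is kept, the table is not "corrected".
    """
    if not records:
        raise ValueError("no records")
    rows = []
    for r in records:
        computed = round(r.specific_rate_computed, 1)
        printed = r.specific_rate_printed_mg_gDCW_h
        rows.append(
            {
                "species": r.species,
                "computed_specific_rate": computed,
                "printed_specific_rate": printed,
                "discrepancy": printed is not None and not math.isclose(computed, printed, abs_tol=1e-9),
            }
        )
    return pd.DataFrame(rows)


class SummaryStats(NamedTuple):
    min_rate: float
    max_rate: float
    median_rate: float
    min_specific: float
    max_specific: float


def _filter(records: Iterable[FixationRecord], group_filter) -> list[FixationRecord]:
    records = list(records)
    if group_filter is None:
        return records
    if callable(group_filter):
        return [r for r in records if group_filter(r)]
    if isinstance(group_filter, str):
        if group_filter == "autotroph":
            groups: tuple[str, ...] = AUTOTROPH_GROUPS
        elif group_filter == "heterotroph":
            groups = HETEROTROPH_GROUPS
        else:
            groups = (group_filter,)
    else:
        groups = tuple(group_filter)
    return [r for r in records if r.group in groups]


def summary_stats(
    records: Sequence[FixationRecord], group_filter=None
) -> SummaryStats:
    """Min/max/median volumetric rate and min/max specific rate.

    ``group_filter`` may be None, "autotroph", "heterotroph", a group name,
    an iterable of group names, or a predicate on records.  The median uses
    the mean-of-middle-two convention for even counts; specific rates come
    from the printed column when present.
    """
    kept = _filter(records, group_filter)
    if not kept:
        raise ValueError("no records after filtering")
    rates = sorted(r.volumetric_rate_mg_L_h for r in kept)
    specifics = [r.specific_rate for r in kept]
    n = len(rates)
    mid = n // 2
    median = rates[mid] if n % 2 else (rates[mid - 1] + rates[mid]) / 2.0
    return SummaryStats(
        min_rate=min(rates),
        max_rate=max(rates),
        median_rate=median,
        min_specific=min(specifics),
        max_specific=max(specifics),
    )


def render_comparison(
    records: Sequence[FixationRecord],
    user_strains: Sequence[FixationRecord] = (),
    format: str = "csv",
) -> str:
    """Render the benchmark, with user strains appended under 'bacteria'.

    Ordering is deterministic: group (microalgae, cyanobacteria, non-green
    algae, bacteria) then descending volumetric rate.  CSV output round-
    trips through :func:`parse_benchmark_csv`.
    """
    if format not in ("csv", "markdown"):
        raise ValueError(f"unknown format {format!r}")
    merged = list(records) + [replace(r, group="bacteria") for r in user_strains]
    order = {g: i for i, g in enumerate(GROUPS)}
    merged.sort(key=lambda r: (order[r.group], -r.volumetric_rate_mg_L_h, r.species))
    frame = pd.DataFrame(
        [
            {
                "species": r.species,
                "group": r.group,
                "volumetric_rate_mg_L_h": r.volumetric_rate_mg_L_h,
                "biomass_gDCW_L": r.biomass_gDCW_L,
                "specific_rate_printed_mg_gDCW_h": r.specific_rate_printed_mg_gDCW_h,
                "co2_percent": r.co2_percent,
                "culture_condition": r.culture_condition,
                "source": r.source,
            }
            for r in merged
        ],
        columns=_COLUMNS,
    )
    if format == "csv":
        return frame.to_csv(index=False)
    show = frame.copy()
    show["specific_rate_mg_gDCW_h"] = [round(r.specific_rate, 1) for r in merged]
    show = show.drop(columns=["specific_rate_printed_mg_gDCW_h"])
    header = "| " + " | ".join(show.columns) + " |"
    sep = "|" + "|".join([" --- "] * len(show.columns)) + "|"
    lines = [header, sep]
    for _, row in show.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
    return "\n".join(lines) + "\n"
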