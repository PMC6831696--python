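"""Standardisation of raw occurrence records.

Raw biological records arrive as "what, when, where" rows of uneven
precision: grid references from 10 m to 10 km, dates from exact days to year
ranges.  The occupancy analysis needs a uniform resolution — 1 km grid cell,
day-level date, years 1970-2015 — with duplicates removed and species names
resolved against a decision table (synonyms, aggregates, exclusions).  Every
rejected record is counted by reason so that raw = clean + rejected holds
exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime

import pandas as pd

from .gridrefs import (
    CoarseGridRefError,
    GridRefError,
    parse_grid_reference,
    truncate_to_1km,
)

REGIONS = ("England", "Scotland", "Wales", "Northern Ireland")

REJECTION_REASONS = (
    "above_species_rank",
    "unparseable_gridref",
    "coarse_gridref",
    "unparseable_date",
    "imprecise_date",
    "out_of_window",
    "outside_territory",
    "excluded_name",
    "duplicate",
)

# Name-decision actions (semantics of the Species_Names table).
ACTIONS = ("keep", "synonym_of", "aggregate_into", "exclude", "retain_no_model")

_ISO_RE = re.compile(r"\d{4}-\d{2}-\d{2}")
_DMY_RE = re.compile(r"\d{2}/\d{2}/\d{4}")
_YEAR_RE = re.compile(r"\d{4}")
_YEAR_RANGE_RE = re.compile(r"\d{4}\s*[-–/]\s*\d{4}")


class ConfigurationError(ValueError):
    """Raised for invalid name-decision tables (e.g. cyclic mappings)."""


@dataclass
class RejectionLog:
    """Counts of rejected records by reason, plus an optional per-record audit."""

    counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in REJECTION_REASONS})
    audit: list[tuple[int, str, str]] = field(default_factory=list)
    defaulted_names: set[str] = field(default_factory=set)

    def add(self, index: int, reason: str, detail: str = "") -> None:
        self.counts[reason] += 1
        self.audit.append((index, reason, detail))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reason": list(self.counts), "count": list(self.counts.values())}
        )


def parse_event_date(date_raw: str) -> date:
    """Parse a day-precision date string (ISO ``YYYY-MM-DD`` or ``DD/MM/YYYY``).

    Year-only and year-range strings are precision failures
    (``imprecise_date``); anything else, including empty strings and
    two-digit years, is ``unparseable_date``.  The distinction is carried by
    the exception message tag.
    """
    s = str(date_raw).strip()
    if _ISO_RE.fullmatch(s):
        try:
            return datetime.strptime(s, "%Y-%m-%d").date()
        except ValueError as e:
            raise ValueError(f"unparseable_date: {e}") from None
    if _DMY_RE.fullmatch(s):
        try:
            return datetime.strptime(s, "%d/%m/%Y").date()
        except ValueError as e:
            raise ValueError(f"unparseable_date: {e}") from None
    if _YEAR_RE.fullmatch(s) or _YEAR_RANGE_RE.fullmatch(s):
        raise ValueError(f"imprecise_date: {s!r} lacks day precision")
    raise ValueError(f"unparseable_date: {date_raw!r}")


def _looks_above_species_rank(name: str) -> bool:
    """Heuristic for records identified above species rank.

    Single-token names (bare genera) and names ending in "sp."/"spp." are
    treated as supra-specific.  Aggregate names ("agg.", "s.l.") stay.
    """
    toks = name.strip().split()
    if len(toks) <= 1:
        return True
    return toks[-1].lower() in {"sp.", "spp.", "sp", "spp"}


def resolve_name_decisions(decisions: pd.DataFrame) -> dict[str, tuple[str, str | None]]:
    """Compile a decision table into ``raw_name -> (action, canonical_name)``.

    Synonym/aggregate chains are followed to their terminal name; cycles are
    a configuration error.  ``canonical_name`` is None for exclusions.
    """
    table: dict[str, tuple[str, str]] = {}
    for row in decisions.itertuples(index=False):
        action = str(row.action).strip()
        if action not in ACTIONS:
            raise ConfigurationError(f"unknown action {action!r} for {row.raw_name!r}")
        target = str(getattr(row, "target_name", "") or "").strip()
        if action in ("synonym_of", "aggregate_into") and not target:
            raise ConfigurationError(f"{action} for {row.raw_name!r} needs a target_name")
        table[str(row.raw_name).strip()] = (action, target)

    resolved: dict[str, tuple[str, str | None]] = {}
    for raw in table:
        name, seen = raw, set()
        while True:
            if name in seen:
                raise ConfigurationError(f"cyclic name decisions through {name!r}")
            seen.add(name)
            act, target = table.get(name, ("keep", ""))
            if act in ("synonym_of", "aggregate_into"):
                name = target
                continue
            # keep / retain_no_model / exclude terminate the chain
            resolved[raw] = (act, None if act == "exclude" else name)
            break
    return resolved


def apply_name_decisions(
    records: pd.DataFrame, decisions: pd.DataFrame | None, log: RejectionLog
) -> pd.DataFrame:
    """Map raw species names to canonical names; drop exclusions.

    Names absent from the table default to ``keep`` and are noted in the
    log.  Adds ``species`` (canonical) and ``modelled`` (False for
    retain-no-model names, which still inform list length) columns.
    """
    if decisions is None or len(decisions) == 0:
        resolved = {}
    else:
        resolved = resolve_name_decisions(decisions)

    keep_idx, canon, modelled = [], [], []
    for idx, raw_name in records["species_raw"].items():
        action, target = resolved.get(str(raw_name).strip(), ("keep", str(raw_name).strip()))
        if action == "exclude":
            log.add(idx, "excluded_name", str(raw_name))
            continue
        if str(raw_name).strip() not in resolved:
            log.defaulted_names.add(str(raw_name).strip())
        keep_idx.append(idx)
        canon.append(target)
        modelled.append(action != "retain_no_model")

    out = records.loc[keep_idx].copy()
    out["species"] = canon
    out["modelled"] = modelled
    return out


def standardise(
    raw: pd.DataFrame,
    decisions: pd.DataFrame | None = None,
    region_lookup: pd.DataFrame | None = None,
    year_window: tuple[int, int] = (1970, 2015),
) -> tuple[pd.DataFrame, RejectionLog]:
    """Full standardisation: raw records -> clean 1 km / day records.

    ``raw`` needs columns ``group, species, gridref, date`` (an optional
    ``source`` column is ignored for deduplication).  ``region_lookup`` maps
    1 km cell labels to regions; cells absent from it are outside the study
    territory.  Returns the clean records and a :class:`RejectionLog`
    satisfying raw = clean + rejected.
    """
    log = RejectionLog()
    df = raw.reset_index(drop=True).rename(
        columns={"species": "species_raw", "gridref": "gridref_raw", "date": "date_raw"}
    )

    # 1. supra-specific identifications go before name decisions
    mask_rank = df["species_raw"].astype(str).map(_looks_above_species_rank).astype(bool)
    for idx in df.index[mask_rank]:
        log.add(idx, "above_species_rank", str(df.at[idx, "species_raw"]))
    df = df[~mask_rank]

    # 2. grid reference -> 1 km cell (parse unique strings once)
    cell_of: dict[str, object] = {}
    for ref in df["gridref_raw"].astype(str).unique():
        try:
            cell_of[ref] = truncate_to_1km(parse_grid_reference(ref))
        except CoarseGridRefError:
            cell_of[ref] = "coarse_gridref"
        except GridRefError:
            cell_of[ref] = "unparseable_gridref"

    keep, cells = [], []
    for idx, ref in df["gridref_raw"].astype(str).items():
        res = cell_of[ref]
        if isinstance(res, str):
            log.add(idx, res, ref)
        else:
            keep.append(idx)
            cells.append(res)
    df = df.loc[keep]
    df = df.assign(cell=[c.label for c in cells], grid_system=[c.system for c in cells])

    # 3. day-precision dates within the study window
    keep, days, years = [], [], []
    for idx, raw_date in df["date_raw"].astype(str).items():
        try:
            d = parse_event_date(raw_date)
        except ValueError as e:
            reason = "imprecise_date" if str(e).startswith("imprecise_date") else "unparseable_date"
            log.add(idx, reason, raw_date)
            continue
        if not (year_window[0] <= d.year <= year_window[1]):
            log.add(idx, "out_of_window", raw_date)
            continue
        keep.append(idx)
        days.append(d)
        years.append(d.year)
    df = df.loc[keep].assign(date=days, year=years)

    # 4. territory check via the cell->region lookup
    if region_lookup is not None and len(region_lookup):
        region_of = dict(
            zip(region_lookup["cell_label"].astype(str), region_lookup["region"].astype(str))
        )
    else:
        region_of = {}
    keep, regions = [], []
    for idx, cell in df["cell"].items():
        reg = region_of.get(cell)
        if reg is None:
            log.add(idx, "outside_territory", cell)
        else:
            keep.append(idx)
            regions.append(reg)
    df = df.loc[keep].assign(region=regions)

    # 5. name decisions (synonyms, aggregates, exclusions)
    df = apply_name_decisions(df, decisions, log)

    # 6. deduplicate on (canonical species, cell, day)
    dup_mask = df.duplicated(subset=["species", "cell", "date"], keep="first")
    for idx in df.index[dup_mask]:
        log.add(idx, "duplicate", f"{df.at[idx, 'species']}@{df.at[idx, 'cell']}")
    df = df[~dup_mask]

    clean = df[
        ["group", "species", "cell", "grid_system", "date", "year", "region", "modelled"]
    ].reset_index(drop=True)
    assert len(raw) == len(clean) + log.total, "record conservation violated"
    return clean, log
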