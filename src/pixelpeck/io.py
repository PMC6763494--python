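"""File formats: ``.pat`` pattern files, choices CSV, flat config files.

The ``.pat`` dialect is one record per pattern: a header line ``>`` +
identifier (optionally ``|key=value`` metadata fields), followed by exactly
7 lines of exactly 5 characters, ``#`` = lit and ``.`` = unlit. Blank lines
are ignored; anything else is a parse error with a line number.

Choices live in a CSV with header
``test_id,pigeon_id,team,n_trials,n_correct[,percent_correct]``; when a
percent column is present it is cross-checked against the tallies.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .grids import PixelGrid
from .stats import TEAMS, ChoiceRecord


class FormatError(ValueError):
    """A malformed input file (message carries the offending line number)."""


# ---------------------------------------------------------------------------
# .pat pattern files
# ---------------------------------------------------------------------------


def read_patterns(path: str | os.PathLike) -> dict[str, PixelGrid]:
    """Parse a ``.pat`` file into an ordered ``id -> PixelGrid`` mapping."""
    grids: dict[str, PixelGrid] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {i + 1}: expected a '>' header line")
        ident = line[1:].split("|", 1)[0].strip()
        if not ident:
            raise FormatError(f"{path}: line {i + 1}: empty pattern identifier")
        if ident in grids:
            raise FormatError(f"{path}: line {i + 1}: duplicate id {ident!r}")
        body = lines[i + 1: i + 8]
        if len(body) < 7:
            raise FormatError(f"{path}: line {i + 1}: truncated record {ident!r}")
        try:
            grids[ident] = PixelGrid.from_text(body)
        except ValueError as exc:
            raise FormatError(f"{path}: record {ident!r} (line {i + 2}): {exc}") from exc
        i += 8
    return grids


def write_patterns(
    path: str | os.PathLike,
    grids: Mapping[str, PixelGrid],
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    with open(path, "w") as fh:
        for ident, grid in grids.items():
            meta = (metadata or {}).get(ident, {})
            suffix = "".join(f"|{k}={v}" for k, v in meta.items())
            fh.write(f">{ident}{suffix}\n{grid.to_text()}\n")


# ---------------------------------------------------------------------------
# Choices CSV
# ---------------------------------------------------------------------------

CHOICES_COLUMNS = ("test_id", "pigeon_id", "team", "n_trials", "n_correct")


def read_choices(path: str | os.PathLike) -> list[ChoiceRecord]:
    """Read and validate a choices CSV.

    When a ``percent_correct`` column is present it must agree with
    ``100 * n_correct / n_trials`` to within half a percent point.
    """
    df = pd.read_csv(path)
    missing = [c for c in CHOICES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        team = str(row["team"])
        if team not in TEAMS:
            raise FormatError(f"{path}: line {line}: unknown team label {team!r}")
        try:
            rec = ChoiceRecord(
                test_id=int(row["test_id"]),
                pigeon_id=str(row["pigeon_id"]),
                team=team,
                n_trials=int(row["n_trials"]),
                n_correct=int(row["n_correct"]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from exc
        if "percent_correct" in df.columns and not pd.isna(row["percent_correct"]):
            stated = float(row["percent_correct"])
            if abs(stated - rec.percent_correct) > 0.5:
                raise FormatError(
                    f"{path}: line {line}: percent_correct {stated} inconsistent "
                    f"with tallies ({rec.percent_correct:.1f})"
                )
        records.append(rec)
    return records


def write_choices(path: str | os.PathLike, records: Iterable[ChoiceRecord]) -> None:
    rows = [
        {
            "test_id": r.test_id, "pigeon_id": r.pigeon_id, "team": r.team,
            "n_trials": r.n_trials, "n_correct": r.n_correct,
            "percent_correct": round(r.percent_correct, 2),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

#: Keys accepted in a run-configuration file, with their defaults.
CONFIG_DEFAULTS: dict = {
    "training_variant": "A",
    "r_threshold": 0.30,
    "max_shift_rows": 2,
    "max_shift_cols": 2,
    "adjust_translocation": True,
    "seed": 0,
}


def read_config(path: str | os.PathLike) -> dict:
    """Flat key-value YAML config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    unknown = set(data) - set(CONFIG_DEFAULTS)
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    merged = dict(CONFIG_DEFAULTS)
    merged.update(data)
    if not (0.0 <= float(merged["r_threshold"]) <= 1.0):
        raise FormatError(f"{path}: r_threshold outside [0, 1]")
    if merged["training_variant"] not in ("A", "B", "C"):
        raise FormatError(f"{path}: unknown training_variant")
    return merged


# ---------------------------------------------------------------------------
# Deposited-spreadsheet adapter (best effort, import only)
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "test_id": ("test_id", "test", "test_no", "testnumber", "test_number"),
    "pigeon_id": ("pigeon_id", "pigeon", "bird", "subject"),
    "team": ("team", "group"),
    "n_trials": ("n_trials", "trials", "n_test_trials"),
    "n_correct": ("n_correct", "correct", "n_choices_correct"),
}


def import_deposited_table(path: str | os.PathLike) -> pd.DataFrame:
    """Best-effort mapping of a locally stored deposited data sheet
    (CSV or Excel) onto the package's choices-CSV column layout.

    The deposited sheets are described only in prose, so this adapter
    matches columns by name heuristically and raises when a required field
    cannot be located. It never fetches anything over the network.
    """
    path = os.fspath(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    lowered = {str(c).strip().lower().replace(" ", "_"): c for c in df.columns}
    out = {}
    for target, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                out[target] = df[lowered[alias]]
                break
        else:
            raise FormatError(
                f"{path}: could not locate a column for {target!r}; "
                f"available: {list(df.columns)}"
            )
    return pd.DataFrame(out)
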