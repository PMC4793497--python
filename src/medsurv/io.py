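"""Reading and writing survival tables and simulation summaries.

Input is a delimited text file with one row per subject and three columns:
observed time, event indicator, group label.  The event convention is
delta = 1 for an observed event and delta = 0 for a right-censored
observation — the opposite of some file formats, so it is worth restating.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .km_core import SurvivalSample
from .median_test import GroupedSurvivalData

__all__ = [
    "SurvivalTableSchema",
    "read_survival_table",
    "write_survival_table",
    "write_simulation_summary",
    "make_fixture",
    "FIXTURE_KINDS",
]

_TRUE_ALIASES = {"1", "true", "dead", "event", "yes"}
_FALSE_ALIASES = {"0", "false", "alive", "censored", "no"}


@dataclass(frozen=True)
class SurvivalTableSchema:
    """Column names and delimiter of a survival table file."""

    time_column: str = "time"
    event_column: str = "event"
    group_column: str = "group"
    delimiter: str = ","
    allow_event_aliases: bool = False

    def __post_init__(self) -> None:
        cols = (self.time_column, self.event_column, self.group_column)
        if len(set(cols)) != 3:
            raise ConfigurationError(f"column names must be distinct, got {cols}")


def _parse_events(raw: pd.Series, schema: SurvivalTableSchema) -> np.ndarray:
    """Map the event column to {0,1}, naming offending rows on failure."""
    out = np.empty(len(raw), dtype=np.int8)
    for pos, (idx, val) in enumerate(raw.items()):
        s = str(val).strip().lower()
        if s in _FALSE_ALIASES and (schema.allow_event_aliases or s == "0"):
            out[pos] = 0
        elif s in _TRUE_ALIASES and (schema.allow_event_aliases or s == "1"):
            out[pos] = 1
        else:
            raise InvalidInputError(
                f"row {idx + 2}: event value {val!r} is not 0/1"
                + ("" if schema.allow_event_aliases else " (aliases disabled)")
            )
    return out


def read_survival_table(
    path: Union[str, Path],
    schema: SurvivalTableSchema = SurvivalTableSchema(),
) -> GroupedSurvivalData:
    """Load a delimited survival table into grouped samples.

    Groups appear in the result in their order of first appearance in the
    file.  Rows with missing or unparseable fields are rejected with their
    (1-based, header-inclusive) line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str)
    for col in (schema.time_column, schema.event_column, schema.group_column):
        if col not in df.columns:
            raise InvalidInputError(
                f"missing column {col!r}; file has {list(df.columns)}"
            )
    missing = df[
        [schema.time_column, schema.event_column, schema.group_column]
    ].isna()
    if missing.any().any():
        rows = [int(i) + 2 for i in df.index[missing.any(axis=1)]]
        raise InvalidInputError(f"missing fields in rows {rows}")
    # float() is a correctly-rounded parser; pandas' fast path is not, and
    # the write-then-read round trip is contractually exact
    times = np.empty(len(df))
    bad_rows = []
    for pos, (idx, val) in enumerate(df[schema.time_column].items()):
        try:
            times[pos] = float(val)
        except (TypeError, ValueError):
            bad_rows.append(int(idx) + 2)
    if bad_rows:
        raise InvalidInputError(f"unparseable time values in rows {bad_rows}")
    events = _parse_events(df[schema.event_column], schema)
    groups = df[schema.group_column].to_numpy()
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise InvalidInputError(
            f"need K >= 2 groups, file has {len(labels)} ({labels})"
        )
    samples = [
        SurvivalSample(
            times=times[groups == lab],
            events=events[groups == lab],
            label=lab,
        )
        for lab in labels
    ]
    return GroupedSurvivalData(samples)


def write_survival_table(
    data: GroupedSurvivalData,
    path: Union[str, Path],
    schema: SurvivalTableSchema = SurvivalTableSchema(),
) -> None:
    """Serialize grouped samples to a delimited file (round-trip exact)."""
    frames = [
        pd.DataFrame(
            {
                schema.time_column: g.times,
                schema.event_column: g.events.astype(int),
                schema.group_column: g.label,
            }
        )
        for g in data.groups
    ]
    # %.17g keeps the binary64 round-trip exact
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=schema.delimiter, index=False, float_format="%.17g"
    )


def write_simulation_summary(
    records: Iterable[dict], path: Union[str, Path], delimiter: str = ","
) -> None:
    """Write one record per scenario x variant as delimited text."""
    pd.DataFrame(list(records)).to_csv(path, sep=delimiter, index=False)


FIXTURE_KINDS = ("toy_uncensored", "toy_censored")


def make_fixture(
    kind: str,
    seed: Optional[int],
    path: Union[str, Path],
    schema: SurvivalTableSchema = SurvivalTableSchema(),
) -> Path:
    """Write a deterministic survival table for demos and smoke tests.

    ``toy_uncensored``: two identical uncensored groups with times 1..4 —
    hand-checkable KM values (composite variance 0.09375 per group at the
    pooled median 2) and a guaranteed p-value of 1.
    ``toy_censored``: two small groups with censored observations.
    ``scenario:<table>:<row>:<rate>``: one dataset drawn from the named
    simulation scenario with the given seed.
    """
    from .sim_engine import generate_grouped_data, scenario_catalog

    path = Path(path)
    if kind == "toy_uncensored":
        data = GroupedSurvivalData(
            [
                SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1], label="A"),
                SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1], label="B"),
            ]
        )
    elif kind == "toy_censored":
        data = GroupedSurvivalData(
            [
                SurvivalSample([1, 2, 3, 4, 5], [0, 1, 1, 1, 0], label="A"),
                SurvivalSample([1, 2, 3, 4], [1, 1, 0, 1], label="B"),
            ]
        )
    elif kind.startswith("scenario:"):
        parts = kind.split(":")
        if len(parts) != 4:
            raise ConfigurationError(
                f"scenario fixture kind must be scenario:<table>:<row>:<rate>, "
                f"got {kind!r}"
            )
        spec = scenario_catalog(
            table=int(parts[1]), row=parts[2], censor_rate=float(parts[3])
        )
        rng = np.random.default_rng(seed)
        data = generate_grouped_data(spec, rng)
        # infinite censoring never reaches the file: Z is always finite
    else:
        raise ConfigurationError(
            f"unknown fixture kind {kind!r}; valid: {FIXTURE_KINDS} "
            "or scenario:<table>:<row>:<rate>"
        )
    write_survival_table(data, path, schema)
    return path
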