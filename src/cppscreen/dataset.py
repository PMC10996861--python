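"""Speaker records, cohorts and the two CSV dialects.

A cohort stores one :class:`SpeakerRecord` per subject: an identifier, sex,
age, age group (young = 5-7 years, older = 8-12), a binary diagnosis label
(``SMS`` for Smith-Magenis syndrome, ``N`` for normotypic controls) and the
pooled sequence of per-frame CPP values extracted from that subject's
recordings.

Two CSV dialects are supported:

* long format (input): one row per CPP value with columns
  ``speaker_id,sex,age,age_group,label,cpp``;
* the windowed feature-table format (output): columns
  ``Name,CPP1..CPPn,Target,Sex,Group`` with dotted subgroup names such as
  ``SMS3.3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

SEXES = ("female", "male")
AGE_GROUPS = ("young", "older")
LABELS = ("SMS", "N")

LONG_COLUMNS = ["speaker_id", "sex", "age", "age_group", "label", "cpp"]


@dataclass
class SpeakerRecord:
    """One subject: metadata plus the pooled CPP value stream."""

    speaker_id: str
    sex: str
    age: float
    age_group: str
    label: str
    cpp_values: np.ndarray

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"unknown age group {self.age_group!r}; expected one of {AGE_GROUPS}"
            )
        if self.label not in LABELS:
            raise ValidationError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )
        values = np.asarray(self.cpp_values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError(
                f"speaker {self.speaker_id}: cpp_values must be a non-empty 1-D sequence"
            )
        self.cpp_values = values

    @property
    def n_values(self) -> int:
        return self.cpp_values.size


@dataclass
class Cohort:
    """A collection of speakers with unique identifiers."""

    records: list[SpeakerRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.speaker_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate speaker ids: {dupes}")
        if len(self.records) < 2:
            raise ValidationError("a cohort needs at least 2 speakers")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def speaker_ids(self) -> list[str]:
        return [r.speaker_id for r in self.records]

    @property
    def counts(self) -> list[int]:
        """Per-speaker CPP value counts, in record order."""
        return [r.n_values for r in self.records]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.label] = out.get(r.label, 0) + 1
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "speaker_id": self.speaker_ids,
                "sex": [r.sex for r in self.records],
                "age": [r.age for r in self.records],
                "age_group": [r.age_group for r in self.records],
                "label": [r.label for r in self.records],
                "n_values": self.counts,
                "mean_cpp": [float(r.cpp_values.mean()) for r in self.records],
            }
        )

    def to_long_frame(self) -> pd.DataFrame:
        parts = []
        for r in self.records:
            parts.append(
                pd.DataFrame(
                    {
                        "speaker_id": r.speaker_id,
                        "sex": r.sex,
                        "age": r.age,
                        "age_group": r.age_group,
                        "label": r.label,
                        "cpp": r.cpp_values,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


def _normalize_token(value: str, vocabulary: tuple[str, ...], column: str, row: int) -> str:
    token = str(value).strip()
    for candidate in vocabulary:
        if token.lower() == candidate.lower():
            return candidate
    raise ValidationError(
        f"row {row}: unknown {column} token {value!r}; expected one of {vocabulary}"
    )


def cohort_from_long_frame(frame: pd.DataFrame) -> Cohort:
    """Build a cohort from a long-format table, grouping rows by speaker_id
    (by key, not adjacency) and preserving within-speaker row order."""
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"long-format table is missing columns {missing}")
    if len(frame) == 0:
        raise ValidationError("long-format table contains no rows")
    records = []
    for speaker_id, group in frame.groupby("speaker_id", sort=False):
        first_row = int(group.index[0])
        records.append(
            SpeakerRecord(
                speaker_id=str(speaker_id),
                sex=_normalize_token(group["sex"].iloc[0], SEXES, "sex", first_row),
                age=float(group["age"].iloc[0]),
                age_group=_normalize_token(
                    group["age_group"].iloc[0], AGE_GROUPS, "age_group", first_row
                ),
                label=_normalize_token(group["label"].iloc[0], LABELS, "label", first_row),
                cpp_values=group["cpp"].to_numpy(dtype=float),
            )
        )
    return Cohort(records)


def read_cohort_csv(path) -> Cohort:
    """Read a long-format cohort CSV (UTF-8, comma-separated, '.' decimal)."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty cohort file") from exc
    return cohort_from_long_frame(frame)


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.to_long_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Windowed feature-table dialect
# ---------------------------------------------------------------------------

_SEX_DIALECT = {"female": "Female", "male": "Male"}
_GROUP_DIALECT = {"young": "Young", "older": "Older"}


@dataclass
class WindowedTable:
    """Fixed-width feature table: one row per subgroup of ``nprime``
    consecutive CPP values from a single speaker.

    ``data`` holds columns ``Name, CPP1..CPPnprime, Target, Sex, Group``;
    names carry a dotted subgroup suffix (``<speaker>.<k>``, k from 1).
    """

    data: pd.DataFrame
    nprime: int

    def __post_init__(self) -> None:
        expected = windowed_columns(self.nprime)
        got = list(self.data.columns)
        if got != expected:
            raise ValidationError(
                f"windowed table columns {got} do not match expected {expected}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def feature_columns(self) -> list[str]:
        return [f"CPP{i}" for i in range(1, self.nprime + 1)]

    def features(self) -> np.ndarray:
        return self.data[self.feature_columns].to_numpy(dtype=float)

    def targets(self) -> np.ndarray:
        return self.data["Target"].to_numpy()

    def speaker_of_rows(self) -> np.ndarray:
        """Speaker id of each row (dotted subgroup suffix stripped)."""
        return self.data["Name"].str.rsplit(".", n=1).str[0].to_numpy()

    def speaker_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.speaker_of_rows():
            seen.setdefault(s)
        return list(seen)


def windowed_columns(nprime: int) -> list[str]:
    return ["Name"] + [f"CPP{i}" for i in range(1, nprime + 1)] + ["Target", "Sex", "Group"]


def write_windowed_csv(table: WindowedTable, path) -> None:
    """Write the feature-table dialect (exact header order, e.g.
    ``Name,CPP1,...,CPP7,Target,Sex,Group``)."""
    out = table.data.copy()
    out["Sex"] = out["Sex"].map(lambda s: _SEX_DIALECT.get(s, s))
    out["Group"] = out["Group"].map(lambda s: _GROUP_DIALECT.get(s, s))
    try:
        out.to_csv(path, index=False)
    except OSError as exc:
        raise ValidationError(f"cannot write windowed table to {path}: {exc}") from exc


def read_windowed_csv(path) -> WindowedTable:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty windowed table") from exc
    feature_cols = [c for c in frame.columns if c.startswith("CPP")]
    nprime = len(feature_cols)
    if nprime == 0:
        raise ValidationError(f"{path}: no CPP feature columns found")
    frame["Sex"] = frame["Sex"].map(lambda s: str(s).strip().lower())
    frame["Group"] = frame["Group"].map(lambda s: str(s).strip().lower())
    for i, target in enumerate(frame["Target"]):
        if target not in LABELS:
            raise ValidationError(f"row {i}: unknown Target token {target!r}")
    return WindowedTable(data=frame[windowed_columns(nprime)], nprime=nprime)
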