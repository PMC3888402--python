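"""Study I/O: a fixed long-form CSV dialect plus validation.

Data CSV columns: ``dyad,person,second,behavior_code,emotion_pixel`` — one row
per person-second, UTF-8, comma-separated, header required. Metadata CSV
columns: ``dyad,group``. Either stream of a record may be absent; absence is
an empty cell, never a zero (0 is a legal pixel value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

VALID_CODES = (1, 2, 3)
PIXEL_RANGE = (0, 1123)
VALID_GROUPS = ("intractable", "tractable", "unknown")

DATA_COLUMNS = ["dyad", "person", "second", "behavior_code", "emotion_pixel"]
META_COLUMNS = ["dyad", "group"]


@dataclass
class SessionRecord:
    """One person's streams within one dyadic session."""

    dyad_id: str
    person: int
    group: str = "unknown"
    behavior: np.ndarray | None = None  # per-second codes in {1,2,3}
    emotion: np.ndarray | None = None   # per-second integer pixels in [0,1123]

    def __eq__(self, other):
        if not isinstance(other, SessionRecord):
            return NotImplemented
        def _arr_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return len(a) == len(b) and bool(np.all(np.asarray(a) == np.asarray(b)))
        return (
            self.dyad_id == other.dyad_id
            and self.person == other.person
            and self.group == other.group
            and _arr_eq(self.behavior, other.behavior)
            and _arr_eq(self.emotion, other.emotion)
        )


@dataclass
class Violation:
    field: str
    index: int | None
    value: object
    message: str


@dataclass
class StudyTable:
    """A validated collection of session records with unique (dyad, person)."""

    records: list[SessionRecord]
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        keys = [(r.dyad_id, r.person) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise FormatError(f"duplicate (dyad, person) records: {dupes}")

    def __eq__(self, other):
        if not isinstance(other, StudyTable):
            return NotImplemented
        return self.records == other.records and self.provenance == other.provenance

    def groups(self) -> dict[str, list[SessionRecord]]:
        out: dict[str, list[SessionRecord]] = {}
        for r in self.records:
            out.setdefault(r.group, []).append(r)
        return out


def validate_session(record: SessionRecord) -> list[Violation]:
    """Check a record against the coding domains; violations are data, not
    exceptions, and the record is never mutated."""
    out: list[Violation] = []
    if record.person not in (1, 2):
        out.append(Violation("person", None, record.person, "person must be 1 or 2"))
    if record.group not in VALID_GROUPS:
        out.append(Violation("group", None, record.group,
                             f"group must be one of {VALID_GROUPS}"))
    if record.behavior is not None:
        codes = np.asarray(record.behavior)
        bad = np.nonzero(~np.isin(codes, VALID_CODES))[0]
        for i in bad[:20]:
            out.append(Violation("behavior", int(i), codes[i],
                                 "behavior code must be in {1,2,3}"))
    if record.emotion is not None:
        px = np.asarray(record.emotion)
        lo, hi = PIXEL_RANGE
        bad = np.nonzero((px < lo) | (px > hi) | (px != np.rint(px)))[0]
        for i in bad[:20]:
            out.append(Violation("emotion", int(i), px[i],
                                 f"emotion pixel must be an integer in [{lo},{hi}]"))
    return out


def write_study(study: StudyTable, data_path, metadata_path) -> None:
    """Write the study deterministically (rows sorted by dyad, person, second)."""
    frames = []
    for rec in sorted(study.records, key=lambda r: (r.dyad_id, r.person)):
        nb = len(rec.behavior) if rec.behavior is not None else 0
        ne = len(rec.emotion) if rec.emotion is not None else 0
        n = max(nb, ne)
        if n == 0:
            continue
        df = pd.DataFrame({
            "dyad": rec.dyad_id,
            "person": rec.person,
            "second": np.arange(n),
            "behavior_code": pd.array(
                list(rec.behavior) + [pd.NA] * (n - nb) if nb else [pd.NA] * n,
                dtype="Int64"),
            "emotion_pixel": pd.array(
                list(rec.emotion) + [pd.NA] * (n - ne) if ne else [pd.NA] * n,
                dtype="Int64"),
        })
        frames.append(df)
    data = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=DATA_COLUMNS))
    data.to_csv(data_path, index=False, lineterminator="\n")

    meta_rows = sorted({(r.dyad_id, r.group) for r in study.records})
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    meta.to_csv(metadata_path, index=False, lineterminator="\n")


def read_study(data_path, metadata_path) -> StudyTable:
    """Read and validate a study; raises FormatError naming the offender."""
    data = pd.read_csv(data_path)
    meta = pd.read_csv(metadata_path)
    for col in DATA_COLUMNS:
        if col not in data.columns:
            raise FormatError(f"data file missing required column '{col}'")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"metadata file missing required column '{col}'")
    group_of = dict(zip(meta["dyad"].astype(str), meta["group"].astype(str)))
    for dyad, grp in group_of.items():
        if grp not in VALID_GROUPS:
            raise FormatError(f"dyad {dyad}: unknown group label {grp!r}")

    records: list[SessionRecord] = []
    warnings: list[str] = []
    for (dyad, person), sub in data.groupby(["dyad", "person"], sort=True):
        dyad = str(dyad)
        person = int(person)
        sub = sub.sort_values("second")
        seconds = sub["second"].to_numpy()
        if len(seconds) == 0:
            continue
        if seconds[0] != 0 or not np.array_equal(seconds, np.arange(len(seconds))):
            raise FormatError(
                f"dyad {dyad}, person {person}: seconds not contiguous from 0"
            )
        behavior = None
        if sub["behavior_code"].notna().any():
            if sub["behavior_code"].isna().any():
                raise FormatError(
                    f"dyad {dyad}, person {person}: behavior stream has gaps"
                )
            behavior = sub["behavior_code"].to_numpy(dtype=np.int64)
            if not np.isin(behavior, VALID_CODES).all():
                bad = behavior[~np.isin(behavior, VALID_CODES)][0]
                raise FormatError(
                    f"dyad {dyad}, person {person}: behavior code {bad} not in {{1,2,3}}"
                )
        emotion = None
        if sub["emotion_pixel"].notna().any():
            if sub["emotion_pixel"].isna().any():
                raise FormatError(
                    f"dyad {dyad}, person {person}: emotion stream has gaps"
                )
            emotion = sub["emotion_pixel"].to_numpy(dtype=np.int64)
            lo, hi = PIXEL_RANGE
            if emotion.min() < lo or emotion.max() > hi:
                bad = emotion[(emotion < lo) | (emotion > hi)][0]
                raise FormatError(
                    f"dyad {dyad}, person {person}: emotion pixel {bad} "
                    f"outside [{lo},{hi}]"
                )
        group = group_of.get(dyad, "unknown")
        records.append(SessionRecord(dyad, person, group, behavior, emotion))

    persons_per_dyad: dict[str, set[int]] = {}
    for r in records:
        persons_per_dyad.setdefault(r.dyad_id, set()).add(r.person)
    for dyad, persons in sorted(persons_per_dyad.items()):
        missing = {1, 2} - persons
        for p in sorted(missing):
            warnings.append(f"dyad {dyad}: person {p} missing")

    return StudyTable(records=records, provenance=str(data_path), warnings=warnings)
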