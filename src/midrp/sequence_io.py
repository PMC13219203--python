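"""Reading, validation and normalization of timestamped diagnosis-code streams.

Raw diagnosis tables (one row per admission) are turned into per-patient
:class:`EventSequence` objects: codes truncated to their 3-character ICD-10
category, times expressed in configurable units since each patient's first
recorded event, and records sorted stably by admission time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MedicalEvent",
    "EventSequence",
    "EventVocabulary",
    "AssemblyResult",
    "ValidationError",
    "FormatError",
    "truncate_code",
    "read_events",
    "write_events",
    "assemble_sequences",
    "clip_pad",
]

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}$")

PAD_ID = 0
UNK_ID = 1


class ValidationError(ValueError):
    """A record violates a domain invariant (bad code, bad time)."""


class FormatError(ValueError):
    """An input file does not match the expected table layout."""


@dataclass(frozen=True)
class MedicalEvent:
    """One diagnosis: 3-character ICD-10 category at a non-negative time."""

    sample_id: str
    code: str
    time: float

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise ValidationError(
                f"code {self.code!r} is not a letter + two digits ICD-10 category"
            )
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(
                f"event time must be finite and >= 0, got {self.time!r}"
            )


@dataclass
class EventSequence:
    """Time-sorted diagnosis events for one patient."""

    sample_id: str
    events: list[MedicalEvent]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"events of sample {self.sample_id!r} are not time-sorted"
            )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.events]

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)


@dataclass
class AssemblyResult:
    """Sequences surviving the minimum-record filter plus a drop report."""

    sequences: list[EventSequence]
    dropped_ids: list[str]

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_ids)

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


class EventVocabulary:
    """Bijective code <-> integer-id map with reserved pad and unknown ids.

    Ids 0 and 1 are reserved for padding and for codes unseen at build time;
    real codes occupy ids ``2 .. K+1`` where ``K`` is the number of distinct
    codes in the training corpus.
    """

    PAD_TOKEN = "<PAD>"
    UNK_TOKEN = "<UNK>"

    def __init__(self, codes: Iterable[str]):
        uniq = sorted(set(codes))
        self._code_to_id = {c: i + 2 for i, c in enumerate(uniq)}
        self._id_to_code = {i: c for c, i in self._code_to_id.items()}
        self.pad_id = PAD_ID
        self.unk_id = UNK_ID

    @property
    def K(self) -> int:
        """Number of distinct (non-reserved) codes."""
        return len(self._code_to_id)

    @property
    def n_ids(self) -> int:
        """Total id range including pad and unknown (model vocabulary size)."""
        return self.K + 2

    def encode(self, code: str) -> int:
        return self._code_to_id.get(code, self.unk_id)

    def decode(self, idx: int) -> str:
        if idx == self.pad_id:
            return self.PAD_TOKEN
        if idx == self.unk_id:
            return self.UNK_TOKEN
        try:
            return self._id_to_code[idx]
        except KeyError:
            raise ValidationError(f"id {idx} is not in the vocabulary") from None

    def encode_sequence(self, seq: EventSequence) -> np.ndarray:
        return np.array([self.encode(c) for c in seq.codes], dtype=np.int64)

    def to_json(self) -> str:
        return json.dumps(self._code_to_id, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "EventVocabulary":
        mapping = json.loads(payload)
        vocab = cls([])
        vocab._code_to_id = {str(c): int(i) for c, i in mapping.items()}
        vocab._id_to_code = {i: c for c, i in vocab._code_to_id.items()}
        return vocab

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EventVocabulary)
            and self._code_to_id == other._code_to_id
        )


def truncate_code(raw_icd10: str) -> str:
    """Return the 3-character ICD-10 category of ``raw_icd10``, uppercased.

    ``"I25.1" -> "I25"``. Raises :class:`ValidationError` when the value has
    no leading letter or fewer than three characters.
    """
    raw = str(raw_icd10).strip()
    if len(raw) < 3 or not raw[0].isalpha():
        raise ValidationError(f"malformed ICD-10 code: {raw_icd10!r}")
    code = raw[:3].upper()
    if not _CODE_RE.match(code):
        raise ValidationError(f"malformed ICD-10 code: {raw_icd10!r}")
    return code


REQUIRED_COLUMNS = ("sample_id", "icd10", "admission_time")


def _parse_times(raw: pd.Series) -> np.ndarray:
    """Admission times in days: numeric day offsets or ISO dates."""
    numeric = pd.to_numeric(raw, errors="coerce")
    days = numeric.to_numpy(dtype=float)
    bad = np.isnan(days)
    if bad.any():
        dates = pd.to_datetime(raw[bad], errors="coerce", format="ISO8601")
        still_bad = dates.isna()
        if still_bad.any():
            line = int(still_bad[still_bad].index[0]) + 2  # header is line 1
            raise FormatError(
                f"unparsable admission_time {raw[still_bad.index[still_bad][0]]!r} "
                f"at line {line}"
            )
        origin = pd.Timestamp("1970-01-01")
        days[bad] = (dates - origin).dt.total_seconds().to_numpy() / 86400.0
    return days


def read_events(path, time_unit: float = 30.0) -> list[MedicalEvent]:
    """Read an events TSV into :class:`MedicalEvent` records.

    Expects header columns ``sample_id, icd10, admission_time``; times are
    converted to ``time_unit``-day units relative to each sample's earliest
    event.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"events table {path} is missing columns: {missing}")
    if df.empty:
        return []
    days = _parse_times(df["admission_time"])
    df = df.assign(days_rel=days)
    df["days_rel"] -= df.groupby("sample_id")["days_rel"].transform("min")
    return [
        MedicalEvent(
            sample_id=str(row.sample_id),
            code=truncate_code(row.icd10),
            time=float(row.days_rel) / float(time_unit),
        )
        for row in df.itertuples()
    ]


def write_events(sequences: Iterable[EventSequence], path, time_unit: float = 30.0) -> None:
    """Write sequences back to the events-TSV dialect read by :func:`read_events`."""
    rows = [
        {
            "sample_id": seq.sample_id,
            "icd10": ev.code,
            "admission_time": repr(ev.time * float(time_unit)),
        }
        for seq in sequences
        for ev in seq.events
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep="\t", index=False)


def assemble_sequences(
    events: Iterable[MedicalEvent], min_records: int = 2
) -> AssemblyResult:
    """Group events by sample, sort stably by time, drop short histories.

    Samples contributing fewer than ``min_records`` events are excluded and
    reported in :attr:`AssemblyResult.dropped_ids`.
    """
    by_sample: dict[str, list[MedicalEvent]] = {}
    for ev in events:
        by_sample.setdefault(ev.sample_id, []).append(ev)
    sequences, dropped = [], []
    for sid, evs in by_sample.items():
        if len(evs) < min_records:
            dropped.append(sid)
            continue
        evs = sorted(evs, key=lambda e: e.time)  # stable: ties keep input order
        sequences.append(EventSequence(sample_id=sid, events=evs))
    return AssemblyResult(sequences=sequences, dropped_ids=dropped)


def clip_pad(
    seq: EventSequence,
    vocab: EventVocabulary,
    max_len: int,
    pad_id: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode one sequence to fixed length ``max_len``.

    Sequences longer than ``max_len`` keep the ``max_len`` most recent events;
    shorter ones are right-padded with ``pad_id``. Returns
    ``(token_ids, times, valid_mask)``, each of length ``max_len``; padded
    positions carry time 0 and ``valid_mask`` False.
    """
    if max_len < 2:
        raise ValueError(f"max_len must be >= 2, got {max_len}")
    pad = vocab.pad_id if pad_id is None else pad_id
    ids = vocab.encode_sequence(seq)[-max_len:]
    times = seq.times[-max_len:]
    n = len(ids)
    out_ids = np.full(max_len, pad, dtype=np.int64)
    out_times = np.zeros(max_len, dtype=float)
    mask = np.zeros(max_len, dtype=bool)
    out_ids[:n] = ids
    out_times[:n] = times
    mask[:n] = True
    return out_ids, out_times, mask
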