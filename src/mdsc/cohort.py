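"""Patient-level cohort data model, CSV I/O, device filtering, feature
encoding, and the train/holdout split protocol.

A cohort is an ordered list of :class:`PatientRecord` plus a
:class:`DeviceCatalog` mapping every device code appearing in the records to
a label and its cohort-wide usage count.  The feature encoding deliberately
excludes the GMFCS level: the Medical Device Score must be computable from
data that routine administrative databases hold (device codes, age, CP
subtype), where a clinical GMFCS assessment is generally absent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mdsc.errors import CohortValidationError, ConfigurationError

#: Canonical clinical CP subtype labels, in fixed encoding order.
SUBTYPES = ("bilateral_spastic", "unilateral_spastic", "dyskinetic", "ataxic", "mixed")

SEXES = ("female", "male")

GMFCS_LEVELS = (1, 2, 3, 4, 5)

ROMAN_OF_LEVEL = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}
LEVEL_OF_ROMAN = {v: k for k, v in ROMAN_OF_LEVEL.items()}

#: Admissible age window (years); the study population spans 2.2-25.5 years.
AGE_MIN, AGE_MAX = 2.0, 26.0

CSV_COLUMNS = ("patient_id", "age", "sex", "cp_subtype", "gmfcs", "gmfm66", "devices")

_DEVICE_SEP = "|"


@dataclass(frozen=True)
class PatientRecord:
    """One patient: demographics, CP subtype, GMFCS, GMFM-66, device set."""

    patient_id: str
    age: float
    sex: str
    cp_subtype: str
    gmfcs: int
    gmfm66: float
    devices: frozenset[str]

    def problems(self) -> list[str]:
        """Invariant violations for this record (empty list when valid)."""
        out = []
        if not (0.0 <= self.gmfm66 <= 100.0):
            out.append(f"gmfm66={self.gmfm66!r} outside [0, 100]")
        if not (AGE_MIN <= self.age < AGE_MAX):
            out.append(f"age={self.age!r} outside [{AGE_MIN}, {AGE_MAX})")
        if self.gmfcs not in GMFCS_LEVELS:
            out.append(f"gmfcs={self.gmfcs!r} not in I-V")
        if self.cp_subtype not in SUBTYPES:
            out.append(f"unknown cp_subtype={self.cp_subtype!r}")
        if self.sex not in SEXES:
            out.append(f"unknown sex={self.sex!r}")
        return out


@dataclass(frozen=True)
class DeviceCatalog:
    """Mapping device code -> (label, cohort-wide usage count)."""

    entries: Mapping[str, tuple[str, int]]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    def count(self, code: str) -> int:
        return self.entries[code][1]

    def label(self, code: str) -> str:
        return self.entries[code][0]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.entries


@dataclass
class Cohort:
    """Ordered patient records plus the device catalog they reference."""

    records: list[PatientRecord]
    catalog: DeviceCatalog

    @classmethod
    def from_records(
        cls,
        records: Sequence[PatientRecord],
        labels: Mapping[str, str] | None = None,
    ) -> "Cohort":
        """Build a cohort, recomputing catalog counts from the records."""
        labels = dict(labels or {})
        counts: Counter[str] = Counter()
        for rec in records:
            counts.update(rec.devices)
        entries = {code: (labels.get(code, code), cnt) for code, cnt in counts.items()}
        cohort = cls(records=list(records), catalog=DeviceCatalog(entries))
        cohort.validate()
        return cohort

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.patient_id for r in self.records)

    @property
    def gmfm66(self) -> np.ndarray:
        return np.array([r.gmfm66 for r in self.records], dtype=float)

    @property
    def gmfcs(self) -> np.ndarray:
        return np.array([r.gmfcs for r in self.records], dtype=int)

    def validate(self) -> None:
        problems = []
        seen: set[str] = set()
        for i, rec in enumerate(self.records):
            if rec.patient_id in seen:
                problems.append(f"record {i}: duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            for msg in rec.problems():
                problems.append(f"record {i} ({rec.patient_id}): {msg}")
            for code in rec.devices:
                if code not in self.catalog:
                    problems.append(
                        f"record {i} ({rec.patient_id}): device {code!r} not in catalog"
                    )
        if problems:
            raise CohortValidationError(problems)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per patient (devices pipe-delimited)."""
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "cp_subtype": [r.cp_subtype for r in self.records],
                "gmfcs": [ROMAN_OF_LEVEL[r.gmfcs] for r in self.records],
                "gmfm66": [r.gmfm66 for r in self.records],
                "devices": [_DEVICE_SEP.join(sorted(r.devices)) for r in self.records],
            }
        )

    def equals(self, other: "Cohort") -> bool:
        """Data equality: identical records and identical catalog counts.

        Catalog labels are presentation metadata and are ignored (they are
        not serialized in the cohort CSV).
        """
        if self.records != other.records:
            return False
        mine = {c: self.catalog.count(c) for c in self.catalog.codes}
        theirs = {c: other.catalog.count(c) for c in other.catalog.codes}
        return mine == theirs


def write_cohort(cohort: Cohort, path) -> None:
    """Serialize a cohort as a UTF-8, comma-separated CSV.

    Device sets are written pipe-delimited inside one field; GMFCS levels
    as Roman numerals.  Float columns use Python's shortest round-tripping
    representation, so write/read is an identity.
    """
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Parse and validate a cohort CSV written by :func:`write_cohort`.

    Raises
    ------
    CohortValidationError
        Listing every malformed row by its CSV line number (header = line 1).
    """
    df = pd.read_csv(path, dtype=str, na_filter=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing required column(s): {', '.join(missing)}"])

    problems: list[str] = []
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        row_problems: list[str] = []

        def _float(name, raw, lo=None, hi=None):
            try:
                val = float(raw)
            except ValueError:
                row_problems.append(f"line {line}: {name}={raw!r} is not a number")
                return math.nan
            return val

        age = _float("age", row.age)
        gmfm = _float("gmfm66", row.gmfm66)
        raw_level = row.gmfcs.strip()
        if raw_level in LEVEL_OF_ROMAN:
            level = LEVEL_OF_ROMAN[raw_level]
        elif raw_level in {"1", "2", "3", "4", "5"}:
            level = int(raw_level)
        else:
            row_problems.append(f"line {line}: gmfcs={raw_level!r} is not a level I-V")
            level = 0
        devices = frozenset(
            tok for tok in row.devices.split(_DEVICE_SEP) if tok.strip()
        )
        rec = PatientRecord(
            patient_id=row.patient_id,
            age=age,
            sex=row.sex,
            cp_subtype=row.cp_subtype,
            gmfcs=level,
            gmfm66=gmfm,
            devices=devices,
        )
        if not row_problems:
            row_problems = [f"line {line}: {msg}" for msg in rec.problems()]
        problems.extend(row_problems)
        records.append(rec)

    ids = [r.patient_id for r in records]
    for pid, cnt in Counter(ids).items():
        if cnt > 1:
            problems.append(f"duplicate patient_id {pid!r} ({cnt} rows)")
    if problems:
        raise CohortValidationError(problems)
    return Cohort.from_records(records)


def apply_grouping(cohort: Cohort, mapping: Mapping[str, str]) -> Cohort:
    """Collapse device codes into groups via ``device code -> group code``.

    Codes absent from the mapping pass through unchanged (identity default),
    so an empty mapping is a no-op.  Grouping is applied before the
    minimum-count filter.
    """
    records = [
        replace(rec, devices=frozenset(mapping.get(c, c) for c in rec.devices))
        for rec in cohort.records
    ]
    labels = {
        mapping.get(code, code): cohort.catalog.label(code)
        for code in cohort.catalog.codes
    }
    return Cohort.from_records(records, labels=labels)


def read_grouping(path) -> dict[str, str]:
    """Read a grouping-map CSV with columns (device_code, group_code)."""
    df = pd.read_csv(path, dtype=str, na_filter=False)
    for col in ("device_code", "group_code"):
        if col not in df.columns:
            raise CohortValidationError([f"grouping map missing column {col!r}"])
    return dict(zip(df["device_code"], df["group_code"]))


def min_count_filter(cohort: Cohort, min_n: int = 5) -> Cohort:
    """Drop devices used by fewer than ``min_n`` patients (inclusive at
    the threshold: a device with exactly ``min_n`` users is kept).

    Patients are never removed; a patient whose every device is dropped
    simply ends up with an empty device set.  Idempotent.
    """
    if min_n < 1:
        raise ConfigurationError(f"min_n must be >= 1, got {min_n}")
    keep = {c for c in cohort.catalog.codes if cohort.catalog.count(c) >= min_n}
    records = [
        replace(rec, devices=frozenset(rec.devices & keep)) for rec in cohort.records
    ]
    labels = {c: cohort.catalog.label(c) for c in keep}
    return Cohort.from_records(records, labels=labels)


@dataclass
class FeatureMatrix:
    """GMFCS-free predictors aligned to the GMFM-66 outcome vector.

    ``X`` rows are indexed by patient id; columns are the retained device
    indicators (lexicographic), then ``age``, then five subtype one-hot
    columns (plus optional debug columns).
    """

    X: pd.DataFrame
    y: pd.Series

    @property
    def row_ids(self) -> tuple[str, ...]:
        return tuple(self.X.index)

    def subset(self, ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(ids)
        return FeatureMatrix(X=self.X.loc[ids], y=self.y.loc[ids])

    def __len__(self) -> int:
        return len(self.X)


def encode_features(
    cohort: Cohort,
    *,
    include_sex: bool = False,
    include_gmfcs: bool = False,
) -> FeatureMatrix:
    """Encode a (already min-count-filtered) cohort as a feature matrix.

    Column layout: one binary indicator per catalog device (lexicographic
    code order), then continuous ``age``, then one-hot ``subtype_*`` columns
    in canonical order.  ``include_gmfcs`` exists solely for leakage audits:
    the production Medical Device Score never sees the GMFCS level.
    """
    codes = list(cohort.catalog.codes)
    if not codes:
        raise ConfigurationError("empty device catalog: nothing to predict from")
    ids = list(cohort.ids)
    data: dict[str, np.ndarray] = {}
    for code in codes:
        data[code] = np.array(
            [1 if code in r.devices else 0 for r in cohort.records], dtype=np.int8
        )
    data["age"] = np.array([r.age for r in cohort.records], dtype=float)
    for sub in SUBTYPES:
        data[f"subtype_{sub}"] = np.array(
            [1 if r.cp_subtype == sub else 0 for r in cohort.records], dtype=np.int8
        )
    if include_sex:
        data["sex_female"] = np.array(
            [1 if r.sex == "female" else 0 for r in cohort.records], dtype=np.int8
        )
    if include_gmfcs:
        data["gmfcs_level"] = np.array([r.gmfcs for r in cohort.records], dtype=float)
    X = pd.DataFrame(data, index=pd.Index(ids, name="patient_id"))
    y = pd.Series(cohort.gmfm66, index=X.index, name="gmfm66")
    return FeatureMatrix(X=X, y=y)


@dataclass(frozen=True)
class HoldoutSplit:
    """A single random train/holdout partition of patient ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int


def holdout_split(cohort: Cohort, fraction: float = 0.7, seed: int = 0) -> HoldoutSplit:
    """Uniformly random partition with ``round(fraction * N)`` training
    patients (round half up; 70% of 1581 gives 1107 train / 474 test).
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError(f"fraction must be in (0, 1), got {fraction}")
    n = len(cohort)
    if n < 2:
        raise ConfigurationError("need at least 2 patients to split")
    n_train = int(math.floor(fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ConfigurationError(
            f"fraction {fraction} yields an empty train or test set for N={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = np.array(cohort.ids, dtype=object)
    return HoldoutSplit(
        train_ids=tuple(ids[perm[:n_train]]),
        test_ids=tuple(ids[perm[n_train:]]),
        fraction=fraction,
        seed=seed,
    )
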