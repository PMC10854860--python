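"""Encounter-history data model, validation and file I/O.

A capture–mark–recapture dataset is a set of binary detection histories,
one per individually marked animal, over a calendar of annual occasions.
Every bird here is of known age (ringed in the nest), so its age class at
any occasion — juvenile, subadult or adult — is a deterministic function
of its birth year and the occasion year.

Two interchange formats are supported: the MARK-style ``.inp`` dialect
(one record per line: an optional ``/* id birth=YYYY */`` comment, a
binary history string, a frequency and a terminating ``;``) and a
long-format CSV with columns ``individual_id, birth_year, year,
detected``. Both round-trip losslessly.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgeClass",
    "StudyDesign",
    "EncounterHistory",
    "EncounterDataset",
    "MArray",
    "age_class",
    "first_capture",
    "read_inp",
    "write_inp",
    "read_long_csv",
    "write_long_csv",
    "build_m_array",
]


class AgeClass(enum.IntEnum):
    """Plumage-based age classes; values double as array indices."""

    JUVENILE = 0
    SUBADULT = 1
    ADULT = 2


class DataError(ValueError):
    """Raised for invalid encounter data or unparseable files."""


@dataclass(frozen=True)
class StudyDesign:
    """Occasion calendar and age-class boundaries.

    Parameters
    ----------
    occasion_years
        Strictly increasing consecutive calendar years, one per annual
        sighting occasion.
    age_class_bounds
        ``(a, b)``: age < a years is juvenile, a <= age <= b subadult,
        age > b adult. Default ``(2, 6)``.
    """

    occasion_years: tuple[int, ...]
    age_class_bounds: tuple[int, int] = (2, 6)

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.occasion_years)
        object.__setattr__(self, "occasion_years", years)
        if len(years) < 2:
            raise DataError("need at least two occasions")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise DataError(
                "occasion_years must be consecutive calendar years, got "
                f"{years}"
            )
        lo, hi = self.age_class_bounds
        if not (0 < lo < hi):
            raise DataError(f"age_class_bounds must satisfy 0 < a < b, got {lo, hi}")

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_years)

    @property
    def n_intervals(self) -> int:
        return len(self.occasion_years) - 1

    @property
    def first_year(self) -> int:
        return self.occasion_years[0]

    def occasion_index(self, year: int) -> int:
        if year not in self.occasion_years:
            raise DataError(f"year {year} is not a study occasion")
        return year - self.occasion_years[0]

    def age_classes_for(self, birth_year: int) -> np.ndarray:
        """Age class at every occasion, as an int8 vector.

        Occasions before birth are clamped to JUVENILE; they are never
        consulted because a history cannot start before birth.
        """
        ages = np.asarray(self.occasion_years) - birth_year
        lo, hi = self.age_class_bounds
        out = np.where(ages < lo, 0, np.where(ages <= hi, 1, 2))
        return out.astype(np.int8)


def age_class(birth_year: int, occasion_year: int, design: StudyDesign) -> AgeClass:
    """Age class of a bird born in ``birth_year`` at ``occasion_year``.

    Age in whole years is ``occasion_year - birth_year``; the default
    boundaries make age 0–1 juvenile, 2–6 subadult, 7+ adult.
    """
    if occasion_year < birth_year:
        raise DataError(
            f"occasion {occasion_year} precedes birth year {birth_year}"
        )
    age = occasion_year - birth_year
    lo, hi = design.age_class_bounds
    if age < lo:
        return AgeClass.JUVENILE
    if age <= hi:
        return AgeClass.SUBADULT
    return AgeClass.ADULT


@dataclass(frozen=True)
class EncounterHistory:
    """One individual's detection record.

    ``detections`` has one 0/1 entry per occasion; at least one entry is
    1 (a never-seen animal cannot be in a CJS dataset).
    """

    individual_id: str
    birth_year: int
    detections: tuple[int, ...]
    excluded: bool = False  # carried but unused: no exclusion rule is encoded

    def __post_init__(self) -> None:
        det = tuple(int(d) for d in self.detections)
        if any(d not in (0, 1) for d in det):
            raise DataError(f"{self.individual_id}: detections must be 0/1")
        if not any(det):
            raise DataError(f"{self.individual_id}: history has no detections")
        object.__setattr__(self, "detections", det)

    @property
    def first_capture(self) -> int:
        return self.detections.index(1)


def first_capture(history: EncounterHistory) -> int:
    """0-based occasion index of the first detection."""
    return history.first_capture


@dataclass(frozen=True)
class EncounterDataset:
    """A study design plus the histories observed under it."""

    design: StudyDesign
    histories: tuple[EncounterHistory, ...]

    def __post_init__(self) -> None:
        hists = tuple(self.histories)
        object.__setattr__(self, "histories", hists)
        T = self.design.n_occasions
        seen: set[str] = set()
        for h in hists:
            if len(h.detections) != T:
                raise DataError(
                    f"{h.individual_id}: history length {len(h.detections)} "
                    f"!= {T} occasions"
                )
            if h.individual_id in seen:
                raise DataError(f"duplicate individual_id {h.individual_id!r}")
            seen.add(h.individual_id)
            fy = self.design.occasion_years[h.first_capture]
            if fy < h.birth_year:
                raise DataError(
                    f"{h.individual_id}: first detection in {fy} precedes "
                    f"birth year {h.birth_year}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.histories)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pack histories into (detections, first_capture, age_class) arrays.

        Returns ``det`` (n, T) int8, ``first`` (n,) int64 and ``ac``
        (n, T) int8 with the age class of each individual at each
        occasion — the flat representation every likelihood kernel
        consumes.
        """
        det = np.array([h.detections for h in self.histories], dtype=np.int8)
        det = det.reshape(len(self.histories), self.design.n_occasions)
        frst = np.array([h.first_capture for h in self.histories], dtype=np.int64)
        ac = np.array(
            [self.design.age_classes_for(h.birth_year) for h in self.histories],
            dtype=np.int8,
        ).reshape(det.shape)
        return det, frst, ac


# ---------------------------------------------------------------------------
# MARK .inp dialect

_INP_RECORD = re.compile(
    r"^\s*(?:/\*\s*(?P<id>\S+)\s+birth=(?P<birth>-?\d+)\s*\*/)?"
    r"\s*(?P<hist>[01]+)\s+(?P<freq>\d+)\s*;\s*$"
)
_INP_HEADER = re.compile(r"^\s*/\*\s*first_year=(?P<year>-?\d+)\s*\*/\s*$")


def read_inp(path, first_year: int | None = None) -> EncounterDataset:
    """Read a MARK-style ``.inp`` file.

    The calendar start is taken from ``first_year`` or, failing that,
    from a ``/* first_year=YYYY */`` header line (as emitted by
    :func:`write_inp`); ``.inp`` itself carries no calendar. Frequencies
    expand to that many independent individuals (suffix ``_2``, ``_3``…).
    """
    histories: list[EncounterHistory] = []
    hist_len: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _INP_HEADER.match(line)
            if m:
                if first_year is None:
                    first_year = int(m.group("year"))
                continue
            m = _INP_RECORD.match(line)
            if m is None:
                raise DataError(f"{path}:{lineno}: unparseable .inp record")
            if m.group("id") is None:
                raise DataError(
                    f"{path}:{lineno}: record lacks the '/* id birth=YYYY */' "
                    "annotation carrying individual id and birth year"
                )
            hist = m.group("hist")
            if hist_len is None:
                hist_len = len(hist)
            elif len(hist) != hist_len:
                raise DataError(
                    f"{path}:{lineno}: history length {len(hist)} differs "
                    f"from {hist_len}"
                )
            det = tuple(int(c) for c in hist)
            base_id = m.group("id")
            birth = int(m.group("birth"))
            freq = int(m.group("freq"))
            if freq < 1:
                raise DataError(f"{path}:{lineno}: frequency must be >= 1")
            for k in range(freq):
                iid = base_id if k == 0 else f"{base_id}_{k + 1}"
                histories.append(EncounterHistory(iid, birth, det))
    if not histories:
        raise DataError(f"{path}: no records found")
    if first_year is None:
        raise DataError(
            f"{path}: no first_year header and none supplied; the .inp "
            "format carries no calendar"
        )
    assert hist_len is not None
    years = tuple(range(first_year, first_year + hist_len))
    return EncounterDataset(StudyDesign(years), tuple(histories))


def write_inp(dataset: EncounterDataset, path) -> None:
    """Write a dataset in the ``.inp`` dialect read by :func:`read_inp`."""
    if not dataset.histories:
        raise DataError("refusing to write an empty dataset")
    with open(path, "w") as fh:
        fh.write(f"/* first_year={dataset.design.first_year} */\n")
        for h in dataset.histories:
            hist = "".join(str(d) for d in h.detections)
            fh.write(f"/* {h.individual_id} birth={h.birth_year} */ {hist} 1;\n")


# ---------------------------------------------------------------------------
# Long-format CSV

_LONG_COLUMNS = ["individual_id", "birth_year", "year", "detected"]


def write_long_csv(dataset: EncounterDataset, path) -> None:
    """Write the long-format table: one row per individual x occasion."""
    if not dataset.histories:
        raise DataError("refusing to write an empty dataset")
    rows = [
        (h.individual_id, h.birth_year, y, d)
        for h in dataset.histories
        for y, d in zip(dataset.design.occasion_years, h.detections)
    ]
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)


def read_long_csv(path) -> EncounterDataset:
    df = pd.read_csv(path)
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    years = np.sort(df["year"].unique())
    design = StudyDesign(tuple(int(y) for y in years))
    histories = []
    for iid, grp in df.groupby("individual_id", sort=False):
        grp = grp.sort_values("year")
        if len(grp) != design.n_occasions:
            raise DataError(
                f"{path}: individual {iid!r} has {len(grp)} rows, expected "
                f"{design.n_occasions}"
            )
        births = grp["birth_year"].unique()
        if len(births) != 1:
            raise DataError(f"{path}: individual {iid!r} has conflicting birth years")
        histories.append(
            EncounterHistory(str(iid), int(births[0]), tuple(int(d) for d in grp["detected"]))
        )
    return EncounterDataset(design, tuple(histories))


# ---------------------------------------------------------------------------
# m-array

@dataclass(frozen=True)
class MArray:
    """Reduced CJS sufficient statistic.

    Row ``i`` counts the animals released (detected) at occasion ``i``;
    ``recaptures[i, j-1]`` of them were next detected at occasion ``j``,
    and ``never_seen_again[i]`` were never detected again. Detections at
    the final occasion release nothing. When stratified, a leading axis
    indexes the age class at release; the per-row multinomial structure
    is unchanged.
    """

    releases: np.ndarray
    recaptures: np.ndarray
    never_seen_again: np.ndarray
    strata: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        rel = np.asarray(self.releases, dtype=np.int64)
        rec = np.asarray(self.recaptures, dtype=np.int64)
        nsa = np.asarray(self.never_seen_again, dtype=np.int64)
        object.__setattr__(self, "releases", rel)
        object.__setattr__(self, "recaptures", rec)
        object.__setattr__(self, "never_seen_again", nsa)
        if np.any(rel < 0) or np.any(rec < 0) or np.any(nsa < 0):
            raise DataError("m-array counts must be non-negative")
        if not np.array_equal(rec.sum(axis=-1) + nsa, rel):
            raise DataError("m-array row sums do not equal releases")

    @property
    def n_release_occasions(self) -> int:
        return self.releases.shape[-1]


def build_m_array(dataset: EncounterDataset, stratify_by_age: bool = False) -> MArray:
    """Reduce a dataset to its m-array.

    Every detection of an individual before the final occasion is a
    release; the column is its next detection occasion (if any). With
    ``stratify_by_age`` rows are additionally split by the age class of
    the individual at the release occasion.
    """
    T = dataset.design.n_occasions
    n_strata = 3 if stratify_by_age else 1
    rel = np.zeros((n_strata, T - 1), dtype=np.int64)
    rec = np.zeros((n_strata, T - 1, T - 1), dtype=np.int64)
    nsa = np.zeros((n_strata, T - 1), dtype=np.int64)
    years = dataset.design.occasion_years
    for h in dataset.histories:
        occs = [t for t, d in enumerate(h.detections) if d]
        for t, nxt in zip(occs, occs[1:] + [None]):
            if t == T - 1:
                continue
            s = age_class(h.birth_year, years[t], dataset.design) if stratify_by_age else 0
            rel[s, t] += 1
            if nxt is None:
                nsa[s, t] += 1
            else:
                rec[s, t, nxt - 1] += 1
    if not stratify_by_age:
        return MArray(rel[0], rec[0], nsa[0])
    return MArray(rel, rec, nsa, strata=tuple(c.name.lower() for c in AgeClass))
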