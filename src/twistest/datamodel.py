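"""Subject records, genotype coding and dataset validation.

One record per subject: follow-up time ``X``, event indicator ``delta``,
pre-immune indicator ``Z`` and the genotype dummies ``(G1, G2)`` of a
bi-allelic marker.  A pre-immune subject (ADA present before the first
drug dose) is stored as ``X = 0, delta = 1, Z = 1`` so that one record
type covers both parts of the two-part model; all survival-part
computations filter on ``Z = 0``.

Genotype coding: with 'A' the reference (most frequent) allele,
``G = [AA], [Aa], [aa]`` maps to ``G1 = 0, 1, 2`` and ``G2 = 1`` for the
heterozygote only.  The pair spans dominant, additive, recessive and
overdominant effects in one parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "Dataset",
    "GenotypeCodingError",
    "DatasetError",
    "encode_genotype",
    "orient_alleles",
    "validate_dataset",
    "dataset_from_arrays",
    "read_table",
    "write_table",
]


class GenotypeCodingError(ValueError):
    """Raised for allele counts outside {0, 1, 2} or inconsistent dummies."""


class DatasetError(ValueError):
    """Raised when subject records violate the two-part data contract."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's observed data ``(X, delta, Z, G1, G2)``."""

    time: float
    event: int
    pre_immune: int
    g1: int
    g2: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetError(f"negative follow-up time {self.time}")
        if self.event not in (0, 1):
            raise DatasetError(f"event indicator must be 0/1, got {self.event}")
        if self.pre_immune not in (0, 1):
            raise DatasetError(
                f"pre-immune indicator must be 0/1, got {self.pre_immune}"
            )
        if (self.g1, self.g2) not in ((0, 0), (1, 1), (2, 0)):
            raise GenotypeCodingError(
                f"(G1, G2) = ({self.g1}, {self.g2}) is not a valid coding"
            )
        if self.pre_immune == 1 and not (self.time == 0.0 and self.event == 1):
            raise DatasetError(
                "pre-immune subject must have X = 0 and delta = 1, got "
                f"(X={self.time}, delta={self.event})"
            )
        if self.pre_immune == 0 and self.time <= 0.0:
            raise DatasetError(
                f"non-pre-immune subject must have X > 0, got X={self.time}"
            )


@dataclass(frozen=True)
class Dataset:
    """Column-oriented collection of subject records.

    Attributes
    ----------
    time, event, pre_immune, g1, g2
        Aligned arrays; see :class:`SubjectRecord` for the invariants.
    time_unit
        Free-text label of the time unit (e.g. ``"months"``).
    """

    time: np.ndarray
    event: np.ndarray
    pre_immune: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    time_unit: str = "months"

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_preimmune(self) -> int:
        return int(self.pre_immune.sum())

    @property
    def n_events(self) -> int:
        """Events among non-pre-immune subjects."""
        return int(((self.pre_immune == 0) & (self.event == 1)).sum())

    @property
    def n_censored(self) -> int:
        return int(((self.pre_immune == 0) & (self.event == 0)).sum())

    @property
    def allele_count(self) -> np.ndarray:
        """Raw minor-allele count per subject (0, 1 or 2)."""
        return np.where(self.g2 == 1, 1, self.g1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": np.arange(self.n),
                "time": self.time,
                "event": self.event,
                "pre_immune": self.pre_immune,
                "genotype": self.allele_count,
            }
        )


def encode_genotype(allele_count: int) -> tuple[int, int]:
    """Map an allele count to the genotype dummies ``(G1, G2)``.

    ``0 -> (0, 0)``, ``1 -> (1, 1)``, ``2 -> (2, 0)``.
    """
    mapping = {0: (0, 0), 1: (1, 1), 2: (2, 0)}
    try:
        return mapping[int(allele_count)]
    except (KeyError, ValueError, TypeError):
        raise GenotypeCodingError(
            f"allele count must be 0, 1 or 2, got {allele_count!r}"
        ) from None


def _encode_many(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts)
    bad = ~np.isin(counts, (0, 1, 2))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise GenotypeCodingError(
            f"allele count must be 0, 1 or 2, got {counts[idx]!r} "
            f"at subject index {idx}"
        )
    counts = counts.astype(np.int64)
    g2 = (counts == 1).astype(np.int64)
    return counts, g2


def orient_alleles(raw_counts: Sequence[int]) -> tuple[np.ndarray, float]:
    """Orient allele counts so 0 counts the most frequent allele.

    If the counted allele is the sample-major one (mean count above 1),
    counts are flipped ``c -> 2 - c``; an exact tie keeps the input
    orientation.  Returns the oriented counts and the resulting minor
    allele frequency.
    """
    counts = np.asarray(raw_counts)
    if counts.size == 0:
        raise GenotypeCodingError("cannot orient an empty genotype vector")
    counts, _ = _encode_many(counts)
    freq = counts.mean() / 2.0
    if freq > 0.5:
        counts = 2 - counts
        freq = counts.mean() / 2.0
    return counts, float(freq)


def dataset_from_arrays(
    time,
    event,
    pre_immune,
    allele_count,
    *,
    time_unit: str = "months",
) -> Dataset:
    """Assemble and validate a :class:`Dataset` from aligned columns."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    pre_immune = np.asarray(pre_immune)
    n = time.shape[0]
    if n < 1:
        raise DatasetError("dataset must contain at least one subject")
    for name, col in (("event", event), ("pre_immune", pre_immune)):
        if not np.isin(col, (0, 1)).all():
            idx = int(np.flatnonzero(~np.isin(col, (0, 1)))[0])
            raise DatasetError(
                f"{name} must be 0/1, got {col[idx]!r} at subject index {idx}"
            )
    event = event.astype(np.int64)
    pre_immune = pre_immune.astype(np.int64)
    if np.any(time < 0):
        idx = int(np.flatnonzero(time < 0)[0])
        raise DatasetError(f"negative time {time[idx]} at subject index {idx}")
    bad = (pre_immune == 1) & ((time != 0.0) | (event != 1))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise DatasetError(
            f"pre-immune subject at index {idx} must have X = 0 and "
            f"delta = 1, got (X={time[idx]}, delta={event[idx]})"
        )
    bad = (pre_immune == 0) & (time <= 0.0)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise DatasetError(
            f"non-pre-immune subject at index {idx} must have X > 0, "
            f"got X={time[idx]}"
        )
    g1, g2 = _encode_many(allele_count)
    return Dataset(
        time=time,
        event=event,
        pre_immune=pre_immune,
        g1=g1,
        g2=g2,
        time_unit=time_unit,
    )


def validate_dataset(records: Iterable[SubjectRecord], time_unit: str = "months") -> Dataset:
    """Validate an iterable of :class:`SubjectRecord` into a :class:`Dataset`."""
    records = list(records)
    if not records:
        raise DatasetError("dataset must contain at least one subject")
    return Dataset(
        time=np.array([r.time for r in records], dtype=float),
        event=np.array([r.event for r in records], dtype=np.int64),
        pre_immune=np.array([r.pre_immune for r in records], dtype=np.int64),
        g1=np.array([r.g1 for r in records], dtype=np.int64),
        g2=np.array([r.g2 for r in records], dtype=np.int64),
        time_unit=time_unit,
    )


REQUIRED_COLUMNS = ("subject_id", "time", "event", "pre_immune", "genotype")


def read_table(path: str | Path, *, orient: bool = True) -> Dataset:
    """Read a subject table (CSV or TSV by extension) into a :class:`Dataset`.

    The file must carry the columns ``subject_id, time, event, pre_immune,
    genotype`` with the genotype as a 0/1/2 allele count.  Rows with a
    missing genotype or pre-immune status are dropped (their count is
    reported via a ``UserWarning``).  With ``orient=True`` (default) the
    allele counts are re-oriented to the sample-major reference allele.
    """
    import warnings

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    n_raw = len(df)
    df = df.dropna(subset=["genotype", "pre_immune", "time", "event"])
    if len(df) < n_raw:
        warnings.warn(
            f"{path.name}: dropped {n_raw - len(df)} subject(s) with missing "
            "genotype/pre-immune/time/event",
            stacklevel=2,
        )
    counts = df["genotype"].to_numpy()
    if orient:
        counts, _ = orient_alleles(counts)
    return dataset_from_arrays(
        df["time"].to_numpy(),
        df["event"].to_numpy(),
        df["pre_immune"].to_numpy(),
        counts,
    )


def write_table(dataset: Dataset, path: str | Path) -> None:
    """Write a :class:`Dataset` in the CSV/TSV subject-table schema."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    dataset.to_frame().to_csv(path, sep=sep, index=False)
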