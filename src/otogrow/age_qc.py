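"""Between-reader ageing precision.

Each otolith is aged independently by two readers.  Precision is quantified
by the coefficient of variation of the two reads (sample standard deviation
over the mean, in percent); otoliths whose CV exceeds a threshold (5% by
convention) are flagged for a common re-read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class ReadPair:
    individual_id: str
    age_reader1: float
    age_reader2: float

    def __post_init__(self):
        if self.age_reader1 < 0 or self.age_reader2 < 0:
            raise ValueError("ages must be non-negative")


@dataclass(frozen=True)
class CVResult:
    individual_id: str
    cv_percent: float
    defined: bool = True


def reader_cv(pair: ReadPair) -> CVResult:
    """CV (%) of the two reads: 100 * s / m with sample sd s = |a1 - a2| / sqrt(2).

    Undefined (flagged, not raised) when both reads are zero.
    """
    m = (pair.age_reader1 + pair.age_reader2) / 2.0
    if m == 0:
        return CVResult(pair.individual_id, float("nan"), defined=False)
    s = abs(pair.age_reader1 - pair.age_reader2) / math.sqrt(2.0)
    return CVResult(pair.individual_id, 100.0 * s / m)


def flag_rereads(pairs: Iterable[ReadPair], threshold: float = 5.0) -> list[str]:
    """IDs whose reader CV is strictly greater than ``threshold`` percent.

    Undefined CVs (both reads zero) are flagged conservatively.  Output is
    sorted by individual id.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    flagged = []
    for pair in pairs:
        res = reader_cv(pair)
        if not res.defined or res.cv_percent > threshold:
            flagged.append(pair.individual_id)
    return sorted(flagged)


def qc_table(pairs: Iterable[ReadPair], threshold: float = 5.0) -> pd.DataFrame:
    """Per-otolith QC table: both reads, CV and the re-read flag."""
    pairs = list(pairs)
    flagged = set(flag_rereads(pairs, threshold))
    rows = [
        dict(
            individual_id=p.individual_id,
            age_reader1=p.age_reader1,
            age_reader2=p.age_reader2,
            cv_percent=reader_cv(p).cv_percent,
            reread=p.individual_id in flagged,
        )
        for p in sorted(pairs, key=lambda p: p.individual_id)
    ]
    return pd.DataFrame(rows)


def read_pairs_csv(path) -> list[ReadPair]:
    df = pd.read_csv(path)
    required = {"individual_id", "age_reader1", "age_reader2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {', '.join(sorted(missing))}")
    return [
        ReadPair(str(r.individual_id), float(r.age_reader1), float(r.age_reader2))
        for r in df.itertuples()
    ]
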