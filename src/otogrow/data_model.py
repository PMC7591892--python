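"""Long-format otolith growth dataset: schema, I/O, validation and group selection.

The canonical exchange format is an 18-column long-format CSV with one row per
(individual, age) increment read.  Capture-level measurements (length, otolith
radius and age at capture, species length-at-hatching, taxonomy, location) are
repeated on every row of an individual; increment-level measurements (``Age_i``,
``R_i``) vary by row.  ``NA`` is the sole missing-value token.

In memory the long table is normalised into a :class:`GrowthDataset` holding one
``individuals`` frame (one row per fish) and one ``increments`` frame (one row
per read).  The ``Li_*`` columns carry previously back-calculated size-at-age;
they are treated as read-only reference annotations and never as model input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Table-2 column order of the exchange CSV.
SCHEMA_COLUMNS: tuple[str, ...] = (
    "Family", "Genus", "Species", "ID", "Age_i", "R_i", "Age_cpt", "R_cpt",
    "L_cpt", "L_0p", "R_0p", "Li_sp_m", "Li_sp_sd", "Li_sploc_m", "Li_sploc_sd",
    "Weight", "Location", "Observer",
)

#: Columns constant across an individual's rows (capture / taxonomy level).
CAPTURE_COLUMNS: tuple[str, ...] = (
    "Family", "Genus", "Species", "Age_cpt", "R_cpt", "L_cpt", "L_0p", "R_0p",
    "Weight", "Location", "Observer",
)

NUMERIC_COLUMNS: tuple[str, ...] = (
    "Age_i", "R_i", "Age_cpt", "R_cpt", "L_cpt", "L_0p", "R_0p",
    "Li_sp_m", "Li_sp_sd", "Li_sploc_m", "Li_sploc_sd", "Weight",
)

RESULT_COLUMNS: tuple[str, ...] = ("Li_sp_m", "Li_sp_sd", "Li_sploc_m", "Li_sploc_sd")

NA_TOKEN = "NA"


class SchemaError(ValueError):
    """The CSV header does not match the expected 18-column schema."""


class IntegrityError(ValueError):
    """Capture-level values are inconsistent within an individual."""


class ParseError(ValueError):
    """A numeric column contains an unparseable value."""


@dataclass(frozen=True)
class IncrementRecord:
    """One otolith increment read: radius at an integer age for one fish."""

    individual_id: str
    age_i: int
    radius_i: float | None  # mm; None when unreadable


@dataclass(frozen=True)
class IndividualSample:
    """One fish at capture with its species-level hatching constants."""

    individual_id: str
    family: str
    genus: str
    species: str
    location: str
    age_cpt: int
    radius_cpt: float      # mm
    length_cpt: float      # mm, total length
    length_0p: float       # mm, species-level length at hatching
    radius_0p: float | None  # mm, otolith radius at hatching; None when unmeasured
    weight: float | None = None  # g
    observer: str | None = None

    @property
    def species_key(self) -> str:
        return f"{self.genus} {self.species}"


@dataclass
class GrowthDataset:
    """Normalised growth dataset: per-fish table + per-read increment table.

    ``individuals`` is indexed by ``ID`` with the capture-level columns;
    ``increments`` has columns ``ID``, ``Age_i``, ``R_i`` plus any retained
    reference ``Li_*`` columns.
    """

    individuals: pd.DataFrame
    increments: pd.DataFrame
    provenance: str = ""

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_increments(self) -> int:
        return len(self.increments)

    def individual(self, individual_id: str) -> IndividualSample:
        row = self.individuals.loc[individual_id]
        return _row_to_sample(individual_id, row)

    def iter_individuals(self) -> Iterable[IndividualSample]:
        for iid, row in self.individuals.iterrows():
            yield _row_to_sample(str(iid), row)

    def increments_of(self, individual_id: str) -> pd.DataFrame:
        return self.increments[self.increments["ID"] == individual_id]

    def copy(self) -> "GrowthDataset":
        return GrowthDataset(
            self.individuals.copy(), self.increments.copy(), self.provenance
        )


def _row_to_sample(iid: str, row: pd.Series) -> IndividualSample:
    def opt(v):
        return None if pd.isna(v) else float(v)

    def opt_str(v):
        return None if pd.isna(v) else str(v)

    return IndividualSample(
        individual_id=iid,
        family=str(row["Family"]),
        genus=str(row["Genus"]),
        species=str(row["Species"]),
        location=str(row["Location"]),
        age_cpt=int(row["Age_cpt"]),
        radius_cpt=float(row["R_cpt"]),
        length_cpt=float(row["L_cpt"]),
        length_0p=float(row["L_0p"]),
        radius_0p=opt(row["R_0p"]),
        weight=opt(row.get("Weight")),
        observer=opt_str(row.get("Observer")),
    )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_growth_csv(path, *, provenance: str | None = None) -> GrowthDataset:
    """Read a long-format growth CSV into a :class:`GrowthDataset`.

    Parameters
    ----------
    path
        CSV path or file-like object.  Comma-separated, UTF-8, ``NA`` missing
        token, exact case-sensitive Table-2 column names.
    provenance
        Free-text source tag stored on the dataset; defaults to ``str(path)``.

    Raises
    ------
    SchemaError
        A required column is missing from the header.
    ParseError
        A numeric column holds a non-numeric, non-``NA`` value.
    IntegrityError
        Capture-level columns differ across rows of one ``ID``.
    """
    raw = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=[NA_TOKEN], comment=None
    )
    missing = [c for c in SCHEMA_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = raw.loc[:, list(SCHEMA_COLUMNS)].copy()
    for col in NUMERIC_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row + 1}"
            )
        df[col] = converted

    # capture-level columns must be constant within each ID
    cap = df[["ID", *CAPTURE_COLUMNS]]
    nunique = cap.groupby("ID", sort=False).nunique(dropna=False)
    offenders = sorted(nunique.index[(nunique > 1).any(axis=1)].tolist())
    if offenders:
        raise IntegrityError(
            "inconsistent capture-level values for ID(s): " + ", ".join(offenders)
        )

    individuals = (
        df.groupby("ID", sort=False)[list(CAPTURE_COLUMNS)].first().sort_index()
    )
    for col in ("Age_cpt",):
        individuals[col] = individuals[col].astype(int)

    increments = df[["ID", "Age_i", "R_i", *RESULT_COLUMNS]].copy()
    increments["Age_i"] = increments["Age_i"].astype(int)
    increments = increments.sort_values(["ID", "Age_i"], kind="mergesort").reset_index(
        drop=True
    )
    return GrowthDataset(
        individuals=individuals,
        increments=increments,
        provenance=provenance if provenance is not None else str(path),
    )


def write_growth_csv(ds: GrowthDataset, path) -> None:
    """Write a :class:`GrowthDataset` back to the long 18-column CSV.

    Emits columns in schema order with ``NA`` for missing values; round-trips
    the informational content of :func:`read_growth_csv`.
    """
    long = ds.increments.merge(
        ds.individuals.reset_index().rename(columns={"index": "ID"}),
        on="ID",
        how="left",
    )
    long = long.loc[:, list(SCHEMA_COLUMNS)]
    for col in ("Age_i", "Age_cpt"):
        long[col] = long[col].astype(int)
    long.to_csv(path, index=False, na_rep=NA_TOKEN)


def to_long_frame(ds: GrowthDataset) -> pd.DataFrame:
    """Return the dataset as a single long-format frame in schema column order."""
    buf = io.StringIO()
    write_growth_csv(ds, buf)
    buf.seek(0)
    return pd.read_csv(buf, keep_default_na=False, na_values=[NA_TOKEN])


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    rule: str
    individual_id: str
    detail: str

    def as_tsv(self) -> str:
        return f"{self.individual_id}\t{self.rule}\t{self.detail}"


def validate_dataset(ds: GrowthDataset) -> list[Violation]:
    """Check every dataset invariant; return an ordered list of violations.

    Violations are data, not exceptions: an empty list means the dataset is
    internally consistent.  The report is deterministic, ordered by
    ``individual_id`` then rule id.  Rules:

    - ``unknown_id``: increment references an ID absent from the individuals table
    - ``duplicate_age``: duplicate (ID, Age_i) pair
    - ``age_range``: Age_i outside [0, Age_cpt]
    - ``radius_positive``: non-positive R_i
    - ``radius_le_capture``: R_i exceeds R_cpt
    - ``radius_monotone``: R_i decreases with age within an individual
    - ``r0p_consistency``: R_0p differs from R_i at age 0
    - ``l0p_lt_lcpt``: L_0p not below L_cpt for a fish aged >= 1
    - ``capture_positive``: non-positive R_cpt, L_cpt or L_0p
    """
    out: list[Violation] = []
    known_ids = set(ds.individuals.index)

    for iid in sorted(set(ds.increments["ID"]) - known_ids):
        out.append(Violation("unknown_id", str(iid), "increment ID not in individuals"))

    dup = ds.increments.duplicated(subset=["ID", "Age_i"], keep=False)
    for iid in sorted(set(ds.increments.loc[dup, "ID"])):
        ages = ds.increments.loc[dup & (ds.increments["ID"] == iid), "Age_i"].tolist()
        out.append(Violation("duplicate_age", str(iid), f"duplicate ages {sorted(set(ages))}"))

    for iid, row in ds.individuals.iterrows():
        iid = str(iid)
        inc = ds.increments[ds.increments["ID"] == iid].sort_values("Age_i")
        age_cpt = int(row["Age_cpt"])
        r_cpt, l_cpt, l_0p = row["R_cpt"], row["L_cpt"], row["L_0p"]

        if any(pd.isna(v) or v <= 0 for v in (r_cpt, l_cpt, l_0p)):
            out.append(Violation("capture_positive", iid, "non-positive capture field"))
            continue
        if age_cpt >= 1 and not l_0p < l_cpt:
            out.append(Violation("l0p_lt_lcpt", iid, f"L_0p={l_0p} >= L_cpt={l_cpt}"))

        ages = inc["Age_i"].to_numpy()
        radii = inc["R_i"].to_numpy(dtype=float)
        bad_age = (ages < 0) | (ages > age_cpt)
        if bad_age.any():
            out.append(
                Violation("age_range", iid, f"ages {ages[bad_age].tolist()} outside [0, {age_cpt}]")
            )
        present = ~np.isnan(radii)
        if (radii[present] <= 0).any():
            out.append(Violation("radius_positive", iid, "non-positive R_i"))
        if (radii[present] > r_cpt + 1e-12).any():
            out.append(Violation("radius_le_capture", iid, f"R_i exceeds R_cpt={r_cpt}"))
        rp = radii[present]
        if len(rp) >= 2 and (np.diff(rp) < -1e-12).any():
            out.append(Violation("radius_monotone", iid, "R_i decreases with age"))

        r0p = row["R_0p"]
        at0 = inc.loc[inc["Age_i"] == 0, "R_i"]
        if not pd.isna(r0p) and len(at0) == 1 and not pd.isna(at0.iloc[0]):
            if abs(float(at0.iloc[0]) - float(r0p)) > 1e-9:
                out.append(
                    Violation("r0p_consistency", iid, f"R_0p={r0p} != R_i(age 0)={at0.iloc[0]}")
                )

    out.sort(key=lambda v: (v.individual_id, v.rule))
    return out


def report_as_tsv(violations: Sequence[Violation]) -> str:
    lines = ["individual_id\trule\tdetail"]
    lines += [v.as_tsv() for v in violations]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# back-calculation group selection
# ---------------------------------------------------------------------------

GROUPINGS = ("species", "species_by_location")


@dataclass
class BackcalcGroup:
    """One eligible fitting group plus its per-individual exclusion ledger."""

    key: tuple[str, ...]
    members: list[IndividualSample] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (ID, reason)

    @property
    def label(self) -> str:
        return " / ".join(self.key)


def group_key(sample: IndividualSample, grouping: str) -> tuple[str, ...]:
    if grouping == "species":
        return (sample.species_key,)
    if grouping == "species_by_location":
        return (sample.species_key, sample.location)
    raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")


def select_backcalc_groups(ds: GrowthDataset, grouping: str) -> list[BackcalcGroup]:
    """Partition individuals into back-calculation groups with exclusions.

    A group (species, or species x location) is eligible only if it has at
    least two individuals with a known hatch radius ``R_0p`` — the proportional
    regression cannot otherwise pin the hatch anchor.  Within eligible groups,
    fish captured at age one are excluded (a single increment gives the
    back-calculation no interior point), as are fish captured at age zero
    (degenerate: hatching and capture coincide).  Ineligible groups are
    returned with all individuals excluded, reason ``insufficient_r0p``.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")

    buckets: dict[tuple[str, ...], list[IndividualSample]] = {}
    for sample in ds.iter_individuals():
        buckets.setdefault(group_key(sample, grouping), []).append(sample)

    groups: list[BackcalcGroup] = []
    for key in sorted(buckets):
        grp = BackcalcGroup(key=key)
        samples = sorted(buckets[key], key=lambda s: s.individual_id)
        age_ok = [s for s in samples if s.age_cpt >= 2]
        # the regression needs >= 2 known hatch radii among fish it can use
        n_known = sum(1 for s in age_ok if s.radius_0p is not None)
        if n_known < 2:
            grp.excluded = [(s.individual_id, "insufficient_r0p") for s in samples]
        else:
            for s in samples:
                if s.age_cpt == 1:
                    grp.excluded.append((s.individual_id, "age_at_capture_one"))
                elif s.age_cpt == 0:
                    grp.excluded.append((s.individual_id, "age_at_capture_zero"))
                else:
                    grp.members.append(s)
        groups.append(grp)
    return groups
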