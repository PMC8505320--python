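"""Individual-tracked census data: domain model, validation and I/O.

The central object is :class:`Census`: a set of uniquely identified
individuals, each with a species label and a 0/1 occupancy vector over an
ordered sequence of census units (survey dates, years, ...). A value of 1 at
unit *j* means the individual was alive and counted at that census. From a
Census a conventional species-by-unit :class:`AbundanceMatrix` is derived;
all pairwise and multiple-unit dissimilarity components in this package are
integer counts computed from these two objects.

Long-format I/O uses one row per (individual, census) presence, the natural
export format of forest-dynamics-plot databases and mark-recapture records.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Census",
    "AbundanceMatrix",
    "CensusWarning",
    "GapPolicyError",
    "read_long_format",
    "write_long_format",
    "apply_gap_policy",
    "to_abundance_matrix",
]

UNITS_HEADER_PREFIX = "#units="


class CensusWarning(UserWarning):
    """Non-fatal data issues found while building a Census."""


class GapPolicyError(ValueError):
    """An occupancy vector violates the requested gap policy."""


@dataclass(frozen=True, eq=False)
class Census:
    """Individuals tracked over an ordered sequence of census units.

    Parameters
    ----------
    units : tuple
        Ordered census labels, length T >= 2, no duplicates.
    ids : tuple of str
        Unique individual identifiers, one per row of ``occupancy``.
    species : tuple of str
        Species label per individual (parallel to ``ids``).
    occupancy : numpy.ndarray
        0/1 matrix of shape (n_individuals, T); each row has at least one 1.
    """

    units: tuple
    ids: tuple
    species: tuple
    occupancy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        units = tuple(self.units)
        ids = tuple(str(i) for i in self.ids)
        species = tuple(str(s) for s in self.species)
        occ = np.ascontiguousarray(np.asarray(self.occupancy, dtype=np.int8))
        object.__setattr__(self, "units", units)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "occupancy", occ)
        if len(units) < 2:
            raise ValueError("a census needs at least two units")
        if len(set(units)) != len(units):
            raise ValueError("duplicate unit labels")
        if occ.ndim != 2 or occ.shape != (len(ids), len(units)):
            raise ValueError(
                f"occupancy shape {occ.shape} does not match "
                f"{len(ids)} individuals x {len(units)} units"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids are not unique")
        if len(species) != len(ids):
            raise ValueError("species labels do not match individuals")
        if occ.size and not np.isin(occ, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")
        if occ.shape[0] and not occ.any(axis=1).all():
            missing = [ids[i] for i in np.flatnonzero(~occ.any(axis=1))][:5]
            raise ValueError(f"individuals with all-zero occupancy: {missing}")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def unit_index(self, unit) -> int:
        try:
            return self.units.index(unit)
        except ValueError:
            raise KeyError(f"unknown unit label: {unit!r}") from None

    def individuals(self) -> Iterable[tuple]:
        """Yield (individual_id, species_id, occupancy row) records."""
        for i, (iid, sp) in enumerate(zip(self.ids, self.species)):
            yield iid, sp, self.occupancy[i].copy()

    def gapped_individuals(self) -> list:
        """Ids whose occupancy has an internal gap (a 1...0...1 pattern)."""
        occ = self.occupancy
        out = []
        for i in range(occ.shape[0]):
            ones = np.flatnonzero(occ[i])
            if ones.size and ones[-1] - ones[0] + 1 != ones.size:
                out.append(self.ids[i])
        return out

    def is_contiguous(self) -> bool:
        """True when every individual's lifespan is an unbroken run of 1s."""
        return not self.gapped_individuals()


@dataclass(frozen=True, eq=False)
class AbundanceMatrix:
    """Species x units count matrix derived from a Census.

    ``counts[i, j]`` is the number of individuals of species *i* counted at
    unit *j* (x_ij). Totals follow the standard notation: S_j species
    richness per unit, S_T pooled richness, I_j individuals per unit, I_T
    distinct individuals over all units, and T_AB the grand total abundance
    (sum of I_j over units).
    """

    species: tuple
    units: tuple
    counts: np.ndarray = field(repr=False)
    n_distinct_individuals: int | None = None

    def __post_init__(self) -> None:
        counts = np.ascontiguousarray(np.asarray(self.counts, dtype=np.int64))
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "units", tuple(self.units))
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape != (len(self.species), len(self.units)):
            raise ValueError("counts shape does not match species x units")
        if counts.size and counts.min() < 0:
            raise ValueError("abundances must be non-negative")

    def unit_index(self, unit) -> int:
        try:
            return self.units.index(unit)
        except ValueError:
            raise KeyError(f"unknown unit label: {unit!r}") from None

    @property
    def S_j(self) -> np.ndarray:
        """Species richness per unit."""
        return (self.counts > 0).sum(axis=0)

    @property
    def S_T(self) -> int:
        """Pooled species richness over all units."""
        return int((self.counts.sum(axis=1) > 0).sum())

    @property
    def I_j(self) -> np.ndarray:
        """Number of individuals counted at each unit (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def I_T(self) -> int | None:
        """Number of distinct individuals pooled over all units.

        Only known when the matrix was derived from a Census; None for
        matrices built from species counts alone.
        """
        return self.n_distinct_individuals

    @property
    def T_AB(self) -> int:
        """Grand total abundance over the whole data set (sum of I_j)."""
        return int(self.counts.sum())


def to_abundance_matrix(census: Census) -> AbundanceMatrix:
    """Collapse individuals to a species x units count matrix.

    ``counts[i, j]`` counts the individuals of species *i* with occupancy 1
    at unit *j*; column sums therefore equal I_j and the grand total equals
    T_AB. Species order is first-appearance order over individuals.
    """
    species_order: list = []
    seen: dict = {}
    for sp in census.species:
        if sp not in seen:
            seen[sp] = len(species_order)
            species_order.append(sp)
    counts = np.zeros((len(species_order), census.n_units), dtype=np.int64)
    rows = np.fromiter((seen[sp] for sp in census.species), dtype=np.int64,
                       count=census.n_individuals)
    np.add.at(counts, rows, census.occupancy.astype(np.int64))
    return AbundanceMatrix(
        species=tuple(species_order),
        units=census.units,
        counts=counts,
        n_distinct_individuals=census.n_individuals,
    )


def apply_gap_policy(census: Census, policy: str = "strict") -> Census:
    """Resolve internal gaps (1...0...1 patterns) in occupancy vectors.

    policy="strict"
        Raise :class:`GapPolicyError` naming the gapped individuals. Gaps
        usually mean census misses; left alone they corrupt the
        mortality/recruitment flows that the null model conditions on.
    policy="fill"
        Set internal zeros between first and last presence to 1 (the
        individual was presumably alive but missed); the number of filled
        cells is logged.
    policy="events"
        Leave vectors untouched. Indices remain computable, but the null
        model refuses such censuses.
    """
    if policy not in ("strict", "fill", "events"):
        raise ValueError(f"unknown gap policy: {policy!r}")
    gapped = census.gapped_individuals()
    if not gapped:
        return census
    if policy == "strict":
        shown = ", ".join(map(str, gapped[:10]))
        more = "" if len(gapped) <= 10 else f" (+{len(gapped) - 10} more)"
        raise GapPolicyError(
            f"{len(gapped)} individual(s) with gapped occupancy under policy "
            f"'strict': {shown}{more}; re-run with policy 'fill' to close gaps"
        )
    if policy == "events":
        return census
    occ = census.occupancy.copy()
    filled = 0
    for i in range(occ.shape[0]):
        ones = np.flatnonzero(occ[i])
        span = slice(ones[0], ones[-1] + 1)
        filled += int((occ[i, span] == 0).sum())
        occ[i, span] = 1
    logger.info("gap policy 'fill': set %d internal cells to 1 across %d individuals",
                filled, len(gapped))
    return Census(census.units, census.ids, census.species, occ)


def _order_units(values: Sequence, unit_order: Sequence | None):
    """Determine the declared unit order for long-format input."""
    distinct = list(dict.fromkeys(values))
    if unit_order is not None:
        unit_order = list(unit_order)
        unknown = set(distinct) - set(unit_order)
        if unknown:
            raise ValueError(f"time_unit values missing from unit order: {sorted(map(str, unknown))}")
        return tuple(unit_order)
    try:
        return tuple(sorted(distinct, key=float))
    except (TypeError, ValueError):
        pass
    as_dates = pd.to_datetime(pd.Series(distinct), errors="coerce", format="ISO8601")
    if not as_dates.isna().any():
        return tuple(pd.Series(distinct).iloc[np.argsort(as_dates.values)])
    raise ValueError(
        "time_unit values are neither numeric nor ISO dates; "
        "pass an explicit unit_order"
    )


def read_long_format(
    stream: TextIO | str,
    *,
    delimiter: str = ",",
    individual_col: str = "individual_id",
    species_col: str = "species_id",
    time_col: str = "time_unit",
    unit_order: Sequence | None = None,
) -> Census:
    """Read a long-format census: one row per (individual, census) presence.

    An optional first line ``#units=u1,u2,...`` declares the full ordered
    unit list (needed to preserve units at which nothing was counted).
    Duplicate (individual, time) rows are deduplicated with a warning. When
    an individual carries different species labels in different rows, the
    label at its first appearance wins and a warning is issued.
    """
    if isinstance(stream, str):
        with open(stream, "r", newline="") as fh:
            return read_long_format(
                fh, delimiter=delimiter, individual_col=individual_col,
                species_col=species_col, time_col=time_col, unit_order=unit_order,
            )

    first = stream.readline()
    header_units = None
    if first.startswith(UNITS_HEADER_PREFIX):
        payload = first[len(UNITS_HEADER_PREFIX):].strip()
        header_units = next(csv.reader([payload], delimiter=delimiter))
        body = stream
    else:
        body = io.StringIO(first + stream.read())
    df = pd.read_csv(body, delimiter=delimiter, dtype=str, skipinitialspace=True)
    needed = {individual_col, species_col, time_col}
    if not needed.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(needed - set(df.columns))}")
    df = df[[individual_col, species_col, time_col]].dropna()
    if df.empty:
        raise ValueError("no records in input")

    dup = df.duplicated(subset=[individual_col, time_col])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (individual, time) rows dropped",
            CensusWarning, stacklevel=2,
        )
        df = df[~dup]

    if unit_order is None and header_units is not None:
        unit_order = header_units
    units = _order_units(df[time_col].tolist(), unit_order)
    unit_idx = {u: t for t, u in enumerate(units)}

    ids: list = []
    species: dict = {}
    row_of: dict = {}
    conflicts = []
    presences: list[tuple[int, int]] = []
    for iid, sp, tu in df.itertuples(index=False):
        if iid not in row_of:
            row_of[iid] = len(ids)
            ids.append(iid)
            species[iid] = sp
        elif species[iid] != sp:
            conflicts.append(iid)
        presences.append((row_of[iid], unit_idx[tu]))
    if conflicts:
        warnings.warn(
            f"conflicting species labels for {len(set(conflicts))} individual(s); "
            "first appearance wins",
            CensusWarning, stacklevel=2,
        )
    occ = np.zeros((len(ids), len(units)), dtype=np.int8)
    pres = np.asarray(presences, dtype=np.int64)
    occ[pres[:, 0], pres[:, 1]] = 1
    return Census(units, tuple(ids), tuple(species[i] for i in ids), occ)


def write_long_format(
    census: Census,
    stream: TextIO | str,
    *,
    delimiter: str = ",",
    individual_col: str = "individual_id",
    species_col: str = "species_id",
    time_col: str = "time_unit",
) -> None:
    """Write a Census in long format; inverse of :func:`read_long_format`.

    The ``#units=`` header is always written so that units where nothing was
    counted survive a round trip.
    """
    if isinstance(stream, str):
        with open(stream, "w", newline="") as fh:
            write_long_format(
                census, fh, delimiter=delimiter, individual_col=individual_col,
                species_col=species_col, time_col=time_col,
            )
        return
    buf = io.StringIO()
    csv.writer(buf, delimiter=delimiter, lineterminator="").writerow(
        [str(u) for u in census.units]
    )
    stream.write(UNITS_HEADER_PREFIX + buf.getvalue() + "\n")
    writer = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    writer.writerow([individual_col, species_col, time_col])
    for iid, sp, occ in census.individuals():
        for t in np.flatnonzero(occ):
            writer.writerow([iid, sp, census.units[t]])


def write_wide_occupancy(census: Census, stream: TextIO | str) -> None:
    """Export a TSV occupancy table: one row per individual, one 0/1 column per unit."""
    if isinstance(stream, str):
        with open(stream, "w", newline="") as fh:
            write_wide_occupancy(census, fh)
        return
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["individual_id", "species_id", *map(str, census.units)])
    for iid, sp, occ in census.individuals():
        writer.writerow([iid, sp, *occ.tolist()])
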