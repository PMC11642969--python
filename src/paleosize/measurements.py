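"""Specimen-level size data: reading, validation, and species/fauna summaries.

Body size is represented by shell length in mm, measured parallel to the
coiling axis.  Specimens are assigned to one of three regional time bins
(pre-extinction Plio-Pleistocene, a post-extinction but pre-modern interval,
and the modern fauna); bin membership is an input column, never computed
from stratigraphy.  Species-level descriptors (mean, maximum, and a
pluggable "typical size") feed the clade-level turnover test, which compares
the pre-extinction and modern species pools only.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("paleosize")

__all__ = [
    "TimeBin",
    "Metric",
    "SpecimenRecord",
    "FaunaTable",
    "TableDialect",
    "MeasurementError",
    "FormatError",
    "RowError",
    "read_measurements",
    "write_measurements",
    "records_to_frame",
    "summarize_species",
    "build_fauna",
]

RECORD_COLUMNS = ["species", "clade", "time_bin", "length_mm", "source", "from_figure"]
SUMMARY_COLUMNS = [
    "species", "clade", "time_bin", "n_specimens", "mean_mm", "max_mm", "typical_mm",
]


class TimeBin(str, enum.Enum):
    """Regional time-bin assignment of a specimen's species occurrence."""

    PRE_EXTINCTION = "pre_extinction"
    POST_PRE_MODERN = "post_pre_modern"
    MODERN = "modern"


class Metric(str, enum.Enum):
    """Which per-species descriptor represents a species' size in a fauna."""

    MEAN = "mean"
    MAX = "max"
    TYPICAL = "typical"


class MeasurementError(ValueError):
    """Base class for measurement-table problems."""


class FormatError(MeasurementError):
    """The table is structurally unusable (e.g. a mandatory column is absent)."""


class RowError(MeasurementError):
    """A single row violates an invariant (non-positive length, unknown bin...)."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured shell.

    length_mm is the shell length in mm, parallel to the coiling axis;
    from_figure flags measurements digitised from published figures rather
    than taken on physical specimens (kept by default, droppable in
    sensitivity runs).
    """

    species: str
    clade: str
    time_bin: TimeBin
    length_mm: float
    source: str = ""
    from_figure: bool = False

    def __post_init__(self) -> None:
        if not self.length_mm > 0:
            raise RowError(
                f"length_mm must be positive, got {self.length_mm!r} "
                f"for {self.species!r}"
            )
        object.__setattr__(self, "time_bin", TimeBin(self.time_bin))


_DEFAULT_BIN_LABELS: dict[str, TimeBin] = {}
for _bin in TimeBin:
    _DEFAULT_BIN_LABELS[_bin.value] = _bin
    _DEFAULT_BIN_LABELS[_bin.name.lower()] = _bin
_DEFAULT_BIN_LABELS.update(
    {
        "pre": TimeBin.PRE_EXTINCTION,
        "pre-extinction": TimeBin.PRE_EXTINCTION,
        "plio-pleistocene": TimeBin.PRE_EXTINCTION,
        "fossil": TimeBin.PRE_EXTINCTION,
        "calabrian-pleistocene": TimeBin.POST_PRE_MODERN,
        "recent": TimeBin.MODERN,
        "extant": TimeBin.MODERN,
    }
)

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


@dataclass(frozen=True)
class TableDialect:
    """CSV column mapping and time-bin label vocabulary.

    The default expects a UTF-8 comma-separated file with a header row and
    columns named ``species, clade, time_bin, length_mm`` (plus optional
    ``source`` and ``from_figure``); bin labels are matched
    case-insensitively against `bin_labels`.
    """

    species_col: str = "species"
    clade_col: str = "clade"
    time_bin_col: str = "time_bin"
    length_col: str = "length_mm"
    source_col: str = "source"
    figure_col: str = "from_figure"
    bin_labels: Mapping[str, TimeBin] = field(
        default_factory=lambda: dict(_DEFAULT_BIN_LABELS)
    )


def _parse_bin(label: object, dialect: TableDialect, row: int) -> TimeBin:
    key = str(label).strip().lower()
    try:
        return dialect.bin_labels[key]
    except KeyError:
        accepted = sorted(set(dialect.bin_labels))
        raise RowError(
            f"row {row}: unknown time-bin label {label!r}; accepted labels: {accepted}"
        ) from None


def read_measurements(
    path,
    dialect: TableDialect | None = None,
    on_bad_rows: str = "raise",
) -> pd.DataFrame:
    """Read and validate a specimen measurement CSV.

    Returns a DataFrame with canonical columns
    ``species, clade, time_bin, length_mm, source, from_figure`` in file
    order.  ``on_bad_rows`` is ``"raise"`` (default) or ``"skip"``; a parse
    report (rows read / rejected) is logged either way.

    Raises FormatError if a mandatory column is missing and RowError for
    non-positive/non-numeric lengths or unknown time-bin labels.
    """
    dialect = dialect or TableDialect()
    if on_bad_rows not in ("raise", "skip"):
        raise ValueError("on_bad_rows must be 'raise' or 'skip'")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (dialect.species_col, dialect.clade_col, dialect.time_bin_col,
                dialect.length_col):
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")

    rows: list[dict] = []
    rejected = 0
    for i, row in enumerate(raw.itertuples(index=False)):
        row = dict(zip(raw.columns, row))
        try:
            length_txt = row[dialect.length_col].strip()
            try:
                length = float(length_txt)
            except ValueError:
                raise RowError(
                    f"row {i}: non-numeric length {length_txt!r}"
                ) from None
            if not length > 0:
                raise RowError(f"row {i}: non-positive length {length}")
            bin_ = _parse_bin(row[dialect.time_bin_col], dialect, i)
            fig_txt = str(row.get(dialect.figure_col, "")).strip().lower()
            if fig_txt in _TRUTHY:
                from_figure = True
            elif fig_txt in _FALSY:
                from_figure = False
            else:
                raise RowError(f"row {i}: unrecognized from_figure flag {fig_txt!r}")
            rows.append(
                {
                    "species": row[dialect.species_col].strip(),
                    "clade": row[dialect.clade_col].strip(),
                    "time_bin": bin_.value,
                    "length_mm": length,
                    "source": str(row.get(dialect.source_col, "")).strip(),
                    "from_figure": from_figure,
                }
            )
        except RowError:
            if on_bad_rows == "raise":
                raise
            rejected += 1
    out = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    logger.info("read_measurements: %d rows read, %d rejected (%s)",
                len(out), rejected, path)
    return out


def write_measurements(records: pd.DataFrame, path) -> None:
    """Write a canonical measurement table as CSV (round-trips with read)."""
    records.loc[:, RECORD_COLUMNS].to_csv(path, index=False)


def records_to_frame(records: Iterable[SpecimenRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce records (DataFrame or iterable of SpecimenRecord) to canonical form."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in ("species", "clade", "time_bin", "length_mm")
                   if c not in records.columns]
        if missing:
            raise FormatError(f"records frame missing columns {missing}")
        df = records.copy()
        if "source" not in df.columns:
            df["source"] = ""
        if "from_figure" not in df.columns:
            df["from_figure"] = False
        df["time_bin"] = [TimeBin(b).value for b in df["time_bin"]]
        df["length_mm"] = df["length_mm"].astype(float)
        if not (df["length_mm"] > 0).all():
            bad = int(np.flatnonzero(~(df["length_mm"].to_numpy() > 0))[0])
            raise RowError(f"row {bad}: non-positive length")
        return df.loc[:, RECORD_COLUMNS].reset_index(drop=True)
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "clade": r.clade,
                "time_bin": r.time_bin.value,
                "length_mm": r.length_mm,
                "source": r.source,
                "from_figure": r.from_figure,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def summarize_species(
    records: Iterable[SpecimenRecord] | pd.DataFrame,
    typical_rule: Callable[[np.ndarray], float] = np.mean,
    include_figures: bool = True,
) -> pd.DataFrame:
    """Collapse specimens to per-(species, time-bin) size descriptors.

    mean_mm and max_mm are the arithmetic mean and maximum of specimen
    lengths; typical_mm applies ``typical_rule`` (default: arithmetic mean —
    exact reproduction of published Conidae "typical" values requires
    configuring that clade's rule).  Empty groups emit no summary; a species
    name appearing under more than one clade is a validation error.
    """
    df = records_to_frame(records)
    if not include_figures:
        df = df.loc[~df["from_figure"]]
    if df.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    clades_per_species = df.groupby("species")["clade"].nunique()
    mixed = clades_per_species[clades_per_species > 1]
    if len(mixed):
        raise MeasurementError(
            f"species assigned to multiple clades: {sorted(mixed.index)}"
        )
    rows = []
    for (species, clade, bin_), grp in df.groupby(
        ["species", "clade", "time_bin"], sort=True
    ):
        lengths = grp["length_mm"].to_numpy(dtype=float)
        rows.append(
            {
                "species": species,
                "clade": clade,
                "time_bin": bin_,
                "n_specimens": len(lengths),
                "mean_mm": float(np.mean(lengths)),
                "max_mm": float(np.max(lengths)),
                "typical_mm": float(typical_rule(lengths)),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass(frozen=True)
class FaunaTable:
    """Per-clade species-size vectors for the two bins the turnover test uses.

    ``pre_sizes``/``modern_sizes`` hold one size (mm) per species present in
    the pre-extinction and modern bins; N_f = len(pre_sizes) and
    N_m = len(modern_sizes).  Species surviving the boundary appear once in
    each vector.
    """

    clade: str
    metric: Metric
    pre_sizes: np.ndarray
    modern_sizes: np.ndarray
    pre_species: tuple[str, ...]
    modern_species: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric", Metric(self.metric))
        pre = np.asarray(self.pre_sizes, dtype=float)
        mod = np.asarray(self.modern_sizes, dtype=float)
        if (pre <= 0).any() or (mod <= 0).any():
            raise MeasurementError("fauna sizes must be positive")
        if len(pre) != len(self.pre_species) or len(mod) != len(self.modern_species):
            raise MeasurementError("species-name vectors must parallel size vectors")
        object.__setattr__(self, "pre_sizes", pre)
        object.__setattr__(self, "modern_sizes", mod)

    @property
    def n_f(self) -> int:
        return len(self.pre_sizes)

    @property
    def n_m(self) -> int:
        return len(self.modern_sizes)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (clade, metric, bin, species, size_mm) table."""
        rows = [
            (self.clade, self.metric.value, TimeBin.PRE_EXTINCTION.value, sp, sz)
            for sp, sz in zip(self.pre_species, self.pre_sizes)
        ] + [
            (self.clade, self.metric.value, TimeBin.MODERN.value, sp, sz)
            for sp, sz in zip(self.modern_species, self.modern_sizes)
        ]
        return pd.DataFrame(
            rows, columns=["clade", "metric", "time_bin", "species", "size_mm"]
        )


_METRIC_COL = {
    Metric.MEAN: "mean_mm",
    Metric.MAX: "max_mm",
    Metric.TYPICAL: "typical_mm",
}


def build_fauna(
    summaries: pd.DataFrame,
    clade: str,
    metric: Metric | str = Metric.MEAN,
    exclusions: Iterable[str] = (),
) -> FaunaTable:
    """Assemble a clade's pre-extinction/modern species-size vectors.

    ``exclusions`` removes species from both bins (e.g. *Cittarium pica*
    sensitivity runs).  Species in the intermediate post-extinction bin are
    not part of the turnover comparison and are dropped.
    """
    metric = Metric(metric)
    excl = set(exclusions)
    sub = summaries.loc[summaries["clade"] == clade]
    if sub.empty:
        raise KeyError(f"clade {clade!r} not present in summaries")
    sub = sub.loc[~sub["species"].isin(excl)]
    col = _METRIC_COL[metric]
    if sub[col].isna().any():
        bad = sorted(sub.loc[sub[col].isna(), "species"])
        raise MeasurementError(
            f"metric {metric.value!r} unavailable for species {bad} in {clade!r}"
        )

    def bin_vectors(bin_: TimeBin) -> tuple[np.ndarray, tuple[str, ...]]:
        b = sub.loc[sub["time_bin"] == bin_.value].sort_values("species")
        return b[col].to_numpy(dtype=float), tuple(b["species"])

    pre_sizes, pre_species = bin_vectors(TimeBin.PRE_EXTINCTION)
    modern_sizes, modern_species = bin_vectors(TimeBin.MODERN)
    return FaunaTable(
        clade=clade,
        metric=metric,
        pre_sizes=pre_sizes,
        modern_sizes=modern_sizes,
        pre_species=pre_species,
        modern_species=modern_species,
    )
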