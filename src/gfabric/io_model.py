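"""Reading, validation, filtering and normalization of replicated expression tables.

The raw unit of input is one microarray spot measured in every
condition x replica sample: foreground and background fluorescence plus
a corrupted-pixel flag. Tables are tab-delimited, one row per
(spot, condition, replica) observation; a :class:`TableSchema` maps the
file's column names onto the canonical fields.

Quality filtering follows the rule that a spot is dropped from *all*
samples if, in any single sample, it is corrupted or its foreground is
less than twice its background. Normalization brings every sample to
median 1 and then rescales globally so that the median gene (over all
genes and samples, after averaging a gene's redundant spots) sits at
exactly 1 — the unit in which AVE is reported downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A required column is missing or the schema/config is malformed."""


class IntegrityError(ValueError):
    """The table violates a structural contract (duplicates, missing samples)."""


class FormatError(ValueError):
    """A gene-set or config file is syntactically invalid."""


class NumericError(ValueError):
    """A numeric contract is violated (non-positive intensities, zero medians)."""


#: canonical field names, in file order used by the writer
CANONICAL_FIELDS = (
    "spot_id",
    "gene",
    "chamber",
    "replica",
    "foreground",
    "background",
    "corrupted",
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


@dataclass(frozen=True)
class TableSchema:
    """Mapping from canonical fields to the column names of a particular file."""

    spot_id: str = "spot_id"
    gene: str = "gene"
    chamber: str = "chamber"
    replica: str = "replica"
    foreground: str = "foreground"
    background: str = "background"
    corrupted: str = "corrupted"

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "TableSchema":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise SchemaError(f"unknown schema fields: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_mapping(self) -> dict[str, str]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SpotMeasurement:
    """One spot's intensities and QC flag in one condition x replica sample."""

    spot_id: str
    gene: str
    chamber: str
    replica: str
    foreground: float
    background: float
    corrupted: bool
    value: float | None = None  # normalized expression, set after normalize()


def _parse_bool(column: pd.Series) -> pd.Series:
    lowered = column.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(_TRUE | _FALSE)
    if bad.any():
        raise FormatError(
            f"unparseable boolean flag value(s): {sorted(lowered[bad].unique())[:5]}"
        )
    return lowered.isin(_TRUE)


def read_expression_table(
    path: str | Path, schema: TableSchema | Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a tab-delimited expression table into canonical measurement form.

    Returns a DataFrame with the canonical columns (one row per
    measurement, row count preserved). Unparseable numeric fields raise
    :class:`NumericError`; a schema column absent from the file raises
    :class:`SchemaError`; duplicated (spot, chamber, replica) rows raise
    :class:`IntegrityError`.
    """
    if schema is None:
        schema = TableSchema()
    elif not isinstance(schema, TableSchema):
        schema = TableSchema.from_mapping(schema)

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = schema.to_mapping()
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"columns named in schema absent from {path}: {missing}")

    out = pd.DataFrame(
        {field: raw[src] for field, src in colmap.items()}, copy=True
    )
    for field in ("foreground", "background"):
        try:
            out[field] = pd.to_numeric(out[field], errors="raise")
        except (ValueError, TypeError) as exc:
            raise NumericError(f"unparseable {field} value: {exc}") from exc
        if (out[field] < 0).any():
            raise NumericError(f"negative {field} intensity")
    out["corrupted"] = _parse_bool(out["corrupted"])

    dup = out.duplicated(["spot_id", "chamber", "replica"])
    if dup.any():
        first = out.loc[dup, ["spot_id", "chamber", "replica"]].iloc[0]
        raise IntegrityError(
            "duplicate measurement for spot "
            f"{first['spot_id']!r} in sample ({first['chamber']}, {first['replica']})"
        )
    return out.reset_index(drop=True)


def filter_spots(
    measurements: pd.DataFrame, n_samples: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the global spot-quality filter.

    A spot is removed from *all* samples if in any sample it is
    corrupted or its foreground is strictly less than twice its
    background (foreground exactly equal to 2x background is retained).
    Returns ``(retained, report)`` where the report lists one row per
    offending (spot, sample) with the reason.
    """
    samples = measurements[["chamber", "replica"]].drop_duplicates()
    if n_samples is None:
        n_samples = len(samples)
    elif len(samples) != n_samples:
        raise IntegrityError(
            f"expected {n_samples} samples, table contains {len(samples)}"
        )
    counts = measurements.groupby("spot_id", sort=False).size()
    incomplete = counts[counts != n_samples]
    if len(incomplete):
        raise IntegrityError(
            f"spot {incomplete.index[0]!r} observed in {int(incomplete.iloc[0])} "
            f"of {n_samples} samples"
        )

    weak = measurements["foreground"] < 2.0 * measurements["background"]
    bad = measurements["corrupted"] | weak
    report = measurements.loc[bad, ["spot_id", "gene", "chamber", "replica"]].copy()
    report["reason"] = np.where(
        measurements.loc[bad, "corrupted"], "corrupted", "foreground<2x background"
    )
    removed_ids = set(report["spot_id"])
    retained = measurements[~measurements["spot_id"].isin(removed_ids)].reset_index(
        drop=True
    )
    return retained, report.reset_index(drop=True)


class ExpressionSet:
    """Normalized expression values indexed by (gene, spot) x (chamber, replica).

    ``values`` is a DataFrame whose row index is the MultiIndex
    (gene, spot_id) and whose columns are the MultiIndex
    (chamber, replica); every cell is a strictly positive normalized
    expression in median-gene units.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        chambers: Sequence[str],
        replicas: Sequence[str],
    ):
        self.values = values
        self.chambers = list(chambers)
        self.replicas = list(replicas)
        self._check_structure()

    def _check_structure(self) -> None:
        if list(self.values.index.names) != ["gene", "spot_id"]:
            raise IntegrityError("row index must be (gene, spot_id)")
        if self.values.isna().any().any():
            raise IntegrityError("expression tensor incomplete: missing values")
        if (self.values.to_numpy() <= 0).any():
            raise NumericError("non-positive normalized expression value")
        expected = [(c, r) for c in self.chambers for r in self.replicas]
        if sorted(map(tuple, self.values.columns)) != sorted(expected):
            raise IntegrityError("columns do not cover chambers x replicas exactly")

    # -- basic structure -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index.get_level_values("gene").unique())

    @property
    def redundancy(self) -> pd.Series:
        """Number of spots probing each gene (R_i >= 1)."""
        return self.values.groupby(level="gene", sort=False).size()

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    # -- views used by the statistics modules ----------------------------
    def spot_values(self, gene: str, chamber: str) -> pd.DataFrame:
        """Spots x replicas matrix of one gene in one chamber."""
        if gene not in self.values.index.get_level_values("gene"):
            raise IntegrityError(f"gene {gene!r} not quantified")
        if chamber not in self.chambers:
            raise IntegrityError(f"unknown chamber {chamber!r}")
        block = self.values.loc[gene, chamber]
        return block[self.replicas]

    def chamber_matrix(self, chamber: str) -> pd.DataFrame:
        """All (gene, spot) rows x replicas for one chamber."""
        return self.values[chamber][self.replicas]

    def replica_means(self, chamber: str) -> pd.DataFrame:
        """Genes x replicas: per-replica mean over each gene's spots (linear scale)."""
        return (
            self.chamber_matrix(chamber)
            .groupby(level="gene", sort=False)
            .mean()
        )

    def gene_sample_means(self) -> pd.DataFrame:
        """Genes x (chamber, replica): spot-averaged expression per sample."""
        return self.values.groupby(level="gene", sort=False).mean()

    def normalization_deviation(self) -> float:
        """|median of per-gene sample-averaged values - 1| (contract <= 1e-6)."""
        return abs(float(np.median(self.gene_sample_means().to_numpy())) - 1.0)


def normalize(
    measurements: pd.DataFrame,
    chambers: Sequence[str] | None = None,
    replicas: Sequence[str] | None = None,
) -> ExpressionSet:
    """Normalize a filtered, complete measurement collection.

    Background-subtracts intensities (floored at 1e-6 x the sample
    median of the net intensities), scales each chamber x replica sample
    to median 1, then rescales globally so the overall median of the
    per-gene sample means equals 1.
    """
    if chambers is None:
        chambers = list(pd.unique(measurements["chamber"]))
    if replicas is None:
        replicas = list(pd.unique(measurements["replica"]))

    work = measurements.copy()
    work["net"] = work["foreground"] - work["background"]

    def _scale_sample(group: pd.DataFrame) -> pd.Series:
        med = float(group["net"].median())
        if med <= 0:
            raise NumericError(
                "sample median of background-subtracted intensities is non-positive"
            )
        floored = group["net"].clip(lower=1e-6 * med)
        return floored / float(floored.median())

    scaled = (
        work.groupby(["chamber", "replica"], group_keys=False, sort=False)
        .apply(_scale_sample, include_groups=False)
    )
    work["value"] = scaled

    wide = work.pivot_table(
        index=["gene", "spot_id"],
        columns=["chamber", "replica"],
        values="value",
        aggfunc="first",
        sort=False,
    )
    if wide.isna().any().any():
        raise IntegrityError("collection incomplete after pivoting")
    wide = wide.loc[:, [(c, r) for c in chambers for r in replicas]]

    gene_means = wide.groupby(level="gene", sort=False).mean()
    global_median = float(np.median(gene_means.to_numpy()))
    if global_median <= 0:
        raise NumericError("global median of gene sample means is non-positive")
    wide = wide / global_median
    return ExpressionSet(wide, chambers, replicas)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named pathway gene lists (GMT provenance), matched case-insensitively."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return list(self.sets[name])

    def quantified(self, name: str, genes: Iterable[str]) -> tuple[list[str], list[str]]:
        """Split a set's members into (quantified, missing) against a gene universe.

        Matching is case-insensitive; the returned quantified symbols use
        the universe's capitalization.
        """
        universe = {g.lower(): g for g in genes}
        present, missing = [], []
        for member in self.sets[name]:
            hit = universe.get(member.lower())
            if hit is None:
                missing.append(member)
            else:
                present.append(hit)
        return present, missing


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...).

    Duplicate member symbols within a set collapse to one
    (case-insensitively, first spelling wins); an empty member list or a
    repeated set name raises :class:`FormatError`.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, description = parts[0], parts[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: dict[str, str] = {}
            for symbol in parts[2:]:
                symbol = symbol.strip()
                if symbol and symbol.lower() not in seen:
                    seen[symbol.lower()] = symbol
            members = list(seen.values())
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = description
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# result-table output
# ---------------------------------------------------------------------------

#: significant digits used by every writer; round-trip lossless at this precision
FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with 12-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_measurements(measurements: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical measurement table in the dialect the reader consumes."""
    out = measurements.loc[:, list(CANONICAL_FIELDS)].copy()
    out["corrupted"] = out["corrupted"].astype(int)
    write_table(out, path)


def read_config(path: str | Path) -> dict:
    """Read a plain-text key: value config file (YAML dialect)."""
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a key: value mapping")
    return cfg
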