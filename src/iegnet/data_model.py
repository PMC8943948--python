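"""Domain types and tabular IO for regional IEG product counts.

The analysis operates on cell counts of two plasticity-related immediate-early
gene (IEG) products, EGR-1 and ARC, measured in 12 brain regions of rats from
four behavioural groups (OPA, NPA, NM, CC).  Counts live in a long-format
table with one row per (animal, region, IEG); downstream statistics consume an
*observation matrix* in which each (animal, IEG) pair contributes one row and
each of the 12 regions one column, so that inter-regional correlations are
computed across animals with both IEGs stacked as separate observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical region order used for every matrix, network and dendrogram.
REGIONS: tuple[str, ...] = (
    "PrL", "IL", "Orb", "Ins", "ACC", "Ssp",
    "aRC", "pRC", "DG", "CA3", "CA1", "EC",
)

GROUPS: tuple[str, ...] = ("OPA", "NPA", "NM", "CC")

IEGS: tuple[str, ...] = ("EGR1", "ARC")

_REGION_ALIASES = {r.lower(): r for r in REGIONS}
_GROUP_ALIASES = {g.lower(): g for g in GROUPS}
_IEG_ALIASES = {"egr1": "EGR1", "egr-1": "EGR1", "zif268": "EGR1",
                "arc": "ARC"}

_REQUIRED_COLUMNS = ("animal", "group", "region", "ieg", "count")

NORMALIZATION_METHODS = ("zscore_per_ieg_region", "cc_ratio", "none")


class CountTableError(ValueError):
    """Raised for malformed or inconsistent count tables."""


def canonical_region(code: str) -> str:
    """Map a region code to its canonical spelling, or raise."""
    try:
        return _REGION_ALIASES[str(code).strip().lower()]
    except KeyError:
        raise CountTableError(
            f"unknown region code {code!r}; valid regions are {', '.join(REGIONS)}"
        ) from None


def canonical_group(code: str) -> str:
    try:
        return _GROUP_ALIASES[str(code).strip().lower()]
    except KeyError:
        raise CountTableError(
            f"unknown group code {code!r}; valid groups are {', '.join(GROUPS)}"
        ) from None


def canonical_ieg(code: str) -> str:
    try:
        return _IEG_ALIASES[str(code).strip().lower()]
    except KeyError:
        raise CountTableError(
            f"unknown IEG code {code!r}; valid IEGs are {', '.join(IEGS)}"
        ) from None


@dataclass(frozen=True)
class CountTable:
    """Validated long-format table of IEG product counts.

    One row per (animal, region, IEG).  ``data`` columns: animal (str),
    group (str), region (str), ieg (str), count (float >= 0).
    """

    data: pd.DataFrame
    normalization: str = "none"

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CountTableError(f"missing columns: {missing}")
        dup = df.duplicated(subset=["animal", "region", "ieg"])
        if dup.any():
            row = df[dup].iloc[0]
            raise CountTableError(
                "duplicate (animal, region, ieg) key: "
                f"({row['animal']}, {row['region']}, {row['ieg']})"
            )
        if self.normalization == "none" and (df["count"] < 0).any():
            row = df[df["count"] < 0].iloc[0]
            raise CountTableError(
                f"negative count {row['count']} for animal {row['animal']!r}, "
                f"region {row['region']}, IEG {row['ieg']}"
            )
        by_animal = df.groupby("animal")["group"].nunique()
        if (by_animal > 1).any():
            bad = by_animal[by_animal > 1].index[0]
            raise CountTableError(f"animal {bad!r} assigned to more than one group")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def animals(self) -> list[str]:
        return sorted(self.data["animal"].unique())

    @property
    def groups(self) -> list[str]:
        present = set(self.data["group"].unique())
        return [g for g in GROUPS if g in present]

    def subset(self, groups: set[str] | list[str]) -> "CountTable":
        groups = {canonical_group(g) for g in groups}
        return CountTable(
            self.data[self.data["group"].isin(groups)].reset_index(drop=True),
            normalization=self.normalization,
        )


def _coerce_table(df: pd.DataFrame, source: str = "<memory>") -> CountTable:
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{source}: missing required columns {missing}")
    out = pd.DataFrame({
        "animal": df["animal"].astype(str),
        "group": [canonical_group(g) for g in df["group"]],
        "region": [canonical_region(r) for r in df["region"]],
        "ieg": [canonical_ieg(i) for i in df["ieg"]],
        "count": pd.to_numeric(df["count"], errors="raise").astype(float),
    })
    return CountTable(out)


def read_counts(path) -> CountTable:
    """Read a long-format count table from CSV or TSV (sniffed by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return _coerce_table(df, source=str(path))


def write_counts(table: CountTable, path) -> None:
    """Write a count table as CSV (or TSV if the path ends in .tsv)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    # 12 significant digits keeps the read/write round trip bit-exact for
    # decimal inputs at that precision.
    table.data.to_csv(path, sep=sep, index=False, float_format="%.12g")


def from_records(records) -> CountTable:
    """Build a CountTable from an iterable of (animal, group, region, ieg, count)."""
    df = pd.DataFrame(records, columns=list(_REQUIRED_COLUMNS))
    return _coerce_table(df)


def normalize_counts(table: CountTable, method: str = "zscore_per_ieg_region") -> CountTable:
    """Normalize counts so the two IEGs share a common scale.

    ``zscore_per_ieg_region``
        within each (region, IEG) cell, transform counts to sample mean 0 and
        sample SD 1 (ddof=1) over all animals in the table.
    ``cc_ratio``
        divide each count by the caged-control (CC) group mean for its
        (region, IEG) cell, expressing counts relative to baseline expression.
    ``none``
        identity.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    if method == "none":
        return table
    df = table.data.copy()
    if method == "zscore_per_ieg_region":
        for (region, ieg), idx in df.groupby(["region", "ieg"]).groups.items():
            vals = df.loc[idx, "count"]
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise CountTableError(
                    f"zero variance in region {region}, IEG {ieg}: "
                    "z-scoring undefined"
                )
            df.loc[idx, "count"] = (vals - vals.mean()) / sd
    else:  # cc_ratio
        cc = df[df["group"] == "CC"]
        if cc.empty:
            raise CountTableError("cc_ratio normalization requires group CC")
        means = cc.groupby(["region", "ieg"])["count"].mean()
        for (region, ieg), idx in df.groupby(["region", "ieg"]).groups.items():
            if (region, ieg) not in means.index or means[(region, ieg)] == 0:
                raise CountTableError(
                    f"CC mean is zero or missing for region {region}, IEG {ieg}"
                )
            df.loc[idx, "count"] = df.loc[idx, "count"] / means[(region, ieg)]
    return CountTable(df, normalization=method)


@dataclass(frozen=True)
class ObservationMatrix:
    """Rows = observations (animal x IEG), columns = the 12 regions."""

    values: pd.DataFrame          # index: "animal|ieg" ids, columns: REGIONS
    group_label: str = "ALL"
    normalization: str = "none"

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != REGIONS:
            raise ValueError("observation matrix columns must be the canonical regions")
        if self.values.isna().any().any():
            raise ValueError("observation matrix contains missing cells")

    @property
    def n_obs(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def build_observation_matrix(
    table: CountTable,
    groups: set[str] | list[str] | None = None,
    iegs: set[str] | list[str] | None = None,
) -> ObservationMatrix:
    """Pivot a count table into an observation matrix.

    Each (animal, IEG) pair contributes one row; pooled matrices
    (``groups=None`` or all four groups) stack the groups' animals.  A
    missing (animal, region, ieg) cell is a hard error: with seven animals
    per group there is no room for silently dropping rows.
    """
    df = table.data
    if groups is not None:
        gset = {canonical_group(g) for g in groups}
        df = df[df["group"].isin(gset)]
        label = gset.pop() if len(gset) == 1 else "ALL"
    else:
        label = "ALL"
    iegs_used = [canonical_ieg(i) for i in iegs] if iegs is not None else list(IEGS)
    df = df[df["ieg"].isin(iegs_used)]
    if df.empty:
        raise CountTableError("no rows match the requested groups/IEGs")

    wide = df.pivot_table(index=["animal", "ieg"], columns="region",
                          values="count", aggfunc="first")
    for region in REGIONS:
        if region not in wide.columns:
            missing_animal = wide.index[0][0]
            raise CountTableError(
                f"missing cell: animal {missing_animal!r} lacks region {region}"
            )
    wide = wide[list(REGIONS)]
    if wide.isna().any().any():
        animal, ieg = wide.index[wide.isna().any(axis=1)][0]
        region = wide.columns[wide.loc[(animal, ieg)].isna()][0]
        raise CountTableError(
            f"missing cell: (animal {animal!r}, region {region}, ieg {ieg})"
        )
    wide.index = [f"{a}|{i}" for a, i in wide.index]
    wide = wide.sort_index()
    wide.columns.name = None
    return ObservationMatrix(wide, group_label=label,
                             normalization=table.normalization)
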