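"""Behavioural performance metrics for the flavour-place paired-associate task.

In each training trial the animal is cued with one of six flavours and must
dig at the matching sandwell; the number of incorrect sandwells dug before
the correct one (0-5 errors) yields a performance index,
100 - 100 * (errors / 5), so chance performance (2.5 expected errors among
the 5 incorrect wells) corresponds to 50%.  In the 120-s cued-recall probe,
dig time at the six open sandwells is split across four location categories
(original/new x cued/non-cued), with non-cued categories reported as the
average over their member wells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIG_CATEGORIES = ("original_cued", "original_noncued", "new_cued", "new_noncued")

#: Expected single-well share of dig time under indifferent digging (6 wells).
CHANCE_PER_WELL_PCT = 100.0 / 6.0

MAX_ERRORS = 5
TEST_DURATION_S = 120.0


def performance_index(errors: float) -> float:
    """Performance index, 100 - 100 * (errors / 5); 50% at 2.5 errors."""
    errors = float(errors)
    if not 0 <= errors <= MAX_ERRORS:
        raise ValueError(f"errors must be in [0, {MAX_ERRORS}], got {errors}")
    return 100.0 - 100.0 * (errors / MAX_ERRORS)


@dataclass(frozen=True)
class DigRecord:
    """Dig times (s) at the 6 sandwells of one probe test, with categories."""

    animal_id: str
    times: tuple[float, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.times) != 6 or len(self.categories) != 6:
            raise ValueError("a dig record covers exactly 6 sandwells")
        if any(t < 0 for t in self.times):
            raise ValueError("dig times must be non-negative")
        if sum(self.times) > TEST_DURATION_S + 1e-9:
            raise ValueError(f"total dig time exceeds the {TEST_DURATION_S:.0f}-s test")
        bad = [c for c in self.categories if c not in DIG_CATEGORIES]
        if bad:
            raise ValueError(f"unknown sandwell category {bad[0]!r}")


def dig_proportions(record: DigRecord) -> dict[str, float]:
    """Percentage of total dig time per category.

    Cued categories (one well each) report that well's share; non-cued
    categories report the *average* share across their member wells, so a
    cued and a non-cued value are directly comparable per well.
    """
    total = float(sum(record.times))
    if total <= 0:
        raise ValueError("zero total dig time: proportions undefined")
    pct = {}
    for cat in DIG_CATEGORIES:
        wells = [t for t, c in zip(record.times, record.categories) if c == cat]
        if not wells:
            pct[cat] = float("nan")
        elif cat.endswith("_cued"):
            pct[cat] = 100.0 * sum(wells) / total
        else:
            pct[cat] = 100.0 * np.mean(wells) / total
    return pct


def read_trials(path) -> pd.DataFrame:
    """Read a long-format trial table (animal, group, trial, errors)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    required = {"animal", "group", "trial", "errors"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    if ((df["errors"] < 0) | (df["errors"] > MAX_ERRORS)).any():
        bad = df[(df["errors"] < 0) | (df["errors"] > MAX_ERRORS)].iloc[0]
        raise ValueError(f"errors out of range for animal {bad['animal']!r}: {bad['errors']}")
    return df


DEFAULT_TRIAL_BINS = {"T1-4": (1, 2, 3, 4), "T5-6": (5, 6)}


def group_trial_summary(records: pd.DataFrame,
                        trial_bins: dict[str, tuple[int, ...]] | None = None) -> pd.DataFrame:
    """Mean +/- SEM performance index per (group, trial bin).

    ``records`` is a long-format trial table; the default bins split the six
    daily trials into the first four and the last two.
    """
    bins = trial_bins if trial_bins is not None else DEFAULT_TRIAL_BINS
    df = records.copy()
    df["pi"] = [performance_index(e) for e in df["errors"]]
    rows = []
    for group, gdf in df.groupby("group"):
        for bin_name, trials in bins.items():
            sub = gdf[gdf["trial"].isin(trials)]
            if sub.empty:
                raise ValueError(f"no trials for group {group!r} in bin {bin_name!r}")
            # animal-level means first, SEM across animals
            per_animal = sub.groupby("animal")["pi"].mean()
            sem = (per_animal.std(ddof=1) / np.sqrt(len(per_animal))
                   if len(per_animal) > 1 else 0.0)
            rows.append({"group": group, "bin": bin_name,
                         "mean_pi": float(per_animal.mean()),
                         "sem_pi": float(sem), "n_animals": len(per_animal)})
    return pd.DataFrame(rows)
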