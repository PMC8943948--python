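"""Synthetic cohorts with planted group-specific correlation structure.

The original count data are not public, so every pipeline stage is
exercised on simulated cohorts that reproduce the *statistical shape* of
the study: four behavioural groups (OPA, NPA, NM, CC) of seven rats, two
IEG measures per rat, twelve brain regions, and a group-specific target
correlation matrix built from planted region blocks.  Each (animal, IEG)
observation row is drawn from a multivariate normal with the group's target
correlation and scaled to per-(region, IEG) count means/SDs.  Default
structure:

* NPA — one strong 6-region block {DG, CA3, CA1, PrL, ACC, aRC}
  (hippocampal-midline-neocortical coupling during schema-consistent
  encoding);
* OPA — only the pairs DG-CA1, CA3-CA1 and aRC-Ssp correlated;
* CC  — an allocortical block {DG, CA3, CA1, EC} against diffuse background;
* NM  — uniform weak background only.

Count means/SDs are arbitrary placeholders (no per-region moments are
published); all downstream statistics are correlation-based and invariant
to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data_model import GROUPS, IEGS, REGIONS, CountTable, from_records

#: Planted block structure of the default simulation.
NPA_MODULE: frozenset[str] = frozenset({"DG", "CA3", "CA1", "PrL", "ACC", "aRC"})
CC_ALLOCORTICAL_BLOCK: frozenset[str] = frozenset({"DG", "CA3", "CA1", "EC"})
OPA_PAIRS: tuple[tuple[str, str], ...] = (("DG", "CA1"), ("CA3", "CA1"), ("aRC", "Ssp"))

#: Defaults chosen so that at 14 observations planted edges clear r > 0.80
#: with high probability while background pairs do not.
DEFAULT_WITHIN_R = 0.9
DEFAULT_BACKGROUND_R = 0.1

_DEFAULT_MEAN = 100.0
_DEFAULT_SD = 20.0


def nearest_psd_correlation(C: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix with unit diagonal.

    Eigenvalue clipping followed by diagonal renormalization (one Higham-style
    pass); adequate for the mildly indefinite block targets built here.
    """
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    if w.min() >= eps:
        return C
    w = np.clip(w, eps, None)
    C2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(C2))
    C2 = C2 / np.outer(d, d)
    np.fill_diagonal(C2, 1.0)
    return (C2 + C2.T) / 2.0


@dataclass(frozen=True)
class GroupSpec:
    """Target correlation structure and count moments for one group."""

    group: str
    n_animals: int = 7
    modules: tuple[frozenset[str], ...] = ()
    pairs: tuple[tuple[str, str], ...] = ()
    within_r: float = DEFAULT_WITHIN_R
    background_r: float = DEFAULT_BACKGROUND_R
    count_mean: dict = field(default_factory=dict)   # (region, ieg) -> mean
    count_sd: dict = field(default_factory=dict)     # (region, ieg) -> sd
    count_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (-1 < self.within_r < 1) or not (-1 < self.background_r < 1):
            raise ValueError("within_r and background_r must lie in (-1, 1)")
        if self.count_model not in ("gaussian", "poisson_rounded"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        for m in self.modules:
            for r in m:
                if r not in REGIONS:
                    raise ValueError(f"unknown region {r!r} in planted module")
        # building the target also validates it (PSD after projection)
        self.target_correlation()

    def target_correlation(self) -> np.ndarray:
        """The implied 12x12 target correlation matrix (PSD, unit diagonal)."""
        k = len(REGIONS)
        idx = {r: i for i, r in enumerate(REGIONS)}
        C = np.full((k, k), self.background_r)
        for module in self.modules:
            ii = [idx[r] for r in module]
            for a in ii:
                for b in ii:
                    if a != b:
                        C[a, b] = self.within_r
        for a, b in self.pairs:
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = self.within_r
        np.fill_diagonal(C, 1.0)
        C = nearest_psd_correlation(C)
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError(f"target correlation for group {self.group} is not PSD")
        return C

    def moments(self, region: str, ieg: str) -> tuple[float, float]:
        return (float(self.count_mean.get((region, ieg), _DEFAULT_MEAN)),
                float(self.count_sd.get((region, ieg), _DEFAULT_SD)))


@dataclass(frozen=True)
class SimulationConfig:
    """Per-group specs plus the master seed of a simulated cohort."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        codes = [g.group for g in self.groups]
        if len(codes) != len(set(codes)):
            raise ValueError("group codes must be unique")

    def spec_for(self, group: str) -> GroupSpec:
        for g in self.groups:
            if g.group == group:
                return g
        raise KeyError(group)

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "groups": [
                {
                    "group": g.group,
                    "n_animals": g.n_animals,
                    "modules": [sorted(m) for m in g.modules],
                    "pairs": [list(p) for p in g.pairs],
                    "within_r": g.within_r,
                    "background_r": g.background_r,
                    "count_model": g.count_model,
                }
                for g in self.groups
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        groups = tuple(
            GroupSpec(
                group=g["group"],
                n_animals=int(g.get("n_animals", 7)),
                modules=tuple(frozenset(m) for m in g.get("modules", [])),
                pairs=tuple(tuple(p) for p in g.get("pairs", [])),
                within_r=float(g.get("within_r", DEFAULT_WITHIN_R)),
                background_r=float(g.get("background_r", DEFAULT_BACKGROUND_R)),
                count_model=g.get("count_model", "gaussian"),
            )
            for g in payload["groups"]
        )
        return cls(groups=groups, seed=int(payload.get("seed", 0)))


def default_paper_spec(n_animals: int = 7, seed: int = 0,
                       within_r: float = DEFAULT_WITHIN_R,
                       background_r: float = DEFAULT_BACKGROUND_R) -> SimulationConfig:
    """The default study design: 4 groups x ``n_animals`` rats x 12 regions x 2 IEGs."""
    return SimulationConfig(
        groups=(
            GroupSpec("OPA", n_animals=n_animals, pairs=OPA_PAIRS,
                      within_r=within_r, background_r=background_r),
            GroupSpec("NPA", n_animals=n_animals, modules=(NPA_MODULE,),
                      within_r=within_r, background_r=background_r),
            GroupSpec("NM", n_animals=n_animals,
                      within_r=within_r, background_r=background_r),
            GroupSpec("CC", n_animals=n_animals, modules=(CC_ALLOCORTICAL_BLOCK,),
                      within_r=within_r, background_r=background_r),
        ),
        seed=seed,
    )


def planted_partition(spec: GroupSpec) -> dict[str, int]:
    """Region -> module map implied by a group's planted blocks.

    Planted modules get ids 1, 2, ...; all remaining regions share one
    background module.  This is the ground truth used when scoring module
    recovery with AMI.
    """
    assignment: dict[str, int] = {}
    for mid, module in enumerate(spec.modules, start=1):
        for r in module:
            assignment[r] = mid
    bg = len(spec.modules) + 1
    for r in REGIONS:
        assignment.setdefault(r, bg)
    return assignment


def simulate_counts(config: SimulationConfig) -> CountTable:
    """Draw a full cohort count table; fully reproducible from ``config.seed``.

    Each (animal, IEG) row is an independent draw from the group's target
    multivariate normal, scaled to the per-(region, IEG) count moments.
    ``poisson_rounded`` replaces each Gaussian count by a Poisson draw with
    that intensity (floored at 0), preserving rank structure for realism
    checks with integer counts.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for gspec in config.groups:
        C = gspec.target_correlation()
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(REGIONS)))
        for a in range(1, gspec.n_animals + 1):
            animal = f"{gspec.group}{a:02d}"
            for ieg in IEGS:
                z = L @ rng.standard_normal(len(REGIONS))
                for ri, region in enumerate(REGIONS):
                    mu, sd = gspec.moments(region, ieg)
                    val = mu + sd * z[ri]
                    if gspec.count_model == "poisson_rounded":
                        val = float(rng.poisson(max(val, 0.0)))
                    records.append((animal, gspec.group, region, ieg, max(val, 0.0)))
    return from_records(records)


def simulate_behaviour(config: SimulationConfig,
                       target_pi: dict[tuple[str, str], float] | None = None,
                       n_trials: int = 6) -> pd.DataFrame:
    """Simulated trial errors whose performance index matches group targets.

    ``target_pi`` maps (group, bin) to a target performance index in
    [0, 100]; bins are "T1-4" (trials 1-4) and "T5-6" (trials 5-6).  Errors
    are Binomial(5, 1 - pi/100) per trial, so the expected index equals the
    target.  Defaults emulate trained groups at ~70% with caged controls
    untested (CC excluded).
    """
    if target_pi is None:
        target_pi = {}
        for g in ("OPA", "NPA", "NM"):
            target_pi[(g, "T1-4")] = 70.0
            target_pi[(g, "T5-6")] = 70.0
    for (g, b), pi in target_pi.items():
        if not 0 <= pi <= 100:
            raise ValueError(f"target performance index out of range for {(g, b)}: {pi}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBEE]))
    rows = []
    groups_present = {g for g, _b in target_pi}
    for gspec in config.groups:
        if gspec.group not in groups_present:
            continue
        for a in range(1, gspec.n_animals + 1):
            animal = f"{gspec.group}{a:02d}"
            for trial in range(1, n_trials + 1):
                bin_name = "T1-4" if trial <= 4 else "T5-6"
                pi = target_pi.get((gspec.group, bin_name))
                if pi is None:
                    continue
                errors = int(rng.binomial(5, 1.0 - pi / 100.0))
                rows.append({"animal": animal, "group": gspec.group,
                             "trial": trial, "errors": errors})
    return pd.DataFrame(rows)
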