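"""Between-group comparison of correlation structure.

Two correlation coefficients r1, r2 estimated from independent samples of
sizes n1, n2 are compared on the variance-stabilized Fisher scale,

    z = (1/2) ln((1 + r) / (1 - r)),
    D = (z1 - z2) / sqrt(1/(n1 - 3) + 1/(n2 - 3)),

with D treated as a standard normal variate for a two-tailed p-value.
Module-level connectivity strength is compared by a paired t-test across the
within-module region pairs (15 pairs for a 6-region module), with Bonferroni
correction over the number of group comparisons performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import CorrelationMatrix


def fisher_z(r: float) -> float:
    """Fisher z-transformation, z = arctanh(r).  Requires |r| < 1."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    return float(np.arctanh(r))


@dataclass(frozen=True)
class FisherComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z1: float
    z2: float
    D: float
    p: float


def fisher_d(r1: float, n1: int, r2: float, n2: int) -> FisherComparison:
    """Normalized difference D between two correlations and its normal p."""
    n1, n2 = int(n1), int(n2)
    if n1 <= 3 or n2 <= 3:
        raise ValueError(f"both sample sizes must exceed 3, got {n1}, {n2}")
    z1 = fisher_z(r1)
    z2 = fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    D = (z1 - z2) / se
    p = float(2.0 * stats.norm.sf(abs(D)))
    return FisherComparison(r1=float(r1), r2=float(r2), n1=n1, n2=n2,
                            z1=z1, z2=z2, D=float(D), p=min(p, 1.0))


def zdiff_matrix(C1: CorrelationMatrix, C2: CorrelationMatrix,
                 regions=None) -> pd.DataFrame:
    """Pairwise Fisher comparison of two groups' correlation matrices.

    Returns a square DataFrame over ``regions`` with the z-difference D in
    the upper triangle and the two-tailed p-value in the lower triangle
    (diagonal NaN) — the mixed-triangle layout conventional for these
    tables.  Use :func:`zdiff_long` for a tidy format.
    """
    if regions is None:
        regions = C1.labels
    regions = list(regions)
    for r in regions:
        if r not in C1.labels or r not in C2.labels:
            raise ValueError(f"region {r!r} missing from a correlation matrix")
    out = pd.DataFrame(np.nan, index=regions, columns=regions)
    for a, b in combinations(regions, 2):
        cmp_ = fisher_d(C1.r(a, b), C1.n_obs, C2.r(a, b), C2.n_obs)
        ia, ib = regions.index(a), regions.index(b)
        out.iat[ia, ib] = cmp_.D
        out.iat[ib, ia] = cmp_.p
    return out


def zdiff_long(C1: CorrelationMatrix, C2: CorrelationMatrix,
               regions=None) -> pd.DataFrame:
    """Tidy long-format Fisher comparison: one row per unordered region pair."""
    if regions is None:
        regions = C1.labels
    rows = []
    for a, b in combinations(list(regions), 2):
        cmp_ = fisher_d(C1.r(a, b), C1.n_obs, C2.r(a, b), C2.n_obs)
        rows.append({"region_a": a, "region_b": b, "r1": cmp_.r1, "r2": cmp_.r2,
                     "z_diff": cmp_.D, "p": cmp_.p})
    return pd.DataFrame(rows)


def module_mean_r(C: CorrelationMatrix, module) -> float:
    """Mean correlation over all unordered within-module region pairs."""
    module = sorted(module)
    if len(module) < 2:
        raise ValueError("module must contain at least 2 regions")
    for r in module:
        if r not in C.labels:
            raise ValueError(f"region {r!r} not in correlation matrix")
    vals = [C.r(a, b) for a, b in combinations(module, 2)]
    return float(np.mean(vals))


@dataclass(frozen=True)
class ModuleStrengthResult:
    module: frozenset
    reference: str
    mean_r: dict[str, float]              # per-group mean within-module r
    comparisons: pd.DataFrame             # group, t, df, p_raw, p_bonferroni


def compare_module_strength(matrices: dict[str, CorrelationMatrix], module,
                            reference: str, use_fisher_z: bool = False) -> ModuleStrengthResult:
    """Paired t-tests of within-module connectivity: reference vs each group.

    The pairing unit is the unordered region pair: each of the module's
    pairs contributes one correlation per group, and the reference group's
    values are compared with each other group's across those pairs.
    Bonferroni correction multiplies each raw p by the number of group
    comparisons.  ``use_fisher_z`` runs the t-test on arctanh(r) instead of
    raw r (r is bounded; the transform removes the ceiling).
    """
    module = sorted(module)
    if len(list(combinations(module, 2))) < 2:
        raise ValueError("module must yield at least 2 region pairs")
    if reference not in matrices:
        raise ValueError(f"reference group {reference!r} not among matrices")
    pairs = list(combinations(module, 2))

    def pair_values(C: CorrelationMatrix) -> np.ndarray:
        vals = np.array([C.r(a, b) for a, b in pairs])
        return np.arctanh(np.clip(vals, -1 + 1e-15, 1 - 1e-15)) if use_fisher_z else vals

    ref_vals = pair_values(matrices[reference])
    others = [g for g in matrices if g != reference]
    n_comparisons = len(others)
    rows = []
    for g in others:
        vals = pair_values(matrices[g])
        diff = ref_vals - vals
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(ref_vals, vals)
        rows.append({"group": g, "t": float(t), "df": len(pairs) - 1,
                     "p_raw": float(p),
                     "p_bonferroni": float(min(1.0, p * n_comparisons))})
    mean_r = {g: module_mean_r(matrices[g], module) for g in matrices}
    return ModuleStrengthResult(
        module=frozenset(module), reference=reference, mean_r=mean_r,
        comparisons=pd.DataFrame(rows),
    )
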