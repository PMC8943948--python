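"""Louvain module detection on correlation matrices with gamma-stability selection.

Modules (communities) are detected directly on the full, unthresholded
correlation matrix by Louvain modularity maximization.  Modularity carries a
resolution parameter gamma multiplying the null term: small gamma yields few
large modules, large gamma many small ones.  Because correlations can be
negative, two weight-handling schemes are provided:

``positive_only``
    negative weights are zeroed and standard Newman-Girvan modularity is
    maximized on the positive part.

``negative_asym`` (default)
    the signed, asymmetrically weighted modularity of Rubinov & Sporns'
    convention: positive and negative parts each get their own null model,
    and the negative contribution is down-weighted by its share of the total
    weight,  Q = Q+ - ( v- / (v+ + v-) ) Q-.

The resolution is chosen by a stability sweep: for each gamma on a grid,
Louvain is run many times with different seeds (seeds shuffle the node
visitation order) and the mean pairwise adjusted mutual information (AMI)
between runs is recorded; the selected gamma is the largest one at which all
runs agree perfectly (mean AMI = 1 within tolerance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

SCHEMES = ("negative_asym", "positive_only")


class GammaSelectionError(RuntimeError):
    """No gamma on the grid achieved perfect between-run agreement."""

    def __init__(self, message: str, best_gamma: float, best_ami: float):
        super().__init__(message)
        self.best_gamma = best_gamma
        self.best_ami = best_ami


@dataclass(frozen=True)
class Partition:
    """Assignment of each region to a module (ids contiguous from 1)."""

    assignment: dict[str, int]
    quality: float
    gamma: float
    scheme: str
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("module ids must be contiguous integers from 1")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, regions) -> np.ndarray:
        return np.array([self.assignment[r] for r in regions])

    def modules(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for region, mid in self.assignment.items():
            out.setdefault(mid, set()).add(region)
        return {k: frozenset(v) for k, v in out.items()}

    def to_json(self, path) -> None:
        payload = {
            "assignment": self.assignment,
            "modularity": self.quality,
            "gamma": self.gamma,
            "scheme": self.scheme,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"region": list(self.assignment), "module": list(self.assignment.values())}
        ).to_csv(path, index=False)


def partition_from_labels(regions, labels, quality=float("nan"),
                          gamma=1.0, scheme="negative_asym", seed=None) -> Partition:
    """Build a Partition from parallel region/label sequences, renumbering
    modules contiguously from 1 in order of first appearance."""
    remap: dict[int, int] = {}
    assignment = {}
    for r, lab in zip(regions, labels):
        lab = int(lab)
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignment[str(r)] = remap[lab]
    return Partition(assignment=assignment, quality=quality, gamma=gamma,
                     scheme=scheme, seed=seed)


def _split_signed(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Wp = np.where(W > 0, W, 0.0)
    Wm = np.where(W < 0, -W, 0.0)
    return Wp, Wm


def _check_adjacency(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    W = (W + W.T) / 2.0
    W = W.copy()
    np.fill_diagonal(W, 0.0)  # self-correlations carry no information
    return W


def _part_quality(Wpart: np.ndarray, labels: np.ndarray, gamma: float) -> tuple[float, float]:
    """(unnormalized quality sum, total weight v) for one sign part."""
    v = Wpart.sum()
    if v <= 0:
        return 0.0, 0.0
    s = Wpart.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    q = (Wpart[same].sum() - gamma * (np.outer(s, s)[same]).sum() / v)
    return q, v


def modularity(W, partition, gamma: float = 1.0,
               scheme: str = "negative_asym", regions=None) -> float:
    """Modularity of a partition of a (possibly signed) weighted network.

    ``partition`` is either a 1-d array of integer labels aligned with W's
    rows, or a Partition — in which case ``regions`` gives the node order of
    W's rows (defaults to the Partition's own insertion order).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    W = _check_adjacency(W)
    if isinstance(partition, Partition):
        if regions is None:
            regions = list(partition.assignment)
        labels = partition.labels_for(regions)
        if labels.size != W.shape[0]:
            raise ValueError("partition size does not match adjacency")
    else:
        labels = np.asarray(partition)
        if labels.shape != (W.shape[0],):
            raise ValueError("label array must have one entry per node")
    Wp, Wm = _split_signed(W)
    qp, vp = _part_quality(Wp, labels, gamma)
    qm, vm = _part_quality(Wm, labels, gamma)
    q = 0.0
    if vp > 0:
        q += qp / vp
    if scheme == "negative_asym" and vm > 0:
        q -= (vm / (vp + vm)) * (qm / vm)
    return float(q)


@njit(cache=True)
def _louvain_kernel(Wp, Wm, vp, vm, gamma, seed):   # pragma: no cover
    """Two-phase Louvain on a signed split (Wp, Wm) of a weight matrix.

    Matrix convention: strength = plain row sum (self-loops counted once),
    v = full matrix sum; both are exactly preserved under aggregation.  Node
    visitation order is reshuffled every pass with a seeded xorshift64 PRNG,
    which is the only source of randomness.  Returns original-node labels.
    """
    n = Wp.shape[0]
    node_of = np.arange(n)
    vtot = vp + vm
    state = np.uint64(seed) * np.uint64(6364136223846793005) \
        + np.uint64(1442695040888963407)
    while True:
        m = Wp.shape[0]
        labels = np.arange(m)
        sp = np.zeros(m)
        sm = np.zeros(m)
        for i in range(m):
            for j in range(m):
                sp[i] += Wp[i, j]
                sm[i] += Wm[i, j]
        cs_p = sp.copy()                 # per-community strengths (singletons)
        cs_m = sm.copy()
        order = np.arange(m)
        w_ip = np.zeros(m)
        w_im = np.zeros(m)
        score = np.zeros(m)
        improved = False
        moved = True
        while moved:
            moved = False
            for i in range(m - 1, 0, -1):   # Fisher-Yates with xorshift64
                state ^= state << np.uint64(13)
                state ^= state >> np.uint64(7)
                state ^= state << np.uint64(17)
                j = int(state % np.uint64(i + 1))
                tmp = order[i]
                order[i] = order[j]
                order[j] = tmp
            for oi in range(m):
                i = order[oi]
                ci = labels[i]
                cs_p[ci] -= sp[i]
                cs_m[ci] -= sm[i]
                for c in range(m):
                    w_ip[c] = 0.0
                    w_im[c] = 0.0
                for j in range(m):
                    w_ip[labels[j]] += Wp[i, j]
                    w_im[labels[j]] += Wm[i, j]
                # a super-node's self-loop travels with it: constant across
                # candidate communities, so exclude it from the score
                w_ip[ci] -= Wp[i, i]
                w_im[ci] -= Wm[i, i]
                for c in range(m):
                    s = 0.0
                    if vp > 0:
                        s += (w_ip[c] - gamma * sp[i] * cs_p[c] / vp) / vp
                    if vm > 0:
                        s -= (w_im[c] - gamma * sm[i] * cs_m[c] / vm) / vtot
                    score[c] = s
                best = 0
                for c in range(1, m):
                    if score[c] > score[best]:
                        best = c
                if score[best] > score[ci] + 1e-12 and best != ci:
                    labels[i] = best
                    moved = True
                    improved = True
                cs_p[labels[i]] += sp[i]
                cs_m[labels[i]] += sm[i]
        if not improved:
            break
        # aggregate communities into super-nodes (self-loops keep internal
        # weight); relabel contiguously in order of first appearance
        remap = np.full(m, -1)
        k = 0
        for i in range(m):
            if remap[labels[i]] < 0:
                remap[labels[i]] = k
                k += 1
        newWp = np.zeros((k, k))
        newWm = np.zeros((k, k))
        for i in range(m):
            ri = remap[labels[i]]
            for j in range(m):
                newWp[ri, remap[labels[j]]] += Wp[i, j]
                newWm[ri, remap[labels[j]]] += Wm[i, j]
        for i in range(n):
            node_of[i] = remap[labels[node_of[i]]]
        if k == m:
            break
        Wp = newWp
        Wm = newWm
    return node_of


def _signed_parts(W0: np.ndarray, scheme: str):
    Wp, Wm = _split_signed(W0)
    if scheme == "positive_only":
        Wm = np.zeros_like(Wm)
    return Wp, Wm, Wp.sum(), Wm.sum()


def louvain(W, regions=None, gamma: float = 1.0, seed: int = 0,
            scheme: str = "negative_asym") -> Partition:
    """Two-phase Louvain heuristic with seeded node visitation order.

    ``W`` is the correlation (or any symmetric weight) matrix; its diagonal
    is zeroed.  The returned Partition's quality equals
    ``modularity(W, partition, gamma, scheme)`` recomputed independently.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    W0 = _check_adjacency(W)
    n = W0.shape[0]
    if regions is None:
        regions = [str(i) for i in range(n)]
    regions = list(regions)
    if len(regions) != n:
        raise ValueError("regions length must match adjacency size")
    Wp, Wm, vp, vm = _signed_parts(W0, scheme)
    node_of = _louvain_kernel(Wp, Wm, vp, vm, float(gamma), int(seed) & 0x7FFFFFFF)
    q = modularity(W, node_of, gamma=gamma, scheme=scheme)
    return partition_from_labels(regions, node_of, quality=q, gamma=gamma,
                                 scheme=scheme, seed=seed)


# ---------------------------------------------------------------------------
# Adjusted mutual information


def _contingency(l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
    u1, i1 = np.unique(l1, return_inverse=True)
    u2, i2 = np.unique(l2, return_inverse=True)
    c = np.zeros((u1.size, u2.size), dtype=int)
    np.add.at(c, (i1, i2), 1)
    return c


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def expected_mutual_information(a: np.ndarray, b: np.ndarray, n: int) -> float:
    """Exact E[MI] under the permutation (hypergeometric) null model.

    ``a`` and ``b`` are the marginal cluster sizes of the two partitions.
    """
    lg = gammaln
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                log_term = (lg(ai + 1) + lg(bj + 1) + lg(n - ai + 1) + lg(n - bj + 1)
                            - lg(n + 1) - lg(nij + 1) - lg(ai - nij + 1)
                            - lg(bj - nij + 1) - lg(n - ai - bj + nij + 1))
                emi += (nij / n) * np.log(n * nij / (ai * bj)) * np.exp(log_term)
    return float(emi)


def ami(p1, p2, regions=None) -> float:
    """Adjusted mutual information between two partitions.

    AMI = (MI - E[MI]) / (mean(H1, H2) - E[MI]) with the exact
    permutation-model expectation; 1 for identical partitions up to
    relabeling, ~0 for independent ones.
    """
    if isinstance(p1, Partition) and isinstance(p2, Partition):
        if set(p1.assignment) != set(p2.assignment):
            raise ValueError("partitions are over different label sets")
        keys = sorted(p1.assignment)
        l1 = np.array([p1.assignment[k] for k in keys])
        l2 = np.array([p2.assignment[k] for k in keys])
    else:
        l1 = np.asarray(p1)
        l2 = np.asarray(p2)
        if l1.shape != l2.shape:
            raise ValueError("label arrays must have equal length")
    n = l1.size
    c = _contingency(l1, l2)
    a = c.sum(axis=1)
    b = c.sum(axis=0)
    # degenerate partitions: both trivial -> identical by convention
    if (a.size == b.size == 1) or (a.size == n and b.size == n):
        return 1.0
    # identical up to relabeling: contingency is a (scaled) permutation matrix
    if a.size == b.size and int((c > 0).sum()) == a.size:
        return 1.0
    nz = c > 0
    mi = float((c[nz] / n * (np.log(c[nz] * n) -
                             np.log(np.outer(a, b)[nz]))).sum())
    emi = expected_mutual_information(a, b, n)
    h1 = _entropy(a, n)
    h2 = _entropy(b, n)
    denom = 0.5 * (h1 + h2) - emi
    if abs(denom) < np.finfo(float).eps:
        denom = np.copysign(np.finfo(float).eps, denom if denom != 0 else 1.0)
    return float((mi - emi) / denom)


# ---------------------------------------------------------------------------
# Gamma stability sweep


@dataclass(frozen=True)
class GammaStabilityProfile:
    """Mean pairwise AMI between repeated Louvain runs, per gamma.

    ``modal_partitions`` holds, per gamma, the most frequent partition across
    runs as a canonical label tuple aligned with ``region_order`` (regions in
    sorted order); at perfectly stable gammas it is the unique partition.
    """

    gammas: np.ndarray
    mean_ami: np.ndarray
    runs: int
    seeds: list[int] = field(default_factory=list)
    modal_partitions: list[tuple[int, ...]] = field(default_factory=list)
    region_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.gammas) <= 0):
            raise ValueError("gamma grid must be strictly increasing")
        if np.any(self.mean_ami > 1 + 1e-12):
            raise ValueError("mean AMI cannot exceed 1")

    def to_csv(self, path) -> None:
        pd.DataFrame({"gamma": self.gammas, "mean_AMI": self.mean_ami}).to_csv(
            path, index=False, float_format="%.12g")


def _canonical_labels(labels: np.ndarray) -> tuple[int, ...]:
    remap: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
        out.append(remap[lab])
    return tuple(out)


def mean_pairwise_ami(label_runs: list[np.ndarray]) -> float:
    """Mean AMI over all unordered pairs of runs.

    Runs yielding identical partitions (up to relabeling) are deduplicated
    first; AMI between equal canonical partitions is exactly 1.
    """
    counts: dict[tuple[int, ...], int] = {}
    for labels in label_runs:
        key = _canonical_labels(np.asarray(labels))
        counts[key] = counts.get(key, 0) + 1
    return _mean_pairwise_ami_counts(counts)


def _mean_pairwise_ami_counts(counts: dict[tuple[int, ...], int]) -> float:
    distinct = list(counts)
    total_pairs = 0
    acc = 0.0
    for i, ki in enumerate(distinct):
        ci = counts[ki]
        acc += 1.0 * (ci * (ci - 1) // 2)
        total_pairs += ci * (ci - 1) // 2
        for kj in distinct[i + 1:]:
            cj = counts[kj]
            acc += ami(np.array(ki), np.array(kj)) * ci * cj
            total_pairs += ci * cj
    if total_pairs == 0:
        raise ValueError("need at least 2 runs")
    return acc / total_pairs


def gamma_sweep(W, regions=None, gamma_min: float = 0.1, gamma_max: float = 2.0,
                step: float = 0.01, runs: int = 100, base_seed: int = 0,
                scheme: str = "negative_asym") -> GammaStabilityProfile:
    """Stability of Louvain module detection across a gamma grid.

    For each gamma, Louvain is run with seeds base_seed+1 .. base_seed+runs
    and the mean AMI over all runs*(runs-1)/2 unordered pairs is recorded.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if runs < 2:
        raise ValueError("need at least 2 runs per gamma")
    W0 = _check_adjacency(W)
    n = W0.shape[0]
    if regions is None:
        regions = [str(i) for i in range(n)]
    ngrid = int(round((gamma_max - gamma_min) / step)) + 1
    gammas = np.round(gamma_min + step * np.arange(ngrid), 10)
    seeds = [base_seed + k for k in range(1, runs + 1)]
    regions = list(regions)
    # reorder once so stored partitions are aligned with sorted region labels
    perm = sorted(range(n), key=lambda i: regions[i])
    order = [regions[i] for i in perm]
    Wp, Wm, vp, vm = _signed_parts(W0, scheme)
    mean_amis = np.empty(ngrid)
    modal: list[tuple[int, ...]] = []
    for gi, gamma in enumerate(gammas):
        counts: dict[tuple[int, ...], int] = {}
        for s in seeds:
            node_of = _louvain_kernel(Wp, Wm, vp, vm, float(gamma),
                                      int(s) & 0x7FFFFFFF)
            key = _canonical_labels(node_of[perm])
            counts[key] = counts.get(key, 0) + 1
        mean_amis[gi] = min(_mean_pairwise_ami_counts(counts), 1.0)
        modal.append(max(counts, key=counts.get))
    return GammaStabilityProfile(gammas=gammas, mean_ami=mean_amis,
                                 runs=runs, seeds=seeds,
                                 modal_partitions=modal, region_order=order)


def select_gamma(profile: GammaStabilityProfile, tol: float = 1e-9) -> float:
    """Largest gamma whose mean pairwise AMI is 1 within tolerance."""
    ok = profile.mean_ami >= 1.0 - tol
    if not ok.any():
        best = int(np.argmax(profile.mean_ami))
        raise GammaSelectionError(
            "no gamma reached perfect between-run similarity; "
            f"best mean AMI {profile.mean_ami[best]:.4f} at gamma "
            f"{profile.gammas[best]:.2f} — consider more runs",
            best_gamma=float(profile.gammas[best]),
            best_ami=float(profile.mean_ami[best]),
        )
    return float(profile.gammas[np.nonzero(ok)[0][-1]])


@dataclass(frozen=True)
class PlateauSelection:
    """A stable resolution plateau and its representative gamma."""

    gamma: float                 # plateau midpoint (on the grid)
    gamma_lo: float
    gamma_hi: float
    assignment: dict[str, int]   # the plateau's (unique) partition
    n_modules: int
    width: float


def select_stable_plateau(profile: GammaStabilityProfile, tol: float = 1e-9,
                          allow_trivial: bool = False,
                          min_module_size: int = 2) -> PlateauSelection:
    """Pick the widest perfectly-stable resolution plateau.

    A plateau is a maximal contiguous run of gammas at which (a) all Louvain
    runs agree (mean AMI = 1 within ``tol``) and (b) the agreed partition is
    the same at every gamma of the run.  Because the partition is constant
    across a plateau, any gamma inside it yields the same modules; the
    midpoint is returned as the representative, being the most robust choice
    when the resolution is reused on a replicate dataset.

    Two kinds of degenerate plateau are deprioritised: single-module
    partitions (the "no structure" answer), and — unless ``min_module_size``
    is lowered — partitions containing modules smaller than
    ``min_module_size``: a "module" of one region carries no co-activation
    information, and such fragmented partitions become trivially stable at
    high resolution.  Deprioritised plateaus are only eligible when nothing
    else is stable (or ``allow_trivial`` is set).  Ties in width go to the
    higher-resolution plateau.

    Rationale: on matrices with sharply separated blocks, very high
    resolutions lock into perfectly *stable* fragmented partitions, so
    "the largest stable gamma" (:func:`select_gamma`) degenerates; plateau
    width measures how robust a partition is to the resolution choice, which
    is what the stability sweep is after.
    """
    if not profile.modal_partitions:
        raise ValueError("profile lacks per-gamma partitions; rerun gamma_sweep")
    ok = profile.mean_ami >= 1.0 - tol
    plateaus: list[PlateauSelection] = []
    i = 0
    ngrid = len(profile.gammas)
    while i < ngrid:
        if not ok[i]:
            i += 1
            continue
        j = i
        while (j + 1 < ngrid and ok[j + 1]
               and profile.modal_partitions[j + 1] == profile.modal_partitions[i]):
            j += 1
        labels = profile.modal_partitions[i]
        assignment = {r: lab + 1 for r, lab in zip(profile.region_order, labels)}
        plateaus.append(PlateauSelection(
            gamma=float(profile.gammas[(i + j) // 2]),
            gamma_lo=float(profile.gammas[i]),
            gamma_hi=float(profile.gammas[j]),
            assignment=assignment,
            n_modules=len(set(labels)),
            width=float(profile.gammas[j] - profile.gammas[i]),
        ))
        i = j + 1
    if not plateaus:
        best = int(np.argmax(profile.mean_ami))
        raise GammaSelectionError(
            "no perfectly stable gamma found",
            best_gamma=float(profile.gammas[best]),
            best_ami=float(profile.mean_ami[best]),
        )
    def well_formed(p: PlateauSelection) -> bool:
        sizes = [sum(1 for v in p.assignment.values() if v == mid)
                 for mid in set(p.assignment.values())]
        return p.n_modules > 1 and min(sizes) >= min_module_size

    candidates = plateaus if allow_trivial else (
        [p for p in plateaus if well_formed(p)] or plateaus)
    return max(candidates, key=lambda p: (p.width, p.gamma))
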