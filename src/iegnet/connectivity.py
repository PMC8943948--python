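"""Inter-regional Pearson correlation matrices and r-thresholded networks.

Functional connectivity between brain regions is estimated as the Pearson
correlation, across observations (animal x IEG rows), of normalized IEG
product counts.  Networks are built by keeping only the strongest
correlations (r strictly above a threshold); at n = 14 observations the
conventional thresholds r > 0.80, 0.87 and 0.92 correspond to two-tailed
significance levels of about p < 0.001, 0.0001 and 0.00001 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ObservationMatrix

#: Default correlation thresholds for network construction.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.80, 0.87, 0.92)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over labelled regions."""

    values: pd.DataFrame
    n_obs: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlation values must lie in [-1, 1]")

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def r(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def to_csv(self, path) -> None:
        self.values.to_csv(path, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, n_obs: int) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df, n_obs=n_obs)


def pearson_matrix(obs: ObservationMatrix) -> CorrelationMatrix:
    """Product-moment correlation between all region pairs.

    Requires at least 3 observations and nonzero variance in every column.
    """
    x = obs.to_numpy()
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 observations, got {n}")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        region = obs.values.columns[int(np.argmax(sd == 0))]
        raise ValueError(f"zero variance in region {region}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    df = pd.DataFrame(r, index=obs.values.columns, columns=obs.values.columns)
    return CorrelationMatrix(df, n_obs=n)


def correlation_pvalue(r: float, n: int, bonferroni_pairs: int | None = None) -> float:
    """Two-tailed p-value of a Pearson correlation via the t-transformation.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom.
    ``bonferroni_pairs`` optionally multiplies p by the number of region
    pairs tested (66 for 12 regions); off by default, mirroring common
    practice for exploratory connectivity matrices.
    """
    n = int(n)
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    r = float(r)
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    if bonferroni_pairs is not None:
        p = min(1.0, p * bonferroni_pairs)
    return float(min(p, 1.0))


def threshold_alpha_map(thresholds=DEFAULT_THRESHOLDS, n: int = 14) -> dict[float, float]:
    """Nominal significance level attained by each r threshold at sample size n.

    Reported for context only; network construction thresholds on r itself.
    The default n = 14 corresponds to 7 animals x 2 IEG observations per group.
    """
    return {float(t): correlation_pvalue(t, n) for t in thresholds}


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Undirected network of regions whose correlation exceeds r_min (strict)."""

    graph: nx.Graph
    r_min: float
    alpha: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("region_a\tregion_b\tr\n")
            for a, b, w in sorted(self.edges):
                fh.write(f"{a}\t{b}\t{w:.12g}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def threshold_network(C: CorrelationMatrix, r_min: float,
                      n_for_alpha: int | None = None) -> ThresholdedNetwork:
    """Keep edges with r strictly greater than ``r_min``; isolated nodes stay."""
    r_min = float(r_min)
    if not (-1.0 <= r_min <= 1.0):
        raise ValueError(f"r_min must be in [-1, 1], got {r_min}")
    g = nx.Graph()
    labels = C.labels
    g.add_nodes_from(labels)
    v = C.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if v[i, j] > r_min:
                g.add_edge(labels[i], labels[j], weight=float(v[i, j]))
    n_alpha = n_for_alpha if n_for_alpha is not None else C.n_obs
    alpha = correlation_pvalue(r_min, n_alpha) if n_alpha >= 4 else float("nan")
    return ThresholdedNetwork(graph=g, r_min=r_min, alpha=alpha)
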