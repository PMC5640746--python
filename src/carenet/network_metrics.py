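"""Network-level exposure metrics for directed service networks.

The structural exposures fall into three families:

* differentiation — network size, composition over the nine service types,
  and the index of dissimilarity (half the L1 distance between a network's
  composition and the study-average composition);
* integration — density, Freeman in-degree centralization, clustering on
  the undirected projection, and reciprocity;
* weak ties / heterophily — the Coleman homophily index per service type,
  which contrasts the observed share of within-type out-ties with its
  random-mixing expectation (+1 all within type, 0 random mixing, -1 none
  within type).

All metrics are returned as fractions in their natural ranges; any
percentage scaling happens only when tables are rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from carenet.network_build import DirectedNetwork
from carenet.survey_io import SERVICE_TYPES

__all__ = [
    "UndefinedMetricError",
    "NetworkMetrics",
    "MetricCorrelationMatrix",
    "density",
    "mean_in_degree_normalized",
    "degree_centralization",
    "clustering",
    "reciprocity",
    "composition",
    "dissimilarity_index",
    "coleman_index",
    "network_metrics",
    "mean_composition",
    "metrics_table",
    "correlation_matrix",
    "METRIC_ORDER",
]


class UndefinedMetricError(ValueError):
    """A metric was requested on a network too small (or too empty) to define it."""


@dataclass
class NetworkMetrics:
    """The full structural-exposure row for one network.

    ``coleman`` maps each service type to its homophily index, with ``None``
    when the index is undefined for that type in that network (no member
    with an out-tie, or the type spans the whole network).
    """

    network_id: str
    n_services: int
    composition: dict[str, float]
    dissimilarity_index: float
    mean_in_degree_normalized: float
    degree_centralization: float
    density: float
    clustering: float
    reciprocity: float
    coleman: dict[str, Optional[float]]

    def as_row(self) -> dict[str, float]:
        """Flatten to one tidy row keyed by metric name."""
        row: dict[str, float] = {
            "network_id": self.network_id,
            "n_services": self.n_services,
            "dissimilarity_index": self.dissimilarity_index,
            "mean_in_degree_normalized": self.mean_in_degree_normalized,
            "degree_centralization": self.degree_centralization,
            "density": self.density,
            "clustering": self.clustering,
            "reciprocity": self.reciprocity,
        }
        for t in SERVICE_TYPES:
            row[f"prop_{t}"] = self.composition.get(t, 0.0)
        for t in SERVICE_TYPES:
            v = self.coleman.get(t)
            row[f"coleman_{t}"] = math.nan if v is None else v
        return row


#: Column order for rendered metric tables.
METRIC_ORDER: tuple[str, ...] = (
    ("n_services",)
    + tuple(f"prop_{t}" for t in SERVICE_TYPES)
    + (
        "dissimilarity_index",
        "mean_in_degree_normalized",
        "degree_centralization",
        "density",
        "clustering",
        "reciprocity",
    )
    + tuple(f"coleman_{t}" for t in SERVICE_TYPES)
)


def density(network: DirectedNetwork) -> float:
    """Directed tie density: reported ties over possible ordered pairs, E/(n(n-1))."""
    n = network.n_nodes
    if n < 2:
        raise UndefinedMetricError(f"density undefined for n={n} (< 2 services)")
    return network.n_edges / (n * (n - 1))


def mean_in_degree_normalized(network: DirectedNetwork) -> float:
    """Mean in-degree divided by its maximum n-1.

    Numerically this equals density (mean in-degree is E/n); it is kept as
    a separate named exposure because the two are reported side by side in
    descriptive tables.
    """
    n = network.n_nodes
    if n < 2:
        raise UndefinedMetricError(f"mean in-degree undefined for n={n} (< 2 services)")
    indeg = _in_degrees(network)
    return float(np.mean(indeg)) / (n - 1)


def _in_degrees(network: DirectedNetwork) -> np.ndarray:
    counts = {sid: 0 for sid in network.node_ids}
    for _, dst in network.edges:
        counts[dst] += 1
    return np.array([counts[sid] for sid in network.node_ids], dtype=float)


def degree_centralization(network: DirectedNetwork, degree: str = "in") -> float:
    """Freeman degree centralization.

    Sum of deviations of node degrees from the maximum degree, normalized
    by its directed-network maximum (n-1)^2, attained by an inward star.
    Returns 0 when every service has the same number of ties and 1 when a
    single service is the only one connected with all others.

    ``degree`` selects ``"in"`` (default: ties received, the resource-flow
    reading of referral networks), ``"out"`` or ``"total"``; for ``"total"``
    the normalization maximum doubles.
    """
    n = network.n_nodes
    if n < 3:
        raise UndefinedMetricError(f"degree centralization undefined for n={n} (< 3 services)")
    if degree == "in":
        degs = _in_degrees(network)
        denom = (n - 1) ** 2
    elif degree == "out":
        counts = {sid: 0 for sid in network.node_ids}
        for src, _ in network.edges:
            counts[src] += 1
        degs = np.array([counts[sid] for sid in network.node_ids], dtype=float)
        denom = (n - 1) ** 2
    elif degree == "total":
        g = network.to_networkx().to_undirected()
        degs = np.array([g.degree(sid) for sid in network.node_ids], dtype=float)
        denom = (n - 1) * (n - 2)
    else:
        raise ValueError(f"unknown degree kind {degree!r}")
    return float(np.sum(degs.max() - degs)) / denom


def clustering(network: DirectedNetwork) -> float:
    """Network-level clustering coefficient on the undirected projection.

    The local coefficient of a service is the density of ties among its
    neighbors (an edge i-j exists when i->j or j->i); services with fewer
    than two neighbors contribute 0, and the network value is the mean over
    all services.  1 when every neighbor pair is itself connected (complete
    network), 0 when no neighbors of any service are connected (star).
    """
    n = network.n_nodes
    if n < 3:
        raise UndefinedMetricError(f"clustering undefined for n={n} (< 3 services)")
    g = network.to_networkx().to_undirected()
    return float(nx.average_clustering(g))


def reciprocity(network: DirectedNetwork) -> float:
    """Proportion of directed ties whose reverse tie also exists."""
    if network.n_edges == 0:
        raise UndefinedMetricError("reciprocity undefined on a network with no ties")
    mutual = sum(1 for (a, b) in network.edges if (b, a) in network.edges)
    return mutual / network.n_edges


def composition(network: DirectedNetwork) -> dict[str, float]:
    """Fraction of services per type; fractions sum to 1."""
    if network.n_nodes < 1:
        raise UndefinedMetricError("composition undefined on an empty network")
    counts = {t: 0 for t in SERVICE_TYPES}
    for node in network.nodes:
        counts[node.service_type] += 1
    n = network.n_nodes
    return {t: c / n for t, c in counts.items()}


def dissimilarity_index(
    comp: Mapping[str, float], reference: Mapping[str, float], tol: float = 1e-6
) -> float:
    """Index of dissimilarity: half the L1 distance between two compositions.

    Measures the departure of a network's service-type mix from a reference
    (by default the study-average) distribution: 0 when the mix equals the
    reference, 0.5 when one type carries a 50-percentage-point excess.
    """
    keys = set(comp) | set(reference)
    s1 = sum(comp.get(k, 0.0) for k in keys)
    s2 = sum(reference.get(k, 0.0) for k in keys)
    if abs(s1 - 1.0) > tol or abs(s2 - 1.0) > tol:
        raise ValueError(f"compositions must sum to 1 (got {s1:.8f} and {s2:.8f})")
    return 0.5 * sum(abs(comp.get(k, 0.0) - reference.get(k, 0.0)) for k in keys)


def coleman_index(network: DirectedNetwork, service_type: str) -> Optional[float]:
    """Coleman homophily index of one service type on a directed network.

    Let ``w`` be the share of out-ties from members of the type that land
    on same-type alters, and ``e = (n_type - 1)/(n - 1)`` the share expected
    under random mixing.  The index is ``(w - e)/(1 - e)`` when ``w >= e``
    (excess homophily, up to +1) and ``(w - e)/e`` otherwise (heterophily,
    down to -1); 0 when ties match the marginal type distribution.

    Returns ``None`` (a missing value, not zero) when the type has no
    members, no out-ties, or spans the whole network (e = 1).
    """
    n = network.n_nodes
    if n < 2:
        raise UndefinedMetricError(f"Coleman index undefined for n={n} (< 2 services)")
    if service_type not in SERVICE_TYPES:
        raise ValueError(f"unknown service_type {service_type!r}")
    types = network._type_map()
    members = {sid for sid, t in types.items() if t == service_type}
    n_type = len(members)
    if n_type == 0 or n_type == n:
        return None
    out_edges = [(a, b) for (a, b) in network.edges if a in members]
    if not out_edges:
        return None
    w = sum(1 for (_, b) in out_edges if b in members) / len(out_edges)
    e = (n_type - 1) / (n - 1)
    if w >= e:
        return (w - e) / (1.0 - e)
    return (w - e) / e


def network_metrics(
    network: DirectedNetwork, reference_composition: Mapping[str, float]
) -> NetworkMetrics:
    """Compute the full exposure row for one network."""
    comp = composition(network)
    return NetworkMetrics(
        network_id=network.network_id,
        n_services=network.n_nodes,
        composition=comp,
        dissimilarity_index=dissimilarity_index(comp, reference_composition),
        mean_in_degree_normalized=mean_in_degree_normalized(network),
        degree_centralization=degree_centralization(network),
        density=density(network),
        clustering=clustering(network),
        reciprocity=reciprocity(network),
        coleman={t: coleman_index(network, t) for t in SERVICE_TYPES},
    )


def mean_composition(networks: Sequence[DirectedNetwork]) -> dict[str, float]:
    """Unweighted mean composition across networks (each network counts once)."""
    if not networks:
        raise ValueError("need at least one network")
    comps = [composition(nw) for nw in networks]
    return {t: float(np.mean([c[t] for c in comps])) for t in SERVICE_TYPES}


def metrics_table(
    networks: Sequence[DirectedNetwork],
    reference_composition: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-network metric rows plus the mean/std/min/max summary.

    The dissimilarity reference defaults to the unweighted mean composition
    of the supplied networks.  Returns ``(rows, summary)``: ``rows`` has one
    row per network indexed by network id; ``summary`` has one row per
    metric with columns mean/std/min/max (std is the sample standard
    deviation; missing Coleman values are dropped pairwise).
    """
    if not networks:
        raise ValueError("need at least one network")
    if reference_composition is None:
        reference_composition = mean_composition(networks)
    rows = pd.DataFrame(
        [network_metrics(nw, reference_composition).as_row() for nw in networks]
    ).set_index("network_id")
    rows = rows[list(METRIC_ORDER)]
    summary = pd.DataFrame(
        {
            "mean": rows.mean(),
            "std": rows.std(ddof=1),
            "min": rows.min(),
            "max": rows.max(),
        }
    )
    return rows, summary


@dataclass
class MetricCorrelationMatrix:
    """Pairwise Pearson correlations among network metrics.

    ``r`` and ``p`` are symmetric DataFrames over the selected metrics;
    constant metrics are reported as all-missing rows/columns and listed in
    ``dropped``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n_networks: int
    dropped: list[str]

    def starred(self) -> pd.DataFrame:
        """Render r with significance stars at 5% / 1% / 0.1%."""

        def star(rv: float, pv: float) -> str:
            if not np.isfinite(rv):
                return ""
            stars = "***" if pv < 0.001 else "**" if pv < 0.01 else "*" if pv < 0.05 else ""
            return f"{rv:.2f}{stars}"

        out = self.r.copy().astype(object)
        for a in self.r.index:
            for b in self.r.columns:
                out.loc[a, b] = star(self.r.loc[a, b], self.p.loc[a, b])
        return out


def correlation_matrix(
    rows: pd.DataFrame | Sequence[NetworkMetrics],
    metrics: Optional[Sequence[str]] = None,
) -> MetricCorrelationMatrix:
    """Pearson correlations (with two-sided p) among network metrics.

    ``rows`` is the per-network table from :func:`metrics_table` (or a list
    of :class:`NetworkMetrics`).  Requires at least 3 networks.  Metrics
    constant across networks cannot be correlated and are reported as
    missing, with a warning entry in ``dropped``.  Pairs with missing
    values (undefined Coleman indices) are correlated on their complete
    networks.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame([m.as_row() for m in rows]).set_index("network_id")
    if metrics is None:
        metrics = [c for c in METRIC_ORDER if c in rows.columns]
    data = rows[list(metrics)].astype(float)
    if len(data) < 3:
        raise ValueError(f"need at least 3 networks for correlations, got {len(data)}")
    dropped = [c for c in metrics if data[c].dropna().nunique() <= 1]
    r = pd.DataFrame(np.nan, index=metrics, columns=metrics, dtype=float)
    p = pd.DataFrame(np.nan, index=metrics, columns=metrics, dtype=float)
    for i, a in enumerate(metrics):
        for b in metrics[i:]:
            if a in dropped or b in dropped:
                continue
            pair = data[[a, b]].dropna()
            if a == b:
                rv, pv = 1.0, 0.0
            elif len(pair) < 3 or pair[a].nunique() <= 1 or pair[b].nunique() <= 1:
                continue
            else:
                rv, pv = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(rv)
            p.loc[a, b] = p.loc[b, a] = float(pv)
    return MetricCorrelationMatrix(r=r, p=p, n_networks=len(data), dropped=dropped)
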