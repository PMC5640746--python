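"""Build binary directed clinical-contact networks from ordinal tie records.

The survey records ordinal contact frequencies (never/sometimes/often) for
four relation kinds.  The analysis network keeps the three clinical kinds
(referrals sent, referrals received, information exchange), dichotomizes
the ordinal ratings, and merges kinds into a single directed relation:

* main rule: "sometimes" and "often" count as a tie ("never" does not);
* sensitivity rule: only "often" counts as a tie;
* scope "participants_only" restricts nodes to services that completed the
  survey; scope "full_matrix" keeps non-participants as nodes, with their
  incident edges coming only from participants' reports.

Directionality: a ``referral_sent`` reported by i about j is an edge i->j;
a ``referral_received`` reported by j about i is reversed to i->j (it is
the mirror of a sent referral); ``info_exchange`` is directed
reporter->alter.  Kinds are merged by logical OR after thresholding, so an
edge means "at least one clinical contact of at least the threshold
frequency was reported on this ordered pair".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from carenet.survey_io import CLINICAL_KINDS, ServiceNode, TieRecord

__all__ = [
    "THRESHOLDS",
    "SCOPES",
    "BuildRule",
    "DirectedNetwork",
    "build_network",
    "summarize_build",
    "write_graphml",
]

#: Dichotomization rules mapped to the minimum ordinal code that counts as a tie.
THRESHOLDS: dict[str, int] = {"sometimes_or_often": 1, "often_only": 2}
SCOPES: tuple[str, ...] = ("participants_only", "full_matrix")


@dataclass(frozen=True)
class BuildRule:
    """The construction rule that produced a network (kept for audit)."""

    threshold: str = "sometimes_or_often"
    scope: str = "participants_only"
    relations_used: tuple[str, ...] = CLINICAL_KINDS
    symmetrize_info_exchange: bool = False

    def __post_init__(self) -> None:
        if self.threshold not in THRESHOLDS:
            raise ValueError(f"unknown threshold rule {self.threshold!r}; use one of {sorted(THRESHOLDS)}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}; use one of {SCOPES}")
        unknown = set(self.relations_used) - set(CLINICAL_KINDS)
        if unknown:
            raise ValueError(f"non-clinical relation kinds in build rule: {sorted(unknown)}")


@dataclass
class DirectedNetwork:
    """A binary directed clinical-contact network for one service network.

    ``nodes`` is an ordered list of :class:`ServiceNode`; ``edges`` a set of
    ordered ``(source_id, target_id)`` pairs over those nodes, with no
    self-loops.  ``build_rule`` records how the adjacency was derived.
    """

    network_id: str
    nodes: list[ServiceNode]
    edges: set[tuple[str, str]]
    build_rule: BuildRule = field(default_factory=BuildRule)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_ids(self) -> list[str]:
        return [n.service_id for n in self.nodes]

    def type_of(self, service_id: str) -> str:
        return self._type_map()[service_id]

    def _type_map(self) -> dict[str, str]:
        return {n.service_id: n.service_type for n in self.nodes}

    def to_networkx(self) -> nx.DiGraph:
        """Export as a :class:`networkx.DiGraph` with node attributes."""
        g = nx.DiGraph(network_id=self.network_id)
        for n in self.nodes:
            g.add_node(n.service_id, service_type=n.service_type, participated=n.participated)
        g.add_edges_from(sorted(self.edges))
        return g


def build_network(
    roster: Sequence[ServiceNode],
    ties: Iterable[TieRecord],
    threshold: str = "sometimes_or_often",
    scope: str = "participants_only",
    relations_used: Sequence[str] = CLINICAL_KINDS,
    symmetrize_info_exchange: bool = False,
) -> DirectedNetwork:
    """Dichotomize and merge tie records into one binary directed network.

    ``roster`` and ``ties`` must belong to a single network.  Organizational
    ties are ignored regardless of ``relations_used``.  Record order never
    affects the result (the merge is an OR).

    Parameters
    ----------
    threshold:
        ``"sometimes_or_often"`` (main analysis) or ``"often_only"``
        (sensitivity variant).
    scope:
        ``"participants_only"`` drops non-responding services and every tie
        incident to them; ``"full_matrix"`` keeps them, relying on
        participants' one-sided reports.
    relations_used:
        Subset of the clinical relation kinds to merge; defaults to all
        three.  Restricting to ``("referral_sent", "referral_received")``
        gives a referral-only network.
    symmetrize_info_exchange:
        When True, an information-exchange tie also adds the reverse edge.
        Off by default: the survey is one-mode and each service rates its
        own contacts.
    """
    roster = list(roster)
    if not roster:
        raise ValueError("empty roster")
    network_ids = {n.network_id for n in roster}
    if len(network_ids) != 1:
        raise ValueError(f"roster spans multiple networks: {sorted(network_ids)}")
    network_id = network_ids.pop()
    rule = BuildRule(
        threshold=threshold,
        scope=scope,
        relations_used=tuple(relations_used),
        symmetrize_info_exchange=symmetrize_info_exchange,
    )
    min_code = THRESHOLDS[threshold]

    if scope == "participants_only":
        nodes = [n for n in roster if n.participated]
    else:
        nodes = list(roster)
    keep = {n.service_id for n in nodes}

    edges: set[tuple[str, str]] = set()
    for t in ties:
        if t.network_id != network_id:
            raise ValueError(f"tie record for network {t.network_id!r} passed with roster {network_id!r}")
        if t.relation_kind not in rule.relations_used:
            continue
        if t.frequency < min_code:
            continue
        if t.relation_kind == "referral_received":
            src, dst = t.alter_id, t.reporter_id
        else:
            src, dst = t.reporter_id, t.alter_id
        if src in keep and dst in keep:
            edges.add((src, dst))
        if (
            t.relation_kind == "info_exchange"
            and rule.symmetrize_info_exchange
            and dst in keep
            and src in keep
        ):
            edges.add((dst, src))
    return DirectedNetwork(network_id=network_id, nodes=nodes, edges=edges, build_rule=rule)


def summarize_build(network: DirectedNetwork) -> dict:
    """A small audit record for the run log."""
    return {
        "network_id": network.network_id,
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "n_participants": sum(1 for n in network.nodes if n.participated),
        "threshold": network.build_rule.threshold,
        "scope": network.build_rule.scope,
        "relations_used": list(network.build_rule.relations_used),
    }


def write_graphml(network: DirectedNetwork, path: str | Path) -> None:
    """Write the network as GraphML with service_type/participated attributes."""
    nx.write_graphml(network.to_networkx(), str(path))
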