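"""Directed, signed, module-annotated signaling networks.

A :class:`SignalingNetwork` is the static substrate every other layer of the
package operates on: the simulator propagates activity over its weighted
adjacency, the attention layer reads its (capped) shortest-path structure,
and the feature layer uses its spectral positional embeddings.

Node semantics follow the information-transduction view of signaling: each
node is a molecular species (or a coarse readout such as contractility) that
receives inputs from its regulators, carries an internal activity state, and
emits an output.  Edges are signed (+1 activation, -1 inhibition) and carry a
nonnegative weight; the signed weighted adjacency W has entry
``W[u, v] = sign * weight`` for each regulatory edge u -> v.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "MODULES",
    "ENTITY_TYPES",
    "Node",
    "Edge",
    "SignalingNetwork",
    "EmbeddingTable",
    "adjacency_matrix",
    "weighted_adjacency",
    "path_length_matrix",
    "spectral_positional_embedding",
    "generate_fixture_network",
    "default_pathway_groups",
    "read_network",
    "write_network",
]

#: The 11 functional modules of the fibroblast-style network.  Modules double
#: as the pathway scale of the hierarchy.
MODULES = (
    "inputs",
    "receptors",
    "second_messengers",
    "kinases",
    "mapk",
    "rho",
    "transcription_factors",
    "ecm_fibrosis",
    "matrix_remodeling",
    "mechanotransduction",
    "feedback",
)

ENTITY_TYPES = (
    "protein",
    "receptor",
    "second-messenger",
    "transcription-factor",
    "readout",
)


class NetworkValidationError(ValueError):
    """Raised when a network (or a serialized network) violates an invariant."""


@dataclass(frozen=True)
class Node:
    """A molecular species: unique id, functional module, entity type."""

    id: str
    module: str
    entity_type: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("node id must be nonempty")
        if self.module not in MODULES:
            raise NetworkValidationError(
                f"unknown module {self.module!r} for node {self.id!r}; "
                f"expected one of {MODULES}"
            )
        if self.entity_type not in ENTITY_TYPES:
            raise NetworkValidationError(
                f"unknown entity_type {self.entity_type!r} for node {self.id!r}"
            )


@dataclass(frozen=True)
class Edge:
    """A signed, weighted regulatory connection source -> target."""

    source: str
    target: str
    sign: int = 1
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: sign must be +1 or -1"
            )
        if not self.weight > 0:
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: weight must be > 0"
            )


class SignalingNetwork:
    """Directed signaling graph with module annotations.

    Parameters
    ----------
    nodes
        Species of the network.  Ids must be unique.
    edges
        Directed edges; at most one edge per ordered pair (duplicates are
        rejected, not merged, so the weighted adjacency is unambiguous).
    """

    def __init__(self, nodes: Iterable[Node], edges: Iterable[Edge]) -> None:
        self.nodes: list[Node] = list(nodes)
        self.edges: list[Edge] = list(edges)

        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate node ids: {dup}")
        self._index: dict[str, int] = {nid: k for k, nid in enumerate(ids)}

        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self._index:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target} references unknown node "
                        f"{endpoint!r}"
                    )
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise NetworkValidationError(
                    f"duplicate edge {e.source}->{e.target}; one edge per "
                    "ordered pair"
                )
            seen_pairs.add(pair)

        self.module_map: dict[str, set[str]] = {}
        for n in self.nodes:
            self.module_map.setdefault(n.module, set()).add(n.id)

    # -- basic accessors ---------------------------------------------------

    @property
    def species(self) -> list[str]:
        """Node ids in canonical (construction) order."""
        return [n.id for n in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node_id: str) -> int:
        return self._index[node_id]

    def node(self, node_id: str) -> Node:
        return self.nodes[self._index[node_id]]

    def has_edge(self, source: str, target: str) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    def predecessors(self, node_id: str) -> list[str]:
        return [e.source for e in self.edges if e.target == node_id]

    def input_nodes(self) -> list[str]:
        """Species in the ``inputs`` module, in canonical order."""
        return [n.id for n in self.nodes if n.module == "inputs"]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, module=n.module, entity_type=n.entity_type)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, weight=e.weight)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalingNetwork):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.edges) == set(
            other.edges
        )

    def __repr__(self) -> str:
        return (
            f"SignalingNetwork({self.n_nodes} nodes, {len(self.edges)} edges, "
            f"{len(self.module_map)} modules)"
        )


# ---------------------------------------------------------------------------
# graph-derived matrices
# ---------------------------------------------------------------------------


def adjacency_matrix(net: SignalingNetwork) -> np.ndarray:
    """Binary adjacency A with ``A[u, v] = 1`` iff edge u -> v exists."""
    a = np.zeros((net.n_nodes, net.n_nodes), dtype=np.int64)
    for e in net.edges:
        a[net.index(e.source), net.index(e.target)] = 1
    return a


def weighted_adjacency(net: SignalingNetwork) -> np.ndarray:
    """Signed weighted adjacency: ``W[u, v] = sign * weight`` on edges, 0 off."""
    w = np.zeros((net.n_nodes, net.n_nodes), dtype=float)
    for e in net.edges:
        w[net.index(e.source), net.index(e.target)] = e.sign * e.weight
    return w


def path_length_matrix(net: SignalingNetwork, max_len: int = 3) -> np.ndarray:
    """Directed shortest-path lengths capped at ``max_len``.

    Entry (i, j) is the length of the shortest directed path i -> j if it is
    at most ``max_len``; unreachable-within-cap pairs carry the sentinel
    ``max_len + 1``.  The diagonal is 0.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    sentinel = max_len + 1
    n = net.n_nodes
    dist = np.full((n, n), sentinel, dtype=np.int64)
    g = net.to_networkx()
    for src, lengths in nx.all_pairs_shortest_path_length(g, cutoff=max_len):
        i = net.index(src)
        for tgt, d in lengths.items():
            dist[i, net.index(tgt)] = d
    np.fill_diagonal(dist, 0)
    return dist


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingTable:
    """Static per-node embedding blocks.

    ``type_block`` is a one-hot encoding of the entity type, ``feature_block``
    is a hook for user-supplied molecular annotations (all-zero by default),
    and ``positional_block`` holds the spectral coordinates (eigenvectors of
    the normalized Laplacian of the symmetrized graph for the k smallest
    nonzero eigenvalues).
    """

    species: list[str]
    type_block: np.ndarray
    feature_block: np.ndarray
    positional_block: np.ndarray
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def combined(self) -> np.ndarray:
        """Concatenated per-node embedding vectors (one row per node)."""
        return np.hstack([self.type_block, self.feature_block, self.positional_block])


def spectral_positional_embedding(net: SignalingNetwork, k: int = 4) -> EmbeddingTable:
    """Spectral positional embedding from the normalized graph Laplacian.

    The directed graph is symmetrized (an undirected edge wherever either
    direction exists), the normalized Laplacian is diagonalized, and each node
    receives the k eigenvector components belonging to the k smallest
    *nonzero* eigenvalues.  Zero eigenvalues (one per connected component)
    carry no positional information and are skipped.
    """
    if k >= net.n_nodes:
        raise ValueError(f"k={k} must be smaller than the node count {net.n_nodes}")
    g = net.to_networkx().to_undirected()
    # unweighted Laplacian: positional structure, not regulatory strength
    lap = nx.normalized_laplacian_matrix(g, nodelist=net.species, weight=None)
    eigvals, eigvecs = np.linalg.eigh(lap.toarray())
    nonzero = np.where(eigvals > 1e-10)[0]
    if k > nonzero.size:
        raise ValueError(
            f"requested k={k} nonzero-eigenvalue components but only "
            f"{nonzero.size} are available"
        )
    sel = nonzero[:k]
    positional = eigvecs[:, sel]

    type_onehot = np.zeros((net.n_nodes, len(ENTITY_TYPES)))
    for i, node in enumerate(net.nodes):
        type_onehot[i, ENTITY_TYPES.index(node.entity_type)] = 1.0

    return EmbeddingTable(
        species=list(net.species),
        type_block=type_onehot,
        feature_block=np.zeros((net.n_nodes, 0)),
        positional_block=positional,
        eigenvalues=eigvals[sel],
    )


# ---------------------------------------------------------------------------
# fixture network
# ---------------------------------------------------------------------------

# Named backbone of canonical fibroblast signaling.  Tuples are
# (id, module, entity_type).
_ANCHOR_NODES: tuple[tuple[str, str, str], ...] = (
    # ligand / stimulus inputs
    ("TGFB", "inputs", "protein"),
    ("PDGF", "inputs", "protein"),
    ("AngII", "inputs", "protein"),
    ("IL6", "inputs", "protein"),
    ("NE", "inputs", "protein"),
    ("mech_strain", "inputs", "protein"),
    # receptors
    ("TGFBR", "receptors", "receptor"),
    ("PDGFR", "receptors", "receptor"),
    ("AT1R", "receptors", "receptor"),
    ("gp130", "receptors", "receptor"),
    ("BAR", "receptors", "receptor"),
    # second messengers
    ("Ca", "second_messengers", "second-messenger"),
    ("cAMP", "second_messengers", "second-messenger"),
    ("DAG", "second_messengers", "second-messenger"),
    ("IP3", "second_messengers", "second-messenger"),
    ("ROS", "second_messengers", "second-messenger"),
    # kinases
    ("PI3K", "kinases", "protein"),
    ("AKT", "kinases", "protein"),
    ("mTOR", "kinases", "protein"),
    ("PKC", "kinases", "protein"),
    ("PKA", "kinases", "protein"),
    ("FAK", "kinases", "protein"),
    ("Src", "kinases", "protein"),
    ("CamKII", "kinases", "protein"),
    # MAPK cascade
    ("RAS", "mapk", "protein"),
    ("RAF", "mapk", "protein"),
    ("MEK", "mapk", "protein"),
    ("ERK", "mapk", "protein"),
    ("MKK3", "mapk", "protein"),
    ("p38", "mapk", "protein"),
    ("JNK", "mapk", "protein"),
    # Rho signaling
    ("RhoA", "rho", "protein"),
    ("ROCK", "rho", "protein"),
    ("Rac1", "rho", "protein"),
    ("Cdc42", "rho", "protein"),
    # transcription factors
    ("SMAD3", "transcription_factors", "transcription-factor"),
    ("SMAD4", "transcription_factors", "transcription-factor"),
    ("STAT3", "transcription_factors", "transcription-factor"),
    ("NFKB", "transcription_factors", "transcription-factor"),
    ("AP1", "transcription_factors", "transcription-factor"),
    ("SRF", "transcription_factors", "transcription-factor"),
    ("MRTF", "transcription_factors", "transcription-factor"),
    # ECM / fibrosis markers
    ("proCI", "ecm_fibrosis", "readout"),
    ("proCIII", "ecm_fibrosis", "protein"),
    ("fibronectin", "ecm_fibrosis", "protein"),
    ("CTGF", "ecm_fibrosis", "protein"),
    ("aSMA", "ecm_fibrosis", "readout"),
    ("periostin", "ecm_fibrosis", "protein"),
    # matrix remodeling
    ("MMP1", "matrix_remodeling", "protein"),
    ("MMP2", "matrix_remodeling", "protein"),
    ("MMP9", "matrix_remodeling", "protein"),
    ("TIMP1", "matrix_remodeling", "protein"),
    ("TIMP2", "matrix_remodeling", "protein"),
    ("PAI1", "matrix_remodeling", "protein"),
    # mechanotransduction
    ("integrins", "mechanotransduction", "receptor"),
    ("talin", "mechanotransduction", "protein"),
    ("vinculin", "mechanotransduction", "protein"),
    ("YAP", "mechanotransduction", "protein"),
    ("contractility", "mechanotransduction", "readout"),
    # feedback / shut-off molecules
    ("SMAD7", "feedback", "protein"),
    ("DUSP1", "feedback", "protein"),
    ("DUSP6", "feedback", "protein"),
    ("PTEN", "feedback", "protein"),
    ("SOCS3", "feedback", "protein"),
    ("BAMBI", "feedback", "protein"),
)

# Canonical regulatory backbone; sign -1 marks inhibition.
_ANCHOR_EDGES: tuple[tuple[str, str, int], ...] = (
    ("TGFB", "TGFBR", 1),
    ("TGFBR", "SMAD3", 1),
    ("TGFBR", "MKK3", 1),
    ("SMAD3", "SMAD4", 1),
    ("SMAD3", "proCI", 1),
    ("SMAD3", "proCIII", 1),
    ("SMAD3", "CTGF", 1),
    ("SMAD3", "aSMA", 1),
    ("SMAD3", "YAP", 1),
    ("SMAD3", "TIMP1", 1),
    ("SMAD3", "PAI1", 1),
    ("SMAD3", "SMAD7", 1),
    ("SMAD3", "PDGFR", 1),  # TGF-beta upregulates PDGF receptors in fibroblasts
    ("SMAD4", "proCI", 1),
    ("SMAD4", "fibronectin", 1),
    ("SMAD7", "TGFBR", -1),
    ("BAMBI", "TGFBR", -1),
    ("PDGF", "PDGFR", 1),
    ("PDGFR", "PI3K", 1),
    ("PDGFR", "RAS", 1),
    ("PI3K", "AKT", 1),
    ("AKT", "mTOR", 1),
    ("mTOR", "proCI", 1),
    ("PTEN", "PI3K", -1),
    ("AngII", "AT1R", 1),
    ("AT1R", "DAG", 1),
    ("AT1R", "IP3", 1),
    ("AT1R", "ROS", 1),
    ("IP3", "Ca", 1),
    ("Ca", "CamKII", 1),
    ("DAG", "PKC", 1),
    ("PKC", "RAF", 1),
    ("ROS", "JNK", 1),
    ("RAS", "RAF", 1),
    ("RAF", "MEK", 1),
    ("MEK", "ERK", 1),
    ("ERK", "AP1", 1),
    ("ERK", "DUSP6", 1),
    ("ERK", "MMP1", 1),
    ("DUSP6", "ERK", -1),
    ("MKK3", "p38", 1),
    ("p38", "DUSP1", 1),
    ("p38", "AP1", 1),
    ("DUSP1", "p38", -1),
    ("JNK", "AP1", 1),
    ("AP1", "MMP1", 1),
    ("AP1", "MMP9", 1),
    ("NFKB", "MMP9", 1),
    ("IL6", "gp130", 1),
    ("gp130", "STAT3", 1),
    ("STAT3", "CTGF", 1),
    ("STAT3", "SOCS3", 1),
    ("SOCS3", "gp130", -1),
    ("NE", "BAR", 1),
    ("BAR", "cAMP", 1),
    ("cAMP", "PKA", 1),
    ("PKA", "RAF", -1),
    ("mech_strain", "integrins", 1),
    ("integrins", "FAK", 1),
    ("integrins", "talin", 1),
    ("talin", "vinculin", 1),
    ("FAK", "Src", 1),
    ("FAK", "RAS", 1),
    ("Src", "PDGFR", 1),  # RTK transactivation under mechanical stimulation
    ("FAK", "RhoA", 1),
    ("Src", "RhoA", 1),
    ("RhoA", "ROCK", 1),
    ("Rac1", "JNK", 1),
    ("Cdc42", "p38", 1),
    ("ROCK", "MRTF", 1),
    ("ROCK", "YAP", 1),
    ("ROCK", "contractility", 1),
    ("MRTF", "SRF", 1),
    ("MRTF", "aSMA", 1),
    ("MRTF", "proCI", 1),  # strain-induced, TGF-beta-independent collagen
    ("SRF", "proCIII", 1),
    ("SRF", "aSMA", 1),
    ("YAP", "aSMA", 1),
    ("YAP", "CTGF", 1),
    ("aSMA", "contractility", 1),
    ("TIMP1", "MMP1", -1),
    ("TIMP2", "MMP2", -1),
    ("PAI1", "MMP9", -1),
)

# Layered ordering used to wire filler nodes predominantly feed-forward.
_MODULE_LAYER = {
    "inputs": 0,
    "receptors": 1,
    "second_messengers": 2,
    "mechanotransduction": 2,
    "kinases": 3,
    "mapk": 4,
    "rho": 4,
    "transcription_factors": 5,
    "ecm_fibrosis": 6,
    "matrix_remodeling": 6,
    "feedback": 7,
}

# Fractions used to distribute filler species over modules (roughly matching
# the composition of curated fibroblast models: heavy in kinases/TFs/ECM).
_FILLER_SHARE = {
    "inputs": 0.02,
    "receptors": 0.10,
    "second_messengers": 0.08,
    "kinases": 0.16,
    "mapk": 0.10,
    "rho": 0.08,
    "transcription_factors": 0.14,
    "ecm_fibrosis": 0.12,
    "matrix_remodeling": 0.08,
    "mechanotransduction": 0.07,
    "feedback": 0.05,
}

_MODULE_ENTITY = {
    "inputs": "protein",
    "receptors": "receptor",
    "second_messengers": "second-messenger",
    "kinases": "protein",
    "mapk": "protein",
    "rho": "protein",
    "transcription_factors": "transcription-factor",
    "ecm_fibrosis": "protein",
    "matrix_remodeling": "protein",
    "mechanotransduction": "protein",
    "feedback": "protein",
}

# Default module-specific (integration, degradation) rates; shared with the
# simulator so fixture edge weights can be scaled to keep steady states inside
# [0, 1] along multi-stage cascades (weight ~ degradation/integration divides
# out the stage gain).
DEFAULT_MODULE_RATES: dict[str, tuple[float, float]] = {
    "inputs": (0.4, 0.05),  # clamped by the simulator; rates unused
    "receptors": (0.4, 0.05),
    "second_messengers": (0.35, 0.08),
    "kinases": (0.35, 0.08),
    "mapk": (0.35, 0.08),
    "rho": (0.35, 0.08),
    "mechanotransduction": (0.35, 0.08),
    "transcription_factors": (0.25, 0.06),
    "feedback": (0.25, 0.06),
    "ecm_fibrosis": (0.15, 0.03),
    "matrix_remodeling": (0.15, 0.03),
}

MIN_EDGES = 200


def _edge_sign(source_module: str, explicit: int | None) -> int:
    if explicit is not None:
        return explicit
    return -1 if source_module == "feedback" else 1


def generate_fixture_network(n_species: int = 132, seed: int = 0) -> SignalingNetwork:
    """Generate the fibroblast-style fixture network.

    The network contains the canonical named backbone (TGF-beta/SMAD, PDGF,
    AngII, IL6, beta-adrenergic, mechanotransduction and MAPK cascades, ECM
    readouts, negative-feedback molecules) plus procedurally generated filler
    species that bring the node count to ``n_species``, partitioned over the
    11 functional modules, with predominantly feed-forward wiring and at
    least 200 edges.  Pure function of ``(n_species, seed)``.

    Edge weights are drawn so that the total activating input weight into a
    node roughly cancels the node's steady-state gain (integration rate over
    degradation rate): signal levels then propagate through cascade stages
    without saturating at the [0, 1] bounds.  Outgoing edges of the feedback
    module and of protease inhibitors (TIMPs, PAI1) are inhibitory; all other
    edges activate.
    """
    if n_species < len(_ANCHOR_NODES):
        raise ValueError(
            f"n_species must be at least {len(_ANCHOR_NODES)} (anchor species)"
        )
    rng = np.random.default_rng(seed)

    nodes: list[Node] = [Node(*t) for t in _ANCHOR_NODES]
    module_of = {t[0]: t[1] for t in _ANCHOR_NODES}

    # distribute filler nodes over modules
    n_fill = n_species - len(nodes)
    shares = np.array([_FILLER_SHARE[m] for m in MODULES])
    counts = np.floor(shares / shares.sum() * n_fill).astype(int)
    while counts.sum() < n_fill:  # hand out remainders deterministically
        counts[int(np.argmax(shares - counts / max(n_fill, 1)))] += 1
    fillers_by_module: dict[str, list[str]] = {m: [] for m in MODULES}
    for m, c in zip(MODULES, counts):
        for j in range(c):
            nid = f"{m}_{j + 1:02d}"
            nodes.append(Node(nid, m, _MODULE_ENTITY[m]))
            module_of[nid] = m
            fillers_by_module[m].append(nid)

    by_module: dict[str, list[str]] = {m: [] for m in MODULES}
    for n in nodes:
        by_module[n.module].append(n.id)

    edge_set: dict[tuple[str, str], int] = {}
    for s, t, sign in _ANCHOR_EDGES:
        edge_set[(s, t)] = sign

    def add_edge(s: str, t: str, sign: int | None = None) -> None:
        if s == t or (s, t) in edge_set:
            return
        edge_set[(s, t)] = _edge_sign(module_of[s], sign)

    def modules_at_layer(layer: int) -> list[str]:
        return [m for m, l in _MODULE_LAYER.items() if l == layer]

    # wire fillers: 1-2 regulators from an upstream layer, 1-2 targets downstream
    for m in MODULES:
        layer = _MODULE_LAYER[m]
        for nid in fillers_by_module[m]:
            if layer > 0:
                upstream_modules = modules_at_layer(layer - 1) or modules_at_layer(
                    max(layer - 2, 0)
                )
                pool = [x for mm in upstream_modules for x in by_module[mm]]
                if pool:
                    for s in rng.choice(pool, size=min(2, len(pool)), replace=False):
                        add_edge(str(s), nid)
            if layer < 7:
                down_modules = modules_at_layer(layer + 1) or modules_at_layer(
                    min(layer + 2, 6)
                )
                # wire mostly into downstream fillers so procedural background
                # circuitry does not swamp the canonical anchor cascades
                filler_pool = [
                    x for mm in down_modules for x in fillers_by_module[mm]
                ]
                anchor_pool = [
                    x
                    for mm in down_modules
                    for x in by_module[mm]
                    if x not in fillers_by_module[mm]
                ]
                # feedback anchors (SMAD7, DUSPs, ...) keep curated drivers only
                if all(_MODULE_LAYER[mm] == 7 for mm in down_modules):
                    anchor_pool = []
                k = int(rng.integers(1, 3))
                for _ in range(k):
                    pool = (
                        filler_pool
                        if (filler_pool and (rng.random() < 0.75 or not anchor_pool))
                        else anchor_pool
                    )
                    if pool:
                        add_edge(nid, str(rng.choice(pool)))
            else:  # feedback fillers: driven by TFs, inhibit signaling layers
                drivers = by_module["transcription_factors"]
                add_edge(str(rng.choice(drivers)), nid)
                # inhibit background (filler) circuitry; canonical anchors keep
                # their curated feedback loops (SMAD7, DUSPs, SOCS3, ...)
                targets = (
                    fillers_by_module["receptors"]
                    + fillers_by_module["kinases"]
                    + fillers_by_module["mapk"]
                )
                for t in rng.choice(targets, size=2, replace=False):
                    add_edge(nid, str(t), sign=-1)

    # extra feed-forward cross edges until comfortably past the edge floor
    all_ids = [n.id for n in nodes]
    attempts = 0
    while len(edge_set) < MIN_EDGES + 10 and attempts < 20000:
        attempts += 1
        s, t = rng.choice(all_ids, size=2, replace=False)
        ls, lt = _MODULE_LAYER[module_of[str(s)]], _MODULE_LAYER[module_of[str(t)]]
        if (
            lt == ls + 1
            and module_of[str(t)] != "inputs"
            and str(t) in fillers_by_module[module_of[str(t)]]
        ):
            add_edge(str(s), str(t))

    # weights scaled by the target's steady-state gain (integration over
    # degradation rate) so signal levels neither die out nor saturate along
    # cascades; the (1 + in-degree)/2 normalization assumes roughly half of a
    # node's regulators are active in any one condition
    in_pos: dict[str, int] = {nid: 0 for nid in all_ids}
    for (s, t), sign in edge_set.items():
        if sign > 0:
            in_pos[t] += 1
    edges: list[Edge] = []
    for (s, t), sign in sorted(edge_set.items()):
        k_int, k_deg = DEFAULT_MODULE_RATES[module_of[t]]
        gain = k_int / k_deg
        base = 2.0 / (gain * (1.0 + max(in_pos[t], 1)))
        if sign < 0:
            base = 0.4 / gain  # inhibition sized against a single strong input
        weight = float(base * rng.uniform(0.85, 1.15))
        edges.append(Edge(str(s), str(t), sign, weight))

    return SignalingNetwork(nodes, edges)


def default_pathway_groups(net: SignalingNetwork) -> dict[str, list[str]]:
    """Canonical pathway groupings used for crosstalk / pathway attention.

    These cut across the 11 structural modules: e.g. the PDGF pathway is the
    receptor-proximal PDGFR/PI3K/AKT axis (ligands are experimental stimuli,
    not pathway members).  Only species present in ``net`` are included.
    """
    groups = {
        "TGFB": ["TGFBR", "SMAD3", "SMAD4"],
        "PDGF": ["PDGFR", "PI3K", "AKT"],
        "MAPK": ["RAS", "RAF", "MEK", "ERK", "MKK3", "p38", "JNK"],
        "mechanotransduction": ["integrins", "FAK", "talin", "vinculin", "YAP"],
        "fibrosis": ["proCI", "proCIII", "fibronectin", "CTGF", "aSMA"],
    }
    present = set(net.species)
    return {k: [s for s in v if s in present] for k, v in groups.items()}


# ---------------------------------------------------------------------------
# I/O: GraphML, SIF, JSON
# ---------------------------------------------------------------------------

_SIF_RELATIONS = {"activates": 1, "inhibits": -1}


def write_network(net: SignalingNetwork, path: str | Path, format: str | None = None) -> None:
    """Write a network as GraphML, SIF, or JSON (inferred from the suffix)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in net.edges:
                rel = "activates" if e.sign > 0 else "inhibits"
                fh.write(f"{e.source}\t{rel}\t{e.target}\t{e.weight!r}\n")
        # SIF carries no node attributes; store them in a sidecar
        sidecar = path.with_suffix(path.suffix + ".nodes.json")
        with open(sidecar, "w") as fh:
            json.dump(
                [
                    {"id": n.id, "module": n.module, "entity_type": n.entity_type}
                    for n in net.nodes
                ],
                fh,
                indent=1,
            )
    elif fmt == "json":
        payload = {
            "nodes": [
                {"id": n.id, "module": n.module, "entity_type": n.entity_type}
                for n in net.nodes
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "sign": e.sign,
                    "weight": e.weight,
                }
                for e in net.edges
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unsupported network format {fmt!r}")


def read_network(path: str | Path, format: str | None = None) -> SignalingNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = []
        for nid, data in g.nodes(data=True):
            if "module" not in data:
                raise NetworkValidationError(f"node {nid!r} missing 'module'")
            nodes.append(
                Node(str(nid), data["module"], data.get("entity_type", "protein"))
            )
        edges = [
            Edge(str(u), str(v), int(d.get("sign", 1)), float(d.get("weight", 1.0)))
            for u, v, d in g.edges(data=True)
        ]
        return SignalingNetwork(nodes, edges)
    if fmt == "sif":
        edges = []
        node_ids: list[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) not in (3, 4):
                    raise NetworkValidationError(
                        f"{path}:{lineno}: expected "
                        "'source<TAB>relation<TAB>target[<TAB>weight]', got "
                        f"{line!r}"
                    )
                src, rel, tgt = parts[:3]
                if rel not in _SIF_RELATIONS:
                    raise NetworkValidationError(
                        f"{path}:{lineno}: unknown relation {rel!r}; expected "
                        f"one of {sorted(_SIF_RELATIONS)}"
                    )
                weight = float(parts[3]) if len(parts) == 4 else 1.0
                edges.append(Edge(src, tgt, _SIF_RELATIONS[rel], weight))
                for nid in (src, tgt):
                    if nid not in node_ids:
                        node_ids.append(nid)
        sidecar = path.with_suffix(path.suffix + ".nodes.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                nodes = [Node(d["id"], d["module"], d["entity_type"]) for d in json.load(fh)]
        else:  # bare SIF: no module info; everything lands in one module
            nodes = [Node(nid, "inputs") for nid in node_ids]
        return SignalingNetwork(nodes, edges)
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        nodes = []
        for d in payload.get("nodes", []):
            if "module" not in d:
                raise NetworkValidationError(
                    f"node entry {d.get('id', '?')!r} missing 'module'"
                )
            nodes.append(Node(d["id"], d["module"], d.get("entity_type", "protein")))
        edges = [
            Edge(d["source"], d["target"], int(d.get("sign", 1)), float(d.get("weight", 1.0)))
            for d in payload.get("edges", [])
        ]
        return SignalingNetwork(nodes, edges)
    raise ValueError(f"unsupported network format {fmt!r}")
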