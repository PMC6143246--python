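"""Per-ego social network construction and structural/compositional measures.

Each interviewed participant (the *ego*) names exactly 30 people (*alters*)
and rates, for every unordered pair of alters, how likely the two are to talk
to each other on a 1-5 scale.  Pairs rated 4 ("likely") or 5 ("very likely")
are treated as tied; the resulting undirected graph on the 30 alters is the
ego's personal network.  From it we compute

* **mean betweenness** -- the average, over all 30 alters, of unnormalized
  betweenness centrality with fractional shortest-path counting
  ``B(v) = sum_{s<t, v not in {s,t}} sigma_st(v) / sigma_st``;
* **mean distance** -- the average geodesic distance over all *reachable*
  unordered alter pairs (unreachable pairs are excluded by default; a
  penalized convention that scores them as ``n`` is available);
* **percent family** -- the share of the 30 alters flagged as family;
* **percent of central positions occupied by family** -- of the three
  central positions (most between, most close, most distant), the fraction
  held by family alters, denominator fixed at 3.

"Most close" uses harmonic closeness ``C(v) = sum_{u reachable} 1/d(v,u)``,
which stays well defined on fragmented graphs; "most distant" is the largest
mean reachable distance (farness), isolates excluded.  All argmax ties break
toward the lowest alter index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_ALTERS = 30
N_PAIRS = N_ALTERS * (N_ALTERS - 1) // 2

#: relationship categories counted as family: blood family, family by
#: marriage, spouse/significant other.
FAMILY_RELATIONSHIP_CODES = frozenset({1, 2, 3})


class NetworkValidationError(ValueError):
    """Raised when an ego's tie table violates the interview schema."""


@dataclass(frozen=True)
class EgoGraph:
    """An undirected simple graph on one ego's alters.

    ``edges`` holds unordered 0-based index pairs ``(i, j)`` with ``i < j``.
    """

    ego_id: object
    n_nodes: int
    edges: frozenset
    family_flags: tuple

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise NetworkValidationError(
                    f"ego {self.ego_id}: self-loop at node {i}")
            if not (0 <= i < j < self.n_nodes):
                raise NetworkValidationError(
                    f"ego {self.ego_id}: edge ({i},{j}) outside 0..{self.n_nodes - 1}")
        if len(self.family_flags) != self.n_nodes:
            raise NetworkValidationError(
                f"ego {self.ego_id}: {len(self.family_flags)} family flags "
                f"for {self.n_nodes} nodes")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a


@dataclass(frozen=True)
class NodeCentralities:
    """Per-node centrality vectors plus the full geodesic distance matrix."""

    betweenness: np.ndarray
    harmonic_closeness: np.ndarray
    farness: np.ndarray          # mean reachable distance; NaN for isolates
    reachable_count: np.ndarray
    distances: np.ndarray        # (n, n), inf where unreachable


@dataclass(frozen=True)
class EgoMeasures:
    ego_id: object
    mean_betweenness: float
    mean_distance: float         # NaN when the graph has no edges
    pct_family: float
    pct_central_family: float
    most_between: int            # -1 when undefined (edgeless graph)
    most_close: int
    most_distant: int
    n_edges: int
    n_isolates: int


def build_graph(tie_ratings, family_flags: Sequence[bool], threshold: int = 4,
                ego_id: object = None, n_alters: int = N_ALTERS) -> EgoGraph:
    """Threshold one ego's alter-pair ratings into an undirected graph.

    Parameters
    ----------
    tie_ratings
        DataFrame with columns ``alter_i, alter_j, rating`` (0-based indices)
        or an iterable of ``(i, j, rating)`` triples; must cover every
        unordered pair of ``n_alters`` alters exactly once.
    family_flags
        Boolean per-alter family indicator, length ``n_alters``.
    threshold
        Minimum rating that constitutes a tie (default 4).
    """
    if isinstance(tie_ratings, pd.DataFrame):
        ai = tie_ratings["alter_i"].to_numpy()
        aj = tie_ratings["alter_j"].to_numpy()
        rr = tie_ratings["rating"].to_numpy()
    else:
        arr = np.asarray([(i, j, r) for i, j, r in tie_ratings], dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 3)
        ai, aj, rr = arr[:, 0], arr[:, 1], arr[:, 2]
    ai = np.asarray(ai, dtype=np.int64)
    aj = np.asarray(aj, dtype=np.int64)
    rr = np.asarray(rr, dtype=float)
    n_pairs = n_alters * (n_alters - 1) // 2
    if (ai == aj).any():
        k = int(np.argmax(ai == aj))
        raise NetworkValidationError(
            f"ego {ego_id}: pair ({ai[k]},{aj[k]}) is a self-pair")
    if len(ai) and (ai.min() < 0 or aj.min() < 0
                    or ai.max() >= n_alters or aj.max() >= n_alters):
        bad = (ai < 0) | (aj < 0) | (ai >= n_alters) | (aj >= n_alters)
        k = int(np.argmax(bad))
        raise NetworkValidationError(
            f"ego {ego_id}: pair ({ai[k]},{aj[k]}) outside 0..{n_alters - 1}")
    ok = (rr == np.floor(rr)) & (rr >= 1) & (rr <= 5)
    if not ok.all():
        k = int(np.argmax(~ok))
        raise NetworkValidationError(
            f"ego {ego_id}: rating {rr[k]} for pair ({ai[k]},{aj[k]}) "
            f"not an integer in 1..5")
    lo = np.minimum(ai, aj)
    hi = np.maximum(ai, aj)
    keys = lo * n_alters + hi
    uniq = np.unique(keys)
    if len(uniq) != len(keys):
        order = np.argsort(keys, kind="stable")
        dup_pos = order[np.argmax(np.diff(keys[order]) == 0) + 1]
        raise NetworkValidationError(
            f"ego {ego_id}: duplicate pair ({lo[dup_pos]},{hi[dup_pos]})")
    if len(uniq) != n_pairs:
        raise NetworkValidationError(
            f"ego {ego_id}: {len(uniq)} of {n_pairs} alter pairs present")
    mask = rr >= threshold
    edges = frozenset((int(a), int(b)) for a, b in zip(lo[mask], hi[mask]))
    return EgoGraph(ego_id=ego_id, n_nodes=n_alters, edges=edges,
                    family_flags=tuple(bool(f) for f in family_flags))


def _shortest_path_counts(adj: np.ndarray):
    """All-sources BFS distances and shortest-path counts.

    Level-synchronous formulation: one boolean frontier per source, advanced
    jointly through matrix products, so the cost per graph is a handful of
    ``n x n`` multiplications instead of ``n`` Python BFS traversals.
    """
    n = adj.shape[0]
    a = adj.astype(np.float64)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    frontier = np.eye(n, dtype=bool)
    level = 0
    while frontier.any():
        counts = (sigma * frontier) @ a
        new = (counts > 0) & np.isinf(dist)
        level += 1
        dist[new] = level
        sigma[new] = counts[new]
        frontier = new
    return dist, sigma


def node_centralities(graph: EgoGraph) -> NodeCentralities:
    """Betweenness, harmonic closeness, and farness for every alter.

    Betweenness uses Brandes' dependency accumulation
    ``delta(v) = sum_w [d(w) = d(v)+1] sigma(v)/sigma(w) (1 + delta(w))``,
    run per source and halved for the undirected double count.
    """
    adj = graph.adjacency()
    n = graph.n_nodes
    a = adj.astype(np.float64)
    dist, sigma = _shortest_path_counts(adj)

    delta = np.zeros((n, n))
    finite = np.isfinite(dist)
    max_level = int(dist[finite].max()) if finite.any() else 0
    safe_sigma = np.where(sigma > 0, sigma, 1.0)
    for level in range(max_level, 0, -1):
        w_mask = dist == level
        coef = np.where(w_mask, (1.0 + delta) / safe_sigma, 0.0)
        contrib = coef @ a
        v_mask = dist == level - 1
        delta += np.where(v_mask, contrib * sigma, 0.0)
    np.fill_diagonal(delta, 0.0)
    betweenness = delta.sum(axis=0) / 2.0

    off = dist.copy()
    np.fill_diagonal(off, np.inf)
    reach = np.isfinite(off)
    reachable_count = reach.sum(axis=1)
    with np.errstate(divide="ignore"):
        harmonic = np.where(reach, 1.0 / off, 0.0).sum(axis=1)
    farness = np.full(n, np.nan)
    has = reachable_count > 0
    farness[has] = np.where(reach, off, 0.0).sum(axis=1)[has] / reachable_count[has]
    return NodeCentralities(betweenness=betweenness, harmonic_closeness=harmonic,
                            farness=farness, reachable_count=reachable_count,
                            distances=dist)


def ego_structural_measures(graph: EgoGraph, cents: NodeCentralities,
                            distance_convention: str = "reachable"):
    """(mean betweenness, mean distance) for one ego.

    Mean distance averages geodesic distance over unordered alter pairs.
    Under the default ``"reachable"`` convention unreachable pairs are
    excluded; under ``"penalized"`` they count as ``n_nodes``.  Returns NaN
    mean distance on an edgeless graph.
    """
    n = graph.n_nodes
    mean_b = float(cents.betweenness.mean())
    iu = np.triu_indices(n, k=1)
    pair_d = cents.distances[iu]
    finite = np.isfinite(pair_d)
    if graph.n_edges == 0:
        warnings.warn(f"ego {graph.ego_id}: edgeless network, mean distance undefined")
        return mean_b, float("nan")
    if distance_convention == "reachable":
        mean_d = float(pair_d[finite].mean())
    elif distance_convention == "penalized":
        mean_d = float(np.where(finite, pair_d, float(n)).mean())
    else:
        raise ValueError(f"unknown distance convention {distance_convention!r}")
    return mean_b, mean_d


def central_positions(graph: EgoGraph, cents: NodeCentralities):
    """(most_between, most_close, most_distant) node indices.

    Most between / most close are the betweenness and harmonic-closeness
    argmaxes; most distant is the largest farness among non-isolates.  Ties
    break toward the lowest index; one node may hold several positions.
    Returns ``(-1, -1, -1)`` for an edgeless graph.
    """
    if graph.n_edges == 0:
        return (-1, -1, -1)
    most_between = int(np.argmax(cents.betweenness))
    most_close = int(np.argmax(cents.harmonic_closeness))
    far = np.where(cents.reachable_count > 0, cents.farness, -np.inf)
    most_distant = int(np.argmax(far))
    return (most_between, most_close, most_distant)


def compositional_measures(graph: EgoGraph, positions):
    """(pct_family, pct_central_family) on the [0, 1] scale.

    Each of the three central positions is counted separately even when one
    node holds more than one of them; an edgeless graph (positions ``-1``)
    scores 0 with a warning.
    """
    flags = graph.family_flags
    pct_family = sum(flags) / graph.n_nodes
    if positions[0] < 0:
        warnings.warn(f"ego {graph.ego_id}: no central positions (edgeless graph)")
        return pct_family, 0.0
    pct_central = sum(bool(flags[p]) for p in positions) / 3.0
    return pct_family, pct_central


def measures_for_graph(graph: EgoGraph,
                       distance_convention: str = "reachable") -> EgoMeasures:
    cents = node_centralities(graph)
    mean_b, mean_d = ego_structural_measures(graph, cents, distance_convention)
    positions = central_positions(graph, cents)
    pct_family, pct_central = compositional_measures(graph, positions)
    n_isolates = int((cents.reachable_count == 0).sum())
    return EgoMeasures(ego_id=graph.ego_id, mean_betweenness=mean_b,
                       mean_distance=mean_d, pct_family=pct_family,
                       pct_central_family=pct_central,
                       most_between=positions[0], most_close=positions[1],
                       most_distant=positions[2], n_edges=graph.n_edges,
                       n_isolates=n_isolates)


def family_flags_from_alters(alters: pd.DataFrame) -> dict:
    """Per-ego family flags from the alters table.

    An alter is family when any of its semicolon-joined relationship codes is
    blood family (1), family by marriage (2), or spouse (3).
    """
    def is_family(codes: str) -> bool:
        return any(int(c) in FAMILY_RELATIONSHIP_CODES
                   for c in codes.split(";") if c.strip())

    col = alters["relationship_codes"].astype(str)
    fam_map = {u: is_family(u) for u in col.unique()}
    tmp = pd.DataFrame({"participant_id": alters["participant_id"],
                        "alter_index": alters["alter_index"],
                        "fam": col.map(fam_map)})
    tmp = tmp.sort_values("alter_index", kind="stable")
    return {ego_id: grp["fam"].to_numpy()
            for ego_id, grp in tmp.groupby("participant_id", sort=False)}


def compute_measures_table(ties: pd.DataFrame, alters: pd.DataFrame,
                           threshold: int = 4,
                           distance_convention: str = "reachable") -> pd.DataFrame:
    """One row of network measures per ego, in first-appearance ego order."""
    flags = family_flags_from_alters(alters)
    rows = []
    n_edgeless = n_fragmented = 0
    for ego_id, grp in ties.groupby("participant_id", sort=False):
        if ego_id not in flags:
            raise NetworkValidationError(f"ego {ego_id}: ties present but no alters")
        graph = build_graph(grp, flags[ego_id], threshold=threshold, ego_id=ego_id)
        m = measures_for_graph(graph, distance_convention)
        if m.n_edges == 0:
            n_edgeless += 1
        elif m.n_isolates > 0:
            n_fragmented += 1
        rows.append({
            "participant_id": ego_id,
            "mean_betweenness": m.mean_betweenness,
            "mean_distance": m.mean_distance,
            "pct_family": m.pct_family,
            "pct_central_family": m.pct_central_family,
            "most_between": m.most_between,
            "most_close": m.most_close,
            "most_distant": m.most_distant,
            "n_edges": m.n_edges,
            "n_isolates": m.n_isolates,
        })
    logger.info("computed measures for %d egos (%d edgeless, %d fragmented)",
                len(rows), n_edgeless, n_fragmented)
    return pd.DataFrame(rows)
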