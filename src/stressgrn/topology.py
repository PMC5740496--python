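"""Signed-network topology: core hubs, feed-forward loops, feedback.

Operates on the confirmed network: a directed graph whose edges carry a
sign (+1 activation, −1 repression).  An incoherent feed-forward loop —
direct and indirect paths from the same input to the same output with
opposite net signs — is the motif that, with a delayed inhibitory arm,
produces pulse-like adaptation of the output.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "signed_network",
    "collapse_dynamic_edges",
    "select_core",
    "find_feedforward_loops",
    "find_feedback_cycles",
    "redundancy_metrics",
]


def signed_network(edges: pd.DataFrame, source: str = "source",
                   target: str = "target", sign: str = "sign") -> nx.DiGraph:
    """Build a signed DiGraph from an edge table; duplicate
    (source, target) pairs and signs outside {+1, −1} are rejected."""
    g = nx.DiGraph()
    seen = set()
    for _, e in edges.iterrows():
        key = (e[source], e[target])
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)
        s = int(e[sign])
        if s not in (1, -1):
            raise ValueError(f"edge {key} has sign {s}, expected +1/-1")
        if key[0] == key[1]:
            raise ValueError(f"self-edge {key}")
        g.add_edge(*key, sign=s)
    return g


def collapse_dynamic_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Collapse time-stamped edges to one signed edge per (regulator,
    target), keeping the earliest time's sign."""
    sub = edges.sort_values("time_h", kind="stable")
    first = sub.drop_duplicates(subset=["regulator", "target"], keep="first")
    return pd.DataFrame({"source": first["regulator"].values,
                         "target": first["target"].values,
                         "sign": first["sign"].values})


def select_core(network: nx.DiGraph,
                coverage: float = 0.85) -> tuple[list[str], float]:
    """Greedy hub selection by out-degree until the selected nodes
    account for ``coverage`` of all edges.

    Nodes are added in order of descending out-degree (ties broken
    lexicographically) until the cumulative out-edge count reaches
    coverage × total edges.  Returns (hub list, attained coverage).
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    total = network.number_of_edges()
    if total == 0:
        raise ValueError("empty network")
    ranked = sorted(network.nodes,
                    key=lambda n: (-network.out_degree(n), str(n)))
    selected, covered = [], 0
    for node in ranked:
        if covered >= coverage * total:
            break
        selected.append(node)
        covered += network.out_degree(node)
    return selected, covered / total


def find_feedforward_loops(network: nx.DiGraph) -> pd.DataFrame:
    """All ordered triples (X, Y, Z) with X→Y, Y→Z and X→Z, labelled
    coherent/incoherent by whether the direct sign equals the product
    of the indirect signs."""
    rows = []
    for x, y in network.edges:
        s_xy = network.edges[x, y]["sign"]
        for z in network.successors(y):
            if z == x or not network.has_edge(x, z):
                continue
            s_yz = network.edges[y, z]["sign"]
            s_xz = network.edges[x, z]["sign"]
            rows.append({
                "x": x, "y": y, "z": z,
                "sign_xy": s_xy, "sign_yz": s_yz, "sign_xz": s_xz,
                "coherent": s_xz == s_xy * s_yz,
            })
    return pd.DataFrame(rows,
                        columns=["x", "y", "z", "sign_xy", "sign_yz",
                                 "sign_xz", "coherent"])


def find_feedback_cycles(network: nx.DiGraph,
                         max_len: int = 4) -> pd.DataFrame:
    """All simple directed cycles of length 2..max_len with their net
    sign; net sign −1 is negative feedback."""
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    rows = []
    for cyc in nx.simple_cycles(network, length_bound=max_len):
        if len(cyc) < 2:
            continue
        signs = [network.edges[cyc[i], cyc[(i + 1) % len(cyc)]]["sign"]
                 for i in range(len(cyc))]
        # canonical rotation so the cycle listing is deterministic
        k = int(np.argmin([str(n) for n in cyc]))
        cyc = cyc[k:] + cyc[:k]
        rows.append({"nodes": tuple(cyc), "length": len(cyc),
                     "net_sign": int(np.prod(signs)),
                     "negative_feedback": int(np.prod(signs)) == -1})
    return pd.DataFrame(rows, columns=["nodes", "length", "net_sign",
                                       "negative_feedback"])


def redundancy_metrics(network: nx.DiGraph) -> dict:
    """Degree summaries and shared-target counts.

    Returns in/out degrees, the targets regulated by ≥2 upstream TFs,
    the unregulated nodes (in-degree 0), and for every regulator pair
    the number of shared targets.
    """
    in_deg = pd.Series(dict(network.in_degree()), dtype=int)
    out_deg = pd.Series(dict(network.out_degree()), dtype=int)
    targets = {n: set(network.successors(n)) for n in network.nodes}
    shared = {}
    for a, b in combinations(sorted(network.nodes, key=str), 2):
        k = len(targets[a] & targets[b])
        if k:
            shared[(a, b)] = k
    return {
        "in_degree": in_deg,
        "out_degree": out_deg,
        "multi_regulated": sorted(n for n in network.nodes
                                  if network.in_degree(n) >= 2),
        "n_multi_regulated": sum(1 for n in network.nodes
                                 if network.in_degree(n) >= 2),
        "unregulated": sorted(n for n in network.nodes
                              if network.in_degree(n) == 0),
        "shared_targets": shared,
    }
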