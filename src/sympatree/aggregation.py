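"""Spatial aggregations of communities with significantly low phylogenetic
turnover.

Community pairs whose betaNTI (or betaNRI) exceeds the significance
threshold share more recent evolutionary history than chance predicts.
Linking those pairs and taking connected components yields a partition of
the landscape into "spatial aggregations" — the formal counterpart of
plotting significant pairs on a map and reading off clusters.  Communities
in no significant pair remain singleton aggregations.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import anova_oneway, StatsError

__all__ = [
    "significant_low_pairs",
    "connected_components",
    "within_between_summary",
]


def significant_low_pairs(
    pairs: pd.DataFrame,
    index: str = "beta_nti",
    threshold: float = 1.96,
) -> list[tuple[str, str]]:
    """Edges = community pairs with ``index`` above ``threshold`` (low turnover).

    Pairs flagged degenerate (zero-variance null) are excluded.
    """
    if index not in ("beta_nti", "beta_nri"):
        raise ValueError("index must be 'beta_nti' or 'beta_nri'")
    if index not in pairs.columns:
        raise ValueError(f"pair table lacks column {index!r}")
    mask = pairs[index].to_numpy() > threshold
    deg_col = f"{index}_degenerate"
    if deg_col in pairs.columns:
        mask &= ~pairs[deg_col].to_numpy(dtype=bool)
    return [
        (a, b) for a, b in pairs.loc[mask, ["comm_a", "comm_b"]].itertuples(index=False)
    ]


def connected_components(
    nodes: Sequence[str],
    edges: Sequence[tuple[str, str]],
    names: Optional[Sequence[str]] = None,
) -> dict[str, object]:
    """Partition nodes into undirected connected components.

    Labels are contiguous integers assigned in order of each component's
    smallest member id (or taken from ``names``), so the partition is
    deterministic and invariant to node/edge input order.
    """
    node_set = set(nodes)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for a, b in edges:
        if a not in node_set or b not in node_set:
            raise ValueError(f"edge ({a!r}, {b!r}) names an unknown community")
        graph.add_edge(a, b)
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    if names is not None and len(names) < len(components):
        raise ValueError(f"{len(components)} components but only {len(names)} names")
    partition: dict[str, object] = {}
    for label, comp in enumerate(components):
        value = names[label] if names is not None else label
        for node in comp:
            partition[node] = value
    return partition


def within_between_summary(
    pairs: pd.DataFrame,
    partition: dict[str, object],
    fields: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean +/- sd of pair metrics within and between aggregations.

    One row per (unordered aggregation-label pair, field) with the number of
    community pairs, mean, sd, and a grouping letter from a one-way ANOVA
    across groups (pairwise Welch + Holm at ``alpha``).  Label pairs with no
    community pair are omitted with a warning.
    """
    missing = set(pairs["comm_a"]) | set(pairs["comm_b"]) - set(partition)
    missing -= set(partition)
    if missing:
        raise ValueError(f"communities without aggregation label: {sorted(missing)}")
    la = pairs["comm_a"].map(partition)
    lb = pairs["comm_b"].map(partition)
    key = [tuple(sorted((a, b), key=str)) for a, b in zip(la, lb)]
    key_str = np.array([f"{a}|{b}" for a, b in key], dtype=object)
    work = pairs.assign(_group=key)

    labels = sorted(set(partition.values()), key=str)
    expected = {
        tuple(sorted((x, y), key=str))
        for i, x in enumerate(labels)
        for y in labels[i:]
    }
    present = set(work["_group"])
    for group in sorted(expected - present, key=str):
        warnings.warn(f"aggregation pair {group} has no community pairs")

    rows = []
    for field in fields:
        if field not in work.columns:
            raise ValueError(f"pair table lacks field {field!r}")
        grouped = work.groupby("_group")[field]
        stats = grouped.agg(["count", "mean", "std"])
        try:
            res = anova_oneway(work[field].to_numpy(), key_str, alpha=alpha)
        except StatsError:
            res = None
        for group, row in stats.iterrows():
            gstr = f"{group[0]}|{group[1]}"
            letter = res.letters.get(gstr, "") if res is not None else ""
            rows.append(
                {
                    "group_a": group[0],
                    "group_b": group[1],
                    "within": group[0] == group[1],
                    "field": field,
                    "n_pairs": int(row["count"]),
                    "mean": row["mean"],
                    "sd": row["std"] if row["count"] > 1 else 0.0,
                    "letter": letter,
                }
            )
    return pd.DataFrame(rows)
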