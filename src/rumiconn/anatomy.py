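"""Anatomical decomposition of a prediction network.

Maps a consensus edge mask onto the 7-network parcellation: how many selected
edges fall within or between each pair of networks, and how strongly each ROI
participates (node strength = sum of |edge-behavior r| over incident selected
edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NETWORKS, Parcellation, edge_pairs, n_edges

__all__ = ["PairCountTable", "pair_counts", "node_strengths", "top_nodes"]


@dataclass
class PairCountTable:
    """Symmetric 7x7 intra/inter-network edge counts plus a ranked pair list."""

    counts: pd.DataFrame   # 7x7, index/columns = NETWORKS
    ranked: pd.DataFrame   # columns net_a, net_b, count; descending
    total: int


def _check_mask(mask: np.ndarray, parc: Parcellation) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    expected = n_edges(len(parc))
    if mask.shape != (expected,):
        raise ValueError(
            f"edge mask length {mask.size} does not match the {len(parc)}-ROI "
            f"parcellation ({expected} edges)"
        )
    return mask


def pair_counts(mask: np.ndarray, parc: Parcellation) -> PairCountTable:
    """Count selected edges per intra/inter-network pair.

    Each selected edge (i, j) increments the symmetric cell
    (network(i), network(j)).  The ranked list flattens the 28 unique pairs
    (upper triangle including the diagonal) in descending count order, ties
    broken lexicographically by pair name.
    """
    mask = _check_mask(mask, parc)
    nets = parc.networks
    idx = {net: k for k, net in enumerate(NETWORKS)}
    net_idx = np.array([idx[n] for n in nets])
    i, j = edge_pairs(len(parc))
    counts = np.zeros((7, 7), dtype=int)
    np.add.at(counts, (net_idx[i[mask]], net_idx[j[mask]]), 1)
    counts = counts + counts.T - np.diag(np.diagonal(counts))
    df = pd.DataFrame(counts, index=list(NETWORKS), columns=list(NETWORKS))
    rows = []
    for a in range(7):
        for b in range(a, 7):
            # later network listed first (DMN-SMN, FPCN-VIS, ...), the
            # customary reporting order for network pairs
            rows.append(
                {
                    "net_a": NETWORKS[b],
                    "net_b": NETWORKS[a],
                    "count": int(counts[a, b]),
                }
            )
    ranked = pd.DataFrame(rows)
    ranked["pair"] = ranked["net_a"] + "-" + ranked["net_b"]
    ranked = ranked.sort_values(
        ["count", "pair"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)[["net_a", "net_b", "count"]]
    return PairCountTable(counts=df, ranked=ranked, total=int(mask.sum()))


def node_strengths(
    mask: np.ndarray, edge_r: np.ndarray, parc: Parcellation
) -> pd.DataFrame:
    """Per-ROI strength: sum of |edge-behavior r| over incident selected edges.

    ``edge_r`` is the per-edge correlation used as the edge weight — for a
    consensus network, the mean training-set r across CV iterations.  ROIs
    touching no selected edge get strength 0.  Satisfies the handshake
    identity: the strengths sum to twice the summed |r| of selected edges.
    """
    mask = _check_mask(mask, parc)
    edge_r = np.asarray(edge_r, dtype=float)
    if edge_r.shape != mask.shape:
        raise ValueError("edge_r length must equal mask length")
    i, j = edge_pairs(len(parc))
    strengths = np.zeros(len(parc))
    w = np.abs(edge_r[mask])
    np.add.at(strengths, i[mask], w)
    np.add.at(strengths, j[mask], w)
    out = parc.data[["roi_id", "roi_name", "network"]].copy()
    out["strength"] = strengths
    return out


def top_nodes(strength_table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k ROIs by strength, ties broken by roi_id; k beyond R gives all."""
    if k < 1:
        raise ValueError("k must be at least 1")
    ranked = strength_table.sort_values(
        ["strength", "roi_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ranked.head(k)
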