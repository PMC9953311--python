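"""Hypergeometric over-representation analysis against GMT collections.

Upper-tail (one-sided) hypergeometric p per gene set, computed in
log-space for numerical stability, with Benjamini-Hochberg adjustment
across the tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from cernet.dge import ValidationError, bh_adjust
from cernet.io import read_gmt

logger = logging.getLogger(__name__)


def _log_choose(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log-space.

    N = universe size, K = gene-set size, n = query size, k = overlap.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}"
        )
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = (
        _log_choose(K, i) + _log_choose(N - K, n - i) - _log_choose(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to an explicit background universe.

    Universe defaults to the union of all member genes; sets that become
    empty after restriction are dropped.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(
                *(genes for _, genes in self.sets.values())
            ) if self.sets else frozenset()
        restricted = {}
        for term, (desc, genes) in self.sets.items():
            members = genes & self.universe
            if members:
                restricted[term] = (desc, members)
        self.sets = restricted

    @classmethod
    def from_gmt(cls, path, universe=None) -> "GeneSetCollection":
        return cls(read_gmt(path), frozenset(universe or ()))

    def __len__(self) -> int:
        return len(self.sets)


def enrich(
    query, collection: GeneSetCollection, min_count: int = 2
) -> pd.DataFrame:
    """Over-representation table, one row per set with overlap >= min_count.

    Columns: term, description, count, set_size, query_size, universe_size,
    p, adj_p, genes (comma-joined overlap); sorted by p ascending
    (ties: term id). BH family = all sets clearing min_count.
    """
    query = set(query)
    outside = query - collection.universe
    if outside:
        logger.warning(
            "%d query genes outside the universe dropped", len(outside)
        )
    query &= collection.universe
    if not query:
        raise ValidationError("query is empty after universe restriction")
    N, n = len(collection.universe), len(query)
    rows = []
    for term in sorted(collection.sets):
        desc, genes = collection.sets[term]
        overlap = sorted(query & genes)
        k = len(overlap)
        if k < min_count:
            continue
        p = hypergeom_upper_tail(k, len(genes), n, N)
        rows.append((term, desc, k, len(genes), n, N, p, ",".join(overlap)))
    table = pd.DataFrame(
        rows,
        columns=[
            "term", "description", "count", "set_size",
            "query_size", "universe_size", "p", "genes",
        ],
    )
    table["adj_p"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table = table[
        ["term", "description", "count", "set_size", "query_size",
         "universe_size", "p", "adj_p", "genes"]
    ]
    return table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
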