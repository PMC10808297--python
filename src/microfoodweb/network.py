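"""Thresholded Spearman co-occurrence networks across kingdoms.

An edge joins two genera when the magnitude of their Spearman rank
correlation across samples exceeds ``r_threshold`` (default 0.6) *and* its
p-value is below ``p_threshold`` (default 0.05); the edge sign is the sign
of rho. Genera are first prevalence-filtered (present in at least
``min_samples`` samples, default 3). Within- and between-kingdom pairs are
all eligible; kingdoms are carried as node attributes.

Two p-value methods are offered:

* ``t_approx`` — the usual rho→t transform against a t(n-2) reference,
  matching common tool behavior (and the only way a perfect |rho| = 1 pair
  can clear p < 0.05 at very small n);
* ``exact_smalln`` — permutation p-values: the full n! enumeration for
  n ≤ 8, otherwise seeded Monte-Carlo permutations with the add-one
  correction (valid, slightly conservative).

No multiple-testing correction is applied by default; an optional
Benjamini-Hochberg step is available for principled use.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotatedNematodeTable, CommunityTable, aggregate_trophic_groups

__all__ = [
    "NetworkStats",
    "prevalence_filter",
    "join_kingdoms",
    "spearman_edges",
    "network_summary",
    "to_graph",
    "group_associations",
]

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["source", "target", "rho", "p", "sign", "kingdom_source", "kingdom_target"]

_EXACT_ENUMERATION_MAX_N = 8
_MC_RESAMPLES = 4999


def prevalence_filter(
    table: CommunityTable, min_samples: int = 3, detection_threshold: float = 0.0
) -> CommunityTable:
    """Keep taxa detected (abundance > threshold) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    present = (table.data > detection_threshold).sum(axis=0)
    keep = [t for t in table.taxa if present[t] >= min_samples]
    if not keep:
        raise ValueError(
            f"no taxon present in >= {min_samples} samples; no network possible"
        )
    return table.subset_taxa(keep)


def join_kingdoms(**tables: CommunityTable) -> tuple[pd.DataFrame, dict[str, str]]:
    """Join per-kingdom tables on shared sample IDs.

    Returns the joined samples × taxa frame and a taxon → kingdom map.
    Taxon names must be unique across kingdoms.
    """
    frames = []
    kingdom_of: dict[str, str] = {}
    shared: pd.Index | None = None
    for kingdom, table in tables.items():
        for taxon in table.taxa:
            if taxon in kingdom_of:
                raise ValueError(f"taxon {taxon!r} appears in more than one kingdom")
            kingdom_of[taxon] = kingdom
        shared = table.data.index if shared is None else shared.intersection(table.data.index)
    if shared is None or len(shared) == 0:
        raise ValueError("no shared samples across kingdoms")
    frames = [t.data.loc[shared] for t in tables.values()]
    return pd.concat(frames, axis=1), kingdom_of


def _t_approx_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def _perm_pvalue(rx: np.ndarray, ry: np.ndarray, observed: float, rng: np.random.Generator) -> float:
    """Permutation p-value for |rho| >= |observed| under exchangeability.

    Exact enumeration of all permutations of one margin when n! is small;
    otherwise Monte-Carlo with the +1 correction. Ties are handled
    naturally because the *actual* rank vectors are permuted.
    """
    n = rx.size
    xc = rx - rx.mean()
    sx = math.sqrt((xc**2).sum())
    yc = ry - ry.mean()
    sy = math.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return math.nan
    tol = 1e-12
    target = abs(observed) - tol
    if n <= _EXACT_ENUMERATION_MAX_N:
        perms = np.array(list(itertools.permutations(yc)))
        null = perms @ xc / (sx * sy)
        return float((np.abs(null) >= target).mean())
    perms = rng.permuted(np.tile(yc, (_MC_RESAMPLES, 1)), axis=1)
    null = perms @ xc / (sx * sy)
    exceed = int((np.abs(null) >= target).sum())
    return (exceed + 1.0) / (_MC_RESAMPLES + 1.0)


def spearman_edges(
    joined: pd.DataFrame | CommunityTable,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
    p_method: str = "t_approx",
    kingdoms: dict[str, str] | None = None,
    seed: int = 0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Edge list of all taxon pairs passing |rho| > r and p < alpha.

    Spearman rho is Pearson correlation of mid-rank (average-rank) ranks.
    Pairs involving a constant taxon have undefined rho and are skipped
    with a log entry. ``seed`` only matters for ``exact_smalln`` at n > 8
    (Monte-Carlo permutations). With ``bh_correct`` the p-threshold is
    applied to Benjamini-Hochberg adjusted p-values over all testable
    pairs.
    """
    if p_method not in ("t_approx", "exact_smalln"):
        raise ValueError(f"unknown p_method {p_method!r}")
    data = joined.data if isinstance(joined, CommunityTable) else joined
    taxa = list(data.columns)
    values = data.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to correlate")
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    constant = values.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "skipping %d constant taxa (rho undefined): %s",
            int(constant.sum()),
            ", ".join(t for t, c in zip(taxa, constant) if c),
        )
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    rho_mat = (centered / safe).T @ (centered / safe)

    rng = np.random.default_rng(seed)
    kingdoms = kingdoms or {}
    candidates = []  # (i, j, rho, p)
    for i, j in itertools.combinations(range(len(taxa)), 2):
        if constant[i] or constant[j]:
            continue
        rho = float(np.clip(rho_mat[i, j], -1.0, 1.0))
        if abs(rho) <= r_threshold and not bh_correct:
            continue  # p-value can't rescue a sub-threshold rho; skip the work
        if p_method == "t_approx":
            p = _t_approx_pvalue(rho, n)
        else:
            p = _perm_pvalue(ranks[:, i], ranks[:, j], rho, rng)
        candidates.append((i, j, rho, p))

    if bh_correct and candidates:
        ps = np.array([c[3] for c in candidates])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, ps[idx] * m / (rank_pos + 1))
            adj[idx] = running
        candidates = [
            (i, j, rho, adj_p) for (i, j, rho, _), adj_p in zip(candidates, adj)
        ]

    rows = []
    for i, j, rho, p in candidates:
        if abs(rho) > r_threshold and p < p_threshold:
            rows.append(
                {
                    "source": taxa[i],
                    "target": taxa[j],
                    "rho": rho,
                    "p": p,
                    "sign": "+" if rho > 0 else "-",
                    "kingdom_source": kingdoms.get(taxa[i], ""),
                    "kingdom_target": kingdoms.get(taxa[j], ""),
                }
            )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


@dataclass(frozen=True)
class NetworkStats:
    """Summary counts of a co-occurrence network.

    ``n_nodes`` counts only nodes incident to at least one edge (isolated
    taxa are not part of the graph); ``average_degree`` = 2·links/nodes,
    NaN for an empty network.
    """

    n_nodes: int
    total_links: int
    positive_links: int
    negative_links: int
    average_degree: float


def network_summary(edges: pd.DataFrame) -> NetworkStats:
    """Node/link counts and mean degree of an edge list."""
    total = len(edges)
    positive = int((edges["sign"] == "+").sum()) if total else 0
    negative = total - positive
    nodes = set(edges["source"]) | set(edges["target"]) if total else set()
    n_nodes = len(nodes)
    avg = 2.0 * total / n_nodes if n_nodes else math.nan
    return NetworkStats(
        n_nodes=n_nodes,
        total_links=total,
        positive_links=positive,
        negative_links=negative,
        average_degree=avg,
    )


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    """Edge list → :class:`networkx.Graph` with rho/p/sign edge attributes
    and kingdom node attributes (for GraphML export)."""
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_node(row["source"], kingdom=row["kingdom_source"])
        g.add_node(row["target"], kingdom=row["kingdom_target"])
        g.add_edge(row["source"], row["target"], rho=row["rho"], p=row["p"], sign=row["sign"])
    return g


def group_associations(
    bacteria: CommunityTable,
    fungi: CommunityTable,
    annotated: AnnotatedNematodeTable,
    r_threshold: float | None = None,
    p_threshold: float | None = None,
    p_method: str = "t_approx",
    seed: int = 0,
) -> pd.DataFrame:
    """Signed Spearman associations between group-level totals.

    Groups are total bacteria, total fungi and the four nematode trophic
    groups (BF/FF/PP/OP), joined on shared samples. All pairs are reported
    with rho, p and sign; pairs with a constant margin are NaN. When
    thresholds are given, a boolean ``retained`` column applies the same
    rule as :func:`spearman_edges`.
    """
    groups = aggregate_trophic_groups(annotated)
    totals = pd.DataFrame(
        {
            "bacteria": bacteria.data.sum(axis=1),
            "fungi": fungi.data.sum(axis=1),
        }
    )
    joined = totals.join(groups, how="inner")
    if joined.empty:
        raise ValueError("no shared samples among the three tables")
    n = len(joined)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(joined.columns, 2):
        xa = joined[a].to_numpy()
        xb = joined[b].to_numpy()
        if xa.std() == 0 or xb.std() == 0:
            rho = p = math.nan
        else:
            ra = stats.rankdata(xa)
            rb = stats.rankdata(xb)
            rho = float(np.corrcoef(ra, rb)[0, 1])
            if p_method == "t_approx":
                p = _t_approx_pvalue(rho, n)
            else:
                p = _perm_pvalue(ra, rb, rho, rng)
        row = {
            "group_a": a,
            "group_b": b,
            "rho": rho,
            "p": p,
            "sign": "" if rho != rho else ("+" if rho > 0 else "-" if rho < 0 else "0"),
        }
        if r_threshold is not None and p_threshold is not None:
            row["retained"] = bool(
                rho == rho and abs(rho) > r_threshold and p < p_threshold
            )
        rows.append(row)
    return pd.DataFrame(rows)
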