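"""Consensus co-clustering selection of an optimal barcode-pair panel.

Each barcode pair is scored on several performance metrics per sample
(PCR yield, Hill diversities, evenness, Bray-Curtis distance to a
reference pair).  Within every sample the metric matrix is z-scored,
reduced by PCA and split by k-means (k=2 by default).  Consistency across
samples is summarized by *co-clustering frequencies* — the fraction of
samples in which two pairs land in the same k-means cluster — and the
matrix ``1 - frequency`` is hierarchically clustered (average linkage)
into *metaclusters* of pairs with consistently similar behaviour.

The final panel is a plate grid ``F' x R'`` with ``|F'| * |R'|`` equal to
the requested panel size (96 by default), chosen to maximize the fraction
of its pairs inside the best-performing metacluster while minimizing the
number of unique primers — e.g. 8 forwards x 12 reverses label 96 samples
with only 20 primers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .catalogue import BarcodeCatalogue

__all__ = [
    "METRIC_COLUMNS",
    "pair_id",
    "split_pair_id",
    "assemble_metrics",
    "reduce_and_cluster",
    "co_clustering",
    "metacluster",
    "MetaclusterResult",
    "select_panel",
    "select_barcode_panel",
    "SelectionResult",
]

#: canonical metric order of a performance matrix
METRIC_COLUMNS = ("yield", "q0", "q1", "q2", "J", "Eq1", "Eq2", "bc_ref")

PAIR_SEP = "__"


def pair_id(forward: str, reverse: str) -> str:
    return f"{forward}{PAIR_SEP}{reverse}"


def split_pair_id(pid: str) -> tuple[str, str]:
    f, _, r = pid.partition(PAIR_SEP)
    if not r:
        raise ValueError(f"not a pair id: {pid!r}")
    return f, r


def assemble_metrics(
    yields: Mapping[str, float],
    profiles: pd.DataFrame,
    bc_ref: Mapping[str, float],
    sample: str = "",
) -> pd.DataFrame:
    """Join yield, diversity profile and distance-to-reference per pair.

    All three sources must cover the same pair ids; rows left with any
    missing metric are kept but masked (NaN) with a warning.
    """
    pairs = list(profiles.index)
    for name, src in (("yields", set(yields)), ("bc_ref", set(bc_ref))):
        diff = set(pairs) ^ src
        if diff:
            raise ValueError(f"pair set mismatch between profiles and {name}: {sorted(diff)}")
    df = pd.DataFrame(index=pd.Index(pairs, name="pair_id"), columns=list(METRIC_COLUMNS), dtype=float)
    df["yield"] = [yields[p] for p in pairs]
    for col in ("q0", "q1", "q2", "J", "Eq1", "Eq2"):
        df[col] = profiles[col].astype(float)
    df["bc_ref"] = [bc_ref[p] for p in pairs]
    masked = df.index[df.isna().any(axis=1)]
    if len(masked):
        warnings.warn(f"{len(masked)} pair(s) with missing metrics masked: {list(masked)}", stacklevel=2)
    df.attrs["sample"] = sample
    return df


def reduce_and_cluster(
    M: pd.DataFrame,
    var_target: float = 0.90,
    k: int = 2,
    max_components: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> pd.Series:
    """Z-score, PCA-reduce and k-means-cluster one sample's metric matrix.

    Retains the smallest number of principal components reaching a
    cumulative explained variance of ``var_target`` (capped at
    ``max_components``), then runs k-means with ``n_init`` restarts and a
    fixed seed.  Masked (NaN) rows receive label -1.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    clean = M.dropna(axis=0, how="any")
    if len(clean) < k:
        raise ValueError(f"fewer unmasked rows ({len(clean)}) than clusters ({k})")
    X = clean.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        warnings.warn("all metric columns are constant; single degenerate cluster", stacklevel=2)
        labels = pd.Series(-1, index=M.index, dtype=int)
        labels.loc[clean.index] = 0
        return labels
    dropped = [c for c, k_ in zip(clean.columns, keep) if not k_]
    if dropped:
        warnings.warn(f"dropping zero-variance metric column(s): {dropped}", stacklevel=2)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_max = min(Z.shape[0], Z.shape[1])
    p = PCA(n_components=n_max, random_state=seed)
    scores = p.fit_transform(Z)
    cum = np.cumsum(p.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    n_comp = min(n_comp, max_components, n_max)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    got = km.fit_predict(scores[:, :n_comp])
    labels = pd.Series(-1, index=M.index, dtype=int)
    labels.loc[clean.index] = got
    return labels


def co_clustering(labels_per_sample: Sequence[Mapping[str, int] | pd.Series]) -> pd.DataFrame:
    """Fraction of samples in which each pair of items shares a cluster.

    Items labelled -1 (masked) in a sample do not count for that sample;
    the denominator for (i, j) is the number of samples where both are
    unmasked.  The result is symmetric with unit diagonal.
    """
    if not labels_per_sample:
        raise ValueError("at least one sample is required")
    maps = [pd.Series(m) for m in labels_per_sample]
    items = sorted(set().union(*[set(m.index) for m in maps]))
    n = len(items)
    same = np.zeros((n, n))
    both = np.zeros((n, n))
    idx = {it: i for i, it in enumerate(items)}
    for m in maps:
        present = [it for it in items if it in m.index and m[it] != -1]
        ii = np.array([idx[it] for it in present])
        lab = np.array([m[it] for it in present])
        if len(ii) == 0:
            continue
        eq = (lab[:, None] == lab[None, :]).astype(float)
        both[np.ix_(ii, ii)] += 1.0
        same[np.ix_(ii, ii)] += eq
    if (both == 0).any():
        bad = [(items[i], items[j]) for i, j in zip(*np.where(both == 0)) if i < j]
        raise ValueError(f"item pairs never jointly unmasked in any sample: {bad[:5]}")
    F = same / both
    np.fill_diagonal(F, 1.0)
    return pd.DataFrame(F, index=items, columns=items)


@dataclass
class MetaclusterResult:
    """Average-linkage tree over 1 - co-clustering frequency."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: pd.Series  # metacluster label (0-based) per item
    newick: str

    @property
    def n_meta(self) -> int:
        return int(self.labels.nunique())


def _tree_to_newick(node, names: Sequence[str]) -> str:
    def rec(nd, parent_dist: float) -> str:
        length = max(parent_dist - nd.dist, 0.0)
        if nd.is_leaf():
            return f"{names[nd.id]}:{length:.6g}"
        return f"({rec(nd.left, nd.dist)},{rec(nd.right, nd.dist)}):{length:.6g}"

    return rec(node, node.dist) + ";"


def metacluster(F: pd.DataFrame, n_meta: int = 2) -> MetaclusterResult:
    """Cut the average-linkage tree of ``1 - F`` into ``n_meta`` groups.

    Deterministic for a given matrix; labels are renumbered by first
    occurrence in the item order.
    """
    items = list(F.index)
    if n_meta > len(items):
        raise ValueError(f"n_meta ({n_meta}) exceeds item count ({len(items)})")
    vals = F.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise ValueError("frequency matrix must be symmetric")
    if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if len(items) == 1:
        return MetaclusterResult(
            linkage=np.empty((0, 4)), labels=pd.Series([0], index=items), newick=f"{items[0]}:0;"
        )
    D = 1.0 - vals
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=n_meta, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap)
        labels.append(remap[r])
    newick = _tree_to_newick(to_tree(Z), items)
    return MetaclusterResult(linkage=Z, labels=pd.Series(labels, index=items), newick=newick)


# ---------------------------------------------------------------------------
# Grid selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Full output of the panel-selection pipeline."""

    forward_ids: list[str]
    reverse_ids: list[str]
    grid: list[tuple[str, str]]
    score: float  # fraction of grid pairs in the best metacluster
    best_metacluster: int
    metacluster_labels: pd.Series
    coclustering: Optional[pd.DataFrame] = None
    linkage: Optional[np.ndarray] = None
    newick: str = ""
    labels_per_sample: Optional[dict] = None
    seed: Optional[int] = None
    exhaustive: bool = True

    @property
    def n_primers(self) -> int:
        return len(self.forward_ids) + len(self.reverse_ids)


def _best_metacluster(labels: pd.Series, F: pd.DataFrame, cohesion_tol: float = 0.1) -> int:
    """Metacluster with the highest mean internal co-clustering frequency.

    Cohesion means within ``cohesion_tol`` of the maximum are treated as
    tied, and ties prefer the larger metacluster, then the smaller label.
    The tolerance matters: a small cluster of pairs that fail in a
    *correlated* way is typically tighter than the large well-behaved
    cluster (its members sit far from every k-means boundary), so raw
    cohesion alone would crown exactly the wrong group.  A cohesion gap
    of ~0.1 corresponds to ordinary per-sample label-flip noise, and
    among comparably consistent metaclusters the majority behaviour is
    the robust panel.  Singletons score 1.0.
    """
    means: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for lab in sorted(labels.unique()):
        members = list(labels.index[labels == lab])
        sizes[lab] = len(members)
        if len(members) == 1:
            means[lab] = 1.0
        else:
            sub = F.loc[members, members].to_numpy()
            iu = np.triu_indices(len(members), 1)
            means[lab] = float(sub[iu].mean())
    top = max(means.values())
    tied = [lab for lab, m in means.items() if m >= top - cohesion_tol]
    return int(min(tied, key=lambda lab: (-sizes[lab], lab)))


def _top_k(sums: np.ndarray, ids: Sequence[str], k: int) -> list[int]:
    """Indices of the k largest sums; ties broken by lexicographic id."""
    order = sorted(range(len(ids)), key=lambda i: (-sums[i], ids[i]))
    return sorted(order[:k])


def select_panel(
    meta_labels: pd.Series,
    F: pd.DataFrame,
    cat: BarcodeCatalogue,
    panel_size: int = 96,
    subset_cap: int = 200_000,
    best: Optional[int] = None,
) -> SelectionResult:
    """Choose the plate grid maximizing membership in the best metacluster.

    Enumerates every factorization ``f * r == panel_size`` feasible within
    the catalogue pools.  For each, the optimum over all ``F' x R'`` grids
    is found exactly by enumerating subsets on the side with the fewer
    combinations and picking the complementary side greedily (optimal for
    a fixed subset, since the objective is a submatrix sum).  When the
    subset count exceeds ``subset_cap`` a deterministic alternating greedy
    search is used instead and the result is flagged non-exhaustive.
    Tie-breaks: higher score, then fewer unique primers, then
    lexicographic ids.
    """
    from math import comb

    fids = [p.id for p in cat.forwards]
    rids = [p.id for p in cat.reverses]
    nF, nR = len(fids), len(rids)
    if best is None:
        best = _best_metacluster(meta_labels, F)
    good = np.zeros((nF, nR))
    for i, f in enumerate(fids):
        for j, r in enumerate(rids):
            pid = pair_id(f, r)
            if pid in meta_labels.index and meta_labels[pid] == best:
                good[i, j] = 1.0
    factorizations = [
        (f, panel_size // f)
        for f in range(1, panel_size + 1)
        if panel_size % f == 0 and f <= nF and panel_size // f <= nR
    ]
    if not factorizations:
        raise ValueError(
            f"panel size {panel_size} admits no factorization within pools ({nF}, {nR})"
        )
    incumbent = None  # (-score, n_primers, fids_tuple, rids_tuple, exhaustive)
    for f, r in factorizations:
        n_f_subsets, n_r_subsets = comb(nF, f), comb(nR, r)
        if min(n_f_subsets, n_r_subsets) <= subset_cap:
            exhaustive = True
            if n_f_subsets <= n_r_subsets:
                sel = _exact_grid(good, fids, rids, f, r, enumerate_rows=True)
            else:
                sel = _exact_grid(good, fids, rids, f, r, enumerate_rows=False)
        else:
            exhaustive = False
            sel = _greedy_grid(good, fids, rids, f, r)
        fsel, rsel, hits = sel
        cand = (-hits / panel_size, f + r, tuple(fids[i] for i in fsel), tuple(rids[j] for j in rsel), exhaustive)
        if incumbent is None or cand[:4] < incumbent[:4]:
            incumbent = cand
    neg_score, _, fsel_ids, rsel_ids, exhaustive = incumbent
    grid = [(f, r) for f in fsel_ids for r in rsel_ids]
    return SelectionResult(
        forward_ids=list(fsel_ids),
        reverse_ids=list(rsel_ids),
        grid=grid,
        score=-neg_score,
        best_metacluster=best,
        metacluster_labels=meta_labels,
        coclustering=F,
        exhaustive=exhaustive,
    )


def _exact_grid(good, fids, rids, f, r, enumerate_rows: bool):
    """Exact optimum: enumerate one side, top-k the other."""
    best = None
    if enumerate_rows:
        for rows in itertools.combinations(range(len(fids)), f):
            col_sums = good[list(rows), :].sum(axis=0)
            cols = _top_k(col_sums, rids, r)
            hits = good[np.ix_(list(rows), cols)].sum()
            key = (-hits, tuple(fids[i] for i in rows), tuple(rids[j] for j in cols))
            if best is None or key < best[0]:
                best = (key, list(rows), cols, hits)
    else:
        for cols in itertools.combinations(range(len(rids)), r):
            row_sums = good[:, list(cols)].sum(axis=1)
            rows = _top_k(row_sums, fids, f)
            hits = good[np.ix_(rows, list(cols))].sum()
            key = (-hits, tuple(fids[i] for i in rows), tuple(rids[j] for j in cols))
            if best is None or key < best[0]:
                best = (key, rows, list(cols), hits)
    _, rows, cols, hits = best
    return list(rows), list(cols), float(hits)


def _greedy_grid(good, fids, rids, f, r, max_rounds: int = 10):
    """Deterministic alternating greedy search (large pools only)."""
    rows = _top_k(good.sum(axis=1), fids, f)
    cols = _top_k(good[rows, :].sum(axis=0), rids, r)
    for _ in range(max_rounds):
        new_rows = _top_k(good[:, cols].sum(axis=1), fids, f)
        new_cols = _top_k(good[new_rows, :].sum(axis=0), rids, r)
        if new_rows == rows and new_cols == cols:
            break
        rows, cols = new_rows, new_cols
    hits = good[np.ix_(rows, cols)].sum()
    return rows, cols, float(hits)


def mean_yield_by_domain(yields: pd.DataFrame) -> pd.Series:
    """Mean PCR yield (ng/uL) per primer-set domain.

    Expects columns ``domain`` (e.g. ``archaea``/``bacteria``) and
    ``yield``; libraries with missing yield are excluded.
    """
    for col in ("domain", "yield"):
        if col not in yields.columns:
            raise ValueError(f"missing column {col!r}")
    return yields.dropna(subset=["yield"]).groupby("domain")["yield"].mean()


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def select_barcode_panel(
    metrics_per_sample: Mapping[str, pd.DataFrame],
    cat: BarcodeCatalogue,
    panel_size: int = 96,
    k: int = 2,
    n_meta: int = 2,
    var_target: float = 0.90,
    max_components: int = 3,
    seed: int = 0,
    mode: str = "per_sample",
    subset_cap: int = 200_000,
    best: Optional[int] = None,
) -> SelectionResult:
    """Run PCA + k-means, co-clustering, metaclustering and grid selection.

    ``mode="per_sample"`` (default) clusters every sample separately and
    aggregates agreement into co-clustering frequencies; ``mode="pooled"``
    stacks all samples' rows into one matrix and clusters once.
    """
    if not metrics_per_sample:
        raise ValueError("at least one sample's metrics are required")
    samples = sorted(metrics_per_sample)
    labels_per_sample: dict[str, pd.Series] = {}
    if mode == "per_sample":
        for i, s in enumerate(samples):
            labels_per_sample[s] = reduce_and_cluster(
                metrics_per_sample[s], var_target=var_target, k=k,
                max_components=max_components, seed=seed + i,
            )
    elif mode == "pooled":
        stacked = pd.concat(
            [metrics_per_sample[s].rename(index=lambda p, s=s: f"{s}::{p}") for s in samples]
        )
        pooled = reduce_and_cluster(
            stacked, var_target=var_target, k=k, max_components=max_components, seed=seed
        )
        for s in samples:
            prefix = f"{s}::"
            sub = pooled[pooled.index.str.startswith(prefix)]
            sub.index = [p[len(prefix):] for p in sub.index]
            labels_per_sample[s] = sub
    else:
        raise ValueError(f"unknown mode {mode!r}")
    F = co_clustering([labels_per_sample[s] for s in samples])
    mres = metacluster(F, n_meta=n_meta)
    result = select_panel(mres.labels, F, cat, panel_size=panel_size,
                          subset_cap=subset_cap, best=best)
    result.linkage = mres.linkage
    result.newick = mres.newick
    result.labels_per_sample = labels_per_sample
    result.seed = seed
    return result
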