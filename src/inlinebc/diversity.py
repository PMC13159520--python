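"""Diversity, evenness, rarefaction, Bray-Curtis distances and PCoA.

Alpha diversity uses the Hill-number framework, which expresses diversity
of any order ``q`` as an effective number of equally abundant taxa:

    D_q = (sum_i p_i^q)^(1/(1-q))        for q != 1
    D_1 = exp(-sum_i p_i ln p_i)          (the q -> 1 limit)

``q=0`` is richness, ``q=1`` the exponential of Shannon entropy, ``q=2``
the inverse Simpson index.  Evenness is reported both as Pielou's
``J = H / ln S`` and as the Hill ratios ``Eq1 = D_1/D_0``, ``Eq2 = D_2/D_0``.
Beta diversity uses Bray-Curtis dissimilarity and classical principal
coordinates; library depth is standardized beforehand by seeded
rarefaction (sampling without replacement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

__all__ = [
    "AbundanceTable",
    "hill_number",
    "pielou",
    "diversity_profile",
    "rarefy",
    "bray_curtis",
    "bc_to_reference",
    "pcoa",
    "PCoAResult",
]


@dataclass
class AbundanceTable:
    """Nonnegative integer feature x library count matrix plus metadata.

    ``counts`` is features x libraries; ``metadata`` (optional) is indexed
    by library id with columns such as sample, forward_id, reverse_id and
    protocol.
    """

    counts: pd.DataFrame
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate library ids")
        if self.metadata is not None:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"libraries missing from metadata: {sorted(missing)}")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, counts_path: str | Path, metadata_path: Optional[str | Path] = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        if metadata_path is not None and self.metadata is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="library_id")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, metadata_path: Optional[str | Path] = None
    ) -> "AbundanceTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = (
            pd.read_csv(metadata_path, sep="\t", index_col=0)
            if metadata_path is not None
            else None
        )
        return cls(counts=counts, metadata=meta)


def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = x / total
    return p[p > 0]


def hill_number(counts, q: float) -> float:
    """Effective number of taxa of order ``q`` (see module docstring)."""
    if q < 0:
        raise ValueError("q must be >= 0")
    p = _proportions(counts)
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def pielou(counts) -> float:
    """Pielou's evenness J = H / ln S; NaN for a single-taxon library."""
    p = _proportions(counts)
    s = len(p)
    if s == 1:
        return float("nan")
    h = -np.sum(p * np.log(p))
    return float(h / np.log(s))


def diversity_profile(table: AbundanceTable) -> pd.DataFrame:
    """Per-library q0, q1, q2, Pielou J and Hill evenness Eq1, Eq2."""
    rows = {}
    for lib in table.libraries:
        c = table.counts[lib].to_numpy()
        q0, q1, q2 = (hill_number(c, q) for q in (0, 1, 2))
        rows[lib] = {
            "q0": q0, "q1": q1, "q2": q2, "J": pielou(c),
            "Eq1": q1 / q0, "Eq2": q2 / q0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample every library without replacement to exactly ``depth`` reads.

    Libraries shallower than ``depth`` are dropped with a warning.  The
    draw is multivariate hypergeometric and fully determined by ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    depths = table.depths()
    keep = [lib for lib in table.libraries if depths[lib] >= depth]
    dropped = [lib for lib in table.libraries if depths[lib] < depth]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} librar{'y' if len(dropped) == 1 else 'ies'} "
            f"below depth {depth}: {dropped}",
            stacklevel=2,
        )
    out = {}
    for lib in keep:
        col = table.counts[lib].to_numpy().astype(np.int64)
        out[lib] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index)
    meta = table.metadata.loc[keep] if table.metadata is not None else None
    return AbundanceTable(counts=counts, metadata=meta)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.sum() + y.sum() <= 0:
        raise ValueError("both vectors are all-zero")
    return float(_scipy_braycurtis(x, y))


def bc_to_reference(
    table: AbundanceTable,
    reference: Optional[str] = None,
    seed: Optional[int] = None,
) -> tuple[dict, str]:
    """Bray-Curtis distance of each library to a reference library.

    The reference is either named or drawn uniformly (seed-deterministic)
    from the table's libraries; it is returned alongside the distances so
    the choice is always logged.
    """
    libs = table.libraries
    if len(libs) < 2:
        raise ValueError("at least two libraries are required")
    if reference is None:
        rng = np.random.default_rng(seed)
        reference = libs[int(rng.integers(len(libs)))]
    elif reference not in libs:
        raise KeyError(f"reference library {reference!r} not in table")
    ref = table.counts[reference].to_numpy()
    return (
        {lib: bray_curtis(table.counts[lib].to_numpy(), ref) for lib in libs},
        reference,
    )


@dataclass
class PCoAResult:
    """Classical-scaling embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame  # objects x retained axes
    proportion_explained: np.ndarray  # over positive eigenvalues, non-increasing
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    negative_eigenvalue_magnitude: float  # sum |negative eigenvalues| dropped


def pcoa(D, ids: Optional[Sequence[str]] = None, atol: float = 1e-8) -> PCoAResult:
    """Principal coordinates (classical metric scaling) of a distance matrix.

    Double-centers ``B = -1/2 J (D*D) J``, eigendecomposes, keeps the
    positive eigenvalues and scales eigenvectors by their square roots.
    Negative eigenvalues (non-Euclidean input) are dropped; their summed
    magnitude is reported.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=atol):
        raise ValueError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=atol):
        raise ValueError("D must have a zero diagonal")
    n = D.shape[0]
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > atol * max(1.0, abs(vals[0]) if n else 1.0)
    neg_mag = float(np.abs(vals[vals < 0]).sum())
    vals_pos, vecs_pos = vals[pos], vecs[:, pos]
    coords = vecs_pos * np.sqrt(vals_pos)
    frac = vals_pos / vals_pos.sum() if vals_pos.size else vals_pos
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        proportion_explained=frac,
        eigenvalues=vals_pos,
        negative_eigenvalue_magnitude=neg_mag,
    )
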