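"""Barcode-recovery statistics: observed vs theoretical read shares.

When every sample is pooled at equal input, reads are expected to spread
uniformly over the valid barcode categories — 1/N per forward barcode,
reverse barcode or pair — while the *unknown* category (reads whose tag
could not be called) has a theoretical share of 0.  Observed shares are
computed over all reads including unknowns, so that unknown-rate and
per-barcode bias can be read off the same table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalogue import BarcodeCatalogue
from .demux import UNKNOWN, DemuxReport

__all__ = [
    "theoretical_proportions",
    "observed_proportions",
    "summarize_across_samples",
    "normalized_pair_ratios",
    "chi_square_uniformity",
    "RecoverySummary",
]

_LEVELS = ("forward", "reverse", "pair")


def _categories(cat: BarcodeCatalogue, level: str) -> list:
    if level == "forward":
        return [p.id for p in cat.forwards]
    if level == "reverse":
        return [p.id for p in cat.reverses]
    if level == "pair":
        return cat.enumerate_pairs()
    raise ValueError(f"level must be one of {_LEVELS}, got {level!r}")


def theoretical_proportions(cat: BarcodeCatalogue, level: str) -> dict:
    """Uniform expectation 1/N per valid category; 0 for ``unknown``."""
    cats = _categories(cat, level)
    n = len(cats)
    if n == 0:
        raise ValueError(f"catalogue has no categories at level {level!r}")
    out = {c: 1.0 / n for c in cats}
    out[UNKNOWN] = 0.0
    return out


def observed_proportions(report: DemuxReport, level: str) -> dict:
    """Observed read share per category, unknowns included in the total.

    At the ``forward``/``reverse`` level a mate contributes to its own
    marginal even when the other mate is unknown; at the ``pair`` level
    any pair with an unknown member is pooled into ``unknown``.
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}, got {level!r}")
    if report.total <= 0:
        raise ValueError("cannot compute proportions of a zero-read report")
    acc: dict = {}
    for (f, r), n in report.counts.items():
        if level == "forward":
            key = f
        elif level == "reverse":
            key = r
        else:
            key = (f, r) if (f != UNKNOWN and r != UNKNOWN) else UNKNOWN
        acc[key] = acc.get(key, 0) + n
    return {k: v / report.total for k, v in acc.items()}


@dataclass
class RecoverySummary:
    """Mean +- SD of observed shares across samples, vs theory."""

    table: pd.DataFrame  # columns: category, theoretical, mean_observed, sd_observed, flag
    n_samples: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarize_across_samples(
    per_sample: Sequence[Mapping],
    theoretical: Optional[Mapping] = None,
) -> RecoverySummary:
    """Summarize observed category shares over samples.

    SD uses the sample (n-1) denominator; with a single sample SD is
    reported as 0 with a warning.  A category is flagged as deviating when
    ``|mean - theoretical| > 2 * SD``.
    """
    if not per_sample:
        raise ValueError("at least one sample is required")
    keys = set(per_sample[0])
    for i, m in enumerate(per_sample[1:], 2):
        if set(m) != keys:
            raise ValueError(f"sample {i} has a different category set")
    n = len(per_sample)
    if n == 1:
        warnings.warn("single sample: SD reported as 0", stacklevel=2)
    rows = []
    for cat in sorted(keys, key=str):
        vals = np.array([m[cat] for m in per_sample], dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        theo = float(theoretical[cat]) if theoretical is not None and cat in theoretical else np.nan
        flag = bool(not math.isnan(theo) and abs(mean - theo) > 2 * sd)
        rows.append(
            {"category": cat, "theoretical": theo, "mean_observed": mean,
             "sd_observed": sd, "flag": flag}
        )
    return RecoverySummary(table=pd.DataFrame(rows), n_samples=n)


def normalized_pair_ratios(
    report: DemuxReport, cat: BarcodeCatalogue, tested_fraction: float = 1.0
) -> dict:
    """Observed/expected read ratio per pair, corrected for partial panels.

    When only a fraction of the catalogue's pairs was actually run, each
    tested pair soaks up ``1/tested_fraction`` times its nominal share, so
    raw observed/theoretical ratios are multiplied by ``tested_fraction``;
    a ratio of 1.0 then means exactly the expected representation.
    """
    if not 0.0 < tested_fraction <= 1.0:
        raise ValueError("tested_fraction must be in (0, 1]")
    theo = theoretical_proportions(cat, "pair")
    obs = observed_proportions(report, "pair")
    return {
        pair: (obs.get(pair, 0.0) / theo[pair]) * tested_fraction
        for pair in cat.enumerate_pairs()
    }


def chi_square_uniformity(report: DemuxReport, cat: BarcodeCatalogue, level: str):
    """Chi-square test of uniformity over valid categories (unknowns excluded).

    Descriptive helper only; the core recovery summary is deliberately
    test-free.
    """
    from scipy import stats

    obs = observed_proportions(report, level)
    cats = _categories(cat, level)
    counts = np.array([obs.get(c, 0.0) for c in cats]) * report.total
    return stats.chisquare(counts)
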