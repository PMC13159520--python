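"""Synthetic barcoded amplicon reads and planted-structure metric tables.

The read generator emulates the dual in-line tagging design: each read
pair carries ``leader + barcode + primer`` on both mates (forward
construct on mate 1, reverse on mate 2) followed by an amplicon fragment
drawn from a mock community.  Substitution/insertion/deletion errors are
injected per base, independently for the tag construct and the amplicon,
and *tag jumping* — a read acquiring another sample's reverse barcode —
is modelled as a seeded reverse-barcode swap.  Every read is logged in a
truth table, so demultiplexing accuracy can be scored exactly.

The metric generator plants a good/bad partition of barcode pairs into
per-sample performance tables, providing ground truth for the
panel-selection pipeline.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalogue import DEFAULT_LEADER, BarcodeCatalogue, BarcodedPrimer, hamming
from .selection import METRIC_COLUMNS, pair_id

__all__ = [
    "PRIMER_338F",
    "PRIMER_785R",
    "PRIMER_519F",
    "PRIMER_915R",
    "ErrorRates",
    "SimulationPlan",
    "random_catalogue",
    "simulate_community",
    "generate_reads",
    "planted_metrics",
    "write_fastq",
]

BASES = "ACGT"

# widely used 16S primer pairs: V3-V4 (bacteria) and V4-V5 (archaea)
PRIMER_338F = "ACTCCTACGGGAGGCAGCAG"
PRIMER_785R = "GACTACHVGGGTATCTAATCC"
PRIMER_519F = "CAGCMGCCGCGGTAA"
PRIMER_915R = "GTGCTCCCCCGCCAATTCCT"


@dataclass(frozen=True)
class ErrorRates:
    """Per-base substitution / insertion / deletion probabilities."""

    substitution: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("substitution", "insertion", "deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate must be in [0, 1]")

    @property
    def any(self) -> bool:
        return self.substitution > 0 or self.insertion > 0 or self.deletion > 0


def random_catalogue(
    n_forward: int,
    n_reverse: int,
    seed: int,
    barcode_length: int = 8,
    min_distance: int = 3,
    leader: str = DEFAULT_LEADER,
    forward_primer: str = PRIMER_519F,
    reverse_primer: str = PRIMER_915R,
) -> BarcodeCatalogue:
    """Seeded catalogue with well-separated random barcodes.

    Barcodes are drawn uniformly and accepted only when at least
    ``min_distance`` Hamming mismatches from every accepted barcode of the
    same direction, so demultiplexer safety margins are controllable.
    """
    rng = np.random.default_rng(seed)

    def draw(n: int) -> list[str]:
        chosen: list[str] = []
        attempts = 0
        while len(chosen) < n:
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError("cannot satisfy the separation constraint; lower min_distance")
            bc = "".join(BASES[i] for i in rng.integers(0, 4, size=barcode_length))
            if all(hamming(bc, other) >= min_distance for other in chosen):
                chosen.append(bc)
        return chosen

    forwards = [
        BarcodedPrimer(id=f"Forward_Sim_{i + 1}", direction="forward", barcode=bc,
                       primer=forward_primer, leader=leader)
        for i, bc in enumerate(draw(n_forward))
    ]
    reverses = [
        BarcodedPrimer(id=f"Reverse_Sim_{i + 1}", direction="reverse", barcode=bc,
                       primer=reverse_primer, leader=leader)
        for i, bc in enumerate(draw(n_reverse))
    ]
    return BarcodeCatalogue(forwards=forwards, reverses=reverses)


def simulate_community(
    S: int,
    preset: str = "even",
    seed: int = 0,
    alpha: float = 1.0,
    amplicon_length: int = 447,
) -> tuple[np.ndarray, list[str]]:
    """Mock community: abundance vector plus random template sequences.

    ``even`` gives 1/S per taxon (mirroring defined mock standards such as
    a 21-strain gut community), ``staggered`` log-spaced abundances over
    two decades, ``dirichlet`` a single seeded Dirichlet(alpha) draw.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    if preset == "even":
        p = np.full(S, 1.0 / S)
    elif preset == "staggered":
        raw = np.logspace(0, -2, S)
        p = raw / raw.sum()
    elif preset == "dirichlet":
        p = rng.dirichlet(np.full(S, alpha))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    templates = [
        "".join(BASES[i] for i in rng.integers(0, 4, size=amplicon_length)) for _ in range(S)
    ]
    return p, templates


@dataclass
class SimulationPlan:
    """Everything needed to generate a deterministic synthetic run."""

    catalogue: BarcodeCatalogue
    reads_per_pair: Union[int, Mapping[tuple[str, str], int]] = 100
    abundances: Optional[np.ndarray] = None
    templates: Optional[list[str]] = None
    tag_rates: ErrorRates = field(default_factory=ErrorRates)
    amplicon_rates: ErrorRates = field(default_factory=ErrorRates)
    tag_jump_rate: float = 0.0
    read_length: int = 300
    quality_phred: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tag_jump_rate <= 1.0:
            raise ValueError("tag_jump_rate must be in [0, 1]")
        if self.abundances is None or self.templates is None:
            p, t = simulate_community(5, "even", seed=self.seed)
            self.abundances = p if self.abundances is None else self.abundances
            self.templates = t if self.templates is None else self.templates
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.abundances) != len(self.templates):
            raise ValueError("abundances and templates must have equal length")
        if not np.isclose(self.abundances.sum(), 1.0):
            raise ValueError("abundances must sum to 1")

    def counts_per_pair(self) -> dict[tuple[str, str], int]:
        pairs = self.catalogue.enumerate_pairs()
        if isinstance(self.reads_per_pair, int):
            return {p: self.reads_per_pair for p in pairs}
        return {p: int(self.reads_per_pair.get(p, 0)) for p in pairs}


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _mutate(seq: str, rates: ErrorRates, rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply per-base errors; returns (sequence, substitutions, indels)."""
    if not rates.any:
        return seq, 0, 0
    out: list[str] = []
    subs = indels = 0
    for ch in seq:
        if rates.insertion and rng.random() < rates.insertion:
            out.append(BASES[int(rng.integers(4))])
            indels += 1
        if rates.deletion and rng.random() < rates.deletion:
            indels += 1
            continue
        if rates.substitution and rng.random() < rates.substitution:
            out.append(BASES[(BASES.index(ch) + 1 + int(rng.integers(3))) % 4] if ch in BASES else ch)
            subs += 1
        else:
            out.append(ch)
    return "".join(out), subs, indels


def _build_mate(
    primer: BarcodedPrimer,
    fragment: str,
    plan: SimulationPlan,
    rng: np.random.Generator,
) -> tuple[str, int, int, int]:
    """One mate: mutated construct + mutated amplicon, truncated to read length.

    Returns (sequence, barcode substitutions, barcode indels, other edits).
    """
    leader, lsub, lind = _mutate(primer.leader, plan.tag_rates, rng)
    barcode, bsub, bind = _mutate(primer.barcode, plan.tag_rates, rng)
    pseq, psub, pind = _mutate(primer.primer, plan.tag_rates, rng)
    frag, asub, aind = _mutate(fragment, plan.amplicon_rates, rng)
    seq = (leader + barcode + pseq + frag)[: plan.read_length]
    other = lsub + lind + psub + pind + asub + aind
    return seq, bsub, bind, int(other)


def generate_reads(
    plan: SimulationPlan,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], pd.DataFrame]:
    """Generate paired reads plus their ground-truth table.

    Returns ``(mate1_records, mate2_records, truth)`` where records are
    ``(id, sequence, quality)`` triples and ``truth`` holds the intended
    pair, the emitted reverse barcode (after any tag jump), the taxon and
    injected barcode edits per mate.  Identical plans and seeds produce
    byte-identical output.
    """
    rng = np.random.default_rng(plan.seed)
    counts = plan.counts_per_pair()
    if all(n == 0 for n in counts.values()):
        raise ValueError("reads_per_pair is zero for every pair")
    qual_char = chr(plan.quality_phred + 33)
    rids_all = [p.id for p in plan.catalogue.reverses]
    r1, r2, truth = [], [], []
    idx = 0
    for (fid, rid), n in counts.items():
        if n == 0:
            continue
        fwd = plan.catalogue.forward_by_id(fid)
        taxa = rng.choice(len(plan.abundances), size=n, p=plan.abundances)
        for t in taxa:
            idx += 1
            read_id = f"sim_{idx:08d}"
            template = plan.templates[int(t)]
            jumped = plan.tag_jump_rate > 0 and len(rids_all) > 1 and rng.random() < plan.tag_jump_rate
            if jumped:
                others = [x for x in rids_all if x != rid]
                emitted_rid = others[int(rng.integers(len(others)))]
            else:
                emitted_rid = rid
            rev = plan.catalogue.reverse_by_id(emitted_rid)
            s1, bs1, bi1, o1 = _build_mate(fwd, template, plan, rng)
            s2, bs2, bi2, o2 = _build_mate(rev, _revcomp(template), plan, rng)
            r1.append((read_id, s1, qual_char * len(s1)))
            r2.append((read_id, s2, qual_char * len(s2)))
            truth.append(
                {
                    "read_id": read_id, "forward_id": fid, "reverse_id": rid,
                    "emitted_reverse_id": emitted_rid, "taxon": int(t),
                    "tag_jump": bool(jumped),
                    "subs_barcode_1": bs1, "indels_barcode_1": bi1,
                    "subs_barcode_2": bs2, "indels_barcode_2": bi2,
                    "other_edits_1": o1, "other_edits_2": o2,
                }
            )
    return r1, r2, pd.DataFrame(truth)


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, seq, qual) records as FASTQ; .gz suffix enables gzip."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Planted performance structure for the selection pipeline
# ---------------------------------------------------------------------------

#: plausible per-metric baselines (mean, SD) for a well-behaved pair:
#: moderate PCR yield in ng/uL, mock-like richness and Hill diversities,
#: high evenness, small distance to the reference pair
_METRIC_BASELINES = {
    "yield": (30.0, 5.0),
    "q0": (25.0, 3.0),
    "q1": (5.25, 0.6),
    "q2": (4.5, 0.5),
    "J": (0.85, 0.05),
    "Eq1": (0.21, 0.03),
    "Eq2": (0.18, 0.03),
    "bc_ref": (0.15, 0.05),
}


def planted_metrics(
    pairs: Union[int, Sequence[str]],
    n_samples: int = 6,
    bad_fraction: float = 0.25,
    effect_size_sd: float = 3.0,
    seed: int = 0,
    bad_pairs: Optional[Sequence[str]] = None,
    shifted_metrics: Sequence[str] = ("q1", "bc_ref"),
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Per-sample metric tables with a planted good/bad pair partition.

    Good pairs draw every metric from a common Gaussian baseline; bad
    pairs are shifted by ``effect_size_sd`` pooled SDs on the designated
    metrics.  The default of six samples mirrors a typical evaluation
    layout of three source communities, each prepared under two library
    protocols.  Returns the tables keyed by sample name and the truth
    labels (0 = good, 1 = bad).
    """
    if isinstance(pairs, int):
        if pairs < 2:
            raise ValueError("at least two pairs are required")
        pair_ids = [f"P{i:03d}" for i in range(pairs)]
    else:
        pair_ids = list(pairs)
        if len(pair_ids) < 2:
            raise ValueError("at least two pairs are required")
    if not 0.0 <= bad_fraction < 1.0:
        raise ValueError("bad_fraction must be in [0, 1)")
    unknown = set(shifted_metrics) - set(METRIC_COLUMNS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    if bad_pairs is None:
        n_bad = int(round(bad_fraction * len(pair_ids)))
        bad_set = set(
            np.array(pair_ids)[rng.permutation(len(pair_ids))[:n_bad]].tolist()
        )
    else:
        bad_set = set(bad_pairs)
        missing = bad_set - set(pair_ids)
        if missing:
            raise ValueError(f"bad_pairs not in pair set: {sorted(missing)}")
    labels = pd.Series([1 if p in bad_set else 0 for p in pair_ids], index=pair_ids)
    tables = {}
    for s in range(n_samples):
        df = pd.DataFrame(index=pd.Index(pair_ids, name="pair_id"),
                          columns=list(METRIC_COLUMNS), dtype=float)
        for m in METRIC_COLUMNS:
            mu, sd = _METRIC_BASELINES[m]
            vals = rng.normal(mu, sd, size=len(pair_ids))
            if m in shifted_metrics:
                vals = vals + labels.to_numpy() * effect_size_sd * sd
            df[m] = vals
        tables[f"sample_{s + 1}"] = df
    return tables, labels
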