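"""Error-tolerant paired-end demultiplexing of in-line barcoded reads.

Every mate of a read pair is expected to start with ``leader + barcode +
primer`` (forward construct on mate 1, reverse construct on mate 2).  A
pair is assigned to a (forward, reverse) barcode pair when both mates
yield an unambiguous barcode call within the configured error tolerance;
otherwise the offending mate is recorded as *unknown*.

Matching is sequence-only (base qualities are never consulted).  The
leader is anchored at position 0 and matched exactly by default; the full
barcode must always be aligned (no partial-prefix matches), with either a
Hamming budget (substitutions only) or separate substitution and indel
budgets when indel tolerance is enabled.  Ties between two catalogue
barcodes at the minimal admissible distance are never broken arbitrarily:
the call is *unknown*, so ambiguous reads can never leak into the wrong
sample.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import pandas as pd

from .catalogue import IUPAC, BarcodeCatalogue, BarcodedPrimer

__all__ = [
    "UNKNOWN",
    "DemuxConfig",
    "DemuxAssignment",
    "DemuxReport",
    "MODE_ORDER",
    "config_for_mode",
    "strip_leader",
    "match_barcode",
    "trim_primer",
    "demultiplex",
    "run_mode_panel",
    "read_fastq_pairs",
    "ReadPair",
]

UNKNOWN = "unknown"

#: canonical stringency ladder, loosest last
MODE_ORDER = ("0err", "1err", "1err+indel", "2err", "2err+indel")


@dataclass(frozen=True)
class DemuxConfig:
    """Demultiplexing tolerances.

    ``max_substitutions`` bounds barcode substitutions (0-2);
    ``allow_indels`` adds a separate indel budget of ``max_indels``.
    Substitutions and indels are budgeted independently, not as a single
    edit total.  ``min_overlap`` is the number of barcode bases that must
    be covered; the default equals the barcode length, i.e. the whole
    barcode must be matched.  Primer trimming tolerates up to
    ``floor(primer_error_rate * |primer|)`` mismatches, with IUPAC
    degeneracy counted as a match.
    """

    max_substitutions: int = 1
    allow_indels: bool = False
    max_indels: int = 1
    leader_policy: str = "anchored_exact"  # or "anchored_tolerant"
    leader_max_mismatches: int = 0
    min_overlap: int = 8
    primer_error_rate: float = 0.10
    on_primer_fail: str = "keep_flagged"  # or "reject"

    def __post_init__(self) -> None:
        if self.max_substitutions not in (0, 1, 2):
            raise ValueError("max_substitutions must be in {0, 1, 2}")
        if self.max_indels < 0:
            raise ValueError("max_indels must be >= 0")
        if self.leader_policy not in ("anchored_exact", "anchored_tolerant"):
            raise ValueError(f"unknown leader_policy {self.leader_policy!r}")
        if not 0.0 <= self.primer_error_rate <= 1.0:
            raise ValueError("primer_error_rate must be in [0, 1]")
        if self.on_primer_fail not in ("keep_flagged", "reject"):
            raise ValueError(f"unknown on_primer_fail {self.on_primer_fail!r}")

    @property
    def mode_label(self) -> str:
        label = f"{self.max_substitutions}err"
        if self.allow_indels:
            label += "+indel"
        return label


def config_for_mode(mode: str, **overrides) -> DemuxConfig:
    """Build a config from a stringency label such as ``"1err+indel"``."""
    base = mode.split("+")
    if not base[0].endswith("err") or not base[0][:-3].isdigit():
        raise ValueError(f"unknown mode label {mode!r}")
    kwargs = dict(
        max_substitutions=int(base[0][:-3]),
        allow_indels=len(base) > 1 and base[1] == "indel",
    )
    kwargs.update(overrides)
    return DemuxConfig(**kwargs)


class ReadPair(NamedTuple):
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class DemuxAssignment:
    """Per-read-pair barcode calls, error accounting and trimmed mates."""

    read_id: str
    forward_call: str  # catalogue id or UNKNOWN
    reverse_call: str
    errors_f: tuple[int, int] = (0, 0)  # (substitutions, indels)
    errors_r: tuple[int, int] = (0, 0)
    primer_trimmed_f: bool = False
    primer_trimmed_r: bool = False
    trimmed_seq1: str = ""
    trimmed_qual1: str = ""
    trimmed_seq2: str = ""
    trimmed_qual2: str = ""

    @property
    def assigned(self) -> bool:
        return self.forward_call != UNKNOWN and self.reverse_call != UNKNOWN


@dataclass
class DemuxReport:
    """Per-(forward, reverse) read tallies for one stringency mode.

    Cells keyed by catalogue ids, with ``unknown`` rows/columns for mates
    that could not be called; cell counts always sum to the number of
    input read pairs.
    """

    counts: dict[tuple[str, str], int]
    total: int
    mode: str

    @property
    def assigned_reads(self) -> int:
        return sum(
            n for (f, r), n in self.counts.items() if f != UNKNOWN and r != UNKNOWN
        )

    @property
    def assigned_fraction(self) -> float:
        return self.assigned_reads / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mode": self.mode,
                "forward_id": f,
                "reverse_id": r,
                "reads": n,
                "fraction": n / self.total if self.total else 0.0,
            }
            for (f, r), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["mode", "forward_id", "reverse_id", "reads", "fraction"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DemuxReport":
        df = pd.read_csv(path, sep="\t", dtype={"forward_id": str, "reverse_id": str})
        counts = {
            (row.forward_id, row.reverse_id): int(row.reads) for row in df.itertuples()
        }
        mode = str(df["mode"].iloc[0]) if len(df) else "unknown"
        return cls(counts=counts, total=sum(counts.values()), mode=mode)


# ---------------------------------------------------------------------------
# Matching primitives
# ---------------------------------------------------------------------------

def strip_leader(seq: str, leader: str, cfg: DemuxConfig) -> Optional[str]:
    """Remove an anchored leader; ``None`` signals NOT_FOUND."""
    if len(seq) < len(leader):
        return None
    head = seq[: len(leader)]
    if cfg.leader_policy == "anchored_exact":
        return seq[len(leader):] if head == leader else None
    mism = sum(a != b for a, b in zip(head, leader))
    return seq[len(leader):] if mism <= cfg.leader_max_mismatches else None


def _bounded_alignment(
    barcode: str, window: str, max_sub: int, max_ind: int
) -> Optional[tuple[int, int, int]]:
    """Best alignment of the whole barcode onto a prefix of ``window``.

    Substitutions and indels are budgeted separately.  Returns
    ``(substitutions, indels, end)`` of the alignment minimizing total
    edits (ties: fewer indels, then end closest to the barcode length),
    or ``None`` if no alignment fits both budgets.
    """
    L = len(barcode)
    W = min(len(window), L + max_ind)
    if W < L - max_ind:
        return None
    INF = 10**6
    # dp[j][d] = min substitutions aligning the consumed barcode prefix to
    # window[:j] using d indels
    dp = [[INF] * (max_ind + 1) for _ in range(W + 1)]
    dp[0][0] = 0
    for j in range(1, min(max_ind, W) + 1):  # leading extra window bases
        dp[j][j] = 0
    for i in range(1, L + 1):
        ndp = [[INF] * (max_ind + 1) for _ in range(W + 1)]
        for j in range(W + 1):
            for d in range(max_ind + 1):
                best = INF
                if j >= 1:
                    cost = dp[j - 1][d] + (barcode[i - 1] != window[j - 1])
                    if cost < best:
                        best = cost
                if d >= 1 and dp[j][d - 1] < best:  # barcode base deleted in read
                    best = dp[j][d - 1]
                if j >= 1 and d >= 1 and ndp[j - 1][d - 1] < best:  # inserted read base
                    best = ndp[j - 1][d - 1]
                ndp[j][d] = best
        dp = ndp
    best: Optional[tuple[int, int, int]] = None
    for j in range(W + 1):
        for d in range(max_ind + 1):
            subs = dp[j][d]
            if subs > max_sub:
                continue
            key = (subs + d, d, abs(j - L))
            if best is None or key < (best[0] + best[1], best[1], abs(best[2] - L)):
                best = (subs, d, j)
    return best


class BarcodeMatch(NamedTuple):
    call: str  # catalogue id or UNKNOWN
    substitutions: int
    indels: int
    end: int  # window offset where the barcode alignment ends


def match_barcode(
    window: str, direction_set: Sequence[BarcodedPrimer], cfg: DemuxConfig
) -> BarcodeMatch:
    """Call the unique nearest catalogue barcode within tolerance.

    ``window`` is the read segment immediately after the leader.  Hamming
    distance over the full barcode when indels are disabled, otherwise a
    budgeted unit-cost alignment over a window of barcode length +-
    ``max_indels``.  Two barcodes tying at the minimal admissible distance
    yield an ``unknown`` (ambiguous) call.
    """
    if not direction_set:
        return BarcodeMatch(UNKNOWN, 0, 0, 0)
    L = len(direction_set[0].barcode)
    candidates: list[tuple[int, int, int, int, str]] = []  # total, subs, ind, end, id
    if not cfg.allow_indels:
        if len(window) < L:
            return BarcodeMatch(UNKNOWN, 0, 0, 0)
        prefix = window[:L]
        for p in direction_set:
            subs = sum(a != b for a, b in zip(p.barcode, prefix))
            if subs <= cfg.max_substitutions:
                candidates.append((subs, subs, 0, L, p.id))
    else:
        for p in direction_set:
            hit = _bounded_alignment(p.barcode, window, cfg.max_substitutions, cfg.max_indels)
            if hit is not None:
                subs, ind, end = hit
                candidates.append((subs + ind, subs, ind, end, p.id))
    if not candidates:
        return BarcodeMatch(UNKNOWN, 0, 0, 0)
    candidates.sort()
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        return BarcodeMatch(UNKNOWN, 0, 0, 0)  # ambiguous tie
    total, subs, ind, end, pid = candidates[0]
    return BarcodeMatch(pid, subs, ind, end)


def trim_primer(seq: str, primer: str, cfg: DemuxConfig) -> tuple[str, bool]:
    """Trim an anchored primer allowing a rate-based mismatch budget.

    IUPAC degeneracy in the primer counts as a match whenever the read
    base belongs to the code's set.  On failure the sequence is returned
    unchanged with ``success=False``.
    """
    if not primer:
        return seq, True
    if len(seq) < len(primer):
        return seq, False
    allowed = int(cfg.primer_error_rate * len(primer))
    mismatches = 0
    for code, base in zip(primer.upper(), seq[: len(primer)].upper()):
        if base not in IUPAC.get(code, ""):
            mismatches += 1
            if mismatches > allowed:
                return seq, False
    return seq[len(primer):], True


# ---------------------------------------------------------------------------
# Per-mate calling and the demultiplexer
# ---------------------------------------------------------------------------

class _MateCall(NamedTuple):
    call: str
    substitutions: int
    indels: int
    primer_trimmed: bool
    seq: str
    qual: str


def _call_mate(
    seq: str,
    qual: str,
    primers: Sequence[BarcodedPrimer],
    exact_index: dict[str, BarcodedPrimer],
    prefix_len: int,
    cfg: DemuxConfig,
) -> _MateCall:
    # fast path: verbatim leader+barcode hit
    hit = exact_index.get(seq[:prefix_len])
    if hit is not None and cfg.leader_policy == "anchored_exact":
        rest, rq = seq[prefix_len:], qual[prefix_len:]
        trimmed, ok = trim_primer(rest, hit.primer, cfg)
        if ok or cfg.on_primer_fail == "keep_flagged":
            tq = rq[len(rest) - len(trimmed):]
            return _MateCall(hit.id, 0, 0, ok, trimmed, tq)
        return _MateCall(UNKNOWN, 0, 0, False, seq, qual)
    # general path: per shared leader, strip then match within tolerance
    for leader in sorted({p.leader for p in primers}):
        rest = strip_leader(seq, leader, cfg)
        if rest is None:
            continue
        group = [p for p in primers if p.leader == leader]
        m = match_barcode(rest, group, cfg)
        if m.call == UNKNOWN:
            continue
        primer = next(p for p in group if p.id == m.call)
        body, bq = rest[m.end:], qual[len(leader) + m.end:]
        trimmed, ok = trim_primer(body, primer.primer, cfg)
        if not ok and cfg.on_primer_fail == "reject":
            return _MateCall(UNKNOWN, 0, 0, False, seq, qual)
        tq = bq[len(body) - len(trimmed):]
        return _MateCall(m.call, m.substitutions, m.indels, ok, trimmed, tq)
    return _MateCall(UNKNOWN, 0, 0, False, seq, qual)


def demultiplex(
    reads: Iterable[ReadPair | tuple],
    cat: BarcodeCatalogue,
    cfg: DemuxConfig = DemuxConfig(),
    keep_assignments: bool = True,
) -> tuple[list[DemuxAssignment], DemuxReport]:
    """Assign read pairs to barcode pairs and tally every pair once.

    The forward barcode is called on mate 1 and the reverse barcode on
    mate 2; no orientation rescue is attempted.  Leader, barcode and (when
    matchable) primer are trimmed from the mates of called barcodes.
    """
    f_index = {p.leader + p.barcode: p for p in cat.forwards}
    r_index = {p.leader + p.barcode: p for p in cat.reverses}
    f_plen = len(cat.forwards[0].leader) + cat.barcode_length if cat.forwards else 0
    r_plen = len(cat.reverses[0].leader) + cat.barcode_length if cat.reverses else 0
    counts: dict[tuple[str, str], int] = {}
    assignments: list[DemuxAssignment] = []
    total = 0
    for rp in reads:
        rp = ReadPair(*rp)
        total += 1
        fc = _call_mate(rp.seq1, rp.qual1, cat.forwards, f_index, f_plen, cfg)
        rc = _call_mate(rp.seq2, rp.qual2, cat.reverses, r_index, r_plen, cfg)
        key = (fc.call, rc.call)
        counts[key] = counts.get(key, 0) + 1
        if keep_assignments:
            assignments.append(
                DemuxAssignment(
                    read_id=rp.id,
                    forward_call=fc.call,
                    reverse_call=rc.call,
                    errors_f=(fc.substitutions, fc.indels),
                    errors_r=(rc.substitutions, rc.indels),
                    primer_trimmed_f=fc.primer_trimmed,
                    primer_trimmed_r=rc.primer_trimmed,
                    trimmed_seq1=fc.seq,
                    trimmed_qual1=fc.qual,
                    trimmed_seq2=rc.seq,
                    trimmed_qual2=rc.qual,
                )
            )
    report = DemuxReport(counts=counts, total=total, mode=cfg.mode_label)
    return assignments, report


def run_mode_panel(
    reads: Sequence[ReadPair | tuple],
    cat: BarcodeCatalogue,
    modes: Sequence[DemuxConfig],
) -> list[DemuxReport]:
    """Demultiplex one input under several stringency modes."""
    if not modes:
        raise ValueError("at least one mode is required")
    reads = list(reads)
    return [demultiplex(reads, cat, cfg, keep_assignments=False)[1] for cfg in modes]


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _mate_key(header: str) -> str:
    token = header.split()[0]
    if token.endswith("/1") or token.endswith("/2"):
        token = token[:-2]
    return token


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from two (optionally gzipped) FASTQs."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(r1) as fh1, _open_text(r2) as fh2:
        it1, it2 = FastqGeneralIterator(fh1), FastqGeneralIterator(fh2)
        index = 0
        for rec1, rec2 in zip(it1, it2, strict=True):
            index += 1
            h1, s1, q1 = rec1
            h2, s2, q2 = rec2
            k1, k2 = _mate_key(h1), _mate_key(h2)
            if k1 != k2:
                raise ValueError(
                    f"desynchronized mates at record {index}: {k1!r} != {k2!r}"
                )
            yield ReadPair(k1, s1, q1, s2, q2)


def write_demux_outputs(
    assignments: Iterable[DemuxAssignment],
    report: DemuxReport,
    out_dir: str | Path,
    compress: bool = True,
) -> None:
    """Write per-pair FASTQ files, the unknown bin and the report TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if compress else ".fastq"
    handles: dict[str, object] = {}

    def handle(stem: str, mate: int):
        key = f"{stem}_R{mate}"
        if key not in handles:
            handles[key] = _open_text(out_dir / f"{key}{suffix}", "wt")
        return handles[key]

    try:
        for a in assignments:
            stem = f"{a.forward_call}__{a.reverse_call}" if a.assigned else UNKNOWN
            handle(stem, 1).write(f"@{a.read_id}\n{a.trimmed_seq1}\n+\n{a.trimmed_qual1}\n")
            handle(stem, 2).write(f"@{a.read_id}\n{a.trimmed_seq2}\n+\n{a.trimmed_qual2}\n")
    finally:
        for fh in handles.values():
            fh.close()
    report.write_tsv(out_dir / f"report_{report.mode}.tsv")
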