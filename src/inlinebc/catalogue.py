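"""Barcoded-primer catalogues and panel combinatorics.

A catalogue holds the forward and reverse barcoded primers of one assay.
Each entry is a three-part construct (5' to 3'): a short neutral *leader*
(default ``GCATC``), an 8-bp *barcode* identifying the sample, and the
target-specific *primer* (IUPAC codes allowed).  Samples are labelled by
(forward barcode, reverse barcode) pairs; with a full cross of ``|F|``
forwards and ``|R|`` reverses, ``|F| x |R|`` samples can be distinguished
— e.g. 8 x 12 = 96 samples from only 20 unique primers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "DNA_ALPHABET",
    "DEFAULT_LEADER",
    "BarcodedPrimer",
    "BarcodeCatalogue",
    "CatalogueError",
    "SeparationReport",
    "load_catalogue",
    "write_catalogue",
    "construct_read_prefix",
    "validate_separation",
    "min_primer_count",
]

DNA_ALPHABET = frozenset("ACGT")
DEFAULT_LEADER = "GCATC"

# IUPAC nucleotide codes and the plain bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class CatalogueError(ValueError):
    """Raised when a catalogue violates its invariants or fails to parse."""


@dataclass(frozen=True)
class BarcodedPrimer:
    """One barcoded primer: leader + barcode + target-specific primer."""

    id: str
    direction: str  # "forward" or "reverse"
    barcode: str
    primer: str = ""
    leader: str = DEFAULT_LEADER

    def __post_init__(self) -> None:
        if not self.id:
            raise CatalogueError("primer id must be non-empty")
        if self.direction not in ("forward", "reverse"):
            raise CatalogueError(
                f"direction must be 'forward' or 'reverse', got {self.direction!r}"
            )
        for name, seq in (("leader", self.leader), ("barcode", self.barcode)):
            if set(seq) - DNA_ALPHABET:
                raise CatalogueError(
                    f"{name} of {self.id!r} contains non-ACGT characters: {seq!r}"
                )
        if not self.barcode:
            raise CatalogueError(f"barcode of {self.id!r} is empty")
        bad = set(self.primer.upper()) - set(IUPAC)
        if bad:
            raise CatalogueError(
                f"primer of {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )


def construct_read_prefix(p: BarcodedPrimer) -> str:
    """Expected read prefix for this primer: leader + barcode + primer."""
    return p.leader + p.barcode + p.primer


@dataclass
class BarcodeCatalogue:
    """Ordered forward and reverse barcoded primers plus their pairing rule.

    ``pairing="full_cross"`` pairs every forward with every reverse;
    ``pairing="explicit"`` restricts to ``explicit_pairs``.
    """

    forwards: list[BarcodedPrimer]
    reverses: list[BarcodedPrimer]
    pairing: str = "full_cross"
    explicit_pairs: Optional[list[tuple[str, str]]] = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.forwards and not self.reverses:
            raise CatalogueError("no catalogue entries")
        if self.pairing not in ("full_cross", "explicit"):
            raise CatalogueError(f"unknown pairing mode {self.pairing!r}")
        lengths = {len(p.barcode) for p in self.forwards + self.reverses}
        if len(lengths) > 1:
            raise CatalogueError(
                f"inconsistent barcode lengths in catalogue: {sorted(lengths)}"
            )
        for direction, entries in (("forward", self.forwards), ("reverse", self.reverses)):
            seen_ids: dict[str, str] = {}
            seen_bc: dict[str, str] = {}
            for p in entries:
                if p.direction != direction:
                    raise CatalogueError(
                        f"{p.id!r} has direction {p.direction!r} but is listed as {direction}"
                    )
                if p.id in seen_ids:
                    raise CatalogueError(f"duplicate {direction} id {p.id!r}")
                if p.barcode in seen_bc:
                    raise CatalogueError(
                        f"duplicate {direction} barcode {p.barcode!r} "
                        f"shared by {seen_bc[p.barcode]!r} and {p.id!r}"
                    )
                seen_ids[p.id] = p.id
                seen_bc[p.barcode] = p.id
        if self.pairing == "explicit":
            if not self.explicit_pairs:
                raise CatalogueError("explicit pairing requires explicit_pairs")
            fids = {p.id for p in self.forwards}
            rids = {p.id for p in self.reverses}
            for f, r in self.explicit_pairs:
                if f not in fids or r not in rids:
                    raise CatalogueError(f"explicit pair ({f!r}, {r!r}) references unknown id")

    @property
    def barcode_length(self) -> int:
        return len((self.forwards + self.reverses)[0].barcode)

    def forward_by_id(self, fid: str) -> BarcodedPrimer:
        return self._by_id(self.forwards, fid)

    def reverse_by_id(self, rid: str) -> BarcodedPrimer:
        return self._by_id(self.reverses, rid)

    @staticmethod
    def _by_id(entries: Sequence[BarcodedPrimer], pid: str) -> BarcodedPrimer:
        for p in entries:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def enumerate_pairs(self) -> list[tuple[str, str]]:
        """All valid (forward id, reverse id) pairs, forward-major order."""
        if self.pairing == "explicit":
            return list(self.explicit_pairs or [])
        return [(f.id, r.id) for f in self.forwards for r in self.reverses]

    def subset(self, forward_ids: Iterable[str], reverse_ids: Iterable[str]) -> "BarcodeCatalogue":
        """Restricted catalogue over the given primer ids (full cross)."""
        fids, rids = set(forward_ids), set(reverse_ids)
        return BarcodeCatalogue(
            forwards=[p for p in self.forwards if p.id in fids],
            reverses=[p for p in self.reverses if p.id in rids],
        )


# ---------------------------------------------------------------------------
# I/O
#
# FASTA dialect: ids start with "Forward_"/"Reverse_" (case-insensitive) and
# the record sequence is the barcode alone; the shared leader and the
# direction-specific primers are supplied by the caller.  Tabular dialect:
# TSV with columns id, direction, leader, barcode, primer.
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        return "fasta"
    return "table"


def load_catalogue(
    path: str | Path,
    format: Optional[str] = None,
    *,
    leader: str = DEFAULT_LEADER,
    forward_primer: str = "",
    reverse_primer: str = "",
) -> BarcodeCatalogue:
    """Parse a catalogue file in the FASTA or tabular dialect.

    Parameters
    ----------
    path:
        Catalogue file. FASTA records are barcodes only; direction is read
        from the id prefix. Tables carry leader/primer per entry.
    leader, forward_primer, reverse_primer:
        Construct segments to attach to FASTA entries (the FASTA dialect
        stores barcodes only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "fasta":
        entries = _load_fasta(path, leader, forward_primer, reverse_primer)
    elif fmt == "table":
        entries = _load_table(path)
    else:
        raise CatalogueError(f"unknown catalogue format {fmt!r}")
    forwards = [p for p in entries if p.direction == "forward"]
    reverses = [p for p in entries if p.direction == "reverse"]
    if not entries:
        raise CatalogueError(f"no catalogue entries in {path}")
    return BarcodeCatalogue(forwards=forwards, reverses=reverses)


def _load_fasta(path: Path, leader: str, fprimer: str, rprimer: str) -> list[BarcodedPrimer]:
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        low = rid.lower()
        if low.startswith("forward"):
            direction, primer = "forward", fprimer
        elif low.startswith("reverse"):
            direction, primer = "reverse", rprimer
        else:
            raise CatalogueError(
                f"cannot infer direction of {rid!r}: id must start with Forward_/Reverse_"
            )
        entries.append(
            BarcodedPrimer(
                id=rid, direction=direction, barcode=str(rec.seq).upper(),
                primer=primer, leader=leader,
            )
        )
    return entries


def _load_table(path: Path) -> list[BarcodedPrimer]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "direction", "leader", "barcode", "primer"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogueError(f"catalogue table missing columns: {sorted(missing)}")
    return [
        BarcodedPrimer(
            id=row["id"], direction=row["direction"].lower(),
            leader=row["leader"], barcode=row["barcode"].upper(),
            primer=row["primer"].upper(),
        )
        for _, row in df.iterrows()
    ]


def write_catalogue(cat: BarcodeCatalogue, path: str | Path, format: Optional[str] = None) -> None:
    """Write a catalogue in the FASTA (barcode-only) or tabular dialect."""
    path = Path(path)
    fmt = format or _infer_format(path)
    entries = cat.forwards + cat.reverses
    if fmt == "fasta":
        with open(path, "w") as fh:
            for p in entries:
                fh.write(f">{p.id}\n{p.barcode}\n")
    elif fmt == "table":
        import pandas as pd

        pd.DataFrame(
            [
                {"id": p.id, "direction": p.direction, "leader": p.leader,
                 "barcode": p.barcode, "primer": p.primer}
                for p in entries
            ]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise CatalogueError(f"unknown catalogue format {fmt!r}")


# ---------------------------------------------------------------------------
# Separation diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeparationReport:
    """Minimum pairwise barcode distance per direction.

    A direction is *safe* under tolerance ``max_errors`` when the minimum
    distance between any two of its barcodes exceeds ``2 * max_errors``:
    no read can then sit within tolerance of two different barcodes, so
    mis-assignment of singly-tagged reads is impossible.
    """

    min_distance_forward: Optional[int]
    min_distance_reverse: Optional[int]
    max_errors: int
    indels: bool

    @property
    def safe_forward(self) -> bool:
        return self.min_distance_forward is None or self.min_distance_forward > 2 * self.max_errors

    @property
    def safe_reverse(self) -> bool:
        return self.min_distance_reverse is None or self.min_distance_reverse > 2 * self.max_errors

    @property
    def safe(self) -> bool:
        return self.safe_forward and self.safe_reverse


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    # classic O(|a||b|) DP; barcodes are 8 bp so cost is negligible
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _min_pairwise(barcodes: Sequence[str], indels: bool) -> Optional[int]:
    if len(barcodes) < 2:
        return None
    dist = levenshtein if indels else hamming
    return min(dist(a, b) for a, b in itertools.combinations(barcodes, 2))


def validate_separation(
    cat: BarcodeCatalogue, max_errors: int, indels: bool = False
) -> SeparationReport:
    """Report minimum pairwise barcode distance within each direction."""
    return SeparationReport(
        min_distance_forward=_min_pairwise([p.barcode for p in cat.forwards], indels),
        min_distance_reverse=_min_pairwise([p.barcode for p in cat.reverses], indels),
        max_errors=max_errors,
        indels=indels,
    )


# ---------------------------------------------------------------------------
# Primer minimization
# ---------------------------------------------------------------------------

def min_primer_count(
    n_samples: int,
    max_f: Optional[int] = None,
    max_r: Optional[int] = None,
    allow_excess: bool = False,
) -> tuple[int, int, int]:
    """Fewest unique primers labelling ``n_samples`` by pairwise combination.

    Searches factor pairs ``f * r == n_samples`` (or ``>= n_samples`` when
    ``allow_excess``) with ``f <= max_f`` and ``r <= max_r`` when caps are
    given, and returns the ``(f, r, f + r)`` minimizing the total primer
    count ``f + r``; ties prefer the more square grid (smaller ``|f - r|``),
    then the smaller ``f``.  For 96 samples the optimum is 8 forward + 12
    reverse = 20 primers.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    candidates: list[tuple[int, int]] = []
    if allow_excess:
        f_hi = max_f if max_f is not None else n_samples
        for f in range(1, f_hi + 1):
            r = math.ceil(n_samples / f)
            if max_r is not None and r > max_r:
                continue
            candidates.append((f, r))
    else:
        for f in range(1, n_samples + 1):
            if n_samples % f:
                continue
            r = n_samples // f
            if max_f is not None and f > max_f:
                continue
            if max_r is not None and r > max_r:
                continue
            candidates.append((f, r))
    if not candidates:
        raise ValueError(
            f"no feasible factorization of {n_samples} under caps "
            f"(max_f={max_f}, max_r={max_r})"
        )
    f, r = min(candidates, key=lambda fr: (fr[0] + fr[1], abs(fr[0] - fr[1]), fr[0]))
    return f, r, f + r
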