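"""Adapter/primer removal by error-tolerant ends-free alignment.

454 cDNA reads carry the library's poly(T) anchor primer (and possibly
other vector sequence) which must be removed before clustering. An adapter
may occur inside the read or run off either end, so matching is semi-global
("ends free"): only the part of the adapter that overlaps the read is
aligned and scored. Errors are unit-cost substitutions and indels; a match
is accepted when its error count is at most
``floor(max_error_rate * overlap)`` where *overlap* is the number of
adapter bases inside the read. IUPAC ambiguity codes (the library primer
ends in V = A/C/G) match any of their expansions at zero cost.

Alignment is done with edlib: mode HW for internal occurrences, mode SHW on
plain/reversed strings for partial occurrences hanging off the 5'/3' read
end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import edlib

from .sequence_io import IUPAC_CODES, Read

__all__ = [
    "AdapterSpec",
    "AdapterMatch",
    "TrimReport",
    "find_adapter",
    "trim_read",
    "trim_reads",
    "filter_length",
    "LIBRARY_PRIMER",
]

logger = logging.getLogger(__name__)

#: The cDNA first-strand synthesis primer used by the study's library
#: protocol (anchored oligo-dT; terminal V = A/C/G).
LIBRARY_PRIMER = "TTTTTTCTTGTTTTCTTTTCTTV"


@dataclass(frozen=True)
class AdapterSpec:
    """An adapter/primer to screen for.

    ``where`` selects which side of the read is removed on a match:
    ``three_prime`` removes from match start to the read end,
    ``five_prime`` removes from the read start to match end, and ``both``
    picks the side the match is anchored to.
    """

    name: str
    seq: str
    where: Literal["three_prime", "five_prime", "both"] = "three_prime"
    max_error_rate: float = 0.1
    min_overlap: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.max_error_rate < 1):
            raise ValueError("max_error_rate must be in [0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if len(self.seq) < self.min_overlap:
            raise ValueError("adapter shorter than min_overlap")


@dataclass(frozen=True)
class AdapterMatch:
    """Best adapter occurrence: read span ``[start, end)``, error count,
    and the number of adapter bases involved (``overlap``)."""

    start: int
    end: int
    n_errors: int
    overlap: int


@dataclass
class TrimReport:
    n_in: int = 0
    n_trimmed: int = 0
    n_dropped: int = 0
    mean_len_before: float = 0.0
    mean_len_after: float = 0.0


def _equalities(*seqs: str) -> list[tuple[str, str]]:
    """edlib equality pairs expanding every IUPAC ambiguity code present."""
    pairs = []
    for ch in set("".join(seqs)):
        bases = IUPAC_CODES.get(ch, ch)
        if len(bases) > 1:
            for b in bases:
                pairs.append((ch, b))
    return pairs


def _shw(query: str, target: str, k: int, eq) -> Optional[tuple[int, int]]:
    """Align full query to a prefix of target; return (edit_distance,
    end_in_target_exclusive) or None if distance exceeds k."""
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="SHW", task="locations", k=k,
                      additionalEqualities=eq)
    if res["editDistance"] < 0:
        return None
    end = res["locations"][0][1] + 1
    return res["editDistance"], end


def find_adapter(seq: str, adapter: AdapterSpec) -> Optional[AdapterMatch]:
    """Locate the best occurrence of `adapter` in `seq`, ends-free.

    A ``three_prime`` adapter may occur internally or run off the 3' end of
    the read; a ``five_prime`` adapter internally or off the 5' end;
    ``both`` allows either overhang. Returns the lowest-error qualifying
    match; ties broken by longest overlap, then leftmost read position.
    None when nothing qualifies.
    """
    if not seq:
        raise ValueError("empty read sequence")
    a = adapter.seq.upper()
    s = seq.upper()
    L, n = len(a), len(s)
    eq = _equalities(a, s)
    rate = adapter.max_error_rate
    candidates: list[tuple[int, int, int, int]] = []  # (errors, -overlap, start, end)

    # Internal occurrence: full adapter somewhere inside the read.
    budget = int(rate * L)
    res = edlib.align(a, s, mode="HW", task="locations", k=budget,
                      additionalEqualities=eq)
    if res["editDistance"] >= 0:
        for st, en in res["locations"]:
            candidates.append((res["editDistance"], -L, st, en + 1))

    # Partial occurrence off the 3' end: adapter prefix vs read suffix.
    if adapter.where in ("three_prime", "both"):
        sr = s[::-1]
        for o in range(adapter.min_overlap, min(L, n + 1)):
            hit = _shw(a[:o][::-1], sr, int(rate * o), eq)
            if hit is not None and hit[0] <= int(rate * o):
                candidates.append((hit[0], -o, n - hit[1], n))

    # Partial occurrence off the 5' end: adapter suffix vs read prefix.
    if adapter.where in ("five_prime", "both"):
        for o in range(adapter.min_overlap, min(L, n + 1)):
            hit = _shw(a[-o:], s, int(rate * o), eq)
            if hit is not None and hit[0] <= int(rate * o):
                candidates.append((hit[0], -o, 0, hit[1]))

    if not candidates:
        return None
    errors, neg_ov, start, end = min(candidates)
    return AdapterMatch(start=start, end=end, n_errors=errors, overlap=-neg_ov)


def _slice(read: Read, start: int, end: int) -> Optional[Read]:
    """Keep read[start:end]; None when nothing is left."""
    if end <= start:
        return None
    qual = read.qual[start:end] if read.qual is not None else None
    return replace(read, seq=read.seq[start:end], qual=qual)


def trim_read(read: Read, adapters: Sequence[AdapterSpec]) -> Optional[Read]:
    """Remove adapter occurrences, re-applying the adapter list until no
    adapter matches. Returns None when the read is consumed entirely."""
    current: Optional[Read] = read
    changed = True
    while changed and current is not None:
        changed = False
        for ad in adapters:
            if current is None:
                break
            m = find_adapter(current.seq, ad)
            if m is None:
                continue
            if ad.where == "three_prime":
                nxt = _slice(current, 0, m.start)
            elif ad.where == "five_prime":
                nxt = _slice(current, m.end, len(current.seq))
            else:  # both: trim the side the match is anchored to
                if m.start == 0 and m.end < len(current.seq):
                    nxt = _slice(current, m.end, len(current.seq))
                else:
                    nxt = _slice(current, 0, m.start)
            current = nxt
            changed = True
    return current


def trim_reads(
    reads: Iterable[Read], adapters: Sequence[AdapterSpec]
) -> tuple[list[Read], TrimReport]:
    """Trim a collection of reads; fully-adapter reads are dropped."""
    report = TrimReport()
    out: list[Read] = []
    len_before = 0
    len_after = 0
    for r in reads:
        report.n_in += 1
        len_before += len(r)
        t = trim_read(r, adapters)
        if t is None:
            report.n_dropped += 1
            continue
        if len(t) != len(r):
            report.n_trimmed += 1
        len_after += len(t)
        out.append(t)
    if report.n_in:
        report.mean_len_before = len_before / report.n_in
    if out:
        report.mean_len_after = len_after / len(out)
    return out, report


def filter_length(
    reads: Iterable[Read], min_len: int = 100
) -> tuple[list[Read], TrimReport]:
    """Keep reads of length >= min_len (boundary inclusive)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    reads = list(reads)
    kept = [r for r in reads if len(r) >= min_len]
    report = TrimReport(n_in=len(reads), n_dropped=len(reads) - len(kept))
    if reads:
        report.mean_len_before = sum(len(r) for r in reads) / len(reads)
    if kept:
        report.mean_len_after = sum(len(r) for r in kept) / len(kept)
    return kept, report
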