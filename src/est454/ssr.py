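"""Microsatellite (SSR) detection with MISA-style parameters.

A perfect SSR is a maximal tandem run of a 1-6 nt motif meeting a
per-motif-size minimum repeat count (defaults: 10 mononucleotide, 6
dinucleotide, 5 for tri- through hexanucleotide). Two or more perfect SSRs
separated by at most ``max_interruption`` (default 100 nt, boundary
inclusive) merge into one compound SSR.

A reported run satisfies, for motif m = seq[start:start+p] and r repeats:
  * r >= min_repeats[p];
  * m is primitive (not itself a repetition of a shorter motif), so a run
    is reported at its smallest period only;
  * left-shift-maximal: the tandem structure cannot be slid one base left
    (start == 0 or seq[start-1] != seq[start+p-1]), which makes the start
    the leftmost position of its run and prevents the same run being
    reported once per phase;
  * unit-maximal on the right: the next p bases do not repeat the motif
    (a trailing partial repeat is allowed but not counted).

Coordinates are 1-based inclusive, as in MISA reports. Output is
strand-dependent by design: motifs are reported as they occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SSRRecord",
    "DEFAULT_MIN_REPEATS",
    "find_ssrs",
    "compound_ssrs",
    "ssr_summary",
]

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRRecord:
    seq_id: str
    motif: str  # as it occurs; "compound" spans use the joined motif list
    motif_size: int
    n_repeats: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    kind: str = "perfect"  # perfect | compound
    component_ssrs: tuple["SSRRecord", ...] = field(default=())


def _primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def find_ssrs(
    seq: str,
    min_repeats: Optional[Mapping[int, int]] = None,
    seq_id: str = "seq",
) -> list[SSRRecord]:
    """All perfect SSRs in `seq`, left to right (by start, then motif size)."""
    if not seq:
        raise ValueError("empty sequence")
    mins = dict(DEFAULT_MIN_REPEATS if min_repeats is None else min_repeats)
    s = seq.upper()
    n = len(s)
    records: list[SSRRecord] = []
    for p, min_rep in sorted(mins.items()):
        i = 0
        while i + p < n:
            if s[i] != s[i + p]:
                i += 1
                continue
            # maximal equality run starting at i for period p
            j = i
            while j + p < n and s[j] == s[j + p]:
                j += 1
            run_len = (j - i) + p  # bases spanned by the tandem structure
            reps = run_len // p
            if reps >= min_rep:
                motif = s[i : i + p]
                if _primitive(motif):
                    records.append(
                        SSRRecord(
                            seq_id=seq_id,
                            motif=motif,
                            motif_size=p,
                            n_repeats=reps,
                            start=i + 1,
                            end=i + reps * p,
                        )
                    )
            i = j + 1
    records.sort(key=lambda r: (r.start, r.motif_size))
    return records


def compound_ssrs(
    ssrs: Sequence[SSRRecord], max_interruption: int = 100
) -> list[SSRRecord]:
    """Merge consecutive perfect SSRs separated by <= max_interruption nt
    (transitively) into compound records; isolated SSRs pass through."""
    ssrs = list(ssrs)
    if any(b.start < a.start for a, b in zip(ssrs, ssrs[1:])):
        raise ValueError("SSR records must be sorted by start")
    if len({r.seq_id for r in ssrs}) > 1:
        raise ValueError("compound_ssrs expects records from one sequence")
    out: list[SSRRecord] = []
    group: list[SSRRecord] = []

    def flush() -> None:
        if not group:
            return
        if len(group) == 1:
            out.append(group[0])
        else:
            out.append(
                SSRRecord(
                    seq_id=group[0].seq_id,
                    motif="-".join(g.motif for g in group),
                    motif_size=0,
                    n_repeats=0,
                    start=group[0].start,
                    end=max(g.end for g in group),
                    kind="compound",
                    component_ssrs=tuple(group),
                )
            )
        group.clear()

    for rec in ssrs:
        if group and rec.start - max(g.end for g in group) - 1 <= max_interruption:
            group.append(rec)
        else:
            flush()
            group.append(rec)
    flush()
    return out


def ssr_summary(
    records: Sequence[SSRRecord], n_sequences: int, total_nt: int
) -> pd.Series:
    """Summary statistics: counts per motif size (perfect components),
    perfect/compound record counts, sequences containing an SSR, and SSR
    density per Mbp."""
    perfect = [r for r in records if r.kind == "perfect"]
    compound = [r for r in records if r.kind == "compound"]
    components = perfect + [c for r in compound for c in r.component_ssrs]
    data: dict[str, float] = {
        "n_sequences": n_sequences,
        "total_nt": total_nt,
        "n_perfect": len(perfect),
        "n_compound": len(compound),
        "n_records": len(records),
        "n_sequences_with_ssr": len({r.seq_id for r in records}),
    }
    for p in range(1, 7):
        data[f"n_motif_{p}nt"] = sum(1 for r in components if r.motif_size == p)
    data["ssr_per_mbp"] = (
        len(records) / (total_nt / 1e6) if total_nt > 0 else 0.0
    )
    return pd.Series(data)
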