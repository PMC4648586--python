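"""Greedy incremental clustering of ESTs at a global identity threshold.

Reads are processed longest-first; each read is compared against the
representatives of all existing clusters on both strands. If no
representative reaches the identity threshold the read founds a new cluster
(becoming its representative); otherwise it joins the cluster whose
representative is MOST similar (not merely the first above threshold), the
greedy scheme of CD-HIT-EST with the most-similar-cluster option.

Identity between two sequences is the number of identical aligned base
pairs in a minimum-edit-distance global (Needleman-Wunsch) alignment,
divided by the length of the shorter sequence — the denominator convention
of CD-HIT's nucleotide mode. Both the forward and reverse-complement
orientations of the candidate are scored and the better one kept.

A lossless prescreen keeps this affordable: from the plain edit distance e
between sequences of lengths l >= s, every minimum-edit alignment has a
match count within [s - d, s - ceil(d/2)] where d = e - (l - s), so a cheap
distance-only alignment bounds the identity from above and prunes
representatives that cannot win; d == 0 proves identity 1.0 exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import pandas as pd

from .sequence_io import Read, revcomp

__all__ = [
    "Cluster",
    "Clustering",
    "identity",
    "greedy_cluster",
    "count_matrix",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class Cluster:
    cluster_id: int
    representative: Read
    #: (read, strand "+"/"-", identity fraction); the representative is a
    #: member with identity 1.0.
    members: list[tuple[Read, str, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Clustering:
    clusters: list[Cluster]
    threshold: float
    n_reads: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters if c.size == 1)

    @property
    def n_multi(self) -> int:
        return sum(1 for c in self.clusters if c.size >= 2)


def _matches_from_cigar(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op == "=")


def _nw_matches(a: str, b: str) -> int:
    """Identical aligned pairs in the minimum-edit NW alignment of a vs b."""
    res = edlib.align(a, b, mode="NW", task="path")
    return _matches_from_cigar(res["cigar"])


def identity(a: str, b: str) -> tuple[float, str]:
    """Global-alignment identity of `a` vs `b`, best over both strands.

    Returns (identity, strand) where identity = identical aligned pairs /
    shorter length, and strand is "+" if the forward orientation of `b` is
    at least as good as its reverse complement, else "-".
    """
    if not a or not b:
        raise ValueError("identity of empty sequence is undefined")
    s = min(len(a), len(b))
    fwd = _nw_matches(a, b) / s
    if fwd == 1.0:
        return 1.0, "+"
    rev = _nw_matches(a, revcomp(b)) / s
    return (fwd, "+") if fwd >= rev else (rev, "-")


def _ubound(a: str, b: str, k: int) -> float:
    """Upper bound on identity(a, b-single-strand) from a distance-only NW
    alignment capped at edit distance k; 0.0 when the cap is exceeded."""
    res = edlib.align(a, b, mode="NW", task="distance", k=k)
    e = res["editDistance"]
    if e < 0:
        return 0.0
    s, l = min(len(a), len(b)), max(len(a), len(b))
    d = e - (l - s)
    return (s - (d + 1) // 2) / s


def greedy_cluster(reads: Sequence[Read], threshold: float = 0.95) -> Clustering:
    """Cluster reads greedily at a global identity threshold (default 0.95,
    the study's cut-off), assigning each read to its most similar qualifying
    representative; ties go to the earlier-founded cluster.

    Deterministic: reads are processed by descending length, input order
    breaking length ties.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    reads = list(reads)
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i]), i))
    clusters: list[Cluster] = []
    reps: list[str] = []  # representative sequences, founding order
    reps_rc: list[str] = []

    for i in order:
        read = reads[i]
        a = read.seq
        best_id = -1.0
        best_c = -1
        best_strand = "+"
        for ci in range(len(clusters)):
            b = reps[ci]
            s = min(len(a), len(b))
            l = max(len(a), len(b))
            # cap: identity >= max(threshold, best) needs d <= 2*(1-v)*s
            v = threshold if best_id < threshold else best_id
            k = (l - s) + int(2 * (1 - v) * s) + 1
            cid, strand = -1.0, "+"
            ub_f = _ubound(a, b, k)
            if ub_f == 1.0:
                cid = 1.0
            else:
                if ub_f > best_id and ub_f >= threshold:
                    cid = _nw_matches(a, b) / s
                ub_r = _ubound(a, reps_rc[ci], k)
                if ub_r > best_id and ub_r >= threshold and ub_r > cid:
                    rid = _nw_matches(a, reps_rc[ci]) / s
                    if rid > cid:
                        cid, strand = rid, "-"
            if cid > best_id:
                best_id, best_c, best_strand = cid, ci, strand
                if best_id == 1.0:
                    break
        if best_c >= 0 and best_id >= threshold:
            clusters[best_c].members.append((read, best_strand, best_id))
        else:
            c = Cluster(cluster_id=len(clusters), representative=read)
            c.members.append((read, "+", 1.0))
            clusters.append(c)
            reps.append(a)
            reps_rc.append(revcomp(a))

    return Clustering(clusters=clusters, threshold=threshold, n_reads=len(reads))


def count_matrix(clustering: Clustering, libraries: Sequence[str]) -> "CountMatrix":
    """Tabulate reads per (cluster, library) with per-library totals N_i."""
    from .diffexpr import CountMatrix

    libraries = list(libraries)
    libset = set(libraries)
    rows = []
    for c in clustering.clusters:
        counts = dict.fromkeys(libraries, 0)
        for read, _, _ in c.members:
            if read.library not in libset:
                raise ValueError(f"unknown library label {read.library!r}")
            counts[read.library] += 1
        rows.append(counts)
    df = pd.DataFrame(rows, index=[c.cluster_id for c in clustering.clusters],
                      columns=libraries, dtype=int)
    totals = df.sum(axis=0)
    return CountMatrix(counts=df, totals=totals)
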