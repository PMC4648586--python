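"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest

from est454.clustering import identity
from est454.sequence_io import Read
from est454.ssr import DEFAULT_MIN_REPEATS, SSRRecord, _primitive

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Exactly n_sub substitutions at distinct positions."""
    s = list(seq)
    for pos in rng.choice(len(s), size=n_sub, replace=False):
        s[pos] = rng.choice([b for b in BASES if b != s[pos]])
    return "".join(s)


# ---------------------------------------------------------------------------
# clustering oracle: exhaustive greedy reference — every read scored against
# every representative with a full both-strand alignment, most-similar
# cluster wins, earlier-founded cluster breaks ties.
# ---------------------------------------------------------------------------

def exhaustive_cluster(reads, threshold):
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i].seq), i))
    clusters: list[dict] = []
    for i in order:
        read = reads[i]
        best_id, best_c, best_strand = -1.0, None, "+"
        for ci, c in enumerate(clusters):
            frac, strand = identity(read.seq, c["rep"])
            if frac > best_id:
                best_id, best_c, best_strand = frac, ci, strand
        if best_c is not None and best_id >= threshold:
            clusters[best_c]["members"].append((read.id, best_strand, best_id))
        else:
            clusters.append({"rep": read.seq,
                             "members": [(read.id, "+", 1.0)]})
    return clusters


# ---------------------------------------------------------------------------
# pure-python edit distance (for bounding identity against an independent
# implementation)
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# SSR brute-force oracle: test every (start, motif size) pair directly.
# ---------------------------------------------------------------------------

def brute_force_ssrs(seq: str, min_repeats=None, seq_id: str = "seq"):
    mins = dict(DEFAULT_MIN_REPEATS if min_repeats is None else min_repeats)
    s = seq.upper()
    n = len(s)
    out = []
    for p, min_rep in sorted(mins.items()):
        for start in range(n - p):
            if s[start] != s[start + p]:
                continue  # cannot even repeat once more
            # leftmost phase of its run only
            if start > 0 and s[start - 1] == s[start - 1 + p]:
                continue
            motif = s[start : start + p]
            if not _primitive(motif):
                continue
            r = 1
            while s[start + r * p : start + (r + 1) * p] == motif:
                r += 1
            if r >= min_rep:
                out.append(
                    SSRRecord(seq_id=seq_id, motif=motif, motif_size=p,
                              n_repeats=r, start=start + 1, end=start + r * p)
                )
    out.sort(key=lambda r: (r.start, r.motif_size))
    return out


# ---------------------------------------------------------------------------
# direct-formula R statistic
# ---------------------------------------------------------------------------

def r_direct(x, N):
    import math

    f = sum(x) / sum(N)
    total = 0.0
    for xi, ni in zip(x, N):
        if xi > 0:
            total += xi * math.log(xi / (ni * f))
    return total


def make_reads(rng, seqs, library="lib"):
    return [Read(id=f"r{i}", library=library, seq=s) for i, s in enumerate(seqs)]
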