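"""Synthetic 454-style EST libraries with planted differential expression.

The generator emulates the study design end to end: a random transcriptome
(uniform base composition, each transcript ending in a short poly(A) stub),
four libraries — two tissues (root, leaf) x treated/untreated — each of
`depth` reads, one read per sampled transcript molecule. Every read is
anchored at the transcript 3' end (the anchored oligo-dT library design
sequences each molecule's 3' UTR exactly once), its insert length drawn
from a truncated normal, and the library's poly(T) anchor primer appended
at the 3' end so trimming is exercised. A configurable fraction of
transcripts is differentially expressed at a fixed fold change in the
treated libraries (half up, half down), recorded in a truth table.

Sequencing errors are a coarse 454 caricature: per-base substitutions at
`error_rate`, plus, whenever errors are enabled (error_rate > 0),
homopolymer runs of length >= 5 gaining or losing one base with
probability 0.2 per run. `error_rate = 0` produces exact 3' suffixes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .clustering import Clustering, identity
from .diffexpr import DECall
from .sequence_io import Read, write_fasta
from .trimming import LIBRARY_PRIMER

__all__ = [
    "SyntheticTranscriptome",
    "AbundanceDesign",
    "LIBRARIES",
    "simulate_transcriptome",
    "four_library_design",
    "simulate_libraries",
    "write_libraries",
    "evaluate_recovery",
]

LIBRARIES = ("root_treated", "root_untreated", "leaf_treated", "leaf_untreated")
TREATED = {"root": "root_treated", "leaf": "leaf_treated"}
UNTREATED = {"root": "root_untreated", "leaf": "leaf_untreated"}

_POLYA_STUB = 8  # < 10-repeat mono-SSR minimum; gives reads a real 3' end


@dataclass
class SyntheticTranscriptome:
    """Random transcripts plus ground truth for any planted SSRs."""

    sequences: dict[str, str]
    planted_ssrs: pd.DataFrame  # transcript_id, motif, n_repeats, start (1-based)
    seed: int

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class AbundanceDesign:
    """Per-library relative transcript abundances and the DE truth.

    `abundances` is a (transcripts x libraries) DataFrame, columns summing
    to 1. `truth` is indexed by transcript id with columns true_de (bool),
    direction (up/down/none, in treated vs untreated) and fold_change.
    """

    abundances: pd.DataFrame
    truth: pd.DataFrame
    depth: int

    def __post_init__(self) -> None:
        if (self.abundances.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if not np.allclose(self.abundances.sum(axis=0), 1.0):
            raise ValueError("abundances must be normalised per library")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _random_primitive_motif(rng: np.random.Generator, size: int) -> str:
    from .ssr import _primitive

    while True:
        motif = "".join(rng.choice(list("ACGT"), size=size))
        if _primitive(motif):
            return motif


def simulate_transcriptome(
    n: int,
    len_range: tuple[int, int] = (400, 3000),
    ssr_spike_rate: float = 0.0,
    seed: int = 1,
) -> SyntheticTranscriptome:
    """Generate `n` uniform-random transcripts ending in a poly(A) stub.

    With probability `ssr_spike_rate` a transcript receives one random SSR
    meeting the detection minima, recorded as ground truth. Deterministic
    per seed.
    """
    lo, hi = len_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if lo < 150 or hi < lo:
        raise ValueError("invalid length range (min >= 150, max >= min)")
    rng = np.random.default_rng(seed)
    from .ssr import DEFAULT_MIN_REPEATS

    seqs: dict[str, str] = {}
    planted = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        core_len = length - _POLYA_STUB
        ssr = ""
        if ssr_spike_rate > 0 and rng.random() < ssr_spike_rate:
            size = int(rng.integers(1, 7))
            reps = int(DEFAULT_MIN_REPEATS[size] + rng.integers(0, 4))
            ssr = _random_primitive_motif(rng, size) * reps
        rand_len = max(core_len - len(ssr), 20)
        core = "".join(rng.choice(list("ACGT"), size=rand_len))
        # keep the base before the poly(A) stub off A so the stub cannot
        # extend into a detectable mononucleotide run
        if core[-1] == "A":
            core = core[:-1] + str(rng.choice(list("CGT")))
        if ssr:
            pos = int(rng.integers(0, len(core) - 1))
            core = core[:pos] + ssr + core[pos:]
        tid = f"tx{i:04d}"
        seqs[tid] = core + "A" * _POLYA_STUB
        if ssr:
            planted.append(
                {"transcript_id": tid, "motif": ssr[: size], "n_repeats": reps,
                 "start": pos + 1}
            )
    return SyntheticTranscriptome(
        sequences=seqs,
        planted_ssrs=pd.DataFrame(
            planted, columns=["transcript_id", "motif", "n_repeats", "start"]
        ),
        seed=seed,
    )


def four_library_design(
    transcript_ids: Sequence[str],
    de_frac: float = 0.1,
    fold: float = 8.0,
    depth: int = 3000,
    seed: int = 1,
) -> AbundanceDesign:
    """Study-shaped four-library design: log-normal base abundances shared
    across libraries; a `de_frac` fraction of transcripts changed `fold`-
    fold in both treated libraries, half up and half down."""
    ids = list(transcript_ids)
    if not 0 <= de_frac < 1:
        raise ValueError("de_frac must be in [0, 1)")
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(ids))
    n_de = int(round(de_frac * len(ids)))
    de_idx = rng.choice(len(ids), size=n_de, replace=False)
    direction = np.full(len(ids), "none", dtype=object)
    direction[de_idx[: n_de // 2]] = "down"
    direction[de_idx[n_de // 2 :]] = "up"

    cols = {}
    for lib in LIBRARIES:
        w = base.copy()
        if lib.endswith("_treated"):
            w[direction == "up"] *= fold
            w[direction == "down"] /= fold
        cols[lib] = w / w.sum()
    truth = pd.DataFrame(
        {
            "true_de": direction != "none",
            "direction": direction,
            "fold_change": np.where(direction != "none", float(fold), 1.0),
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    return AbundanceDesign(
        abundances=pd.DataFrame(cols, index=ids), truth=truth, depth=depth
    )


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitutions at error_rate per base plus +-1 homopolymer-length
    errors (runs >= 5, probability 0.2 per run). No-op at error_rate 0."""
    if error_rate <= 0:
        return seq
    bases = list(seq)
    n_sub = rng.binomial(len(bases), error_rate)
    for pos in rng.choice(len(bases), size=n_sub, replace=False):
        alts = [b for b in "ACGT" if b != bases[pos]]
        bases[pos] = str(rng.choice(alts))
    s = "".join(bases)
    out = []
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        run = s[i:j]
        if j - i >= 5 and rng.random() < 0.2:
            run = run[:-1] if rng.random() < 0.5 else run + run[0]
        out.append(run)
        i = j
    return "".join(out)


def simulate_libraries(
    tx: SyntheticTranscriptome,
    design: AbundanceDesign,
    error_rate: float = 0.0,
    seed: int = 1,
    mean_len: float = 360.0,
    sd_len: float = 25.0,
    primer: str = LIBRARY_PRIMER,
) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """Draw the four read libraries and return (reads per library, truth).

    Per library, `depth` molecules are drawn multinomially from that
    library's abundances; each molecule yields one read: the transcript's
    3'-terminal `L` bases (L ~ Normal(mean_len, sd_len) truncated to
    [150, transcript length]), sequencing errors applied, and the anchor
    primer appended 3' (its terminal V instantiated to a random A/C/G).
    """
    rng = np.random.default_rng(seed)
    ids = tx.ids
    if list(design.abundances.index) != ids:
        raise ValueError("design is not indexed by this transcriptome")
    libs: dict[str, list[Read]] = {}
    for lib in design.abundances.columns:
        p = design.abundances[lib].to_numpy()
        counts = rng.multinomial(design.depth, p)
        reads: list[Read] = []
        k = 0
        for t_idx in np.repeat(np.arange(len(ids)), counts):
            tid = ids[t_idx]
            full = tx.sequences[tid]
            L = int(np.clip(round(rng.normal(mean_len, sd_len)), 150, len(full)))
            insert = _apply_errors(full[-L:], error_rate, rng)
            tail = primer.replace("V", str(rng.choice(list("ACG"))))
            reads.append(Read(id=f"{lib}_r{k:05d}", library=lib, seq=insert + tail))
            k += 1
        order = rng.permutation(len(reads))
        libs[lib] = [reads[i] for i in order]
    return libs, design.truth.copy()


def write_libraries(libs: Mapping[str, Sequence[Read]], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lib, reads in libs.items():
        path = outdir / f"{lib}.fasta"
        write_fasta(reads, path)
        paths[lib] = path
    return paths


def _best_transcript(
    rep: str, transcripts: Mapping[str, str], min_identity: float
) -> Optional[str]:
    """Map a cluster representative to its most similar transcript
    (identity >= min_identity over the shorter sequence), or None."""
    best_id, best_tx = -1.0, None
    for tid, seq in transcripts.items():
        if rep in seq:  # exact 3'-anchored suffix: identity 1.0
            return tid
        res = edlib.align(rep, seq, mode="NW", task="distance")
        s, l = min(len(rep), len(seq)), max(len(rep), len(seq))
        ub = (s - (res["editDistance"] - (l - s) + 1) // 2) / s
        if ub > best_id:
            frac, _ = identity(rep, seq)
            if frac > best_id:
                best_id, best_tx = frac, tid
    return best_tx if best_id >= min_identity else None


def evaluate_recovery(
    calls: Sequence[DECall],
    truth: pd.DataFrame,
    representatives: Mapping[object, str],
    transcripts: Mapping[str, str],
    min_identity: float = 0.8,
) -> tuple[float, float, float]:
    """Score DE calls against the planted truth.

    Clusters are mapped to transcripts by best representative-to-transcript
    identity; a significant call whose cluster maps to no transcript or to
    a non-DE transcript is a false positive. Returns (sensitivity,
    observed_fdr, direction_accuracy): sensitivity is the fraction of true
    DE transcripts recovered by a correctly-directed significant call;
    observed FDR is false positives over all positives (0 when none);
    direction accuracy is scored over true-positive calls (vacuously 1.0).
    """
    positives = [c for c in calls if c.significant]
    n_fp = 0
    tp_calls: list[tuple[DECall, str]] = []
    for call in positives:
        rep = representatives.get(call.cluster_id)
        tid = (
            _best_transcript(rep, transcripts, min_identity)
            if rep is not None
            else None
        )
        if tid is None or not bool(truth.loc[tid, "true_de"]):
            n_fp += 1
        else:
            tp_calls.append((call, tid))
    true_ids = set(truth.index[truth["true_de"]])
    recovered = {
        tid for call, tid in tp_calls if call.direction == truth.loc[tid, "direction"]
    }
    sensitivity = len(recovered) / len(true_ids) if true_ids else 1.0
    observed_fdr = n_fp / len(positives) if positives else 0.0
    if tp_calls:
        direction_accuracy = sum(
            1 for call, tid in tp_calls if call.direction == truth.loc[tid, "direction"]
        ) / len(tp_calls)
    else:
        direction_accuracy = 1.0
    return sensitivity, observed_fdr, direction_accuracy
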