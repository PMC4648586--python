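"""Likelihood-ratio R-statistic differential expression for library counts.

Digital expression compares, per transcript cluster j, the read counts
x_{i,j} across m libraries with totals N_i. Under the null the x_i are
multinomial with probabilities proportional to the N_i; the log
likelihood-ratio statistic is

    f = (sum_i x_i) / (sum_i N_i)
    R = sum_i x_i * ln( x_i / (N_i * f) ),    0 * ln(0) := 0

R is 0 exactly when the proportions x_i/N_i are equal across libraries and
grows with heterogeneity. The study applied this with m = 2 per tissue
(treated vs untreated) and m = 4 across all libraries.

No analytic null is assumed; the significance cutoff is set empirically by
multinomial resampling: each cluster's total is redistributed across
libraries with probabilities N_i / sum(N), the statistic recomputed, and
the cutoff chosen as the smallest observed R* at which the estimated FDR
(mean null exceedance count / observed exceedance count) drops to the
requested level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "DECall",
    "CrossTissueTable",
    "r_statistic",
    "r_statistics",
    "null_threshold",
    "classify_de",
    "cross_tissue_categories",
]

logger = logging.getLogger(__name__)

CATEGORY_NAMES = (
    "down_both",
    "up_both",
    "up_leaf_down_root",
    "down_leaf_up_root",
    "leaf_only_up",
    "leaf_only_down",
    "root_only_up",
    "root_only_down",
)


@dataclass
class CountMatrix:
    """Clusters x libraries read counts with per-library totals N_i.

    ``counts`` is a DataFrame indexed by cluster_id with one integer column
    per library; ``totals`` the per-library read totals (column sums when
    the matrix covers every read, possibly larger for a subset).
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if len(self.counts) and (self.totals <= 0).any():
            raise ValueError("library totals must be positive")
        if list(self.counts.columns) != list(self.totals.index):
            raise ValueError("totals index must match count columns")
        if self.counts.shape[1] < 2:
            raise ValueError("need at least 2 libraries")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def subset(self, libraries: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(libraries)].copy(),
                           self.totals[list(libraries)].copy())


@dataclass
class DECall:
    cluster_id: object
    R: float
    significant: bool
    direction: str  # up / down / ns, in treated relative to untreated
    total_reads: int
    #: sign of the raw proportion difference regardless of significance
    #: (up / down / tie); used when partitioning cross-tissue categories.
    raw_direction: str = "tie"


@dataclass
class CrossTissueTable:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def r_statistic(x: Sequence[float], N: Sequence[float]) -> float:
    """R for one cluster: counts x_i over libraries with totals N_i."""
    x = np.asarray(x, dtype=float)
    N = np.asarray(N, dtype=float)
    if x.shape != N.shape:
        raise ValueError("x and N must have the same length")
    if (x < 0).any() or (N <= 0).any() or (x > N).any():
        raise ValueError("require 0 <= x_i <= N_i and N_i > 0")
    total = x.sum()
    if total == 0:
        raise ValueError("R-statistic undefined for an all-zero cluster")
    f = total / N.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / (N * f)), 0.0)
    return float(max(terms.sum(), 0.0))


def r_statistics(X: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Vectorised R over a (clusters x libraries) count array."""
    X = np.asarray(X, dtype=float)
    N = np.asarray(N, dtype=float)
    tot = X.sum(axis=1, keepdims=True)
    f = tot / N.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = X / (N[None, :] * f)
        terms = np.where(X > 0, X * np.log(np.where(X > 0, ratio, 1.0)), 0.0)
    return np.maximum(terms.sum(axis=1), 0.0)


def _testable(cm: CountMatrix, min_total: int) -> pd.DataFrame:
    tot = cm.counts.sum(axis=1)
    return cm.counts.loc[tot >= max(min_total, 1)]


def null_threshold(
    cm: CountMatrix,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 1,
    min_total: int = 2,
) -> float:
    """Empirical-FDR R cutoff by multinomial resampling.

    Each cluster's total is redistributed over the libraries with
    probabilities N_i/sum(N) for `n_perm` rounds. The cutoff is the
    smallest observed R* with (mean null count >= R*)/(observed count
    >= R*) <= fdr; +inf (with a warning) when no observed value qualifies.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    counts = _testable(cm, min_total)
    if counts.empty:
        logger.warning("no testable clusters; cutoff = +inf")
        return math.inf
    N = cm.totals.to_numpy(dtype=float)
    p = N / N.sum()
    X = counts.to_numpy(dtype=int)
    obs = np.sort(r_statistics(X, N))

    rng = np.random.default_rng(seed)
    totals = X.sum(axis=1)
    null_all = []
    for t in np.unique(totals):
        k = int((totals == t).sum())
        draws = rng.multinomial(int(t), p, size=(n_perm, k))
        null_all.append(r_statistics(draws.reshape(-1, len(p)), N))
    null = np.sort(np.concatenate(null_all))

    n_obs = len(obs)
    # exceedance counts at each candidate cutoff (the observed R values)
    obs_ge = n_obs - np.searchsorted(obs, obs, side="left")
    null_ge = (len(null) - np.searchsorted(null, obs, side="left")) / n_perm
    ok = null_ge / obs_ge <= fdr
    if not ok.any():
        logger.warning("no R cutoff reaches FDR %.3g; cutoff = +inf", fdr)
        return math.inf
    return float(obs[ok.argmax()])


def _directions(x_t: float, n_t: float, x_u: float, n_u: float) -> str:
    pt, pu = x_t / n_t, x_u / n_u
    if pt > pu:
        return "up"
    if pt < pu:
        return "down"
    return "tie"


def classify_de(
    cm: CountMatrix,
    cutoff: float,
    treated: str,
    untreated: str,
    min_total: int = 2,
    R: Optional[pd.Series] = None,
) -> list[DECall]:
    """Call significance (R >= cutoff on all of cm's libraries) and
    direction (treated vs untreated proportions) per testable cluster.

    `R` may supply precomputed statistics (e.g. from a 4-library combined
    test whose cutoff is applied while direction is read off one tissue's
    treated/untreated pair); by default R is computed from `cm` itself.
    """
    for lab in (treated, untreated):
        if lab not in cm.counts.columns:
            raise ValueError(f"library {lab!r} not in count matrix")
    counts = _testable(cm, min_total)
    if R is None:
        Rvals = pd.Series(
            r_statistics(counts.to_numpy(dtype=int), cm.totals.to_numpy(dtype=float)),
            index=counts.index,
        )
    else:
        Rvals = R.loc[counts.index]
    n_t = float(cm.totals[treated])
    n_u = float(cm.totals[untreated])
    calls = []
    for cid, row in counts.iterrows():
        r = float(Rvals[cid])
        sig = r >= cutoff
        raw = _directions(row[treated], n_t, row[untreated], n_u)
        if sig:
            if raw == "tie":
                logger.warning("cluster %r significant with tied proportions; "
                               "reported as up", cid)
                direction = "up"
            else:
                direction = raw
        else:
            direction = "ns"
        calls.append(
            DECall(cluster_id=cid, R=r, significant=sig, direction=direction,
                   total_reads=int(row.sum()), raw_direction=raw)
        )
    return calls


def cross_tissue_categories(
    root_calls: Sequence[DECall], leaf_calls: Sequence[DECall]
) -> CrossTissueTable:
    """Partition clusters significant in >= 1 tissue into the cross-tissue
    categories (up/down in both, opposite directions, tissue-specific).

    A cluster is tissue-specific when it has zero reads in the other
    tissue's libraries (total_reads of that tissue's call is 0, or the
    cluster is absent from that tissue's calls). For a tissue where the
    call is not significant the raw proportion direction is used; a raw
    tie inherits the other tissue's direction.
    """
    root = {c.cluster_id: c for c in root_calls}
    leaf = {c.cluster_id: c for c in leaf_calls}
    if len(root) != len(root_calls) or len(leaf) != len(leaf_calls):
        raise ValueError("duplicate cluster_id in calls")
    counts = dict.fromkeys(CATEGORY_NAMES, 0)
    for cid in set(root) | set(leaf):
        rc, lc = root.get(cid), leaf.get(cid)
        sig = (rc is not None and rc.significant) or (
            lc is not None and lc.significant)
        if not sig:
            continue
        r_expr = rc is not None and rc.total_reads > 0
        l_expr = lc is not None and lc.total_reads > 0
        rdir = _effective_direction(rc)
        ldir = _effective_direction(lc)
        if rdir == "tie" and ldir != "tie":
            rdir = ldir
        if ldir == "tie" and rdir != "tie":
            ldir = rdir
        if rdir == "tie":  # fully tied yet significant: the up convention
            rdir = ldir = "up"
        if l_expr and not r_expr:
            counts["leaf_only_up" if ldir == "up" else "leaf_only_down"] += 1
        elif r_expr and not l_expr:
            counts["root_only_up" if rdir == "up" else "root_only_down"] += 1
        elif rdir == "up" and ldir == "up":
            counts["up_both"] += 1
        elif rdir == "down" and ldir == "down":
            counts["down_both"] += 1
        elif rdir == "down" and ldir == "up":
            counts["up_leaf_down_root"] += 1
        else:
            counts["down_leaf_up_root"] += 1
    return CrossTissueTable(counts=counts)


def _effective_direction(call: Optional[DECall]) -> str:
    if call is None:
        return "tie"
    if call.direction != "ns":
        return call.direction
    return call.raw_direction
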