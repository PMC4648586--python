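"""Whole-pipeline validation runs on synthetic data.

Two study-shaped benchmarks: `parameter_recovery` plants known differential
expression, runs trim -> cluster -> count -> R-test (per-tissue m=2 and
combined m=4) and scores the calls against the truth table;
`null_calibration` measures the false-positive rate of the empirical-FDR
cutoff on pure multinomial null count matrices.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import diffexpr as de
from .clustering import count_matrix, greedy_cluster
from .simulate import (
    TREATED,
    UNTREATED,
    evaluate_recovery,
    four_library_design,
    simulate_libraries,
    simulate_transcriptome,
)
from .trimming import LIBRARY_PRIMER, AdapterSpec, filter_length, trim_reads

__all__ = ["parameter_recovery", "null_calibration"]


def parameter_recovery(
    seeds: Sequence[int] = (1, 2, 3, 4, 5),
    n_transcripts: int = 300,
    de_frac: float = 0.1,
    fold: float = 8.0,
    depth: int = 3000,
    error_rate: float = 0.0,
    threshold: float = 0.95,
    fdr: float = 0.05,
    n_perm: int = 1000,
    min_len: int = 100,
) -> pd.DataFrame:
    """End-to-end planted-truth recovery, one row per seed.

    Columns: sensitivity, observed_fdr, direction_accuracy (over the union
    of per-tissue m=2 and combined m=4 calls), raw_len_mean (nt, before
    trimming) and trim_recovery (fraction of trimmed reads equal to their
    exact planted insert; meaningful at error_rate 0).
    """
    adapter = AdapterSpec("primer", LIBRARY_PRIMER)
    rows = []
    for seed in seeds:
        tx = simulate_transcriptome(n_transcripts, seed=seed)
        design = four_library_design(
            tx.ids, de_frac=de_frac, fold=fold, depth=depth, seed=seed + 1000
        )
        libs, truth = simulate_libraries(
            tx, design, error_rate=error_rate, seed=seed + 2000
        )
        raw_len_mean = float(
            np.mean([len(r.seq) for reads in libs.values() for r in reads])
        )
        trimmed: dict[str, list] = {}
        n_exact = n_trimmed = 0
        tx_seqs = set(tx.sequences.values())
        for lib, reads in libs.items():
            tr, _ = trim_reads(reads, [adapter])
            n_trimmed += len(tr)
            n_exact += sum(any(t.endswith(r.seq) for t in tx_seqs) for r in tr)
            trimmed[lib], _ = filter_length(tr, min_len)

        all_calls: list[de.DECall] = []
        all_reps: dict[object, str] = {}
        # per-tissue m=2 tests
        for tissue, t_lab in TREATED.items():
            u_lab = UNTREATED[tissue]
            pool = trimmed[t_lab] + trimmed[u_lab]
            clustering = greedy_cluster(pool, threshold)
            cm = count_matrix(clustering, [t_lab, u_lab])
            cutoff = de.null_threshold(cm, fdr=fdr, n_perm=n_perm, seed=seed)
            for call in de.classify_de(cm, cutoff, t_lab, u_lab):
                all_calls.append(replace(call, cluster_id=(tissue, call.cluster_id)))
            for c in clustering.clusters:
                all_reps[(tissue, c.cluster_id)] = c.representative.seq
        # combined m=4 test, directions per tissue
        pool = [r for lib in libs for r in trimmed[lib]]
        combined = greedy_cluster(pool, threshold)
        cm4 = count_matrix(combined, list(libs))
        cutoff4 = de.null_threshold(cm4, fdr=fdr, n_perm=n_perm, seed=seed)
        testable = cm4.counts.loc[cm4.counts.sum(axis=1) >= 2]
        R4 = pd.Series(
            de.r_statistics(testable.to_numpy(int), cm4.totals.to_numpy(float)),
            index=testable.index,
        )
        for tissue, t_lab in TREATED.items():
            u_lab = UNTREATED[tissue]
            sub = de.CountMatrix(
                cm4.counts.loc[testable.index, [t_lab, u_lab]],
                cm4.totals[[t_lab, u_lab]],
            )
            for call in de.classify_de(sub, cutoff4, t_lab, u_lab,
                                       min_total=1, R=R4):
                all_calls.append(
                    replace(call, cluster_id=("combined", tissue, call.cluster_id))
                )
            for c in combined.clusters:
                all_reps[("combined", tissue, c.cluster_id)] = c.representative.seq

        sens, obs_fdr, dir_acc = evaluate_recovery(
            all_calls, truth, all_reps, tx.sequences
        )
        rows.append(
            {"seed": seed, "sensitivity": sens, "observed_fdr": obs_fdr,
             "direction_accuracy": dir_acc, "raw_len_mean": raw_len_mean,
             "trim_recovery": n_exact / n_trimmed if n_trimmed else 0.0}
        )
    return pd.DataFrame(rows).set_index("seed")


def null_calibration(
    n_seeds: int = 20,
    n_clusters: int = 200,
    library_total: int = 5000,
    fdr: float = 0.05,
    n_perm: int = 1000,
    base_seed: int = 10_000,
) -> np.ndarray:
    """False-positive fraction per seed on pure-null two-library matrices.

    Cluster totals are drawn log-normally (a plausible cluster-size
    profile) and split binomially between the libraries, so every
    significant call is a false positive.
    """
    fractions = []
    for i in range(n_seeds):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        totals = np.maximum(1, np.round(rng.lognormal(2.5, 1.0, n_clusters))).astype(int)
        t = rng.binomial(totals, 0.5)
        df = pd.DataFrame({"treated": t, "untreated": totals - t})
        cm = de.CountMatrix(
            df, pd.Series({"treated": library_total, "untreated": library_total})
        )
        cutoff = de.null_threshold(cm, fdr=fdr, n_perm=n_perm, seed=seed)
        calls = de.classify_de(cm, cutoff, "treated", "untreated")
        fractions.append(sum(c.significant for c in calls) / len(calls))
    return np.asarray(fractions)
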