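import numpy as np
import pandas as pd
import pytest

from est454.diffexpr import DECall
from est454.simulate import (
    LIBRARIES,
    evaluate_recovery,
    four_library_design,
    simulate_libraries,
    simulate_transcriptome,
)
from est454.ssr import find_ssrs
from est454.trimming import LIBRARY_PRIMER, AdapterSpec, trim_reads


class TestTranscriptome:
    def test_deterministic_per_seed(self):
        a = simulate_transcriptome(10, seed=42)
        b = simulate_transcriptome(10, seed=42)
        assert a.sequences == b.sequences
        assert a.planted_ssrs.equals(b.planted_ssrs)
        assert simulate_transcriptome(10, seed=43).sequences != a.sequences

    def test_lengths_within_range(self):
        tx = simulate_transcriptome(50, len_range=(400, 3000), seed=1)
        # planted poly(A) stub keeps lengths close to the sampled value
        assert all(380 <= len(s) <= 3050 for s in tx.sequences.values())
        assert all(s.endswith("A" * 8) for s in tx.sequences.values())

    def test_no_spike_background_near_zero(self):
        tx = simulate_transcriptome(100, ssr_spike_rate=0.0, seed=7)
        n = sum(len(find_ssrs(s)) for s in tx.sequences.values())
        assert n <= 3  # chance tandem runs in ~170 kb of random sequence

    def test_full_spike_rate_all_detectable(self):
        tx = simulate_transcriptome(30, ssr_spike_rate=1.0, seed=7)
        assert len(tx.planted_ssrs) == 30
        for tid, seq in tx.sequences.items():
            assert find_ssrs(seq), f"{tid} lacks a detectable SSR"

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_transcriptome(5, len_range=(100, 3000))


class TestDesign:
    def test_abundances_normalised_and_truth_consistent(self):
        d = four_library_design([f"t{i}" for i in range(50)], de_frac=0.2,
                                fold=8, depth=500, seed=3)
        assert np.allclose(d.abundances.sum(axis=0), 1.0)
        assert list(d.abundances.columns) == list(LIBRARIES)
        assert d.truth["true_de"].sum() == 10
        up = d.truth.index[d.truth["direction"] == "up"]
        # planted up-transcripts are enriched in treated vs untreated
        ratio = (d.abundances.loc[up, "root_treated"]
                 / d.abundances.loc[up, "root_untreated"])
        assert (ratio > 1).all()

    def test_fold_ratio_applied(self):
        d = four_library_design([f"t{i}" for i in range(40)], de_frac=0.25,
                                fold=8, depth=500, seed=5)
        ab = d.abundances
        for direction, expected in (("up", 8.0), ("down", 1 / 8.0)):
            ids = d.truth.index[d.truth["direction"] == direction]
            # compare unnormalised ratios through a non-DE reference transcript
            ref = d.truth.index[~d.truth["true_de"]][0]
            rel_t = ab.loc[ids, "leaf_treated"] / ab.loc[ref, "leaf_treated"]
            rel_u = ab.loc[ids, "leaf_untreated"] / ab.loc[ref, "leaf_untreated"]
            assert np.allclose(rel_t / rel_u, expected)


class TestLibraries:
    def _small(self, seed=11, depth=200, error_rate=0.0):
        tx = simulate_transcriptome(20, len_range=(400, 1200), seed=seed)
        d = four_library_design(tx.ids, de_frac=0.2, fold=8, depth=depth,
                                seed=seed + 1)
        libs, truth = simulate_libraries(tx, d, error_rate=error_rate,
                                         seed=seed + 2)
        return tx, libs, truth

    def test_depth_exact_per_library(self):
        _, libs, _ = self._small(depth=150)
        assert {lib: len(reads) for lib, reads in libs.items()} == {
            lib: 150 for lib in LIBRARIES
        }

    def test_deterministic_per_seed(self):
        _, a, _ = self._small(seed=21)
        _, b, _ = self._small(seed=21)
        assert {k: [(r.id, r.seq) for r in v] for k, v in a.items()} == {
            k: [(r.id, r.seq) for r in v] for k, v in b.items()
        }

    def test_error_free_reads_are_exact_primered_suffixes(self):
        tx, libs, _ = self._small(error_rate=0.0)
        primer_len = len(LIBRARY_PRIMER)
        for reads in libs.values():
            for r in reads:
                insert, tail = r.seq[:-primer_len], r.seq[-primer_len:]
                assert tail[:-1] == LIBRARY_PRIMER[:-1] and tail[-1] in "ACG"
                assert any(t.endswith(insert) for t in tx.sequences.values())

    def test_trimming_recovers_exact_inserts(self):
        tx, libs, _ = self._small(error_rate=0.0)
        ad = AdapterSpec("primer", LIBRARY_PRIMER)
        suffixes = set(tx.sequences.values())
        n = exact = 0
        for reads in libs.values():
            trimmed, _ = trim_reads(reads, [ad])
            for t in trimmed:
                n += 1
                exact += any(s.endswith(t.seq) for s in suffixes)
        assert exact / n >= 0.99

    def test_raw_length_mean_in_454_envelope(self):
        """Mean raw read length over ~10,000 reads falls in 332-388 nt."""
        tx = simulate_transcriptome(100, seed=31)
        d = four_library_design(tx.ids, depth=2500, seed=32)
        libs, _ = simulate_libraries(tx, d, seed=33)
        lengths = [len(r.seq) for reads in libs.values() for r in reads]
        assert len(lengths) == 10_000
        assert 332 <= np.mean(lengths) <= 388

    def test_errors_perturb_reads(self):
        tx, libs, _ = self._small(error_rate=0.02)
        primer_len = len(LIBRARY_PRIMER)
        mismatched = 0
        for reads in libs.values():
            for r in reads:
                insert = r.seq[:-primer_len]
                if not any(t.endswith(insert) for t in tx.sequences.values()):
                    mismatched += 1
        assert mismatched > 0


class TestEvaluateRecovery:
    def _truth(self):
        return pd.DataFrame(
            {"true_de": [True, True, False, False],
             "direction": ["up", "down", "none", "none"],
             "fold_change": [8.0, 8.0, 1.0, 1.0]},
            index=pd.Index(["t1", "t2", "t3", "t4"], name="transcript_id"),
        )

    @staticmethod
    def _call(cid, sig, direction):
        return DECall(cluster_id=cid, R=9.0 if sig else 0.1, significant=sig,
                      direction=direction, total_reads=10,
                      raw_direction=direction if direction != "ns" else "tie")

    def test_perfect_calls(self):
        truth = self._truth()
        seqs = {t: "ACGT" * 50 if t != "t2" else "GGCC" * 50
                for t in truth.index}
        reps = {1: seqs["t1"], 2: seqs["t2"]}
        calls = [self._call(1, True, "up"), self._call(2, True, "down")]
        assert evaluate_recovery(calls, truth, reps, seqs) == (1.0, 0.0, 1.0)

    def test_zero_calls_vacuous(self):
        truth = self._truth()
        seqs = {t: "ACGT" * 50 for t in truth.index}
        calls = [self._call(1, False, "ns")]
        assert evaluate_recovery(calls, truth, {1: seqs["t1"]}, seqs) == (
            0.0, 0.0, 1.0
        )

    def test_false_positive_and_unmappable_counted(self):
        truth = self._truth()
        seqs = {"t1": "ACGTAG" * 40, "t2": "GGCCAT" * 40,
                "t3": "TTGACA" * 40, "t4": "CATCGT" * 40}
        reps = {1: seqs["t1"], 3: seqs["t3"], 9: "TGCA" * 60}
        calls = [self._call(1, True, "up"), self._call(3, True, "up"),
                 self._call(9, True, "down")]
        sens, fdr, dacc = evaluate_recovery(calls, truth, reps, seqs)
        assert sens == pytest.approx(0.5)  # t1 recovered, t2 missed
        assert fdr == pytest.approx(2 / 3)  # t3 call + unmappable call
        assert dacc == 1.0

    def test_wrong_direction_counts_against_sensitivity_not_fdr(self):
        truth = self._truth()
        seqs = {"t1": "ACGTAG" * 40, "t2": "GGCCAT" * 40,
                "t3": "TTGACA" * 40, "t4": "CATCGT" * 40}
        reps = {1: seqs["t1"]}
        calls = [self._call(1, True, "down")]  # truth says up
        sens, fdr, dacc = evaluate_recovery(calls, truth, reps, seqs)
        assert sens == 0.0 and fdr == 0.0 and dacc == 0.0
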