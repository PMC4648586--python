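"""Remove the library anchor primer by error-tolerant ends-free alignment.

The cDNA synthesis primer (anchored oligo-dT, terminal V = A/C/G) sits at
the 3' end of every raw read; trimming locates it — tolerating up to 10%
errors and partial occurrences hanging off the read end — and cuts from
the match start to the read end, then drops reads shorter than 100 nt.
"""

from est454 import (
    LIBRARY_PRIMER,
    AdapterSpec,
    filter_length,
    four_library_design,
    simulate_libraries,
    simulate_transcriptome,
    trim_reads,
)

tx = simulate_transcriptome(n=50, seed=1)
design = four_library_design(tx.ids, depth=500, seed=2)
libs, _ = simulate_libraries(tx, design, seed=3)

adapter = AdapterSpec(name="anchor_primer", seq=LIBRARY_PRIMER,
                      where="three_prime", max_error_rate=0.1, min_overlap=3)
reads = libs["root_treated"]
trimmed, report = trim_reads(reads, [adapter])
kept, length_report = filter_length(trimmed, min_len=100)

print(f"reads in:            {report.n_in}")
print(f"reads trimmed:       {report.n_trimmed}")
print(f"dropped (all-primer): {report.n_dropped}")
print(f"dropped (<100 nt):   {length_report.n_dropped}")
print(f"mean length before/after: {report.mean_len_before:.1f} / "
      f"{length_report.mean_len_after:.1f} nt")
# Every simulated read carries the 23-nt primer, so all reads are trimmed
# and mean length drops by ~23 nt; error-free inserts are recovered exactly.
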