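"""Microsatellite detection with the study's MISA-style parameters.

Perfect SSRs require >= 10 mononucleotide, >= 6 dinucleotide or >= 5 tri-
to hexanucleotide repeats; perfect runs separated by at most 100 nt merge
into compound records.
"""

from est454 import compound_ssrs, find_ssrs, ssr_summary

seq = (
    "GATCCGTTAGC" + "A" * 11          # (A)11   - passes the mono minimum
    + "CGGATT" + "AG" * 6             # (AG)6   - passes the di minimum
    + "T" * 30                        # (T)30 within 100 nt: compound partner
    + "GCGGCATTACG" + "ATG" * 4       # (ATG)4  - below the tri minimum
)
perfect = find_ssrs(seq)
records = compound_ssrs(perfect, max_interruption=100)

print("perfect runs found:")
for r in perfect:
    print(f"  ({r.motif}){r.n_repeats}  at {r.start}-{r.end}")
print("\nafter compounding (gap <= 100 nt):")
for r in records:
    label = "-".join(c.motif for c in r.component_ssrs) or r.motif
    print(f"  {r.kind:8s} {label}  at {r.start}-{r.end}")

summary = ssr_summary(records, n_sequences=1, total_nt=len(seq))
print(f"\nSSR density: {summary['ssr_per_mbp']:.0f} per Mbp "
      f"({int(summary['n_perfect'])} perfect, "
      f"{int(summary['n_compound'])} compound record(s))")
# (ATG)4 is rejected (minimum is 5 repeats); the three passing runs all lie
# within 100 nt of their neighbours and merge into one compound record.
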