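"""Reference miRNA expression profile, TPM normalization and summary.

Counts, for every canonical mature miRNA, the reads whose sequence matches it
exactly, converts to TPM (counts per million of the library total), and
summarises the profile: how many miRNAs are expressed, how many are
singletons (seen once), which are highly expressed (> 10,000 raw counts) and
how the raw counts spread over orders of magnitude.
"""

from mirnome import SimulationSpec, expression_summary, filter_by_length, reference_profile
from mirnome.io import write_profile_tsv
from mirnome.simulate import simulate_sample

spec = SimulationSpec(n_hairpins=30, total_reads=80_000, seed=6)
ref, regions, library, truth = simulate_sample(spec, sample_id="demo")
filtered = filter_by_length(library, 14)

profile = reference_profile(filtered, ref)
print(f"expressed reference miRNAs: {profile.n_expressed}")

summary = expression_summary(profile, high_threshold=10_000)
print(f"singletons (raw count == 1): {summary.n_singletons}")
print(f"highly expressed (> 10,000): {summary.highly_expressed or 'none at this depth'}")
print("order-of-magnitude histogram (log10 bin -> n miRNAs):")
for b, n in summary.log10_histogram.items():
    print(f"  10^{b}: {'#' * n} {n}")

top = sorted(profile.rows.items(), key=lambda kv: -kv[1].raw)[:5]
print("\ntop 5 by raw count (name, raw, TPM):")
for name, row in top:
    print(f"  {name:>16s}  {row.raw:>6d}  {row.tpm:>12.2f}")

write_profile_tsv([profile], "scratch_profile.tsv")
print("\nwrote scratch_profile.tsv (miRNA, count, TPM per sample)")
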