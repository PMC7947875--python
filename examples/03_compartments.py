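"""Call A/B compartments from trans contacts and check them against truth.

The leading eigenvector of the trans O/E correlation matrix is oriented so
that it correlates positively with GC content (A = GC-rich open chromatin),
then each bin is labeled by the eigenvector sign.
"""

from microhic import balance, default_params, generate_dataset
from microhic import compartment_calling as cc

ds = generate_dataset(default_params(seed=1))
cmap = balance(ds.cmap)
track = cc.call_compartments(cmap, ds.gc)

print(f"orientation: corr(E1, GC) = {track.orientation_correlation:.3f} "
      f"(ambiguous={track.orientation_ambiguous})")
print(track.per_chromosome_table().to_string(index=False, float_format=lambda v: f"{v:.2f}"))

props, test = cc.a_proportions(track)
print(f"\nA-compartment proportion, micro vs macro: "
      f"{test.mean_micro:.2f} vs {test.mean_macro:.2f} "
      f"(Student t={test.statistic:.2f}, p={test.pvalue:.4f})")

called = track.labels != "NA"
acc = (track.labels[called] == ds.truth.labels[called]).mean()
print(f"planted-label recovery on called bins: {acc:.1%}")
# Microchromosomes come out strongly A-enriched, matching the planted
# micro_A_fraction of 0.9 against 0.45 on macrochromosomes.
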