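"""The sequencing arm: catalogs, mapping, and the donor-unique cascade.

Part 1 replays the bundled pooled-plasma tables: mapping percentages and
the 17 -> 6 -> 1 evidence cascade for bovine-specific miRNAs.
Part 2 simulates the positive control the real data failed to show: reads
with donor-unique miRNAs spiked in along a dose-time kernel, which the
pipeline correctly calls intake-consistent.
"""

import pandas as pd

from xenomir import (
    MiRNACatalog,
    ReadSimConfig,
    classify_catalog,
    datasets,
    evaluate_evidence,
    filter_min_count,
    map_reads,
    mapping_percentage,
    simulate_catalogs,
    simulate_timecourse,
    ubiquitous,
)

# --- Part 1: the published pooled libraries ---------------------------
stats = datasets.pooled_mapping_stats()
print("mapping percentage per pooled plasma library (miRge route):")
for run, row in stats.iterrows():
    print(f"  {run} ({row['timepoint']}): "
          f"{mapping_percentage(row['mirge_mapped'], row['total_reads'])}%")
# T3 collapses to ~47% mapped while the other time points sit at 97-99%.

table = datasets.bovine_unique_counts()
kept = filter_min_count(table, 10)
ubiq = ubiquitous(kept)
print(f"\nbovine-specific candidates: {len(table)} -> >=10 reads: {len(kept)}"
      f" -> present at all time points: {len(ubiq)} ({', '.join(ubiq.index)})")
verdicts = evaluate_evidence(table, "T0", ["T3", "T6", "T9"])
v = next(x for x in verdicts if x.mirna == "bta-mir-1839")
print(f"{v.mirna}: peak at {v.peak_timepoint} -> {v.consistency} with dietary intake")

# --- Part 2: a simulated positive control -----------------------------
host, donor = simulate_catalogs(n_host=60, n_donor=30, shared_fraction=0.5, seed=11)
part = classify_catalog(host, donor, max_distance=0)
print(f"\nsimulated catalogs: {len(part.shared)} shared, "
      f"{len(part.donor_unique)} donor-unique, {len(part.host_unique)} host-unique")

pool = MiRNACatalog("pool", [*host.entries, *donor.entries])
spiked = part.donor_unique[:2]
cfg = ReadSimConfig(catalog=pool, n_reads=20000,
                    spike=(spiked, {"T0": 0.0, "T3": 0.4, "T6": 0.15, "T9": 0.03}),
                    error_rate=0.005, seed=12)
readsets, truth = simulate_timecourse(cfg)
counts = pd.DataFrame({tp: map_reads(recs, donor, max_mismatch=1).counts
                       for tp, recs in readsets.items()})
unique_counts = counts.loc[list(part.donor_unique)].round(1)
for v in evaluate_evidence(unique_counts, "T0", ["T3", "T6", "T9"], min_count=10):
    if v.mirna in spiked:
        print(f"spiked {v.mirna}: peak {v.peak_timepoint} -> {v.consistency}")
# The spiked miRNAs peak at T3 and are called consistent — the signature
# the real plasma libraries never produced.
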