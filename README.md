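# xenomir

Tools for validating (or refuting) claims of **dietary xenomiR uptake** —
the hypothesis that food-derived microRNAs, e.g. from cow milk, enter the
consumer's circulation in functionally meaningful amounts.

The package implements the two complementary analysis arms such a
validation needs, plus a synthetic-data generator that produces inputs
with known ground truth:

**qPCR array arm** (`xenomir.qpcr`, `xenomir.screen`, `xenomir.cluster`)

* Crt matrix handling for a paired design (donors at baseline T0 and a
  post-intake peak), with "Undetermined" wells as missing values and a
  replicate-QC rule (CqSD > 0.4 flags unreliable triplicates).
* Detection filtering (≥ 9 of 10 samples) and four normalization
  strategies: raw, geometric mean of k invariant features (GM22-style),
  single reference assay (miR-16-style), and quantile normalization.
* Per-feature paired t-tests with fold change FC = 2^(−ΔCrt) and an
  uncorrected p < 0.01 hit rule, disciplined by a **concordance
  criterion**: only features significant under *every* normalization are
  treated as robust. Hits appearing under a single normalization are the
  signature of type I error.
* Sample clustering with Pearson distance (d = 1 − r) and UPGMA average
  linkage, exported as ultrametric newick.

**Sequencing arm** (`xenomir.xenomap`, `xenomir.evidence`)

* Host/donor mature-miRNA catalog partition by sequence identity: a
  donor-species miRNA with no host homolog ("donor-unique") cannot be
  produced endogenously, so its reads are the only unambiguous uptake
  signal.
* An exact, ungapped read→mature-miRNA mapper (5′-anchored, ≤ 1
  substitution, ≤ 2 nt of 3′-length tolerance), mapping percentages, RPM
  normalization, and dominance statistics.
* Evidence rules for donor-unique counts: ≥ 10 raw reads in some sample,
  presence at every time point, and an **intake-consistent** temporal
  profile (low at baseline, peaking after ingestion).
* Uptake stoichiometry: the mass balance
  `required volume = (target increase × blood volume) / (milk concentration × efficiency)`
  relating milk miRNA content to an achievable blood-level change.

## Worked example

```sh
python examples/qpcr_screen.py
```

```
simulated 223 features x 10 samples, 73 undetected wells

hits (p < 0.01) per normalization:
feature normalization        p   avg_fc
miR-029       geomean 0.000040 3.889229
miR-029          none 0.000025 4.019612
miR-029      quantile 0.000010 3.812685
miR-041      quantile 0.009937 1.129549
miR-029    single_ref 0.000151 3.796819

concordant hits: ['miR-029']
```

A −2-cycle effect planted in miR-029 at the peak time point is recovered
under all four normalizations with avg FC near 4 (a two-cycle earlier Crt
is a 2² = 4-fold increase) and survives the concordance intersection.
miR-041 is significant under quantile normalization only — exactly the
kind of single-normalization artifact the concordance criterion exists to
discard. The other examples cover the sequencing arm
(`examples/sequence_evidence.py`: mapping percentages, the 17 → 6 → 1
donor-unique evidence cascade ending in a baseline-peaking and therefore
intake-*inconsistent* candidate, and a simulated spike-in positive
control) and the stoichiometry (`examples/feasibility.py`: 75 L of milk,
or ≥ 1% systemic uptake, for a 300 fmol/L rise in blood).

A thin CLI wraps the same pipelines:

```sh
xenomir simulate --seed 3 --out fixtures/
xenomir qpcr-screen fixtures/crt_matrix.csv --out screen/
xenomir xeno-evidence --counts-csv counts.csv --out evidence/
xenomir feasibility --milk-concentration 20
```

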