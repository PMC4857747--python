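"""Synthetic qPCR matrices and small-RNA read sets with ground truth.

The generators emulate the statistical structure the analysis assumes:

* :func:`simulate_crt_matrix` — a features x samples Crt table for a
  paired design (five donors at baseline and peak by default), with
  per-feature baselines, per-donor offsets, optional injected time-point
  effects and outlier shifts, Gaussian replicate noise on the cycle scale,
  and deterministic censoring above a limit of detection (wells that would
  amplify later than the LOD "did not amplify" and become missing);
* :func:`simulate_catalogs` — host and donor mature-miRNA catalogs with a
  controlled fraction of byte-identical (shared) sequences;
* :func:`simulate_readset` — FASTQ reads drawn from a catalog with known
  per-miRNA abundance, substitution-only sequencing errors, optional
  single-miRNA dominance and donor-unique spike-ins following a dose–time
  kernel, plus exact truth counts;
* :func:`null_screen_calibration` — empirical type-I error of the full
  screen under a no-effect configuration.

Every generator draws from a named RNG stream derived from one integer
seed, so identical seeds give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rng import stream
from .errors import ConfigError
from .qpcr import CrtMatrix, make_sample_name
from .xenomap import MAX_MATURE_LEN, MIN_MATURE_LEN, MiRNACatalog

__all__ = [
    "CrtSimConfig",
    "CrtTruth",
    "ReadSimConfig",
    "simulate_crt_matrix",
    "simulate_catalogs",
    "simulate_readset",
    "simulate_timecourse",
    "null_screen_calibration",
    "CalibrationResult",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Crt matrix simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrtSimConfig:
    """Study-design parameters for the Crt simulator.

    Defaults emulate the screening design: 223 array features, five
    donors sampled at baseline (T0) and at the reported peak (T3 for
    plasma).  ``effects`` are injected differential signals as
    ``(feature, timepoint, delta_crt)`` (a negative delta means earlier
    amplification, i.e. upregulation); ``outliers`` are whole-sample
    shifts ``(donor, timepoint, shift)`` emulating compromised specimens
    that amplify several cycles late.
    """

    n_features: int = 223
    donors: int = 5
    timepoints: tuple[str, ...] = ("T0", "T3")
    tissue: str = "plasma"
    baseline_mean: float = 27.0
    baseline_sd: float = 4.0
    donor_effect_sd: float = 0.5
    noise_sd: float = 0.5
    lod: float = 35.0
    effects: tuple = ()
    outliers: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.donors < 1:
            raise ConfigError("n_features and donors must be positive")
        if len(self.timepoints) < 2:
            raise ConfigError("need at least 2 timepoints")
        for name in ("baseline_sd", "donor_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.baseline_mean < self.lod < 45:
            raise ConfigError("lod must exceed baseline_mean and stay below 45 cycles")

    def feature_names(self) -> list[str]:
        width = len(str(self.n_features))
        return [f"miR-{i + 1:0{width}d}" for i in range(self.n_features)]


@dataclass(frozen=True)
class CrtTruth:
    """Ground truth for one simulated Crt matrix."""

    baselines: pd.Series                     # per-feature baseline Crt
    donor_offsets: pd.DataFrame              # feature x donor additive profile
    effects: dict[tuple[str, str], float]    # (feature, timepoint) -> delta Crt
    outliers: dict[tuple[int, str], float]   # (donor, timepoint) -> shift
    uncensored: pd.DataFrame                 # values before LOD censoring


def simulate_crt_matrix(config: CrtSimConfig) -> tuple[CrtMatrix, CrtTruth]:
    """Draw one Crt matrix plus its ground-truth record.

    Cell model:  Crt[f, (d, t)] = baseline_f + donor_(f,d) + effect_(f,t)
    + outlier_(d,t) + N(0, noise_sd).  Values above ``lod`` are censored
    to missing ("did not amplify").

    The donor effect is a *feature-wise* profile (i.i.d. N(0,
    donor_effect_sd) per feature, shared by all of that donor's samples):
    donors differ in which miRNAs run high or low, not by a uniform
    cycle shift.  The paired design cancels it exactly in ΔCrt, while
    correlation-based clustering can see it — which is precisely how
    samples come to cluster by donor rather than by time point.
    """
    rng = stream(config.seed, "crt-matrix")
    features = config.feature_names()
    baselines = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_features),
        index=features,
    )
    donor_ids = list(range(1, config.donors + 1))
    donor_offsets = pd.DataFrame(
        rng.normal(0.0, config.donor_effect_sd, size=(config.n_features, config.donors)),
        index=features, columns=donor_ids,
    )

    effects: dict[tuple[str, str], float] = {}
    for feat, tp, delta in config.effects:
        fname = features[feat] if isinstance(feat, (int, np.integer)) else str(feat)
        if fname not in baselines.index:
            raise ConfigError(f"effect references unknown feature {feat!r}")
        if tp not in config.timepoints:
            raise ConfigError(f"effect references unknown timepoint {tp!r}")
        effects[(fname, tp)] = float(delta)
    outliers: dict[tuple[int, str], float] = {}
    for donor, tp, shift in config.outliers:
        if donor not in donor_ids or tp not in config.timepoints:
            raise ConfigError(f"outlier references unknown donor/timepoint ({donor!r}, {tp!r})")
        outliers[(int(donor), tp)] = float(shift)

    samples = [
        make_sample_name(config.tissue, d, tp) for d in donor_ids for tp in config.timepoints
    ]
    values = pd.DataFrame(index=features, columns=samples, dtype=float)
    for d in donor_ids:
        for tp in config.timepoints:
            col = make_sample_name(config.tissue, d, tp)
            eff = np.array([effects.get((f, tp), 0.0) for f in features])
            noise = rng.normal(0.0, config.noise_sd, size=config.n_features)
            values[col] = (
                baselines.to_numpy()
                + donor_offsets[d].to_numpy()
                + eff
                + outliers.get((d, tp), 0.0)
                + noise
            )
    uncensored = values.copy()
    values = values.mask(values > config.lod)
    # Guard against (astronomically unlikely) draws outside the valid range.
    values = values.clip(lower=1e-6)
    matrix = CrtMatrix(values)
    truth = CrtTruth(baselines, donor_offsets, effects, outliers, uncensored)
    return matrix, truth


# ---------------------------------------------------------------------------
# Catalog simulation
# ---------------------------------------------------------------------------

def _unique_sequences(rng: np.random.Generator, n: int, length_range, forbidden: set) -> list[str]:
    lo, hi = length_range
    out: list[str] = []
    seen = set(forbidden)
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise ConfigError(
                f"cannot draw {n} unique sequences of length {lo}-{hi}; alphabet too small"
            )
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def simulate_catalogs(
    n_host: int,
    n_donor: int,
    shared_fraction: float,
    length_range: tuple[int, int] = (19, 23),
    seed: int = 0,
) -> tuple[MiRNACatalog, MiRNACatalog]:
    """Host and donor mature-miRNA catalogs with a known shared core.

    Exactly ``round(shared_fraction * n_donor)`` donor sequences are
    byte-identical to host sequences (the cross-species homolog set); the
    remainder are unique to the donor catalog.  All sequences are unique
    within each catalog, with uniform random lengths in *length_range*
    (bounded by the mature-miRNA range 16–28 nt).
    """
    if not 0 <= shared_fraction <= 1:
        raise ConfigError("shared_fraction must be in [0, 1]")
    lo, hi = length_range
    if not (MIN_MATURE_LEN <= lo <= hi <= MAX_MATURE_LEN):
        raise ConfigError(f"length_range must lie within [{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]")
    n_shared = round(shared_fraction * n_donor)
    if n_shared > n_host:
        raise ConfigError("shared_fraction requires more host sequences than available")
    if 4 ** lo < 4 * (n_host + n_donor):
        raise ConfigError("alphabet too small for the requested catalog sizes")

    rng = stream(seed, "catalogs")
    host_seqs = _unique_sequences(rng, n_host, length_range, forbidden=set())
    shared = list(rng.choice(np.array(host_seqs, dtype=object), size=n_shared, replace=False))
    novel = _unique_sequences(rng, n_donor - n_shared, length_range, forbidden=set(host_seqs))
    donor_seqs = shared + novel

    host = MiRNACatalog.from_pairs(
        "host", [(f"hsa-sim-mir-{i + 1}", s) for i, s in enumerate(host_seqs)]
    )
    donor = MiRNACatalog.from_pairs(
        "donor", [(f"bta-sim-mir-{i + 1}", s) for i, s in enumerate(donor_seqs)]
    )
    return host, donor


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters for the small-RNA read simulator.

    ``abundance`` maps miRNA names to non-negative weights (default
    uniform over the catalog).  ``dominance`` forces one miRNA to a fixed
    fraction of reads, emulating the red-blood-cell miRNA that dominates
    plasma libraries.  ``spike`` assigns donor-unique miRNAs a
    per-timepoint dose weight (a dose–time kernel) used by
    :func:`simulate_timecourse`.
    """

    catalog: MiRNACatalog
    n_reads: int = 10000
    abundance: dict | None = None
    error_rate: float = 0.0
    dominance: tuple[str, float] | None = None
    spike: tuple[tuple[str, ...], dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.catalog) == 0:
            raise ConfigError("catalog must be non-empty")
        if self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")
        if not 0 <= self.error_rate < 0.25:
            raise ConfigError("error_rate must be in [0, 0.25)")
        names = set(self.catalog.names)
        if self.abundance is not None:
            w = np.array([self.abundance.get(n, 0.0) for n in self.catalog.names], dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ConfigError("abundance weights must be >= 0 and not all zero")
            unknown = set(self.abundance) - names
            if unknown:
                raise ConfigError(f"abundance references unknown miRNAs: {sorted(unknown)}")
        if self.dominance is not None:
            name, frac = self.dominance
            if name not in names:
                raise ConfigError(f"dominant miRNA {name!r} not in catalog")
            if not 0 < frac < 1:
                raise ConfigError("dominance fraction must be in (0, 1)")
        if self.spike is not None:
            spiked, doses = self.spike
            unknown = set(spiked) - names
            if unknown:
                raise ConfigError(f"spike references unknown miRNAs: {sorted(unknown)}")
            if any(v < 0 for v in doses.values()):
                raise ConfigError("spike dose weights must be >= 0")

    def weights(self, timepoint: str | None = None) -> pd.Series:
        """Resolved per-miRNA sampling probabilities for one sample."""
        names = self.catalog.names
        if self.abundance is None:
            w = pd.Series(1.0, index=names)
        else:
            w = pd.Series([self.abundance.get(n, 0.0) for n in names], index=names, dtype=float)
        if self.spike is not None and timepoint is not None:
            spiked, doses = self.spike
            dose = doses.get(timepoint, 0.0)
            base = w.sum()
            for n in spiked:
                # dose is expressed as a fraction of the baseline library mass
                w[n] = w[n] + dose * base / max(len(spiked), 1)
        if self.dominance is not None:
            name, frac = self.dominance
            w[name] = 0.0
            rest = w.sum()
            if rest <= 0:
                raise ConfigError("dominance needs at least one other miRNA with weight > 0")
            w = w * (1.0 - frac) / rest
            w[name] = frac
        return w / w.sum()


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(arr.size) < error_rate
    if hits.any():
        for i in np.flatnonzero(hits):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_readset(
    config: ReadSimConfig, timepoint: str | None = None, label: str | None = None
) -> tuple[list[SeqRecord], pd.Series]:
    """Draw one FASTQ read set plus exact truth counts.

    Reads are full-length copies of their source mature sequence with
    i.i.d. substitution errors at ``error_rate`` per base (no indels, the
    dominant short-read error mode).  Quality is constant 'I' (Phred 40).
    Truth counts sum to ``n_reads`` by construction.
    """
    rng = stream(config.seed, f"reads:{timepoint or 'single'}")
    names = config.catalog.names
    seqs = config.catalog.sequences
    probs = config.weights(timepoint)
    counts = pd.Series(
        rng.multinomial(config.n_reads, probs.to_numpy()), index=names, name=label or timepoint
    )
    records: list[SeqRecord] = []
    i = 0
    prefix = label or (timepoint or "sim")
    for name in names:
        for _ in range(int(counts[name])):
            seq = _mutate(seqs[name], config.error_rate, rng)
            rec = SeqRecord(Seq(seq), id=f"{prefix}_read_{i:07d}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
            i += 1
    order = rng.permutation(len(records))
    records = [records[j] for j in order]
    return records, counts


def simulate_timecourse(
    config: ReadSimConfig, timepoints=("T0", "T3", "T6", "T9")
) -> tuple[dict[str, list[SeqRecord]], pd.DataFrame]:
    """One read set per time point, sharing the config's abundance profile.

    The spike dose kernel (if any) modulates the donor-unique miRNAs per
    time point; returns the per-timepoint records and the truth CountTable
    (miRNA x timepoint).
    """
    readsets: dict[str, list[SeqRecord]] = {}
    cols = {}
    for tp in timepoints:
        recs, counts = simulate_readset(config, timepoint=tp)
        readsets[tp] = recs
        cols[tp] = counts
    return readsets, pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Screen calibration under the null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """Empirical type-I rates of the screen under a no-effect simulation."""

    rates: dict[str, float]     # normalization label -> fraction with p < alpha
    tested: dict[str, int]      # normalization label -> number of feature-tests
    alpha: float
    n_sim: int


def null_screen_calibration(
    n_sim: int,
    config: CrtSimConfig,
    alpha: float = 0.01,
    seed: int = 0,
    normalizations=None,
    **screen_kwargs,
) -> CalibrationResult:
    """Empirical per-normalization type-I rate of the full screen.

    Simulates ``n_sim`` null experiments (the config must inject no
    effects), runs the complete screen on each, and reports the fraction
    of testable feature-tests with p < alpha under every normalization.
    A well-calibrated screen should sit near alpha; because no correction
    is applied, a 223-feature array is *expected* to produce ~2 spurious
    hits per normalization at alpha = 0.01.
    """
    from .qpcr import NORMALIZATIONS
    from .screen import run_screen

    if n_sim < 1:
        raise ConfigError("n_sim must be >= 1")
    if config.effects:
        raise ConfigError("calibration requires a config with no injected effects")
    normalizations = tuple(normalizations or NORMALIZATIONS)
    baseline, peak = config.timepoints[0], config.timepoints[1]
    hits = {lab: 0 for lab in normalizations}
    tested = {lab: 0 for lab in normalizations}
    base = stream(seed, "null-calibration").integers(0, 2**31 - 1)
    for i in range(n_sim):
        cfg_i = CrtSimConfig(
            **{**config.__dict__, "seed": int((base + i) % (2**31 - 1))}
        )
        matrix, _ = simulate_crt_matrix(cfg_i)
        results = run_screen(
            matrix, baseline, peak, normalizations=normalizations, alpha=alpha, **screen_kwargs
        )
        for r in results:
            if r.status == "ok":
                tested[r.normalization] += 1
                if r.p < alpha:
                    hits[r.normalization] += 1
    rates = {lab: (hits[lab] / tested[lab] if tested[lab] else math.nan) for lab in normalizations}
    return CalibrationResult(rates=rates, tested=tested, alpha=alpha, n_sim=n_sim)
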