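"""qPCR array data model, replicate QC, detection filtering, and normalization.

The central container is :class:`CrtMatrix`: a features x samples table of
relative threshold cycles (Crt) from a medium-density qPCR array, with
per-sample metadata (donor, time point, tissue).  A missing cell means the
well did not amplify within the run ("Undetermined").  Lower Crt means more
template; one cycle earlier is approximately a two-fold higher abundance.

Four normalization strategies are provided, mirroring common practice for
circulating-miRNA arrays:

* ``normalize_geomean`` -- per-sample additive correction from the geometric
  mean of a set of invariant reference features (the GM22/GM26/RN3 style);
* ``normalize_single_ref`` -- correction from a single reference assay
  (e.g. miR-16, a common biofluids reference);
* ``normalize_quantile`` -- classical quantile normalization onto the
  across-sample mean order statistics;
* raw ("none") as the implicit fourth option handled by callers.

Corrections are centred on the across-sample mean so the overall Crt scale
is preserved and paired fold changes do not depend on the anchor.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

#: Cell contents recognized as "did not amplify".
MISSING_TOKENS = frozenset({"", "Undetermined", "undetermined", "NA", "NaN", "nan"})

#: Valid open interval for a present Crt value (a 40-cycle run with headroom).
CRT_RANGE = (0.0, 45.0)

_TISSUE_CODE = {"P": "plasma", "C": "pbmc"}
_TISSUE_PREFIX = {v: k for k, v in _TISSUE_CODE.items()}

_SAMPLE_RE = re.compile(r"^([PC])_(\d+)_(\d+)$")


def parse_sample_name(name: str) -> tuple[str, int, str]:
    """Parse a sample id like ``"P_4_3"`` into (tissue, donor, timepoint).

    The convention encodes tissue (P = plasma, C = cellular/PBMC), donor
    number, and the hour of the blood draw; ``"P_4_3"`` is plasma from donor
    4 at 3 h post-intake, returned as ``("plasma", 4, "T3")``.
    """
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise InputError(f"sample name {name!r} does not match the <P|C>_<donor>_<hour> convention")
    code, donor, hour = m.groups()
    return _TISSUE_CODE[code], int(donor), f"T{int(hour)}"


def make_sample_name(tissue: str, donor: int, timepoint: str) -> str:
    """Inverse of :func:`parse_sample_name` (timepoint given as ``"T3"``)."""
    try:
        prefix = _TISSUE_PREFIX[tissue]
    except KeyError:
        raise ConfigError(f"unknown tissue {tissue!r}; expected 'plasma' or 'pbmc'") from None
    hour = timepoint[1:] if timepoint.startswith("T") else timepoint
    return f"{prefix}_{int(donor)}_{int(hour)}"


@dataclass
class CrtMatrix:
    """Features x samples Crt table with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id;
        NaN encodes a non-amplifying well.
    meta
        DataFrame indexed by sample id with columns ``donor`` (int),
        ``timepoint`` (str, e.g. ``"T0"``) and ``tissue``
        (``"plasma"`` or ``"pbmc"``).
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    #: Range checking is relaxed for derived matrices (e.g. mean-centred data
    #: fed to clustering) that are no longer on the raw cycle scale.
    check_range: bool = True

    def __post_init__(self) -> None:
        if self.meta is None:
            # Derive metadata from conventional sample names.
            rows = [parse_sample_name(s) for s in self.values.columns]
            self.meta = pd.DataFrame(
                rows, index=self.values.columns, columns=["tissue", "donor", "timepoint"]
            )[["donor", "timepoint", "tissue"]]
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            raise InputError("duplicate feature ids")
        if vals.columns.has_duplicates:
            raise InputError("duplicate sample ids")
        arr = vals.to_numpy(dtype=float)
        present = arr[~np.isnan(arr)]
        if present.size and not np.all(np.isfinite(present)):
            raise InputError("present Crt values must be finite")
        lo, hi = CRT_RANGE
        if self.check_range and present.size and (present.min() <= lo or present.max() >= hi):
            raise InputError(f"present Crt values must lie in the open interval {CRT_RANGE}")
        missing_meta = set(vals.columns) - set(self.meta.index)
        if missing_meta:
            raise InputError(f"samples without metadata: {sorted(missing_meta)}")
        for col in ("donor", "timepoint"):
            if col not in self.meta.columns or self.meta.loc[list(vals.columns), col].isna().any():
                raise InputError(f"every sample needs {col} metadata")

    # -- conveniences --------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def detected_counts(self) -> pd.Series:
        """Number of non-missing values per feature."""
        return self.values.notna().sum(axis=1)

    def with_values(self, values: pd.DataFrame, check_range: bool | None = None) -> "CrtMatrix":
        """New matrix sharing this one's metadata."""
        cr = self.check_range if check_range is None else check_range
        return CrtMatrix(values, self.meta.copy(), check_range=cr)

    def copy(self) -> "CrtMatrix":
        return CrtMatrix(self.values.copy(), self.meta.copy(), check_range=self.check_range)

    def to_csv(self, path) -> None:
        """Write as CSV (feature rows, sample columns, blank = undetected)."""
        self.values.to_csv(path, na_rep="")


def load_crt_table(path) -> CrtMatrix:
    """Load a Crt CSV (first column feature ids, one column per sample).

    Sample metadata is parsed from the sample ids, which must follow the
    ``<P|C>_<donor>_<hour>`` convention.  Cells equal to one of the
    recognized missing tokens (blank, "Undetermined", "NA", "NaN") become
    missing; any other non-numeric cell is an error.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)

    def parse_cell(tok: str) -> float:
        tok = tok.strip()
        if tok in MISSING_TOKENS:
            return math.nan
        try:
            return float(tok)
        except ValueError:
            raise InputError(f"unparseable Crt cell {tok!r}") from None

    values = raw.map(parse_cell).astype(float)
    values.index = values.index.astype(str)
    return CrtMatrix(values)


# ---------------------------------------------------------------------------
# Replicate QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateQC:
    """Quality verdict for a group of technical qPCR replicates."""

    mean_cq: float
    sd_cq: float
    flagged: bool
    threshold: float


def qc_replicates(cq_values, threshold: float = 0.4) -> ReplicateQC:
    """Flag a replicate group whose Cq standard deviation exceeds *threshold*.

    High replicate scatter (CqSD > 0.4 by default) is characteristic of
    late, near-stochastic amplification and marks the measurement as
    unreliable.  Uses the sample standard deviation (ddof=1).
    """
    arr = np.asarray(list(cq_values), dtype=float)
    if arr.size < 2:
        raise InputError("replicate QC needs at least 2 Cq values")
    sd = float(arr.std(ddof=1))
    return ReplicateQC(mean_cq=float(arr.mean()), sd_cq=sd, flagged=sd > threshold, threshold=threshold)


# ---------------------------------------------------------------------------
# Detection filtering and reference selection
# ---------------------------------------------------------------------------

def filter_by_detection(matrix: CrtMatrix, min_detected: int) -> CrtMatrix:
    """Keep features that amplified in at least *min_detected* samples.

    The screening convention is ≥9 of 10 samples, which guarantees at
    least four complete baseline-to-peak pairs in a five-donor design.
    """
    n = matrix.n_samples
    if not 1 <= min_detected <= n:
        raise ConfigError(f"min_detected must be in [1, {n}], got {min_detected}")
    keep = matrix.detected_counts() >= min_detected
    return matrix.with_values(matrix.values.loc[keep[keep].index])


def select_invariant_features(matrix: CrtMatrix, k: int) -> list[str]:
    """The k fully-observed features with the smallest across-sample SD.

    Ties are broken lexicographically by feature id so the selection is
    deterministic.  Raises if fewer than k features are fully observed.
    """
    full = matrix.values.dropna(axis=0)
    if len(full) < k:
        raise InputError(f"need {k} fully-observed features, have {len(full)}")
    sds = full.std(axis=1, ddof=1)
    order = sorted(full.index, key=lambda f: (sds[f], f))
    return order[:k]


# ---------------------------------------------------------------------------
# Normalizations
# ---------------------------------------------------------------------------

def _geomean(frame: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of the given (fully observed) Crt rows."""
    arr = frame.to_numpy(dtype=float)
    if np.any(arr <= 0):
        raise InputError("geometric mean requires strictly positive Crt values")
    return pd.Series(np.exp(np.log(arr).mean(axis=0)), index=frame.columns)


def normalize_geomean(matrix: CrtMatrix, ref_features) -> CrtMatrix:
    """Reference-gene normalization by geometric mean of invariant features.

    The per-sample correction is

        c_s = geomean(ref Crts in sample s) - mean_s[ geomean(ref Crts) ]

    and every Crt in sample s becomes ``Crt - c_s``.  Centring on the
    across-sample mean keeps the matrix on the original cycle scale.
    """
    refs = list(ref_features)
    if not refs:
        raise ConfigError("ref_features must be non-empty")
    missing = [f for f in refs if f not in matrix.values.index]
    if missing:
        raise InputError(f"reference features absent from matrix: {missing}")
    ref_block = matrix.values.loc[refs]
    if ref_block.isna().any().any():
        raise InputError("reference features must be observed in every sample")
    gm = _geomean(ref_block)
    corrections = gm - gm.mean()
    return matrix.with_values(matrix.values.sub(corrections, axis=1))


def normalize_single_ref(matrix: CrtMatrix, ref_feature: str) -> CrtMatrix:
    """ΔCrt-style normalization on a single reference assay.

    Equivalent to :func:`normalize_geomean` with a singleton reference set;
    after normalization the reference feature is constant across samples.
    """
    return normalize_geomean(matrix, [ref_feature])


def normalize_quantile(matrix: CrtMatrix) -> CrtMatrix:
    """Quantile normalization onto the across-sample mean order statistics.

    The reference distribution is built from the fully-observed features
    (sort each sample, average across samples rank-by-rank).  Samples with
    missing cells rank only their observed values and are mapped onto the
    reference by linear interpolation of quantile position; missing cells
    stay missing.  With no missing data this is the classical algorithm and
    every sample's sorted value vector becomes identical.

    The caller is expected to have applied :func:`filter_by_detection`
    first, as in the screening pipeline.
    """
    if matrix.n_samples < 2:
        raise InputError("quantile normalization needs at least 2 samples")
    full = matrix.values.dropna(axis=0)
    m = len(full)
    if m < 2:
        raise InputError("quantile normalization needs >=2 fully-observed features for the reference")
    reference = np.sort(full.to_numpy(dtype=float), axis=0).mean(axis=1)

    from scipy.stats import rankdata

    out = matrix.values.copy()
    grid = np.arange(m, dtype=float)
    for s in out.columns:
        col = out[s]
        obs = col.dropna()
        n_s = len(obs)
        if n_s == 0:
            continue
        if n_s == 1:
            out.loc[obs.index, s] = reference[(m - 1) // 2]
            continue
        ranks = rankdata(obs.to_numpy(dtype=float))  # 1..n_s, ties averaged
        pos = (ranks - 1.0) / (n_s - 1.0) * (m - 1.0)
        out.loc[obs.index, s] = np.interp(pos, grid, reference)
    return matrix.with_values(out)


#: Normalization labels understood by the screening pipeline.
NORMALIZATIONS = ("none", "geomean", "single_ref", "quantile")
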