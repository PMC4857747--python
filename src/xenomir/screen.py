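"""Paired baseline-vs-peak differential screen over multiple normalizations.

For each array feature the screen computes per-donor ΔCrt (peak − baseline),
runs a two-tailed paired t-test, converts ΔCrt to linear fold change
(FC = 2^−ΔCrt), and flags hits at an uncorrected p < alpha.  The screen is
repeated under several normalization strategies; the robustness device is
*concordance*: only features significant under every strategy are treated
as credible.  No multiple-testing correction is applied by default (an
optional Benjamini–Hochberg adjustment is available), mirroring the
exploratory design the concordance criterion is meant to discipline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import stdtr

from .errors import ConfigError, InputError, ZeroVarianceError
from .qpcr import (
    NORMALIZATIONS,
    CrtMatrix,
    filter_by_detection,
    normalize_geomean,
    normalize_quantile,
    normalize_single_ref,
    select_invariant_features,
)

__all__ = [
    "ScreenResult",
    "paired_differences",
    "paired_t_test",
    "fold_change",
    "run_screen",
    "concordant_hits",
    "screen_frame",
]


@dataclass(frozen=True)
class ScreenResult:
    """Per-feature, per-normalization outcome of the paired screen.

    ``status`` is ``"ok"`` for a tested feature, ``"na"`` when the feature
    failed the inclusion criteria (detection filter or too few complete
    pairs), and ``"degenerate"`` when the paired differences had zero
    variance.  ``hit`` can only be True for status ``"ok"``.
    """

    feature: str
    normalization: str
    n_pairs: int
    t: float | None
    df: int | None
    p: float | None
    avg_fc: float | None
    hit: bool
    status: str
    q: float | None = None  # BH-adjusted p, populated only on request


def paired_differences(matrix: CrtMatrix, baseline: str, peak: str) -> dict[str, pd.Series]:
    """Per-feature ΔCrt = Crt(peak) − Crt(baseline), one entry per donor.

    Donors missing either side of the pair are dropped from that feature's
    series, so a feature detected in 9 of 10 samples contributes exactly
    four complete pairs in a five-donor design.
    """
    tps = set(matrix.meta["timepoint"])
    for tp in (baseline, peak):
        if tp not in tps:
            raise InputError(f"unknown timepoint {tp!r}; design has {sorted(tps)}")
    base_cols: dict[int, str] = {}
    peak_cols: dict[int, str] = {}
    for sample, row in matrix.meta.iterrows():
        if sample not in matrix.values.columns:
            continue
        if row["timepoint"] == baseline:
            base_cols[row["donor"]] = sample
        elif row["timepoint"] == peak:
            peak_cols[row["donor"]] = sample
    donors = sorted(set(base_cols) & set(peak_cols))
    out: dict[str, pd.Series] = {}
    for feature, row in matrix.values.iterrows():
        diffs = {}
        for d in donors:
            b, p = row[base_cols[d]], row[peak_cols[d]]
            if not (math.isnan(b) or math.isnan(p)):
                diffs[d] = p - b
        out[feature] = pd.Series(diffs, dtype=float)
    return out


def paired_t_test(diffs) -> tuple[float, int, float]:
    """Two-tailed one-sample t-test of the paired differences against zero.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` and the
    p value from the Student t distribution with ``n − 1`` degrees of
    freedom.  Raises :class:`ZeroVarianceError` when all differences are
    identical — constant data gives no evidence either way and must not be
    reported as p = 0.
    """
    arr = np.asarray(list(diffs), dtype=float)
    n = arr.size
    if n < 2:
        raise InputError("paired t-test needs at least 2 differences")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise ZeroVarianceError("paired differences have zero variance")
    t = float(arr.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * stdtr(df, -abs(t)))
    return t, df, p


def fold_change(diffs, geometric: bool = False) -> float:
    """Average linear fold change implied by per-donor ΔCrt values.

    Each donor's FC is 2^(−ΔCrt): a one-cycle earlier Crt at peak doubles
    the implied abundance.  The default is the arithmetic mean of per-donor
    FCs; ``geometric=True`` returns 2^(−mean ΔCrt) instead.
    """
    arr = np.asarray(list(diffs), dtype=float)
    if arr.size == 0:
        raise InputError("fold_change needs at least one difference")
    if geometric:
        return float(2.0 ** (-arr.mean()))
    return float(np.mean(2.0 ** (-arr)))


def _apply_normalization(
    label: str,
    filtered: CrtMatrix,
    n_invariant: int,
    ref_feature: str | None,
) -> CrtMatrix:
    if label == "none":
        return filtered
    if label == "geomean":
        refs = select_invariant_features(filtered, n_invariant)
        return normalize_geomean(filtered, refs)
    if label == "single_ref":
        ref = ref_feature or select_invariant_features(filtered, 1)[0]
        return normalize_single_ref(filtered, ref)
    if label == "quantile":
        return normalize_quantile(filtered)
    raise ConfigError(f"unknown normalization {label!r}; choose from {NORMALIZATIONS}")


def run_screen(
    matrix: CrtMatrix,
    baseline: str,
    peak: str,
    normalizations=NORMALIZATIONS,
    min_detected: float = 0.9,
    min_pairs: int = 4,
    alpha: float = 0.01,
    n_invariant: int = 22,
    ref_feature: str | None = None,
    geometric_fc: bool = False,
    bh_correct: bool = False,
) -> list[ScreenResult]:
    """Run the paired screen under each normalization strategy.

    Parameters
    ----------
    min_detected
        Detection-filter threshold.  A value ≤ 1 is a fraction of the
        sample count (default 0.9, i.e. ≥9 of 10 samples); a value > 1 is
        an absolute sample count.
    min_pairs
        Minimum complete baseline→peak pairs required to test a feature.
    alpha
        Uncorrected significance threshold for the hit flag (default 0.01).
    n_invariant, ref_feature
        Reference-set size for ``geomean`` and the assay used by
        ``single_ref`` (default: the single most invariant feature).
    bh_correct
        If True, attach Benjamini–Hochberg adjusted p values (per
        normalization) and flag hits on q < alpha instead.

    Every feature of the input matrix yields a result under every
    normalization; features failing inclusion are reported with status
    ``"na"`` rather than silently dropped.
    """
    if not 0 < alpha <= 1:
        raise ConfigError("alpha must be in (0, 1]")
    n = matrix.n_samples
    min_det = int(math.ceil(min_detected * n - 1e-9)) if min_detected <= 1 else int(min_detected)
    filtered = filter_by_detection(matrix, min_det)

    results: list[ScreenResult] = []
    for label in normalizations:
        normed = _apply_normalization(label, filtered, n_invariant, ref_feature)
        diffs_by_feature = paired_differences(normed, baseline, peak)
        label_results: list[ScreenResult] = []
        for feature in matrix.features:
            diffs = diffs_by_feature.get(feature)
            if diffs is None or len(diffs) < min_pairs:
                label_results.append(
                    ScreenResult(feature, label, 0 if diffs is None else len(diffs),
                                 None, None, None, None, False, "na")
                )
                continue
            try:
                t, df, p = paired_t_test(diffs)
            except ZeroVarianceError:
                label_results.append(
                    ScreenResult(feature, label, len(diffs), None, None, None,
                                 fold_change(diffs, geometric_fc), False, "degenerate")
                )
                continue
            fc = fold_change(diffs, geometric_fc)
            label_results.append(
                ScreenResult(feature, label, len(diffs), t, df, p, fc, p < alpha, "ok")
            )
        if bh_correct:
            label_results = _attach_bh(label_results, alpha)
        results.extend(label_results)
    return results


def _attach_bh(results: list[ScreenResult], alpha: float) -> list[ScreenResult]:
    """Benjamini–Hochberg adjustment over the tested features of one label."""
    tested = [(i, r.p) for i, r in enumerate(results) if r.status == "ok"]
    if not tested:
        return results
    order = sorted(tested, key=lambda ip: ip[1])
    m = len(order)
    qs = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i, p = order[rank - 1]
        running = min(running, p * m / rank)
        qs[rank - 1] = running
    out = list(results)
    for (i, _), q in zip(order, qs):
        r = out[i]
        out[i] = ScreenResult(r.feature, r.normalization, r.n_pairs, r.t, r.df,
                              r.p, r.avg_fc, q < alpha, r.status, q=q)
    return out


def concordant_hits(results: list[ScreenResult]) -> set[str]:
    """Features that are hits under *every* normalization present.

    An empty intersection is the expected null outcome: hits that appear
    under one normalization only are the signature of type I error, not of
    a robust biological change.
    """
    by_label: dict[str, set[str]] = {}
    for r in results:
        by_label.setdefault(r.normalization, set())
        if r.hit:
            by_label[r.normalization].add(r.feature)
    if len(by_label) < 2:
        raise ConfigError("concordance needs results from at least 2 normalizations")
    sets = list(by_label.values())
    return set.intersection(*sets)


def screen_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabular view of screen results (one row per feature x normalization)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "normalization": r.normalization,
                "n_pairs": r.n_pairs,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "q": r.q,
                "avg_fc": r.avg_fc,
                "hit": r.hit,
                "status": r.status,
            }
            for r in results
        ]
    )
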