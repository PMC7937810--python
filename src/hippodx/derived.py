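"""Per-subject and per-group derived morphometric statistics.

Implements the quantities a volumetry workup reports for each subject and
cohort: head-size-normalized volumes (percent of total intracranial volume),
the left-right laterality asymmetry index, z-scores of patients against a
healthy-control reference, and mean/95%-CI reference ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable


def normalize_to_tiv(volume, tiv):
    """Volume as percent of total intracranial volume: ``v * 100 / tiv``.

    Accepts scalars or arrays; invariant under joint rescaling of both
    arguments.  ``tiv <= 0`` is an error.
    """
    volume = np.asarray(volume, dtype=float)
    tiv = np.asarray(tiv, dtype=float)
    if np.any(tiv <= 0):
        raise ValueError("TIV must be > 0")
    if np.any(volume < 0):
        raise ValueError("volumes must be >= 0")
    out = volume * 100.0 / tiv
    return float(out) if out.ndim == 0 else out


def asymmetry_index(right, left):
    """Laterality index in percent: ``(R - L) / ((R + L)/2) * 100``.

    Positive values mean the right structure is larger.  The index is
    bounded in (-200, 200); it reaches +/-200 only when one side has zero
    volume, which is propagated with a warning rather than NaN.  Both sides
    zero is undefined and raises.
    """
    right = np.asarray(right, dtype=float)
    left = np.asarray(left, dtype=float)
    if np.any(right < 0) or np.any(left < 0):
        raise ValueError("volumes must be >= 0")
    both_zero = (right == 0) & (left == 0)
    if np.any(both_zero):
        raise ValueError("asymmetry undefined when both sides are zero")
    if np.any((right == 0) | (left == 0)):
        warnings.warn(
            "zero volume on one side: asymmetry index saturates at +/-200",
            stacklevel=2,
        )
    out = (right - left) / ((right + left) / 2.0) * 100.0
    return float(out) if out.ndim == 0 else out


def zscore(value, hc_mean, hc_sd):
    """Standardize against the healthy-control reference: ``(x - m) / s``."""
    hc_sd = np.asarray(hc_sd, dtype=float)
    if np.any(hc_sd <= 0):
        raise ValueError("reference SD must be > 0")
    out = (np.asarray(value, dtype=float) - np.asarray(hc_mean, dtype=float)) / hc_sd
    return float(out) if out.ndim == 0 else out


@dataclass
class ReferenceRange:
    """Mean and confidence interval of one measure in one group."""

    region: str
    group: str
    mean: float
    ci_low: float
    ci_high: float
    sd: float
    n: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("CI must bracket the mean")
        if self.sd < 0 or self.n < 2:
            raise ValueError("need sd >= 0 and n >= 2")


def reference_range(samples, level: float = 0.95, region: str = "", group: str = "") -> ReferenceRange:
    """Mean, sample SD (n-1 denominator), and t-based CI of a sample.

    CI = mean +/- t_{n-1, (1+level)/2} * SD / sqrt(n), the usual normal-theory
    interval reported by standard statistics packages.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for a reference range")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = stats.t.ppf((1 + level) / 2, df=n - 1) * sd / np.sqrt(n)
    return ReferenceRange(region, group, mean, mean - half, mean + half, sd, n, level)


# ---------------------------------------------------------------------------
# Table-level helpers
# ---------------------------------------------------------------------------

def paired_regions(table: FeatureTable) -> list[tuple[str, str, str]]:
    """Find (stem, right_feature, left_feature) volume pairs in a table.

    Pairing is by name: ``<stem>_right`` / ``<stem>_left`` (only volume
    features participate).
    """
    vols = set(table.features_of_kind("volume"))
    pairs = []
    for f in sorted(vols):
        if table.registry[f][1] == "right" and f.endswith("_right"):
            stem = f[: -len("_right")]
            lf = stem + "_left"
            if lf in vols:
                pairs.append((stem, f, lf))
    return pairs


def derived_features(table: FeatureTable) -> pd.DataFrame:
    """Per-subject derived feature table.

    For every volume feature adds ``<name>_pct`` (percent of TIV); for every
    right/left pair adds ``<stem>_asym`` (asymmetry index, %).  Original
    absolute columns are retained.
    """
    out = {f: table.data[f] for f in table.feature_names}
    for f in table.features_of_kind("volume"):
        if table.registry[f][1] != "global" and not f.endswith("_pct"):
            out[f + "_pct"] = normalize_to_tiv(table.data[f].to_numpy(), table.tiv.to_numpy())
    for stem, rf, lf in paired_regions(table):
        out[stem + "_asym"] = asymmetry_index(table.data[rf].to_numpy(), table.data[lf].to_numpy())
    return pd.DataFrame(out, index=table.data.index)


def reference_table(table: FeatureTable, level: float = 0.95) -> pd.DataFrame:
    """Group reference ranges in the published two-method table layout.

    One row per (group, region, measure) with measure in
    {volume_mm3, pct_tiv, asym_pct}: mean, CI bounds, SD, n, and explicit
    units.  The group asymmetry is the mean of per-subject indices (how the
    published tables are read), not the index of the group means; the latter
    is exposed as ``asym_of_means`` for the asym_pct rows.
    """
    feats = derived_features(table)
    rows = []
    for group in [g for g in ("HC", "RHS", "LHS", "unknown") if (table.groups == g).any()]:
        sub = feats.loc[table.groups == group]
        for f in table.feature_names:
            if table.registry[f][0] != "volume" or table.registry[f][1] == "global":
                continue
            for col, measure, unit in ((f, "volume_mm3", "mm3"), (f + "_pct", "pct_tiv", "%TIV")):
                rr = reference_range(sub[col], level, region=f, group=group)
                rows.append(
                    dict(group=group, region=f, measure=measure, unit=unit,
                         mean=rr.mean, ci_low=rr.ci_low, ci_high=rr.ci_high,
                         sd=rr.sd, n=rr.n, asym_of_means=np.nan)
                )
        for stem, rf, lf in paired_regions(table):
            rr = reference_range(sub[stem + "_asym"], level, region=stem, group=group)
            rows.append(
                dict(group=group, region=stem, measure="asym_pct", unit="%",
                     mean=rr.mean, ci_low=rr.ci_low, ci_high=rr.ci_high,
                     sd=rr.sd, n=rr.n,
                     asym_of_means=asymmetry_index(sub[rf].mean(), sub[lf].mean()))
            )
    return pd.DataFrame(rows)


def zscore_table(table: FeatureTable, reference_group: str = "HC") -> pd.DataFrame:
    """Per-subject z-scores of %TIV volumes against a reference group.

    Returns a subjects-by-features frame of z-scores for every non-global
    volume feature, standardized by the reference group's mean and sample SD
    of the %TIV value.
    """
    if not (table.groups == reference_group).any():
        raise ValueError(f"reference group {reference_group!r} absent from table")
    feats = derived_features(table)
    pct_cols = [
        f + "_pct"
        for f in table.features_of_kind("volume")
        if table.registry[f][1] != "global" and not f.endswith("_pct")
    ]
    ref = feats.loc[table.groups == reference_group, pct_cols]
    mean, sd = ref.mean(), ref.std(ddof=1)
    if (sd <= 0).any():
        raise ValueError("degenerate reference SD")
    z = (feats[pct_cols] - mean) / sd
    z.columns = [c.replace("_pct", "_z") for c in z.columns]
    return z
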