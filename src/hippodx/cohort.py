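"""Synthetic cohort generation from published group distributions.

The package ships a parameter file transcribing, for each volumetry method
(FreeSurfer-style ``FS``, volBrain-style ``vB``), region and group (healthy
controls, right and left hippocampal sclerosis), the printed group mean and
95% CI of the %TIV volume per hemisphere and of the per-subject asymmetry
index.  From those the generator builds cohorts with the same first- and
second-moment structure:

* per subject, a total intracranial volume TIV ~ Normal(tiv_mean, tiv_sd),
  truncated positive;
* per region, a bilateral mean %TIV level m ~ Normal((right+left)/2, pct_sd)
  truncated positive, and an asymmetry a ~ Normal(asym_mean, asym_sd)
  truncated to (-200, 200); the hemispheres are reconstructed as
  right% = m (1 + a/200) and left% = m (1 - a/200), which makes the
  per-subject asymmetry index reproduce a exactly;
* absolute volumes in mm3 follow as pct * TIV / 100;
* group-invariant nuisance features (bilateral volumes and cortical
  thicknesses) are drawn i.i.d. from the same per-feature Gaussian in every
  group, emulating non-hippocampal regions that carry no diagnostic signal.

Group SDs are back-derived from the printed 95% CIs via
``sd = CI_half_width * sqrt(n) / 1.96``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import FeatureTable, SubjectRecord, assemble_table

GROUP_SIZES = {"HC": 61, "RHS": 22, "LHS": 35}
METHODS = ("FS", "vB")


def sd_from_ci(mean: float, ci_low: float, ci_high: float, n: int) -> float:
    """Back-derive a sample SD from a normal-theory 95% CI.

    ``sd = ((ci_high - ci_low)/2) * sqrt(n) / 1.96``.  The z quantile is
    used rather than t; at the group sizes involved the difference is under
    2% and well inside downstream tolerances.
    """
    if ci_low > ci_high:
        raise ValueError("inverted CI bounds")
    if n < 2:
        raise ValueError("need n >= 2")
    return float((ci_high - ci_low) / 2.0 * np.sqrt(n) / 1.96)


@dataclass
class GroupParams:
    """Generating parameters of one region in one group."""

    n_ref: int
    right_pct_mean: float
    left_pct_mean: float
    right_pct_sd: float
    left_pct_sd: float
    asym_mean: float
    asym_sd: float

    @property
    def pct_sd(self) -> float:
        """SD of the bilateral mean %TIV level (average of the side SDs)."""
        return 0.5 * (self.right_pct_sd + self.left_pct_sd)

    @property
    def mid_pct_mean(self) -> float:
        return 0.5 * (self.right_pct_mean + self.left_pct_mean)


@dataclass
class RegionParams:
    """Per-group generating parameters for one region of one method."""

    region: str
    method: str
    groups: dict[str, GroupParams] = field(default_factory=dict)


def load_reference_params(method: str) -> list[RegionParams]:
    """Load the packaged per-region group parameters for one method.

    ``FS`` yields the whole hippocampus plus 12 subfields; ``vB`` the whole
    hippocampus plus 5 subfield groupings.  Every region carries parameters
    for all three groups.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    text = resources.files("hippodx.data").joinpath("reference_params.csv").read_text()
    rows = [r for r in csv.DictReader(l for l in text.splitlines() if not l.startswith("#"))]
    regions: dict[str, RegionParams] = {}
    for r in rows:
        if r["method"] != method:
            continue
        reg = regions.setdefault(r["region"], RegionParams(region=r["region"], method=method))
        n = int(r["n"])
        reg.groups[r["group"]] = GroupParams(
            n_ref=n,
            right_pct_mean=float(r["right_pct_mean"]),
            left_pct_mean=float(r["left_pct_mean"]),
            right_pct_sd=sd_from_ci(float(r["right_pct_mean"]), float(r["right_pct_lo"]),
                                    float(r["right_pct_hi"]), n),
            left_pct_sd=sd_from_ci(float(r["left_pct_mean"]), float(r["left_pct_lo"]),
                                   float(r["left_pct_hi"]), n),
            asym_mean=float(r["asym_mean"]),
            asym_sd=sd_from_ci(float(r["asym_mean"]), float(r["asym_lo"]),
                               float(r["asym_hi"]), n),
        )
    out = list(regions.values())
    for reg in out:
        if set(reg.groups) != set(GROUP_SIZES):
            raise ValueError(f"region {reg.region}: missing groups {set(GROUP_SIZES) - set(reg.groups)}")
    return out


@dataclass
class CohortSpec:
    """Design of a simulated cohort.

    Defaults reproduce the reference study conditions: 61 healthy controls,
    22 right- and 35 left-HS patients, TIV ~ Normal(1.5e6, 1.5e5) mm3, and
    20 nuisance volume + 40 nuisance thickness features with no group
    effect.
    """

    n_hc: int = 61
    n_rhs: int = 22
    n_lhs: int = 35
    method: str = "FS"          # FS | vB | both
    tiv_mean: float = 1.5e6
    tiv_sd: float = 1.5e5
    n_nuisance_volume: int = 20
    n_nuisance_thickness: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_rhs, self.n_lhs) < 2:
            raise ValueError("group sizes must be >= 2")
        if self.tiv_sd < 0:
            raise ValueError("tiv_sd must be >= 0")
        if self.method not in ("FS", "vB", "both"):
            raise ValueError(f"method must be FS, vB or both, got {self.method!r}")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"HC": self.n_hc, "RHS": self.n_rhs, "LHS": self.n_lhs}


def _truncated_normal(rng, mean, sd, size, low=0.0, high=np.inf):
    """Rejection-sampled truncated normal (open interval)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    sd = np.broadcast_to(np.asarray(sd, dtype=float), size).copy()
    x = rng.normal(mean, sd)
    bad = (x <= low) | (x >= high)
    while bad.any():
        x[bad] = rng.normal(mean[bad], sd[bad])
        bad = (x <= low) | (x >= high)
    return x


def simulate_cohort(spec: CohortSpec) -> tuple[FeatureTable, dict[str, str]]:
    """Simulate a cohort; returns the feature table and a labels dict.

    Feature names are ``<method>_<Region>_<side>`` (absolute mm3 volumes),
    ``nonhipp_vol_##`` and ``nonhipp_thickness_##``.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    methods = list(METHODS) if spec.method == "both" else [spec.method]
    params = {m: load_reference_params(m) for m in methods}

    # group-invariant nuisance feature population parameters (drawn once)
    nuis_vol_mean = rng.uniform(0.05, 1.0, size=spec.n_nuisance_volume)       # %TIV
    nuis_thk_mean = rng.uniform(1.5, 3.5, size=spec.n_nuisance_thickness)     # mm

    records: list[SubjectRecord] = []
    labels: dict[str, str] = {}
    registry: dict[str, tuple[str, str]] = {}
    counter = 0
    for group, n in spec.group_sizes.items():
        tiv = _truncated_normal(rng, spec.tiv_mean, spec.tiv_sd, n)
        region_sides: dict[str, np.ndarray] = {}
        for m in methods:
            for reg in params[m]:
                gp = reg.groups[group]
                mlevel = _truncated_normal(rng, gp.mid_pct_mean, gp.pct_sd, n)
                a = _truncated_normal(rng, gp.asym_mean, gp.asym_sd, n, low=-200.0, high=200.0)
                right_pct = mlevel * (1 + a / 200.0)
                left_pct = mlevel * (1 - a / 200.0)
                base = f"{m}_{reg.region}"
                region_sides[f"{base}_right"] = right_pct * tiv / 100.0
                region_sides[f"{base}_left"] = left_pct * tiv / 100.0
                registry.setdefault(f"{base}_right", ("volume", "right"))
                registry.setdefault(f"{base}_left", ("volume", "left"))
        nuis_vol = _truncated_normal(
            rng, nuis_vol_mean[None, :], 0.1 * nuis_vol_mean[None, :], (n, spec.n_nuisance_volume)
        ) * tiv[:, None] / 100.0
        nuis_thk = _truncated_normal(
            rng, nuis_thk_mean[None, :], 0.15, (n, spec.n_nuisance_thickness)
        )
        for j in range(spec.n_nuisance_volume):
            registry.setdefault(f"nonhipp_vol_{j:02d}", ("volume", "bilateral"))
        for j in range(spec.n_nuisance_thickness):
            registry.setdefault(f"nonhipp_thickness_{j:02d}", ("thickness", "bilateral"))

        for i in range(n):
            counter += 1
            sid = f"sub-{counter:04d}"
            measures = {name: float(vals[i]) for name, vals in region_sides.items()}
            measures.update(
                {f"nonhipp_vol_{j:02d}": float(nuis_vol[i, j]) for j in range(spec.n_nuisance_volume)}
            )
            measures.update(
                {f"nonhipp_thickness_{j:02d}": float(nuis_thk[i, j])
                 for j in range(spec.n_nuisance_thickness)}
            )
            kinds = {name: registry[name][0] for name in measures}
            records.append(
                SubjectRecord(subject_id=sid, tiv=float(tiv[i]), measures=measures,
                              group=group, kinds=kinds)
            )
            labels[sid] = group

    table = assemble_table(records, registry=registry)
    return table, labels


def group_scalar_params(method: str, region: str, measure: str, group: str) -> tuple[float, float, int]:
    """(mean, sd, n) of one scalar discriminator in one group.

    ``measure`` is ``right_pct``, ``left_pct`` or ``asym``; SDs are
    CI-back-derived.  This is the Gaussian summary the generator and the
    ROC replication sample from.
    """
    for reg in load_reference_params(method):
        if reg.region == region:
            gp = reg.groups[group]
            if measure == "right_pct":
                return gp.right_pct_mean, gp.right_pct_sd, gp.n_ref
            if measure == "left_pct":
                return gp.left_pct_mean, gp.left_pct_sd, gp.n_ref
            if measure == "asym":
                return gp.asym_mean, gp.asym_sd, gp.n_ref
            raise ValueError(f"unknown measure {measure!r}")
    raise KeyError(f"region {region!r} not in {method} parameter set")


def simulate_discriminator_auc(
    method: str,
    region: str,
    measure: str,
    positive_group: str,
    direction: str,
    n_replicates: int = 200,
    seed: int = 0,
    negative_group: str = "HC",
) -> np.ndarray:
    """Monte-Carlo replication of a scalar discriminator's ROC AUC.

    For each replicate, draws the discriminator for the two groups from
    their published Gaussian summaries (group sizes as published) and
    computes the pair-counting AUC with the patient group positive.
    Returns the per-replicate AUCs.
    """
    from .roc import auc as _auc

    pos_mean, pos_sd, n_pos = group_scalar_params(method, region, measure, positive_group)
    neg_mean, neg_sd, n_neg = group_scalar_params(method, region, measure, negative_group)
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    for i in range(n_replicates):
        scores = np.r_[rng.normal(pos_mean, pos_sd, n_pos), rng.normal(neg_mean, neg_sd, n_neg)]
        out[i] = _auc(scores, labels, direction)
    return out


# ---------------------------------------------------------------------------
# Fixture writers (round-trip partners of hippodx.io readers)
# ---------------------------------------------------------------------------

def write_fixture_stats(record: SubjectRecord, outdir) -> list[str]:
    """Write one subject as reader-compatible plain-text fixture files.

    Emits a FreeSurfer-dialect ``<id>.stats`` (volume measures), an optional
    ``<id>.thickness.stats`` (thickness measures), and a volBrain-dialect
    ``<id>_vb.csv`` for all right/left volume pairs.  Values are written as
    ``repr`` decimal text, so reading them back is numerically exact.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = []
    vol = {n: v for n, v in record.measures.items() if record.kind_of(n) == "volume"}
    thk = {n: v for n, v in record.measures.items() if record.kind_of(n) == "thickness"}

    def _write_stats(path, measures):
        with open(path, "w") as fh:
            fh.write("# synthetic morphometry fixture\n")
            fh.write(
                "# Measure EstimatedTotalIntraCranialVol, eTIV, "
                f"Estimated Total Intracranial Volume, {record.tiv!r}, mm^3\n"
            )
            fh.write("# ColHeaders StructName Value\n")
            for name, value in measures.items():
                fh.write(f"{name} {value!r}\n")
        paths.append(str(path))

    if vol:
        _write_stats(os.path.join(outdir, f"{record.subject_id}.stats"), vol)
    if thk:
        _write_stats(os.path.join(outdir, f"{record.subject_id}.thickness.stats"), thk)

    stems = sorted(
        {n[: -len("_right")] for n in vol if n.endswith("_right") and n[: -len("_right")] + "_left" in vol}
    )
    if stems:
        vb_path = os.path.join(outdir, f"{record.subject_id}_vb.csv")
        with open(vb_path, "w") as fh:
            fh.write("structure,right_mm3,left_mm3,right_pct,left_pct\n")
            fh.write(f"TIV,{record.tiv!r},,100,\n")
            for stem in stems:
                r, l = vol[stem + "_right"], vol[stem + "_left"]
                fh.write(
                    f"{stem},{r!r},{l!r},{r * 100.0 / record.tiv!r},{l * 100.0 / record.tiv!r}\n"
                )
        paths.append(vb_path)
    return paths


def write_cohort_fixtures(table: FeatureTable, outdir) -> str:
    """Write every subject's fixture files plus a ``labels.csv``."""
    os.makedirs(outdir, exist_ok=True)
    for sid in table.subject_ids:
        rec = SubjectRecord(
            subject_id=sid,
            tiv=float(table.tiv[sid]),
            measures={f: float(table.data.at[sid, f]) for f in table.feature_names},
            group=str(table.groups[sid]),
            kinds={f: table.registry[f][0] for f in table.feature_names},
        )
        write_fixture_stats(rec, outdir)
    labels_path = os.path.join(outdir, "labels.csv")
    pd.DataFrame({"subject_id": table.subject_ids, "group": table.groups.values}).to_csv(
        labels_path, index=False
    )
    return labels_path
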