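"""End-to-end orchestration: cohort -> derived stats -> ROC -> RF validation.

A single :class:`RunConfig` drives the whole pipeline.  One master seed
governs every stochastic stage; per-stage seeds are derived by stable
hashing of (master seed, stage name), and a hash of the full configuration
is embedded in every output header so artifacts can be traced back to the
run that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import derived, forest, roc
from .cohort import CohortSpec, simulate_cohort
from .forest import PFEConfig
from .io import FeatureTable, read_freesurfer_stats, read_labels, assemble_table

logger = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input mode)."""

    mode: str = "simulate"                    # simulate | ingest
    outdir: str = "hippodx_out"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    pfe: PFEConfig = field(default_factory=PFEConfig)
    stats_dir: str | None = None
    labels_csv: str | None = None
    seed: int = 0
    run_validation: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and not (self.stats_dir and self.labels_csv):
            raise ValueError("ingest mode needs stats_dir and labels_csv")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortSpec(**raw["cohort"])
        if "pfe" in raw:
            raw["pfe"] = PFEConfig(**raw["pfe"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def ingest_cohort(stats_dir, labels_csv) -> FeatureTable:
    """Read per-subject stats fixtures plus a labels file into a table.

    Expects ``<id>.stats`` (volumes, with an eTIV header line) and optional
    ``<id>.thickness.stats`` companions, as written by
    :func:`hippodx.cohort.write_fixture_stats`.
    """
    labels = read_labels(labels_csv)
    records = []
    for fname in sorted(os.listdir(stats_dir)):
        if not fname.endswith(".stats") or fname.endswith(".thickness.stats"):
            continue
        sid = fname[: -len(".stats")]
        rec = read_freesurfer_stats(os.path.join(stats_dir, fname), subject_id=sid)
        tpath = os.path.join(stats_dir, sid + ".thickness.stats")
        if os.path.exists(tpath):
            trec = read_freesurfer_stats(tpath, subject_id=sid, kind="thickness")
            rec.measures.update(trec.measures)
            rec.kinds.update(trec.kinds)
        records.append(rec)
    if not records:
        raise ValueError(f"no .stats files found in {stats_dir}")
    return assemble_table(records, labels=labels)


def standard_roc_tasks(table: FeatureTable) -> list[dict]:
    """The published diagnostic grid: per method, hippocampal %TIV volume,
    absolute volume, and asymmetry, each against HC for both patient groups.

    For volumes the ipsilateral (smaller) side is the discriminator with
    lower values positive; for the signed asymmetry index, right-HS shifts
    negative and left-HS positive.
    """
    methods = sorted({f.split("_")[0] for f in table.feature_names
                      if f.endswith("_Hippocampus_right") or f == "Hippocampus_right"})
    tasks = []
    for m in methods:
        stem = f"{m}_Hippocampus" if f"{m}_Hippocampus_right" in table.feature_names else "Hippocampus"
        for side, group, direction_asym in (("right", "RHS", "lower_is_positive"),
                                            ("left", "LHS", "higher_is_positive")):
            tasks += [
                dict(column=f"{stem}_{side}_pct", positive_group=group,
                     direction="lower_is_positive"),
                dict(column=f"{stem}_{side}", positive_group=group,
                     direction="lower_is_positive"),
                dict(column=f"{stem}_asym", positive_group=group, direction=direction_asym),
            ]
    return tasks


def _write_csv(df: pd.DataFrame, path, header: str, **to_csv_kw) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, **to_csv_kw)


def run_all(config: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``config.outdir``.

    Artifacts: ``cohort.csv`` (canonical table), ``derived.csv`` (%TIV and
    asymmetry per subject), ``reference_ranges.csv``, ``roc_table.csv``,
    ``zscores.csv`` (per-region mean z by HS side), three
    ``rfc_<task>.json`` validation reports, and ``run.log``.  Any stage
    error is re-raised with the stage name in the message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    h = config.config_hash()
    header = f"# hippodx config_hash={h} seed={config.seed}\n"
    artifacts: dict = {"config_hash": h}

    def stage(name):
        def wrap(fn):
            try:
                logger.info("stage %s", name)
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    if config.mode == "simulate":
        spec = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, "simulate"))
        table, _labels = stage("simulate")(lambda: simulate_cohort(spec))
    else:
        table = stage("ingest")(lambda: ingest_cohort(config.stats_dir, config.labels_csv))

    cohort_path = os.path.join(config.outdir, "cohort.csv")
    _write_csv(table.to_dataframe(), cohort_path, header, index_label="subject_id")
    artifacts["cohort"] = cohort_path

    feats = stage("derive")(lambda: derived.derived_features(table))
    derived_path = os.path.join(config.outdir, "derived.csv")
    _write_csv(feats, derived_path, header, index_label="subject_id")
    artifacts["derived"] = derived_path

    ranges = stage("refvalues")(lambda: derived.reference_table(table))
    ranges_path = os.path.join(config.outdir, "reference_ranges.csv")
    _write_csv(ranges, ranges_path, header, index=False)
    artifacts["reference_ranges"] = ranges_path

    roc_df = stage("roc-table")(
        lambda: roc.diagnostic_table(feats, table.groups, standard_roc_tasks(table))
    )
    roc_path = os.path.join(config.outdir, "roc_table.csv")
    _write_csv(roc_df, roc_path, header, index=False)
    artifacts["roc_table"] = roc_path

    def _zscores():
        z = derived.zscore_table(table)
        rows = []
        for group in ("RHS", "LHS"):
            sub = z.loc[table.groups == group]
            for col in z.columns:
                side = "right" if col.endswith("_right_z") else (
                    "left" if col.endswith("_left_z") else "bilateral")
                ipsi = (group == "RHS" and side == "right") or (group == "LHS" and side == "left")
                rr = derived.reference_range(sub[col], region=col, group=group)
                rows.append(dict(group=group, feature=col.replace("_z", ""), side=side,
                                 ipsilateral=ipsi, mean_z=rr.mean,
                                 ci_low=rr.ci_low, ci_high=rr.ci_high, n=rr.n))
        return pd.DataFrame(rows)

    z_df = stage("zscores")(_zscores)
    z_path = os.path.join(config.outdir, "zscores.csv")
    _write_csv(z_df, z_path, header, index=False)
    artifacts["zscores"] = z_path

    if config.run_validation:
        pfe_cfg = dataclasses.replace(config.pfe, seed=stage_seed(config.seed, "validate"))
        results = stage("validate-rfc")(lambda: forest.run_tasks(table, pfe_cfg))
        for task, res in results.items():
            path = os.path.join(config.outdir, f"rfc_{task}.json")
            payload = {"config_hash": h, "seed": config.seed, **res.to_dict()}
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            artifacts[f"rfc_{task}"] = path

    log_path = os.path.join(config.outdir, "run.log")
    with open(log_path, "w") as fh:
        fh.write(f"config_hash={h}\nseed={config.seed}\n")
        fh.write(json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True, default=str))
    artifacts["log"] = log_path
    return artifacts
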