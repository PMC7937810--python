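"""Readers and writers for morphometric feature tables.

Two upstream volumetry tools are supported as plain-text inputs:

* FreeSurfer-style ``.stats`` files: hash-comment header lines, one of which
  carries the estimated total intracranial volume (eTIV), followed by
  whitespace-delimited data rows (either ``<name> <value>`` pairs or
  aseg-style multi-column rows with ``Volume_mm3`` and ``StructName``).
* volBrain-HIPS-style CSV reports: one row per structure with left/right
  absolute volumes (mm3) and percent-of-intracranial-volume columns.

Both are loaded into :class:`SubjectRecord` objects and assembled into a
:class:`FeatureTable`, the canonical subjects-by-features container used by
every downstream stage.  All volumes are held in mm3; values printed with
thousands separators are normalized on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("HC", "RHS", "LHS", "unknown")
KINDS = ("volume", "thickness")
SIDES = ("left", "right", "bilateral", "global")

#: feature names treated as whole-brain ("global") measures, which carry no
#: regional information and are excluded from classifier matrices.
GLOBAL_FEATURE_NAMES = frozenset(
    {
        "BrainSegVol",
        "BrainSegVolNotVent",
        "CortexVol",
        "TotalGrayVol",
        "SupraTentorialVol",
        "MeanThickness",
        "VentricleChoroidVol",
        "EstimatedTotalIntraCranialVol",
        "eTIV",
    }
)

_TIV_ROW_NAMES = frozenset({"tiv", "icv", "ic", "intracranial cavity", "intracranial cavity (ic)"})


def _parse_number(token: str, context: str) -> float:
    """Parse a decimal number, tolerating thousands separators ("3,454")."""
    try:
        return float(token.replace(",", ""))
    except ValueError:
        raise ValueError(f"non-numeric value {token!r} in {context}") from None


@dataclass
class SubjectRecord:
    """Morphometric measures for one subject.

    ``measures`` maps region name -> value (mm3 for volumes, mm for
    thickness); ``kinds`` tags each measure as ``volume`` or ``thickness``
    (missing entries default to ``volume``).
    """

    subject_id: str
    tiv: float
    measures: dict[str, float]
    group: str = "unknown"
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tiv > 0:
            raise ValueError(f"subject {self.subject_id}: TIV must be > 0, got {self.tiv}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for name, kind in self.kinds.items():
            if kind not in KINDS:
                raise ValueError(f"measure {name!r}: unknown kind {kind!r}")

    def kind_of(self, name: str) -> str:
        return self.kinds.get(name, "volume")


def infer_side(name: str) -> str:
    """Infer laterality from a feature name suffix; globals by known name."""
    if name in GLOBAL_FEATURE_NAMES:
        return "global"
    low = name.lower()
    if low.endswith(("_right", "_r", ".right")) or low.startswith(("right_", "rh_", "rh.")):
        return "right"
    if low.endswith(("_left", "_l", ".left")) or low.startswith(("left_", "lh_", "lh.")):
        return "left"
    return "bilateral"


@dataclass
class FeatureTable:
    """Subjects-by-features table with group labels, TIV, and a registry.

    The registry maps each feature name to a ``(kind, side)`` pair shared by
    every subject.  Internally the measures live in a pandas DataFrame
    indexed by subject id, which :meth:`to_dataframe` exposes.
    """

    data: pd.DataFrame
    groups: pd.Series
    tiv: pd.Series
    registry: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if set(self.data.columns) != set(self.registry):
            raise ValueError("feature registry does not match table columns")
        if not (self.tiv > 0).all():
            raise ValueError("all TIV values must be > 0")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    # -- basic introspection -------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def features_of_kind(self, kind: str) -> list[str]:
        return [f for f in self.data.columns if self.registry[f][0] == kind]

    def subset(self, groups: list[str]) -> "FeatureTable":
        mask = self.groups.isin(groups)
        return FeatureTable(
            self.data.loc[mask], self.groups.loc[mask], self.tiv.loc[mask], dict(self.registry)
        )

    # -- serialization -------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Canonical layout: subject_id index, group, tiv_mm3, features."""
        out = pd.DataFrame(
            {"group": self.groups, "tiv_mm3": self.tiv}, index=self.data.index
        )
        return pd.concat([out, self.data], axis=1)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, registry: dict[str, tuple[str, str]] | None = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id", comment="#")
        df.index = df.index.astype(str)
        feats = [c for c in df.columns if c not in ("group", "tiv_mm3")]
        if registry is None:
            registry = {f: (_infer_kind(f), infer_side(f)) for f in feats}
        return cls(
            data=df[feats].astype(float),
            groups=df["group"].astype(str),
            tiv=df["tiv_mm3"].astype(float),
            registry=registry,
        )


def _infer_kind(name: str) -> str:
    low = name.lower()
    if "thick" in low or low.endswith("_thk") or "_thk_" in low:
        return "thickness"
    return "volume"


# ---------------------------------------------------------------------------
# FreeSurfer-style stats files
# ---------------------------------------------------------------------------

def read_freesurfer_stats(
    path,
    subject_id: str | None = None,
    group: str = "unknown",
    kind: str = "volume",
    strict: bool = True,
) -> SubjectRecord:
    """Read a FreeSurfer-dialect stats file into a :class:`SubjectRecord`.

    The eTIV is taken from the ``# Measure EstimatedTotalIntraCranialVol``
    (or ``eTIV``) header line; its absence is a hard error.  Data rows are
    either ``<name> <value>`` pairs or aseg-style rows whose fourth and fifth
    columns are ``Volume_mm3`` and ``StructName``.  With ``strict=False``
    malformed rows are logged and skipped instead of raising.
    """
    path = str(path)
    if subject_id is None:
        subject_id = path.rsplit("/", 1)[-1].split(".")[0]
    tiv: float | None = None
    measures: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("Measure"):
                    parts = [p.strip() for p in body[len("Measure"):].split(",")]
                    if parts and parts[0] in ("EstimatedTotalIntraCranialVol", "eTIV"):
                        # value is the last numeric field before the unit
                        for tok in reversed(parts):
                            try:
                                tiv = float(tok.replace(",", ""))
                                break
                            except ValueError:
                                continue
                continue
            tokens = line.split()
            try:
                if len(tokens) == 2:
                    name, value = tokens[0], _parse_number(tokens[1], f"line {lineno}")
                elif len(tokens) >= 5 and tokens[0].lstrip("-").isdigit():
                    # aseg-style: Index SegId NVoxels Volume_mm3 StructName ...
                    name = tokens[4]
                    value = _parse_number(tokens[3], f"line {lineno}")
                else:
                    raise ValueError(f"unparseable data row at line {lineno}: {line!r}")
            except ValueError:
                if strict:
                    raise
                logger.warning("%s: skipping malformed row %d: %r", path, lineno, line)
                continue
            if name in measures:
                raise ValueError(f"duplicate region {name!r} in {path}")
            measures[name] = value
    if tiv is None:
        raise ValueError(f"no eTIV measure line found in {path}")
    if not measures:
        raise ValueError(f"no data rows found in {path}")
    return SubjectRecord(
        subject_id=subject_id,
        tiv=tiv,
        measures=measures,
        group=group,
        kinds={m: kind for m in measures},
    )


# ---------------------------------------------------------------------------
# volBrain-style reports
# ---------------------------------------------------------------------------

def read_volbrain_report(
    path,
    subject_id: str | None = None,
    group: str = "unknown",
    rel_tol: float = 0.01,
) -> SubjectRecord:
    """Read a volBrain-HIPS-like CSV report.

    Expected columns: ``structure, right_mm3, left_mm3, right_pct, left_pct``;
    a row whose structure is ``TIV`` (or ``Intracranial Cavity``/``ICV``)
    carries the intracranial volume in its first value column.  Each
    structure yields four measures, ``<structure>_<side>`` (absolute, mm3)
    and ``<structure>_<side>_pct`` (percent of TIV).  If a percent value
    disagrees with absolute*100/TIV beyond ``rel_tol`` relative tolerance, a
    warning is issued and the absolute value is treated as canonical.
    """
    path = str(path)
    if subject_id is None:
        subject_id = path.rsplit("/", 1)[-1].split(".")[0]
    df = pd.read_csv(path, dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"structure", "right_mm3", "left_mm3", "right_pct", "left_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")

    tiv: float | None = None
    rows = []
    for _, row in df.iterrows():
        name = str(row["structure"]).strip()
        if name.lower() in _TIV_ROW_NAMES:
            tiv = _parse_number(str(row["right_mm3"]), f"TIV row of {path}")
        else:
            rows.append(row)
    if tiv is None:
        raise ValueError(f"no TIV/intracranial-cavity row in {path}")
    if not rows:
        raise ValueError(f"no structure rows in {path}")

    measures: dict[str, float] = {}
    for row in rows:
        name = str(row["structure"]).strip()
        for side in ("right", "left"):
            absval = _parse_number(str(row[f"{side}_mm3"]), f"{name}/{side} of {path}")
            pct = _parse_number(str(row[f"{side}_pct"]), f"{name}/{side} of {path}")
            implied = absval * 100.0 / tiv
            if pct > 0 and abs(pct - implied) / pct > rel_tol:
                warnings.warn(
                    f"{path}: {name} {side} percent {pct} inconsistent with "
                    f"absolute {absval} at TIV {tiv} (implies {implied:.4g}); "
                    "keeping absolute as canonical",
                    stacklevel=2,
                )
            key = f"{name}_{side}"
            if key in measures:
                raise ValueError(f"duplicate structure {name!r} in {path}")
            measures[key] = absval
            measures[f"{key}_pct"] = pct
    return SubjectRecord(
        subject_id=subject_id,
        tiv=tiv,
        measures=measures,
        group=group,
        kinds={m: "volume" for m in measures},
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def read_labels(path) -> dict[str, str]:
    """Read a ``subject_id,group`` CSV into a dict."""
    df = pd.read_csv(path, dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"subject_id", "group"}.issubset(df.columns):
        raise ValueError(f"labels file {path} needs subject_id,group columns")
    return dict(zip(df["subject_id"].str.strip(), df["group"].str.strip()))


def assemble_table(
    records: list[SubjectRecord],
    labels: dict[str, str] | None = None,
    policy: str = "strict",
    registry: dict[str, tuple[str, str]] | None = None,
) -> FeatureTable:
    """Assemble subject records into a :class:`FeatureTable`.

    ``policy='strict'`` requires every record to carry the same measure set;
    ``policy='intersection'`` keeps the common subset (an empty intersection
    is an error) and drops the rest.  Group labels come from ``labels``
    (subject_id -> group) when given, else from each record.
    """
    if not records:
        raise ValueError("no records to assemble")
    if policy not in ("strict", "intersection"):
        raise ValueError(f"unknown policy {policy!r}")

    common = set(records[0].measures)
    for rec in records[1:]:
        if policy == "strict" and set(rec.measures) != common:
            extra = set(rec.measures) ^ common
            raise ValueError(
                f"subject {rec.subject_id} measure set differs (strict policy); "
                f"mismatched features: {sorted(extra)[:5]}"
            )
        common &= set(rec.measures)
    if not common:
        raise ValueError("empty feature intersection across records")
    feats = sorted(common)

    ids, groups, tivs, rows = [], [], [], []
    for rec in records:
        grp = labels.get(rec.subject_id, rec.group) if labels else rec.group
        ids.append(rec.subject_id)
        groups.append(grp)
        tivs.append(rec.tiv)
        rows.append([rec.measures[f] for f in feats])

    if registry is None:
        registry = {f: (records[0].kind_of(f), infer_side(f)) for f in feats}
    idx = pd.Index(ids, name="subject_id")
    return FeatureTable(
        data=pd.DataFrame(np.asarray(rows, dtype=float), index=idx, columns=feats),
        groups=pd.Series(groups, index=idx, name="group"),
        tiv=pd.Series(np.asarray(tivs, dtype=float), index=idx, name="tiv_mm3"),
        registry=registry,
    )
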