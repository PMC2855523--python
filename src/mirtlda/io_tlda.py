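"""Readers/writers for TLDA cycle-threshold exports and sample annotations.

Raw data come off the instrument as one CT value per well.  A well is
identified by (sample, assay, well index, panel); the endogenous-control
assay (MammU6 by default) occupies four replicate wells per card, so the
in-memory matrix keeps one row per (assay, well) and replicate aggregation
is deferred to normalization.  CT cells flagged "Undetermined" (reaction
never crossed threshold) are carried as an explicit mask, never as a
sentinel number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CtParseError,
    FormatError,
    IntegrityError,
    LayoutError,
    ValidationError,
)

UNDETERMINED_TOKEN = "Undetermined"
DEFAULT_CONTROL_NAME = "MammU6"
DEFAULT_NEGATIVE_NAME = "ath-miR159a"

#: Closed set of sample group labels used by the study design.
GROUP_LABELS = ("Mel 60", "Mel 30", "Nevus 60", "Nevus 30")

_ASSAY_ID_SUFFIX = re.compile(r"-(\d{5,})$")


def human_name(assay_id: str) -> str:
    """Strip the trailing numeric assay-ID suffix (``hsa-miR-204-4373094``
    -> ``hsa-miR-204``).  The full string remains the primary key; miR and
    miR* (STAR) forms never collide because their assay IDs differ."""
    return _ASSAY_ID_SUFFIX.sub("", assay_id)


@dataclass
class CtMatrix:
    """Raw CT values, one row per (assay, well), one column per sample.

    Parameters
    ----------
    assay_ids
        Per-row assay name carrying the assay-ID suffix.  Duplicated for
        replicate control wells (distinct ``wells`` entries).
    wells
        Per-row replicate well index (1-based).
    panel
        Per-row card label, ``"A"`` or ``"B"``.
    sample_ids
        Column labels.
    ct
        ``(n_rows, n_samples)`` float array of CT values (PCR cycles).
    mask
        Boolean array, same shape; ``True`` marks undetermined/missing.
    batch
        Optional per-sample processing-batch labels.
    control_roles
        Map assay_id -> role in ``{"endogenous", "negative"}``; assays
        absent from the map are ordinary measurement assays.
    """

    assay_ids: list[str]
    wells: np.ndarray
    panel: np.ndarray
    sample_ids: list[str]
    ct: np.ndarray
    mask: np.ndarray
    batch: np.ndarray | None = None
    control_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wells = np.asarray(self.wells, dtype=int)
        self.panel = np.asarray(self.panel, dtype=object)
        self.ct = np.asarray(self.ct, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_rows, n_samples = len(self.assay_ids), len(self.sample_ids)
        if self.ct.shape != (n_rows, n_samples):
            raise ValidationError(
                f"ct shape {self.ct.shape} != ({n_rows}, {n_samples})"
            )
        if self.mask.shape != self.ct.shape:
            raise ValidationError("mask shape differs from ct shape")
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
            if self.batch.shape != (n_samples,):
                raise ValidationError("batch must be per-sample")
        keys = list(zip(self.assay_ids, self.wells, self.panel))
        if len(set(keys)) != len(keys):
            raise IntegrityError("duplicate (assay, well, panel) rows")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def role_of(self, assay_id: str) -> str:
        return self.control_roles.get(assay_id, "none")

    def measurement_rows(self) -> np.ndarray:
        """Boolean row selector for ordinary (non-control) assays."""
        return np.array(
            [self.role_of(a) == "none" for a in self.assay_ids], dtype=bool
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None


@dataclass
class SampleAnnotation:
    """One row of the patient/specimen table."""

    sample_id: str
    group: str
    age: float | None = None
    stage_group: str | None = None
    n_stage: str | None = None
    node_positive: bool | None = None
    batch: str | None = None
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValidationError(
                f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}"
            )


def node_status_from_n_stage(n_stage: str | None) -> bool | None:
    """pN1/pN2/pN3 (any sub-letter) -> positive; pN0/cN0 -> negative;
    anything else (n/a, blank) -> unknown."""
    if n_stage is None:
        return None
    s = str(n_stage).strip()
    if re.match(r"^[pc]?N[123]", s, flags=re.IGNORECASE):
        return True
    if re.match(r"^[pc]?N0", s, flags=re.IGNORECASE):
        return False
    return None


def _infer_control_roles(
    assay_ids,
    control_name: str = DEFAULT_CONTROL_NAME,
    negative_name: str = DEFAULT_NEGATIVE_NAME,
) -> dict[str, str]:
    roles: dict[str, str] = {}
    for a in set(assay_ids):
        if control_name.lower() in a.lower():
            roles[a] = "endogenous"
        elif negative_name.lower() in a.lower():
            roles[a] = "negative"
    return roles


_LONG_COLUMNS = {
    "sample": ("sample", "sample name", "sample_id"),
    "assay": ("assay", "detector", "assay name", "mir"),
    "panel": ("panel", "array", "card"),
    "well": ("well", "well index"),
    "ct": ("ct", "avg ct", "cq", "ct value"),
    "batch": ("batch",),
}


def _resolve_column(df: pd.DataFrame, key: str, options: dict) -> str | None:
    explicit = options.get(f"{key}_col")
    if explicit is not None:
        if explicit not in df.columns:
            raise FormatError(f"configured column {explicit!r} not in file")
        return explicit
    lowered = {c.lower().strip(): c for c in df.columns}
    for cand in _LONG_COLUMNS[key]:
        if cand in lowered:
            return lowered[cand]
    return None


def _parse_ct_value(raw, token: str) -> tuple[float, bool]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan, True
    s = str(raw).strip()
    if s == "" or s.lower() == token.lower() or s.lower() in ("na", "nan", "undet"):
        return np.nan, True
    try:
        return float(s), False
    except ValueError:
        raise CtParseError(f"cannot parse CT value {raw!r}") from None


def read_ct_table(path, format_options: dict | None = None) -> CtMatrix:
    """Read a delimited CT export (long or wide layout) into a CtMatrix.

    ``format_options`` keys (all optional): ``layout`` ("long"/"wide"),
    ``sep`` (inferred when omitted), ``sample_col``/``assay_col``/
    ``panel_col``/``well_col``/``ct_col``/``batch_col`` overrides,
    ``undetermined_token`` (default "Undetermined"), ``control_name``,
    ``negative_name``, ``assay_panel_map`` (assay -> panel when the file
    has no panel column).
    """
    options = dict(format_options or {})
    sep = options.get("sep")
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if df.empty:
        raise FormatError(f"no rows in {path}")
    layout = options.get("layout", "long")
    if layout == "long":
        return _read_long(df, options)
    if layout == "wide":
        return _read_wide(df, options)
    raise FormatError(f"unknown layout {layout!r}")


def _read_long(df: pd.DataFrame, options: dict) -> CtMatrix:
    token = options.get("undetermined_token", UNDETERMINED_TOKEN)
    cols = {k: _resolve_column(df, k, options) for k in _LONG_COLUMNS}
    for required in ("sample", "assay", "ct"):
        if cols[required] is None:
            raise FormatError(f"cannot resolve a {required!r} column")

    panel_map = options.get("assay_panel_map")
    samples = list(dict.fromkeys(df[cols["sample"]]))
    sample_pos = {s: i for i, s in enumerate(samples)}

    seen: set[tuple] = set()
    row_key_pos: dict[tuple, int] = {}
    assay_ids: list[str] = []
    wells: list[int] = []
    panels: list[str] = []
    values: list[list[float]] = []
    masks: list[list[bool]] = []
    batch_by_sample: dict[str, str] = {}

    sample_arr = df[cols["sample"]].to_numpy()
    assay_arr = df[cols["assay"]].to_numpy()
    well_arr = (
        df[cols["well"]].to_numpy() if cols["well"] is not None else np.ones(len(df))
    )
    if cols["panel"] is not None:
        panel_arr = df[cols["panel"]].to_numpy()
    elif panel_map is not None:
        panel_arr = np.array([panel_map.get(a, "A") for a in assay_arr], dtype=object)
    else:
        panel_arr = np.array(["A"] * len(df), dtype=object)
    ct_arr = df[cols["ct"]].to_numpy()
    batch_arr = df[cols["batch"]].to_numpy() if cols["batch"] is not None else None

    for i in range(len(df)):
        sample = sample_arr[i]
        key = (assay_arr[i], int(float(well_arr[i])), str(panel_arr[i]), sample)
        if key in seen:
            raise IntegrityError(f"duplicate record for {key}")
        seen.add(key)
        row_key = key[:3]
        if row_key not in row_key_pos:
            row_key_pos[row_key] = len(assay_ids)
            assay_ids.append(str(assay_arr[i]))
            wells.append(int(float(well_arr[i])))
            panels.append(str(panel_arr[i]))
            values.append([np.nan] * len(samples))
            masks.append([True] * len(samples))
        r = row_key_pos[row_key]
        c = sample_pos[sample]
        val, miss = _parse_ct_value(ct_arr[i], token)
        values[r][c] = val
        masks[r][c] = miss
        if batch_arr is not None:
            batch_by_sample[sample] = str(batch_arr[i])

    batch = (
        np.array([batch_by_sample.get(s) for s in samples], dtype=object)
        if batch_by_sample
        else None
    )
    roles = _infer_control_roles(
        assay_ids,
        options.get("control_name", DEFAULT_CONTROL_NAME),
        options.get("negative_name", DEFAULT_NEGATIVE_NAME),
    )
    return CtMatrix(
        assay_ids=assay_ids,
        wells=np.array(wells),
        panel=np.array(panels, dtype=object),
        sample_ids=[str(s) for s in samples],
        ct=np.array(values, dtype=float),
        mask=np.array(masks, dtype=bool),
        batch=batch,
        control_roles=roles,
    )


def _read_wide(df: pd.DataFrame, options: dict) -> CtMatrix:
    token = options.get("undetermined_token", UNDETERMINED_TOKEN)
    lowered = {c.lower().strip(): c for c in df.columns}
    assay_col = options.get("assay_col") or lowered.get("assay")
    if assay_col is None:
        raise FormatError("wide layout needs an 'Assay' column")
    panel_col = options.get("panel_col") or lowered.get("panel")
    well_col = options.get("well_col") or lowered.get("well")
    meta = {assay_col, panel_col, well_col} - {None}
    sample_cols = [c for c in df.columns if c not in meta]
    if not sample_cols:
        raise FormatError("wide layout has no sample columns")

    assay_ids = [str(a) for a in df[assay_col]]
    panel_map = options.get("assay_panel_map")
    if panel_col is not None:
        panels = [str(p) for p in df[panel_col]]
    elif panel_map is not None:
        panels = [panel_map.get(a, "A") for a in assay_ids]
    else:
        panels = ["A"] * len(assay_ids)
    wells = (
        [int(float(w)) for w in df[well_col]]
        if well_col is not None
        else [1] * len(assay_ids)
    )
    values = np.empty((len(assay_ids), len(sample_cols)))
    mask = np.empty_like(values, dtype=bool)
    for j, c in enumerate(sample_cols):
        for i, raw in enumerate(df[c]):
            values[i, j], mask[i, j] = _parse_ct_value(raw, token)
    roles = _infer_control_roles(
        assay_ids,
        options.get("control_name", DEFAULT_CONTROL_NAME),
        options.get("negative_name", DEFAULT_NEGATIVE_NAME),
    )
    return CtMatrix(
        assay_ids=assay_ids,
        wells=np.array(wells),
        panel=np.array(panels, dtype=object),
        sample_ids=[str(c) for c in sample_cols],
        ct=values,
        mask=mask,
        batch=None,
        control_roles=roles,
    )


def write_ct_table(ctm: CtMatrix, path, sep: str = "\t") -> None:
    """Write the long-form export that :func:`read_ct_table` reads back
    losslessly (masks round-trip as the undetermined token)."""
    records = []
    for r, assay in enumerate(ctm.assay_ids):
        for c, sample in enumerate(ctm.sample_ids):
            rec = {
                "Sample": sample,
                "Assay": assay,
                "Panel": ctm.panel[r],
                "Well": int(ctm.wells[r]),
                "CT": UNDETERMINED_TOKEN
                if ctm.mask[r, c]
                else format(ctm.ct[r, c], ".6f"),
            }
            if ctm.batch is not None:
                rec["Batch"] = ctm.batch[c]
            records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep=sep, index=False)


_ANNOTATION_COLS = {
    "sample_id": ("sample_id", "sample", "sample name"),
    "group": ("group", "class", "mel 60/30 or nevus 60/30"),
    "age": ("age",),
    "stage_group": ("stage_group", "stage group", "stage"),
    "n_stage": ("n_stage", "n stage"),
    "batch": ("batch",),
    "is_calibrator": ("is_calibrator", "calibrator"),
}


def read_sample_annotations(path, sep: str | None = None) -> list[SampleAnnotation]:
    """Read the sample-annotation CSV/TSV; ``node_positive`` is derived
    from the N-stage text, never read directly."""
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    lowered = {c.lower().strip(): c for c in df.columns}
    resolved = {}
    for key, cands in _ANNOTATION_COLS.items():
        for cand in cands:
            if cand in lowered:
                resolved[key] = lowered[cand]
                break
    for required in ("sample_id", "group"):
        if required not in resolved:
            raise FormatError(f"annotation file lacks a {required!r} column")

    def get(row, key):
        col = resolved.get(key)
        if col is None:
            return None
        val = row[col]
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return None
        s = str(val).strip()
        return s if s and s.lower() not in ("n/a", "na", "nan") else None

    annotations = []
    for _, row in df.iterrows():
        n_stage = get(row, "n_stage")
        age = get(row, "age")
        calib = get(row, "is_calibrator")
        annotations.append(
            SampleAnnotation(
                sample_id=get(row, "sample_id"),
                group=get(row, "group"),
                age=float(age) if age is not None else None,
                stage_group=get(row, "stage_group"),
                n_stage=n_stage,
                node_positive=node_status_from_n_stage(n_stage),
                batch=get(row, "batch"),
                is_calibrator=str(calib).strip().lower() in ("1", "true", "yes")
                if calib is not None
                else False,
            )
        )
    return annotations


def write_sample_annotations(annotations, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "group": a.group,
                "age": a.age,
                "stage_group": a.stage_group,
                "n_stage": a.n_stage,
                "batch": a.batch,
                "is_calibrator": a.is_calibrator,
            }
            for a in annotations
        ]
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Result-table layouts (column orders mirror the published report tables)
# ---------------------------------------------------------------------------


def _fmt(x, nd=4):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "N/A"
    return format(float(x), f".{nd}f")


def write_result_table(results, path, layout: str, sep: str = "\t") -> None:
    """Write comparison/prediction results in a named column layout.

    Layouts: ``fold_change`` (miR, FC, Log2(FC), p value, FDR (BH), FC
    Bin), ``class_comparison`` (parametric/permutation p, FDR, per-class
    geometric-mean intensities, fold-change), ``prediction`` (t-value and
    CV support per marker), ``cv_performance`` (per-class sensitivity,
    specificity, PPV, NPV per classifier).
    """
    if layout == "fold_change":
        header = ["miR", "FC", "Log2(FC)", "p value", "FDR (BH)", "FC Bin"]
        rows = [
            [
                r.assay_id,
                _fmt(r.fc),
                _fmt(r.log2_fc),
                _fmt(r.p),
                _fmt(r.fdr_bh),
                r.fc_bin or "",
            ]
            for r in results
        ]
    elif layout == "class_comparison":
        class_labels = list(results[0].class_means) if results else []
        header = (
            ["MiR", "Parametric p-value", "FDR", "Permutation p-value"]
            + [f"Geom mean of intensities in class {i + 1}" for i in range(len(class_labels))]
            + (["Fold-change"] if len(class_labels) == 2 else [])
        )
        rows = []
        for r in results:
            row = [r.assay_id, _fmt(r.p), _fmt(r.fdr_bh), _fmt(r.perm_p)]
            row += [_fmt(r.class_means[c]) for c in class_labels]
            if len(class_labels) == 2:
                row.append(_fmt(r.fc))
            rows.append(row)
    elif layout == "prediction":
        class_labels = list(results[0].class_means) if results else []
        header = (
            ["Parametric p-value", "t-value", "% CV support"]
            + [f"Geom mean of intensities in class {i + 1}" for i in range(len(class_labels))]
            + ["Fold-change", "MiR"]
        )
        rows = []
        for r in results:
            row = [_fmt(r.p), _fmt(r.t_or_f), _fmt(getattr(r, "cv_support", None))]
            row += [_fmt(r.class_means[c]) for c in class_labels]
            row += [_fmt(r.fc), r.assay_id]
            rows.append(row)
    elif layout == "cv_performance":
        header = [
            "Classifier",
            "Class",
            "Sensitivity",
            "Specificity",
            "PPV",
            "NPV",
            "CV error rate",
            "Permutation p",
        ]
        rows = []
        for rep in results:
            for cls in rep.classes:
                rows.append(
                    [
                        rep.method,
                        cls,
                        _fmt(rep.sensitivity[cls]),
                        _fmt(rep.specificity[cls]),
                        _fmt(rep.ppv[cls]),
                        _fmt(rep.npv[cls]),
                        _fmt(rep.error_rate),
                        _fmt(rep.perm_p),
                    ]
                )
    else:
        raise LayoutError(f"unknown result-table layout {layout!r}")

    with open(path, "w") as fh:
        fh.write(sep.join(header) + "\n")
        for row in rows:
            fh.write(sep.join(str(x) for x in row) + "\n")
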