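"""Relative quantification: dCt, ddCt, FC = 2^-ddCt and group fold changes.

The comparative-CT model expresses every assay relative to a stably
expressed endogenous control on the same card (MammU6, four replicate
wells per panel) and to a calibrator sample:

    dCt[a, s]  = CT[a, s] - mean CT(control wells, same sample & panel)
    ddCt[a, s] = dCt[a, s] - dCt[a, calibrator]
    RQ[a, s]   = 2 ** -ddCt[a, s]

A lower CT means more template, so one cycle equals a two-fold change in
abundance.  Group-level fold change is the ratio of group geometric-mean
RQ, equivalently 2**-(mean dCt difference); the calibrator cancels in
that ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import NormalizationError, ValidationError
from .io_tlda import CtMatrix, DEFAULT_CONTROL_NAME

FC_BIN_LABELS = ("FC 1.2-1.6", "FC 1.6-2.0", "FC 2.0-4.0", "FC > 4")


@dataclass
class NormalizedMatrix:
    """dCt values (assay CT minus per-sample/per-panel control CT).

    Control assays themselves are excluded (their dCt is identically 0
    for the endogenous control and meaningless for the negative control).
    """

    assay_ids: list[str]
    panel: np.ndarray
    sample_ids: list[str]
    delta_ct: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(~self.mask & ~np.isfinite(self.delta_ct)):
            raise ValidationError("non-finite dCt outside the mask")

    def values_nan(self) -> np.ndarray:
        """dCt with masked cells as NaN (convenience for statistics)."""
        out = self.delta_ct.copy()
        out[self.mask] = np.nan
        return out

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None


@dataclass
class RelativeQuantification:
    """ddCt and fold change relative to a calibrator sample."""

    assay_ids: list[str]
    sample_ids: list[str]
    ddct: np.ndarray
    rq: np.ndarray
    mask: np.ndarray
    calibrator_id: str


@dataclass
class FoldChangeRecord:
    """Group-level fold change for one assay (one row of a report table)."""

    assay_id: str
    fc: float
    log2_fc: float
    fc_bin: str | None
    evaluable: bool = True


def apply_censoring(ctm: CtMatrix, ceiling: float = 40.0) -> CtMatrix:
    """Optional policy replacing undetermined CTs by a ceiling value
    (default 40 cycles) and clearing the mask.  The default pipeline
    leaves undetermined cells masked instead."""
    ct = ctm.ct.copy()
    ct[ctm.mask] = ceiling
    return replace(ctm, ct=ct, mask=np.zeros_like(ctm.mask))


def aggregate_endogenous_control(
    ctm: CtMatrix, control_name: str = DEFAULT_CONTROL_NAME
) -> dict[str, np.ndarray]:
    """Arithmetic mean CT of unmasked control replicate wells, per sample
    per panel (the control is spotted once per card, i.e. per panel).

    Returns ``{panel: array of per-sample control CT}``.  A sample/panel
    with no usable control well is a hard error naming the sample.
    """
    is_control = np.array(
        [
            ctm.role_of(a) == "endogenous" and control_name.lower() in a.lower()
            for a in ctm.assay_ids
        ],
        dtype=bool,
    )
    if not is_control.any():
        raise NormalizationError(f"no endogenous-control wells match {control_name!r}")
    out: dict[str, np.ndarray] = {}
    for panel in sorted(set(ctm.panel[is_control])):
        rows = is_control & (ctm.panel == panel)
        vals = np.where(ctm.mask[rows], np.nan, ctm.ct[rows])
        n_ok = np.sum(~np.isnan(vals), axis=0)
        if np.any(n_ok == 0):
            bad = [s for s, n in zip(ctm.sample_ids, n_ok) if n == 0]
            raise NormalizationError(
                f"no unmasked {control_name} well on panel {panel} for sample(s) {bad}"
            )
        with np.errstate(invalid="ignore"):
            out[panel] = np.nanmean(vals, axis=0)
    return out


def compute_delta_ct(
    ctm: CtMatrix, control_ct: dict[str, np.ndarray]
) -> NormalizedMatrix:
    """Subtract the per-sample, per-panel control CT from every
    measurement assay; masks propagate unchanged."""
    rows = ctm.measurement_rows()
    assay_ids = [a for a, keep in zip(ctm.assay_ids, rows) if keep]
    panels = ctm.panel[rows]
    for panel in set(panels):
        if panel not in control_ct:
            raise NormalizationError(f"no control CT for panel {panel!r}")
    ref = np.stack([control_ct[p] for p in panels])  # rows x samples
    delta = ctm.ct[rows] - ref
    mask = ctm.mask[rows].copy()
    delta[mask] = np.nan
    delta = np.where(mask, 0.0, delta)  # keep finite under the mask
    return NormalizedMatrix(
        assay_ids=assay_ids,
        panel=panels.copy(),
        sample_ids=list(ctm.sample_ids),
        delta_ct=delta,
        mask=mask,
    )


def normalize(
    ctm: CtMatrix, control_name: str = DEFAULT_CONTROL_NAME
) -> NormalizedMatrix:
    """Convenience: control aggregation followed by dCt."""
    return compute_delta_ct(ctm, aggregate_endogenous_control(ctm, control_name))


def compute_rq(
    norm: NormalizedMatrix, calibrator_id: str
) -> RelativeQuantification:
    """ddCt against the calibrator sample and RQ = 2^-ddCt.

    Assays whose calibrator dCt is masked have no reference point; their
    RQ is masked for every sample.
    """
    cal = norm.sample_index(calibrator_id)
    cal_delta = norm.delta_ct[:, cal].copy()
    cal_masked = norm.mask[:, cal]
    ddct = norm.delta_ct - cal_delta[:, None]
    mask = norm.mask | cal_masked[:, None]
    ddct = np.where(mask, 0.0, ddct)
    rq = np.where(mask, np.nan, 2.0 ** (-ddct))
    rq = np.where(mask, 0.0, rq)
    return RelativeQuantification(
        assay_ids=list(norm.assay_ids),
        sample_ids=list(norm.sample_ids),
        ddct=ddct,
        rq=rq,
        mask=mask,
        calibrator_id=calibrator_id,
    )


def fc_bin(fc: float) -> str | None:
    """Bin a fold change by its magnitude m = max(fc, 1/fc); symmetric
    under fc -> 1/fc so up- and down-regulation bin identically."""
    if not np.isfinite(fc) or fc <= 0:
        raise ValidationError(f"fold change must be positive, got {fc}")
    m = max(fc, 1.0 / fc)
    if m > 4.0:
        return "FC > 4"
    if m > 2.0:
        return "FC 2.0-4.0"
    if m > 1.6:
        return "FC 1.6-2.0"
    if m > 1.2:
        return "FC 1.2-1.6"
    return None


def group_fold_change(
    rq: RelativeQuantification,
    groups: dict[str, list[str]],
    numerator: str,
    denominator: str,
) -> list[FoldChangeRecord]:
    """Per-assay group fold change: geometric mean RQ of the numerator
    group over that of the denominator group, i.e.
    2**-(mean ddCt_num - mean ddCt_den).  Masked values are excluded from
    the means; an assay with an empty unmasked group is flagged
    not-evaluable."""
    for g in (numerator, denominator):
        if g not in groups or not groups[g]:
            raise ValidationError(f"group {g!r} missing or empty")
    sample_pos = {s: i for i, s in enumerate(rq.sample_ids)}
    idx_num = [sample_pos[s] for s in groups[numerator]]
    idx_den = [sample_pos[s] for s in groups[denominator]]

    ddct = np.where(rq.mask, np.nan, rq.ddct)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)  # all-masked groups
        mean_num = np.nanmean(ddct[:, idx_num], axis=1)
        mean_den = np.nanmean(ddct[:, idx_den], axis=1)
    records = []
    for i, assay in enumerate(rq.assay_ids):
        diff = mean_num[i] - mean_den[i]
        if not np.isfinite(diff):
            records.append(FoldChangeRecord(assay, np.nan, np.nan, None, False))
            continue
        fc = 2.0 ** (-diff)
        records.append(FoldChangeRecord(assay, fc, float(np.log2(fc)), fc_bin(fc)))
    return records


def intensity_transform(norm: NormalizedMatrix) -> np.ndarray:
    """Linear-scale intensity 2^-dCt (higher expression -> larger value);
    masked cells come back as NaN.  Class geometric means of these
    intensities equal 2**-(class mean dCt), so intensity ratios reproduce
    group fold changes exactly."""
    vals = norm.values_nan()
    return 2.0 ** (-vals)
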