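"""Synthetic CT datasets with the statistical structure the pipeline assumes.

The generator emulates a two-panel low-density qPCR card experiment:
666 assays split 377/289 across panels A and B, four endogenous-control
(MammU6) wells per card, a negative-control well per card, 26 samples in
four groups run in three processing batches, and right-censoring of
high CTs as "Undetermined".  Ground truth (which assays carry planted
group effects, and how large) is returned alongside, so recovery and
calibration tests know the answer.

The additive model on the cycle scale is

    CT[a, s] = baseline_a + sample_shift_s + batch_shift_b(s)
               - effect(a, group(s)) + noise

Control wells share the sample and batch shifts, so dCt normalization
removes them exactly; effects are planted on the -dCT scale, i.e. one
cycle equals a two-fold expression change, matching the 2^-ddCt model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io_tlda import (
    CtMatrix,
    DEFAULT_CONTROL_NAME,
    DEFAULT_NEGATIVE_NAME,
    SampleAnnotation,
)

_GROUP_PREFIX = {"Mel 60": "AM", "Mel 30": "PM", "Nevus 60": "AN", "Nevus 30": "PN"}

#: log2 effect sizes planted by the study-like preset: a spread of up-
#: and down-regulation magnitudes covering every fold-change bin, echoing
#: the published contrast tables (strongest ~2^5, weakest ~1.3-fold).
PRESET_EFFECT_SIZES = (
    5.1, 2.1, -1.8, 0.9, -1.4, 1.4, 0.95, 0.7, 1.0, 0.85,
    -0.6, 1.45, 0.86, -0.55, 1.15, 1.25, -0.8, 1.05, -0.75, 1.8,
    1.15, 0.8, 0.5, 1.1, 1.17, 1.44, 1.4, 1.16, -1.3, 0.35,
)


@dataclass
class SyntheticConfig:
    """Full parameterization of the generator (units: PCR cycles)."""

    n_assays: int = 666
    panel_split: tuple[int, int] = (377, 289)
    n_control_replicates: int = 4
    groups: dict[str, int] = field(
        default_factory=lambda: {
            "Mel 60": 10,
            "Mel 30": 10,
            "Nevus 60": 3,
            "Nevus 30": 3,
        }
    )
    n_batches: int = 3
    baseline_ct_range: tuple[float, float] = (22.0, 34.0)
    control_ct_mean: float = 20.0
    control_ct_sd: float = 0.15
    noise_sd: float = 0.5
    sample_shift_sd: float = 1.0
    batch_shift_sd: float = 0.3
    #: list of (assay_id, group label, log2 effect); positive = higher
    #: expression (lower CT) in that group
    effects: list[tuple[str, str, float]] = field(default_factory=list)
    censor_ct: float = 38.0
    batch_calibration: bool = False
    seed: int = 0

    def validate(self) -> None:
        if sum(self.panel_split) != self.n_assays:
            raise ValidationError("panel split must sum to n_assays")
        if any(n < 1 for n in self.groups.values()):
            raise ValidationError("group counts must be >= 1")
        for sd in (
            self.control_ct_sd,
            self.noise_sd,
            self.sample_shift_sd,
            self.batch_shift_sd,
        ):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")
        for g in self.groups:
            if g not in _GROUP_PREFIX:
                raise ValidationError(f"unknown group label {g!r}")
        assay_set = set(assay_catalog(self))
        for assay, group, _ in self.effects:
            if assay not in assay_set:
                raise ValidationError(f"planted assay {assay!r} does not exist")
            if group not in self.groups:
                raise ValidationError(f"planted group {group!r} not in design")

    def save(self, path) -> None:
        data = asdict(self)
        data["panel_split"] = list(self.panel_split)
        data["baseline_ct_range"] = list(self.baseline_ct_range)
        data["effects"] = [list(e) for e in self.effects]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["panel_split"] = tuple(data["panel_split"])
        data["baseline_ct_range"] = tuple(data["baseline_ct_range"])
        data["effects"] = [tuple(e) for e in data.get("effects", [])]
        return cls(**data)


def assay_catalog(config: SyntheticConfig) -> list[str]:
    """Deterministic synthetic assay names (with assay-ID suffixes),
    panel A first."""
    return [f"syn-miR-{i + 1:04d}-{4000000 + i}" for i in range(config.n_assays)]


def _sample_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    names, groups = [], []
    for g, count in config.groups.items():
        prefix = _GROUP_PREFIX[g]
        for i in range(count):
            names.append(f"{prefix}{i + 1}")
            groups.append(g)
    return names, groups


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[CtMatrix, list[SampleAnnotation], pd.DataFrame]:
    """Draw one dataset; fully reproducible from ``config.seed``.

    Returns the raw CT matrix (control wells included), the sample
    annotations (batch assignments and calibrator flags), and a truth
    table with one row per planted (assay, group, log2 effect).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    assays = assay_catalog(config)
    n_a, n_b = config.panel_split
    panel_of = {a: ("A" if i < n_a else "B") for i, a in enumerate(assays)}

    samples, sample_group = _sample_names(config)
    n_samples = len(samples)
    batches = [f"batch{(i % config.n_batches) + 1}" for i in range(n_samples)]

    lo, hi = config.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=config.n_assays)
    sample_shift = rng.normal(0.0, config.sample_shift_sd, size=n_samples)
    batch_levels = sorted(set(batches))
    batch_shift = dict(
        zip(batch_levels, rng.normal(0.0, config.batch_shift_sd, len(batch_levels)))
    )
    shift = sample_shift + np.array([batch_shift[b] for b in batches])

    effect = np.zeros((config.n_assays, n_samples))
    assay_pos = {a: i for i, a in enumerate(assays)}
    for assay, group, log2_fc in config.effects:
        cols = [j for j, g in enumerate(sample_group) if g == group]
        effect[assay_pos[assay], cols] += log2_fc

    ct = (
        baseline[:, None]
        + shift[None, :]
        - effect
        + rng.normal(0.0, config.noise_sd, size=(config.n_assays, n_samples))
    )

    rows_assay: list[str] = list(assays)
    rows_well = [1] * config.n_assays
    rows_panel = [panel_of[a] for a in assays]
    blocks = [ct]
    mask_blocks = [np.zeros_like(ct, dtype=bool)]

    control_id = f"{DEFAULT_CONTROL_NAME}-4395470"
    negative_id = f"{DEFAULT_NEGATIVE_NAME}-4373390"
    for panel in ("A", "B"):
        for w in range(1, config.n_control_replicates + 1):
            well_ct = (
                config.control_ct_mean
                + shift
                + rng.normal(0.0, config.control_ct_sd, size=n_samples)
            )
            rows_assay.append(control_id)
            rows_well.append(w)
            rows_panel.append(panel)
            blocks.append(well_ct[None, :])
            mask_blocks.append(np.zeros((1, n_samples), dtype=bool))
        # negative control: no mammalian template, sits at/above the censor
        neg_ct = 39.0 + rng.normal(0.0, 0.5, size=n_samples)
        rows_assay.append(negative_id)
        rows_well.append(1)
        rows_panel.append(panel)
        blocks.append(neg_ct[None, :])
        mask_blocks.append(np.zeros((1, n_samples), dtype=bool))

    ct_all = np.concatenate(blocks, axis=0)
    mask_all = np.concatenate(mask_blocks, axis=0)
    # censoring after noise: masking correlates with low expression
    mask_all |= ct_all > config.censor_ct

    ctm = CtMatrix(
        assay_ids=rows_assay,
        wells=np.array(rows_well),
        panel=np.array(rows_panel, dtype=object),
        sample_ids=samples,
        ct=ct_all,
        mask=mask_all,
        batch=np.array(batches, dtype=object),
        control_roles={control_id: "endogenous", negative_id: "negative"},
    )

    calibrators = _calibrator_flags(config, samples, sample_group, batches)
    annotations = [
        SampleAnnotation(
            sample_id=s,
            group=g,
            batch=b,
            is_calibrator=s in calibrators,
        )
        for s, g, b in zip(samples, sample_group, batches)
    ]
    truth = pd.DataFrame(
        [
            {"assay_id": a, "group": g, "log2_effect": e, "panel": panel_of[a]}
            for a, g, e in config.effects
        ],
        columns=["assay_id", "group", "log2_effect", "panel"],
    )
    return ctm, annotations, truth


def _calibrator_flags(config, samples, sample_group, batches) -> set[str]:
    if config.batch_calibration:
        chosen: dict[str, str] = {}
        for s, b in zip(samples, batches):
            chosen.setdefault(b, s)
        return set(chosen.values())
    # global calibrator: first Nevus 30 sample (PN1-style) when present
    for s, g in zip(samples, sample_group):
        if g == "Nevus 30":
            return {s}
    return {samples[0]}


def study_like_preset(
    seed: int = 0, with_effects: bool = True
) -> SyntheticConfig:
    """Configuration mirroring the study design: 26 samples in groups of
    10/10/3/3, 666 assays on two panels, three batches, and (optionally)
    30 planted group effects on the older-adult melanoma group spanning
    all fold-change bins."""
    config = SyntheticConfig(seed=seed)
    if with_effects:
        assays = assay_catalog(config)
        step = config.n_assays // len(PRESET_EFFECT_SIZES)
        config.effects = [
            (assays[i * step], "Mel 60", float(e))
            for i, e in enumerate(PRESET_EFFECT_SIZES)
        ]
        config.validate()
    return config


def null_preset(seed: int = 0) -> SyntheticConfig:
    """Study-like design with no planted effects (global null)."""
    return study_like_preset(seed=seed, with_effects=False)


def two_group_preset(
    n_per_group: int = 10,
    n_effect_assays: int = 30,
    log2_effect: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticConfig:
    """Balanced two-group design (older vs younger melanoma) with a block
    of equal-size planted effects; the workhorse for power/FDR studies."""
    config = SyntheticConfig(
        groups={"Mel 60": n_per_group, "Mel 30": n_per_group},
        noise_sd=noise_sd,
        seed=seed,
    )
    assays = assay_catalog(config)
    step = max(1, config.n_assays // max(n_effect_assays, 1))
    config.effects = [
        (assays[i * step], "Mel 60", log2_effect) for i in range(n_effect_assays)
    ]
    config.validate()
    return config
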