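import numpy as np
import pytest

from mirtlda.errors import ValidationError
from mirtlda.normalization import compute_rq, group_fold_change, normalize
from mirtlda.synthetic_data import (
    SyntheticConfig,
    assay_catalog,
    generate_dataset,
    null_preset,
    study_like_preset,
    two_group_preset,
)


def _groups(annotations):
    groups = {}
    for a in annotations:
        groups.setdefault(a.group, []).append(a.sample_id)
    return groups


class TestPreset:
    def test_study_design_dimensions(self):
        cfg = study_like_preset()
        assert cfg.n_assays == 666
        assert cfg.panel_split == (377, 289)
        assert cfg.groups == {"Mel 60": 10, "Mel 30": 10, "Nevus 60": 3, "Nevus 30": 3}
        assert cfg.n_batches == 3
        assert cfg.n_control_replicates == 4
        assert len(cfg.effects) == 30

    def test_preset_effects_span_all_bins(self):
        from mirtlda.normalization import fc_bin

        bins = {fc_bin(2.0 ** abs(e)) for _, _, e in study_like_preset().effects}
        assert bins == {"FC 1.2-1.6", "FC 1.6-2.0", "FC 2.0-4.0", "FC > 4"}

    def test_generated_matrix_shape_and_controls(self, study_dataset):
        ctm, annotations, truth = study_dataset
        assert len(ctm.sample_ids) == 26
        # 666 measurement rows + per panel: 4 control wells + 1 negative
        assert len(ctm.assay_ids) == 666 + 2 * 5
        assert ctm.measurement_rows().sum() == 666
        assert sum(1 for a in ctm.assay_ids if ctm.role_of(a) == "endogenous") == 8
        assert len(truth) == 30
        assert sum(a.is_calibrator for a in annotations) == 1
        assert {a.batch for a in annotations} == {"batch1", "batch2", "batch3"}


class TestGenerate:
    def test_zero_noise_zero_effects_gives_unit_fc(self):
        cfg = SyntheticConfig(
            n_assays=40,
            panel_split=(25, 15),
            groups={"Mel 60": 3, "Mel 30": 3, "Nevus 30": 2},
            noise_sd=0.0,
            control_ct_sd=0.0,
            baseline_ct_range=(22.0, 30.0),
            seed=5,
        )
        ctm, annotations, _ = generate_dataset(cfg)
        norm = normalize(ctm)
        cal = [a.sample_id for a in annotations if a.is_calibrator][0]
        rq = compute_rq(norm, cal)
        np.testing.assert_allclose(rq.ddct[~rq.mask], 0.0, atol=1e-10)
        np.testing.assert_allclose(rq.rq[~rq.mask], 1.0, atol=1e-10)

    def test_same_seed_byte_identical(self):
        a = generate_dataset(study_like_preset(seed=3))
        b = generate_dataset(study_like_preset(seed=3))
        np.testing.assert_array_equal(a[0].ct, b[0].ct)
        np.testing.assert_array_equal(a[0].mask, b[0].mask)
        assert a[0].assay_ids == b[0].assay_ids
        assert [x.sample_id for x in a[1]] == [x.sample_id for x in b[1]]
        assert a[2].equals(b[2])

    def test_planted_two_cycle_effect_recovered(self):
        """A +2 log2 effect (true FC 4) at n=10+10, noise 0.5 cycles: the
        group fold-change estimator is unbiased on the log2 scale and
        lands in the [3.0, 5.3] band in most seeds.  The log2 estimate
        has standard error ~0.25 (cell noise 0.5 plus control-replicate
        and batch terms, two groups of 10), so the band is ~1.7 standard
        errors wide on each side: expected coverage ~0.90."""
        hits = 0
        log2_fcs = []
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = two_group_preset(
                n_effect_assays=1, log2_effect=2.0, noise_sd=0.5, seed=seed
            )
            ctm, annotations, truth = generate_dataset(cfg)
            norm = normalize(ctm)
            cal = [a.sample_id for a in annotations if a.is_calibrator][0]
            rq = compute_rq(norm, cal)
            recs = group_fold_change(rq, _groups(annotations), "Mel 60", "Mel 30")
            fc = {r.assay_id: r.fc for r in recs}[truth.assay_id.iloc[0]]
            hits += 3.0 <= fc <= 5.3
            log2_fcs.append(np.log2(fc))
        assert abs(np.mean(log2_fcs) - 2.0) < 0.15
        assert hits >= int(0.75 * n_seeds)

    def test_sample_shift_invariance(self):
        """Estimated fold changes do not depend on the per-sample global
        CT offset (the control subtraction removes it)."""
        base = dict(
            n_assays=120,
            panel_split=(70, 50),
            groups={"Mel 60": 5, "Mel 30": 5},
            baseline_ct_range=(22.0, 30.0),  # stays clear of the censor
            seed=9,
        )
        cfg0 = SyntheticConfig(sample_shift_sd=0.0, **base)
        cfg2 = SyntheticConfig(sample_shift_sd=2.0, **base)
        assays = assay_catalog(cfg0)
        cfg0.effects = cfg2.effects = [(assays[3], "Mel 60", 1.5)]
        fcs = []
        for cfg in (cfg0, cfg2):
            ctm, annotations, _ = generate_dataset(cfg)
            norm = normalize(ctm)
            cal = [a.sample_id for a in annotations if a.is_calibrator][0]
            rq = compute_rq(norm, cal)
            recs = group_fold_change(rq, _groups(annotations), "Mel 60", "Mel 30")
            fcs.append(np.array([r.fc for r in recs]))
        np.testing.assert_allclose(fcs[0], fcs[1], rtol=1e-9)

    def test_censoring_masks_high_ct(self):
        cfg = SyntheticConfig(
            n_assays=60,
            panel_split=(40, 20),
            groups={"Mel 60": 3, "Mel 30": 3},
            baseline_ct_range=(36.0, 40.0),
            censor_ct=38.0,
            seed=1,
        )
        ctm, _, _ = generate_dataset(cfg)
        rows = ctm.measurement_rows()
        assert ctm.mask[rows].any()
        assert (ctm.ct[rows][~ctm.mask[rows]] <= 38.0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(n_assays=10, panel_split=(5, 4)).validate()
        with pytest.raises(ValidationError):
            SyntheticConfig(noise_sd=-1.0).validate()
        cfg = SyntheticConfig()
        cfg.effects = [("no-such-assay", "Mel 60", 1.0)]
        with pytest.raises(ValidationError):
            cfg.validate()

    def test_config_round_trips_through_yaml(self, tmp_path):
        cfg = study_like_preset(seed=7)
        path = tmp_path / "config.yaml"
        cfg.save(path)
        back = SyntheticConfig.load(path)
        assert back == cfg


class TestNullBehaviour:
    def test_null_preset_has_no_effects(self):
        assert null_preset().effects == []

    def test_null_false_positive_rate_near_nominal(self):
        """Across a few null replicates the two-sample t at 0.05 flags
        about 5% of assays on the Mel 60 vs Mel 30 contrast."""
        from mirtlda.class_comparison import compare_classes

        fracs = []
        for seed in range(5):
            ctm, annotations, _ = generate_dataset(null_preset(seed=seed))
            norm = normalize(ctm)
            res = compare_classes(norm, annotations, ("Mel 60", "Mel 30"), mode="I")
            fracs.append(np.mean([r.p < 0.05 for r in res]))
        assert 0.02 < np.mean(fracs) < 0.09
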