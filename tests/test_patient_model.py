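"""Density-image rendering, patient classifiers, composition invariances."""

import numpy as np
import pandas as pd
import pytest

from leukoflow.alot_synth import SimConfig, simulate_cohort, simulate_patient, default_phenotypes
from leukoflow.errors import ConfigError, PanelMismatch
from leukoflow.evaluation import split_cohort
from leukoflow.fcs_io import EventMatrix
from leukoflow.features import (
    composition_vector,
    composition_with_summaries,
    transform_events,
)
from leukoflow.patient_model import (
    DEFAULT_PAIRS,
    FLUOR_RANGE,
    PatientModelConfig,
    density_images_from_manifest,
    load_checkpoint,
    predict_patient,
    predict_patients,
    render_density_image,
    save_checkpoint,
    train_phase1,
    train_phase3,
)
from leukoflow.vocab import CELL_TYPES, DIAGNOSES


def _em(values):
    return EventMatrix("s", values)


class TestDensityImage:
    def test_identical_events_single_bin(self, rng):
        values = np.tile(rng.uniform(100, 1000, 12), (50, 1))
        img = render_density_image(_em(values), bins=32)
        for plane in img.planes:
            assert (plane > 0).sum() == 1
            assert plane.max() == 1.0

    def test_raw_count_conservation(self, rng):
        values = rng.uniform(0, 250_000, (321, 12))
        img = render_density_image(_em(values), bins=16, normalization="raw-count")
        for plane in img.planes:
            assert plane.sum() == 321

    def test_unknown_channel_raises(self, rng):
        em = _em(rng.uniform(0, 100, (10, 12)))
        with pytest.raises(PanelMismatch):
            render_density_image(em, pairs=(("CD45", "CD99"),))

    def test_permutation_invariant(self, rng):
        values = rng.uniform(0, 100_000, (200, 12))
        i1 = render_density_image(_em(values))
        i2 = render_density_image(_em(values[rng.permutation(200)]))
        np.testing.assert_array_equal(i1.planes, i2.planes)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_binning(self, seed):
        rng = np.random.default_rng(seed)
        n, bins = rng.integers(5, 60), 8
        values = rng.uniform(0, 250_000, (n, 12))
        em = _em(values)
        img = render_density_image(em, bins=bins, normalization="raw-count")
        t = transform_events(em)
        panel = em.panel
        for p, (cx, cy) in enumerate(DEFAULT_PAIRS):
            rx = FLUOR_RANGE if panel.roles[panel.index(cx)] == "fluorescence" else (0.0, 1.0)
            ry = FLUOR_RANGE if panel.roles[panel.index(cy)] == "fluorescence" else (0.0, 1.0)
            expected = np.zeros((bins, bins))
            for ev in range(n):  # double-loop oracle
                x = min(max(t[ev, panel.index(cx)], rx[0]), rx[1])
                y = min(max(t[ev, panel.index(cy)], ry[0]), ry[1])
                bx = min(int((x - rx[0]) / (rx[1] - rx[0]) * bins), bins - 1)
                by = min(int((y - ry[0]) / (ry[1] - ry[0]) * bins), bins - 1)
                expected[bx, by] += 1
            np.testing.assert_array_equal(img.planes[p], expected)


def _toy_compositions(n_per_class=8):
    """One-hot-ish compositions perfectly separable by diagnosis."""
    comps, diags = [], []
    for d_idx, diag in enumerate(DIAGNOSES):
        for j in range(n_per_class):
            labels = np.array([CELL_TYPES[d_idx]] * 50 + [CELL_TYPES[15]] * j)
            comps.append(composition_vector(labels, sample_id=f"{diag}{j}"))
            diags.append(diag)
    return comps, np.array(diags)


class TestPhase3:
    def test_separable_toy_compositions_perfect(self):
        comps, diags = _toy_compositions()
        cfg = PatientModelConfig(seed=0, max_epochs=30, batch_size=8)
        model = train_phase3(comps, diags, config=cfg)
        pred, proba = predict_patients(model, comps)
        assert (pred == diags).mean() == 1.0
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_prediction_invariant_to_event_count(self):
        # composition input depends only on fractions: duplicating every
        # event must not change the prediction
        comps, diags = _toy_compositions()
        cfg = PatientModelConfig(seed=1, max_epochs=10, batch_size=8)
        model = train_phase3(comps, diags, config=cfg)
        labels = np.array(["Neu"] * 30 + ["B-lym"] * 10)
        c1 = composition_vector(labels)
        c2 = composition_vector(np.concatenate([labels, labels]))
        l1, p1 = predict_patient(model, c1)
        l2, p2 = predict_patient(model, c2)
        assert l1 == l2
        np.testing.assert_allclose(p1, p2)

    def test_feature_dimension_mismatch_raises(self):
        comps, diags = _toy_compositions()
        with pytest.raises(ConfigError):
            train_phase3(np.zeros((10, 7)), diags[:10])

    def test_duplicate_sample_identical_prediction(self):
        comps, diags = _toy_compositions()
        cfg = PatientModelConfig(seed=2, max_epochs=5, batch_size=8)
        model = train_phase3(comps, diags, config=cfg)
        l1, p1 = predict_patient(model, comps[0])
        l2, p2 = predict_patient(model, comps[0])
        assert l1 == l2
        np.testing.assert_array_equal(p1, p2)

    def test_with_summaries_at_least_as_good_on_training_set(self):
        # feature-superset check at convergence on an easy cohort
        rng = np.random.default_rng(0)
        comps, diags = [], []
        for diag in DIAGNOSES:
            spec = default_phenotypes()[diag]
            for j in range(6):
                p = simulate_patient(spec, 400, seed=int(rng.integers(2**31)))
                comps.append(composition_with_summaries(p.em, p.labels))
                diags.append(diag)
        diags = np.array(diags)
        accs = {}
        for ws in (False, True):
            # train to convergence: no validation carve-out, no early stop
            cfg = PatientModelConfig(
                seed=3, max_epochs=150, batch_size=8,
                val_fraction=0.0, patience=150,
            )
            model = train_phase3(comps, diags, with_summaries=ws, config=cfg)
            pred, _ = predict_patients(model, comps)
            accs[ws] = (pred == diags).mean()
        assert accs[True] >= accs[False]


@pytest.fixture(scope="module")
def small_cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("p1")
    config = SimConfig(
        n_patients_per_diagnosis={"Normal": 10, "AML": 10},
        n_events=800,
        seed=13,
    )
    return pd.read_csv(simulate_cohort(config, out), dtype=str)


class TestPhase1:
    def test_two_class_high_accuracy(self, small_cohort):
        split = split_cohort(small_cohort, seed=13)
        train = small_cohort[small_cohort.sample_id.isin(split.train_ids)]
        test = small_cohort[small_cohort.sample_id.isin(split.test_ids)]
        cfg = PatientModelConfig(seed=13, max_epochs=25, batch_size=8)
        model = train_phase1(train, cfg)
        X, _, _ = density_images_from_manifest(test, cfg)
        pred, _ = predict_patients(model, X)
        assert (pred == test.diagnosis.to_numpy()).mean() >= 0.95

    def test_fixed_seed_reproducible_loss(self, small_cohort):
        train = small_cohort.iloc[6:14]  # both diagnoses present
        cfg = PatientModelConfig(seed=5, max_epochs=2, batch_size=4)
        m1 = train_phase1(train, cfg)
        m2 = train_phase1(train, cfg)
        assert m1.history.train_loss == m2.history.train_loss


class TestCheckpoint:
    def test_phase3_round_trip(self, tmp_path):
        comps, diags = _toy_compositions()
        cfg = PatientModelConfig(seed=4, max_epochs=3, batch_size=8)
        model = train_phase3(comps, diags, config=cfg)
        path = save_checkpoint(model, tmp_path / "p3.npz")
        back = load_checkpoint(path)
        _, p1 = predict_patients(model, comps[:4])
        _, p2 = predict_patients(back, comps[:4])
        np.testing.assert_allclose(p1, p2)
        assert back.input_mode == "composition"
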