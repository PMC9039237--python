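"""Compartment classification and percent-positive scoring."""
import logging

import numpy as np
import pandas as pd
import pytest

from senesurv.quantification import (
    apply_positivity_threshold,
    classify_compartments,
    percent_positive,
    train_compartment_classifier,
)


def _cells_frame(intensities, positives, patient=1, core=1, marker="p21",
                 compartment="epithelium"):
    n = len(intensities)
    return pd.DataFrame({
        "patient_id": patient, "core_id": core, "section_id": "S1",
        "cell_id": np.arange(n), "x_um": 0.0, "y_um": 0.0,
        "compartment": compartment, "marker": marker,
        "intensity": intensities, "positive": np.asarray(positives, dtype=int),
    })


class TestClassifier:
    def test_separable_gaussians_high_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 1, (500, 3)), rng.normal(4, 1, (500, 3))])
        y = np.array(["epithelium"] * 500 + ["stroma"] * 500)
        hold = rng.random(1000) < 0.3
        clf = train_compartment_classifier(X[~hold], y[~hold], seed=0)
        acc = np.mean(clf.predict(X[hold]) == y[hold])
        assert acc >= 0.95

    def test_no_signal_accuracy_near_chance(self):
        r = np.random.default_rng(42)
        X = r.normal(0, 1, (2000, 3))
        y = np.array(["epithelium", "stroma"])[r.integers(0, 2, 2000)]
        Xt = r.normal(0, 1, (1000, 3))
        yt = np.array(["epithelium", "stroma"])[r.integers(0, 2, 1000)]
        clf = train_compartment_classifier(X, y, seed=0)
        assert abs(np.mean(clf.predict(Xt) == yt) - 0.5) <= 0.05

    def test_single_class_raises(self, rng):
        X = rng.normal(0, 1, (50, 3))
        with pytest.raises(ValueError, match="2 classes"):
            train_compartment_classifier(X, np.repeat("epithelium", 50))

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            train_compartment_classifier(rng.normal(0, 1, (50, 3)), np.repeat("a", 49))


class TestThreshold:
    def test_zero_threshold_flags_all(self, rng):
        cells = _cells_frame(rng.uniform(0.1, 5, 100), np.zeros(100))
        out = apply_positivity_threshold(cells, "p21", 0.0)
        assert out["positive"].sum() == 100

    def test_threshold_above_max_flags_none(self, rng):
        cells = _cells_frame(rng.uniform(0, 5, 100), np.ones(100))
        out = apply_positivity_threshold(cells, "p21", 6.0)
        assert out["positive"].sum() == 0

    def test_counting_oracle_and_idempotence(self, rng):
        inten = rng.uniform(0, 4, 200)
        cells = _cells_frame(inten, np.zeros(200))
        thr = np.sort(inten)[::-1][49]  # exactly 50 intensities >= thr
        out = apply_positivity_threshold(cells, "p21", thr)
        assert out["positive"].sum() == 50
        again = apply_positivity_threshold(out, "p21", thr)
        pd.testing.assert_frame_equal(out, again)

    def test_unknown_marker_raises(self, rng):
        cells = _cells_frame(rng.uniform(0, 4, 10), np.zeros(10))
        with pytest.raises(KeyError):
            apply_positivity_threshold(cells, "CD8", 1.0)


class TestPercentPositive:
    def test_counting_oracle(self):
        cells = _cells_frame(np.ones(200), [1] * 50 + [0] * 150)
        out = percent_positive(cells, "p21")
        assert out.loc[0, "percent_positive"] == 25.0
        assert out.loc[0, "n_cells_scored"] == 200

    @pytest.mark.parametrize("flags,expected", [(1, 100.0), (0, 0.0)])
    def test_extremes(self, flags, expected):
        cells = _cells_frame(np.ones(80), [flags] * 80)
        assert percent_positive(cells, "p21").loc[0, "percent_positive"] == expected

    def test_invariant_to_row_order_and_core_relabel(self, rng):
        parts = [_cells_frame(rng.uniform(0, 4, 60), rng.integers(0, 2, 60), core=c)
                 for c in (1, 2, 3)]
        cells = pd.concat(parts, ignore_index=True)
        base = percent_positive(cells, "p21")
        shuffled = cells.sample(frac=1.0, random_state=0).reset_index(drop=True)
        relabeled = cells.assign(core_id=cells["core_id"].map({1: 9, 2: 4, 3: 5}))
        for variant in (shuffled, relabeled):
            pd.testing.assert_frame_equal(percent_positive(variant, "p21"), base)

    def test_pooled_equals_weighted_mean_of_cores(self, rng):
        sizes = [37, 81, 12]
        parts = [_cells_frame(rng.uniform(0, 4, n), rng.integers(0, 2, n), core=c)
                 for c, n in enumerate(sizes, 1)]
        cells = pd.concat(parts, ignore_index=True)
        pooled = percent_positive(cells, "p21").loc[0, "percent_positive"]
        per_core = [100.0 * p["positive"].mean() for p in parts]
        weighted = np.average(per_core, weights=sizes)
        assert pooled == pytest.approx(weighted, abs=1e-12)

    def test_unclassified_cells_excluded(self, rng):
        epi = _cells_frame(np.ones(50), [1] * 25 + [0] * 25)
        unc = _cells_frame(np.ones(30), [1] * 30, compartment="unclassified")
        unc["cell_id"] += 100
        out = percent_positive(pd.concat([epi, unc], ignore_index=True), "p21")
        assert out.loc[0, "percent_positive"] == 50.0
        assert out.loc[0, "n_cells_scored"] == 50

    def test_patient_without_epithelium_dropped_with_warning(self, caplog):
        a = _cells_frame(np.ones(40), [1] * 40, patient=1)
        b = _cells_frame(np.ones(40), [1] * 40, patient=2, compartment="stroma")
        cells = pd.concat([a, b], ignore_index=True)
        with caplog.at_level(logging.WARNING):
            out = percent_positive(cells, "p21")
        assert list(out["patient_id"]) == [1]
        assert any("excluded" in r.message for r in caplog.records)


def test_classifier_scoring_end_to_end():
    """Predicted compartments reproduce latent percent positives within +/-3 points.

    ~2100 cells per patient leave binomial sampling noise of at most ~1.4
    points sd, so classification errors would have to be gross to push 5%
    of patients past the 3-point band.
    """
    from senesurv.config import SimConfig
    from senesurv.synthetic_data import simulate_cohort

    cfg = SimConfig(n_patients=30, seed=19, cells_per_core=700.0, cd8_per_core=5.0,
                    marker_panel=("NTAL", "p21"), driver_marker="NTAL")
    cohort = simulate_cohort(cfg)
    cells = classify_compartments(cohort.cells, train_frac=0.2, seed=0)
    truth = cohort.truth.set_index("patient_id")
    scores = percent_positive(cells, "NTAL").set_index("patient_id")
    err = (scores["percent_positive"] - truth.loc[scores.index, "percent_NTAL"]).abs()
    assert np.mean(err < 3.0) >= 0.95
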