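import math

import numpy as np
import pandas as pd
import pytest

from ormsim import NNStructure, SurrogateModel, rmse, select_structure, split_train_test, train
from ormsim.doe import L9_ARRAY
from ormsim.scenario import default_fixture_scenario


def toy_table(n_reps=50, noise=0.01, seed=0):
    """Nine L9 settings with d linear in the holding-nurse factor plus noise."""
    levels = default_fixture_scenario().factor_levels
    rng = np.random.default_rng(seed)
    rows = []
    for sid, idx in enumerate(L9_ARRAY, start=1):
        a, b, c, d4 = levels.setting_from_indices(idx).as_tuple()
        for _ in range(n_reps):
            target = 0.2 + 0.6 * (a - 10) / 10 + rng.normal(0.0, noise)
            rows.append((sid, a, b, c, d4, min(max(target, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["setting_id", "A", "B", "C", "D", "d"])


def test_rmse_textbook_three_points():
    assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 5.0]) == pytest.approx(math.sqrt(4 / 3))
    assert rmse([0.5], [0.5]) == 0.0
    with pytest.raises(ValueError):
        rmse([1.0], [1.0, 2.0])


def test_structure_bounds():
    with pytest.raises(ValueError):
        NNStructure(0)
    with pytest.raises(ValueError):
        NNStructure(7)
    assert NNStructure(3).label() == "4, 3, 1"


def test_split_is_stratified_and_deterministic():
    table = toy_table(n_reps=10)
    tr, te = split_train_test(table, fraction=0.8, seed=4)
    assert len(tr) == 72 and len(te) == 18
    assert set(tr["setting_id"]) == set(range(1, 10))
    assert set(te["setting_id"]) == set(range(1, 10))
    tr2, te2 = split_train_test(table, fraction=0.8, seed=4)
    pd.testing.assert_frame_equal(tr, tr2)
    pd.testing.assert_frame_equal(te, te2)


def test_split_rejects_tiny_groups():
    table = toy_table(n_reps=1)
    with pytest.raises(ValueError, match="too few"):
        split_train_test(table, fraction=0.8, seed=0)


def test_training_fits_linear_response():
    table = toy_table()
    model, report = train(table, NNStructure(3), seed=0, epochs=2000)
    assert report.rmse_train < 0.05


def test_training_is_deterministic():
    table = toy_table()
    m1, r1 = train(table, NNStructure(2), seed=9, epochs=300)
    m2, r2 = train(table, NNStructure(2), seed=9, epochs=300)
    assert np.array_equal(m1.w1, m2.w1)
    assert np.array_equal(m1.w2, m2.w2)
    assert r1.rmse_train == r2.rmse_train


def test_predictions_stay_in_unit_interval(rng):
    table = toy_table()
    model, _ = train(table, NNStructure(4), seed=1, epochs=300)
    probes = rng.uniform([10, 15, 15, 5], [20, 35, 25, 15], size=(200, 4))
    preds = model.predict_many(probes)
    assert np.all((preds > 0.0) & (preds < 1.0))
    one = model.predict(probes[0])
    assert one == model.predict(probes[0])   # deterministic forward pass


def test_hand_built_forward_pass():
    # setting at the scaling minimum -> scaled inputs all zero -> only biases act
    model = SurrogateModel(
        structure=NNStructure(2),
        w1=np.zeros((4, 2)), b1=np.array([0.3, -0.2]),
        w2=np.array([1.0, 2.0]), b2=0.1,
        x_min=np.array([10.0, 15.0, 15.0, 5.0]),
        x_max=np.array([20.0, 35.0, 25.0, 15.0]))
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    expected = sig(1.0 * sig(0.3) + 2.0 * sig(-0.2) + 0.1)
    assert model.predict(np.array([10.0, 15.0, 15.0, 5.0])) == pytest.approx(expected)


def test_model_json_round_trip(tmp_path):
    table = toy_table()
    model, _ = train(table, NNStructure(2), seed=3, epochs=100)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = SurrogateModel.load(path)
    probe = np.array([[14, 22, 18, 9]], dtype=float)
    assert loaded.predict_many(probe) == pytest.approx(model.predict_many(probe))


def test_structure_selection_contract():
    table = toy_table(n_reps=20)
    model, report, report_table = select_structure(
        table, candidates=range(1, 7), seed=2, epochs=400)
    assert len(report_table) == 6
    best_row = report_table.loc[report_table["rmse_test"].idxmin()]
    assert best_row["hidden_nodes"] == model.structure.hidden_nodes
    assert report.rmse_test == pytest.approx(report_table["rmse_test"].min())
    # repeat run selects identically
    model2, report2, _ = select_structure(
        table, candidates=range(1, 7), seed=2, epochs=400)
    assert report2.structure == report.structure
    assert np.array_equal(model2.w1, model.w1)


def test_rmse_approaches_noise_floor_with_more_data():
    noisy = toy_table(n_reps=200, noise=0.05, seed=1)
    tr, te = split_train_test(noisy, 0.8, 0)
    _, report = train(tr, NNStructure(3), seed=0, test_table=te, epochs=2000)
    assert 0.04 < report.rmse_test < 0.07     # close to the injected 0.05 noise


def test_against_independent_mlp_reference():
    """scikit-learn's MLP, as an independent fit of the same toy response,
    reaches the same noise floor our trainer does."""
    sklearn = pytest.importorskip("sklearn.neural_network")
    table = toy_table(n_reps=30, noise=0.02, seed=5)
    ours, report = train(table, NNStructure(3), seed=0, epochs=2000)
    x = table[["A", "B", "C", "D"]].to_numpy(float)
    y = table["d"].to_numpy(float)
    ref = sklearn.MLPRegressor(hidden_layer_sizes=(3,), activation="logistic",
                               solver="lbfgs", max_iter=5000, random_state=0)
    ref.fit((x - x.min(0)) / (x.max(0) - x.min(0)), y)
    ref_rmse = rmse(ref.predict((x - x.min(0)) / (x.max(0) - x.min(0))), y)
    assert report.rmse_train < 0.05
    assert abs(report.rmse_train - ref_rmse) < 0.03
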