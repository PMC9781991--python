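"""Time-domain predictors: closed-form spot checks, scaling laws, matrix
layout, and CSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emgselect import (
    FeatureMatrix,
    PredictorSpec,
    compute_predictor,
    extract_matrix,
    select_columns,
)
from emgselect.errors import DataError, ParameterError, ShapeError
from emgselect.features import (
    PREDICTOR_NAMES,
    SCREENED_OUT_PREDICTORS,
    compute_features,
    default_predictors,
)
from emgselect.preprocess import WindowSpec, segment


def test_predictor_set_is_the_closed_26():
    assert len(PREDICTOR_NAMES) == 26
    assert set(SCREENED_OUT_PREDICTORS) <= set(PREDICTOR_NAMES)


@pytest.mark.parametrize(
    "name,x,expected",
    [
        ("MAV", [1, -1, 1, -1], 1.0),
        ("SSI", [1, 2], 5.0),
        ("IEMG", [1, 2], 3.0),
        ("ZC", [1, -1, 1, -1], 3.0),
        ("RMS", [3, -4], 3.5355339),
        ("WL", [0, 1, -1, 2], 6.0),
        ("AAC", [0, 1, -1, 2], 2.0),
        ("VAR", [1, 2, 3], 7.0),          # Σx²/(N−1), zero-mean convention
        ("MAD", [1, 2, 3], 2.0 / 3.0),
        ("Y3", [1, 2, 3], 12.0),
        ("MYOP", [0.01, 0.5, -0.5, 0.0], 0.5),
        ("WAMP", [0.0, 0.5, 0.51, -0.5], 2.0),
    ],
)
def test_closed_form_examples(name, x, expected):
    assert compute_predictor(np.asarray(x, dtype=float), name) == pytest.approx(expected)


def test_zero_crossings_brute_force_oracle():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(200)
    brute = sum(1 for a, b in zip(x, x[1:]) if a * b < 0)
    assert compute_predictor(x, "ZC") == brute


def test_slope_sign_changes_brute_force_oracle():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(200)
    brute = sum(
        1 for i in range(1, len(x) - 1)
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0
    )
    assert compute_predictor(x, "SSC") == brute


def test_unknown_predictor_rejected():
    with pytest.raises(ParameterError):
        PredictorSpec("MAVX")


def test_window_too_short_rejected():
    with pytest.raises(DataError):
        compute_predictor(np.array([1.0]), "MAV")


LINEAR_SCALING = ("MAV", "RMS", "STD", "IEMG", "WL", "AAC", "DASDV", "MAD")
GAIN_INVARIANT = ("ZC", "SSC", "K", "SK", "FC", "SE")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    x=arrays(np.float64, 64, elements=st.floats(-5, 5, allow_nan=False)),
    gain=st.floats(0.1, 50.0),
)
def test_amplitude_scaling_laws(x, gain):
    if np.std(x) < 1e-6:
        return  # degenerate constant window
    for name in LINEAR_SCALING:
        base = compute_predictor(x, name)
        scaled = compute_predictor(gain * x, name)
        assert scaled == pytest.approx(gain * base, rel=1e-8, abs=1e-10)
    for name in GAIN_INVARIANT:
        base = compute_predictor(x, name)
        scaled = compute_predictor(gain * x, name)
        assert scaled == pytest.approx(base, rel=1e-6, abs=1e-8)


def test_batch_matches_scalar_path():
    rng = np.random.default_rng(0)
    windows = rng.standard_normal((3, 2, 50))
    preds = default_predictors()
    batch = compute_features(windows, preds)
    assert batch.shape == (3, 2, 26)
    for i, p in enumerate(preds):
        assert batch[1, 0, i] == pytest.approx(
            compute_predictor(windows[1, 0], p), rel=1e-9, abs=1e-12
        )


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


def test_unsegmented_matrix_layout(tiny_db, tiny_spec):
    preds = default_predictors(["MAV", "RMS", "ZC"])
    m = extract_matrix(tiny_db, preds, list(tiny_spec.movement_names))
    assert m.shape == (len(tiny_db), 4 * 3)
    # channel-major column order
    assert list(m.columns[:4]) == [
        ("ch1", "MAV"), ("ch1", "RMS"), ("ch1", "ZC"), ("ch2", "MAV"),
    ]
    # rows subject-major, then movement in the declared order
    assert m.rows["subject"].is_monotonic_increasing
    first = m.rows[m.rows["subject"] == 0]["movement"].tolist()
    assert first == ["A"] * 4 + ["B"] * 4 + ["RR"] * 4


def test_segmented_matrix_rows_are_windows(tiny_db, tiny_spec):
    subset = tiny_db[:6]
    wsets = [segment(r, WindowSpec(), 0.3, 0.0) for r in subset]
    n_win = wsets[0].n_windows
    m = extract_matrix(wsets, default_predictors(["MAV"]), list(tiny_spec.movement_names))
    assert m.shape == (6 * n_win, 4)
    assert m.rows["window"].tolist()[:n_win] == list(range(n_win))


def test_single_recording_single_predictor_consistency(tiny_db):
    rec = tiny_db[0]
    one_channel = rec.samples[:1]
    from emgselect.synth import Recording

    solo = Recording(samples=one_channel, fs=rec.fs, subject=0, movement="A", repetition=0)
    m = extract_matrix([solo], default_predictors(["RMS"]))
    assert m.shape == (1, 1)
    assert m.values[0, 0] == pytest.approx(compute_predictor(one_channel[0], "RMS"))


def test_segmented_equals_unsegmented_for_one_window_recording():
    from emgselect.synth import Recording

    rng = np.random.default_rng(1)
    rec = Recording(
        samples=rng.standard_normal((2, 250)), fs=1000.0,
        subject=0, movement="A", repetition=0,
    )
    preds = default_predictors(["MAV", "WL", "ZC", "RMS"])
    seg = extract_matrix([segment(rec, WindowSpec())], preds)
    unseg = extract_matrix([rec], preds)
    np.testing.assert_allclose(seg.values, unseg.values, rtol=1e-12)


def test_heterogeneous_channel_counts_rejected(tiny_db):
    from emgselect.synth import Recording

    other = Recording(
        samples=np.zeros((2, 100)) + 1.0, fs=1000.0,
        subject=9, movement="A", repetition=0,
    )
    with pytest.raises(ShapeError):
        extract_matrix([tiny_db[0], other], default_predictors(["MAV"]))


def test_select_columns_identity_and_errors(tiny_db, tiny_spec):
    m = extract_matrix(tiny_db[:3], default_predictors(["MAV", "RMS"]))
    same = select_columns(m, np.ones(m.shape[1], dtype=int))
    np.testing.assert_array_equal(same.values, m.values)
    with pytest.raises(DataError):
        select_columns(m, np.zeros(m.shape[1], dtype=int))
    with pytest.raises(ShapeError):
        select_columns(m, np.ones(3))


def test_removing_six_predictors_drops_24_columns(tiny_db):
    m = extract_matrix(tiny_db[:3], default_predictors(PREDICTOR_NAMES))
    assert m.shape[1] == 104
    keep = ~m.columns.get_level_values("predictor").isin(SCREENED_OUT_PREDICTORS)
    reduced = select_columns(m, keep.astype(int))
    assert m.shape[1] - reduced.shape[1] == 24
    assert reduced.shape[1] == 80


def test_csv_round_trip(tmp_path, tiny_db):
    m = extract_matrix(tiny_db[:4], default_predictors(["MAV", "ZC"]))
    path = tmp_path / "m.csv"
    m.to_csv(path)
    back = FeatureMatrix.from_csv(path)
    np.testing.assert_allclose(back.values, m.values, rtol=1e-12)
    assert list(back.columns) == list(m.columns)
    assert back.rows["movement"].tolist() == m.rows["movement"].tolist()
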