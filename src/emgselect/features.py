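"""Time-domain EMG predictors and labelled feature matrices.

26 classical time-domain (TD) features are computed per window (or whole
signal) and channel.  Writing x_1..x_N for the samples and Δx_i = x_{i+1} −
x_i, the implemented closed forms are:

==========  =============================================================
IEMG        Σ|x_i|                       (integrated EMG)
MAV         (1/N) Σ|x_i|
MMAV1       (1/N) Σ w_i|x_i|, w = 1 on the middle half, 0.5 elsewhere
MMAV2       (1/N) Σ w_i|x_i|, w = 4i/N rising, 1 middle, 4(N−i)/N falling
MAVSLP      mean of consecutive segment-MAV differences (3 equal segments)
SSI         Σ x_i²                       (simple square integral)
VAR         (1/(N−1)) Σ x_i²             (EMG convention: zero-mean signal)
RMS         sqrt((1/N) Σ x_i²)
STD         sample standard deviation about the mean (ddof = 1)
WL          Σ|Δx_i|                      (waveform length)
AAC         (1/(N−1)) Σ|Δx_i|            (average amplitude change)
AAV         (1/N) Σ|Δx_i|                (amplitude average, per-sample)
DASDV       sqrt((1/(N−1)) Σ Δx_i²)
ZC          #{i : x_i·x_{i+1} < 0 and |x_i − x_{i+1}| ≥ thr}
SSC         #{i : (x_i − x_{i−1})(x_i − x_{i+1}) > thr}
WAMP        #{i : |Δx_i| > thr}          (Willison amplitude)
MYOP        (1/N) #{i : |x_i| > thr}     (myopulse percentage rate)
LOG         exp((1/N) Σ log|x_i|)        (log detector)
K           Pearson kurtosis m4/m2²
SK          skewness m3/m2^1.5
MAD         (1/N) Σ|x_i − mean(x)|       (mean absolute deviation)
Y3/Y4/Y5    |(1/N) Σ x_i^k|, k = 3, 4, 5 (absolute temporal moments)
SE          sample entropy, m = 2, r = 0.2·STD
FC          Higuchi fractal dimension, k_max = 8
==========  =============================================================

Thresholds (ZC/SSC default 0; WAMP/MYOP default 0.02 in unit-scaled
amplitudes) and the SE/FC estimator constants are configurable per
:class:`PredictorSpec`.

All formulas except SE and FC are evaluated vectorised over arbitrary
leading axes, so extracting features for tens of thousands of windows is a
handful of array passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, ShapeError
from .preprocess import WindowSet
from .synth import Recording

# ---------------------------------------------------------------------------
# predictor implementations (axis=-1, arbitrary leading dimensions)
# ---------------------------------------------------------------------------


def _iemg(x):
    return np.abs(x).sum(axis=-1)


def _mav(x):
    return np.abs(x).mean(axis=-1)


def _mmav1(x):
    n = x.shape[-1]
    i = np.arange(1, n + 1)
    w = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
    return (w * np.abs(x)).sum(axis=-1) / n


def _mmav2(x):
    n = x.shape[-1]
    i = np.arange(1, n + 1)
    w = np.ones(n)
    lo = i < 0.25 * n
    hi = i > 0.75 * n
    w[lo] = 4.0 * i[lo] / n
    w[hi] = 4.0 * (n - i[hi]) / n
    return (w * np.abs(x)).sum(axis=-1) / n


def _mavslp(x, segments=3):
    n = x.shape[-1]
    bounds = np.linspace(0, n, segments + 1).astype(int)
    mavs = np.stack(
        [np.abs(x[..., bounds[k]:bounds[k + 1]]).mean(axis=-1) for k in range(segments)],
        axis=-1,
    )
    return np.diff(mavs, axis=-1).mean(axis=-1)


def _ssi(x):
    return (x * x).sum(axis=-1)


def _var(x):
    return (x * x).sum(axis=-1) / (x.shape[-1] - 1)


def _rms(x):
    return np.sqrt((x * x).mean(axis=-1))


def _std(x):
    return x.std(axis=-1, ddof=1)


def _wl(x):
    return np.abs(np.diff(x, axis=-1)).sum(axis=-1)


def _aac(x):
    return np.abs(np.diff(x, axis=-1)).mean(axis=-1)


def _aav(x):
    return np.abs(np.diff(x, axis=-1)).sum(axis=-1) / x.shape[-1]


def _dasdv(x):
    d = np.diff(x, axis=-1)
    return np.sqrt((d * d).sum(axis=-1) / d.shape[-1])


def _zc(x, threshold=0.0):
    a, b = x[..., :-1], x[..., 1:]
    return ((a * b < 0) & (np.abs(a - b) >= threshold)).sum(axis=-1).astype(float)


def _ssc(x, threshold=0.0):
    prev = x[..., 1:-1] - x[..., :-2]
    nxt = x[..., 1:-1] - x[..., 2:]
    return (prev * nxt > threshold).sum(axis=-1).astype(float)


def _wamp(x, threshold=0.02):
    return (np.abs(np.diff(x, axis=-1)) > threshold).sum(axis=-1).astype(float)


def _myop(x, threshold=0.02):
    return (np.abs(x) > threshold).mean(axis=-1)


def _log(x, eps=1e-12):
    return np.exp(np.log(np.abs(x) + eps).mean(axis=-1))


def _kurtosis(x):
    return stats.kurtosis(x, axis=-1, fisher=False, bias=True)


def _skewness(x):
    return stats.skew(x, axis=-1, bias=True)


def _mad(x):
    return np.abs(x - x.mean(axis=-1, keepdims=True)).mean(axis=-1)


def _abs_moment(x, order):
    return np.abs(np.power(x, order).mean(axis=-1))


def _sampen_1d(x: np.ndarray, m: int, r_frac: float) -> float:
    """Sample entropy of one signal: −ln(A/B) with A, B the counts of
    template pairs (length m+1 and m) within Chebyshev distance
    r = r_frac·STD.  Degenerate counts are capped: B = 0 → 0, A = 0 →
    −ln(1/B) (one-match upper bound), keeping the value finite."""
    n = x.size
    r = r_frac * x.std(ddof=1)
    if r == 0 or n <= m + 1:
        return 0.0

    def _count(mm: int) -> int:
        idx = np.arange(n - mm + 1)
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=-1)
        within = d <= r
        # exclude self-matches; count unordered pairs
        return int((within.sum() - len(idx)) // 2)

    b = _count(m)
    if b == 0:
        return 0.0
    a = _count(m + 1)
    if a == 0:
        return float(np.log(b))
    return float(-np.log(a / b))


def _sampen(x, m=2, r_frac=0.2):
    flat = x.reshape(-1, x.shape[-1])
    out = np.array([_sampen_1d(row, m, r_frac) for row in flat])
    return out.reshape(x.shape[:-1])


def _higuchi_1d(x: np.ndarray, k_max: int) -> float:
    """Higuchi fractal dimension: slope of log(L(k)) vs log(1/k) for the
    mean normalized curve lengths over k = 1..k_max."""
    n = x.size
    lks = []
    ks = []
    for k in range(1, k_max + 1):
        lm = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            length = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lm.append(length * norm / k)
        if lm:
            mean_l = np.mean(lm)
            if mean_l > 0:
                lks.append(np.log(mean_l))
                ks.append(np.log(1.0 / k))
    if len(ks) < 2:
        return 1.0
    slope, _ = np.polyfit(ks, lks, 1)
    return float(slope)


def _higuchi(x, k_max=8):
    flat = x.reshape(-1, x.shape[-1])
    out = np.array([_higuchi_1d(row, k_max) for row in flat])
    return out.reshape(x.shape[:-1])


_REGISTRY: dict[str, Callable] = {
    "AAC": _aac,
    "AAV": _aav,
    "DASDV": _dasdv,
    "FC": _higuchi,
    "SE": _sampen,
    "K": _kurtosis,
    "SK": _skewness,
    "MAD": _mad,
    "WAMP": _wamp,
    "Y3": lambda x: _abs_moment(x, 3),
    "Y4": lambda x: _abs_moment(x, 4),
    "Y5": lambda x: _abs_moment(x, 5),
    "MYOP": _myop,
    "VAR": _var,
    "WL": _wl,
    "ZC": _zc,
    "LOG": _log,
    "MAV": _mav,
    "MAVSLP": _mavslp,
    "MMAV1": _mmav1,
    "MMAV2": _mmav2,
    "RMS": _rms,
    "SSC": _ssc,
    "SSI": _ssi,
    "STD": _std,
    "IEMG": _iemg,
}

#: the closed 26-predictor set, in canonical order
PREDICTOR_NAMES: tuple[str, ...] = tuple(_REGISTRY)

#: the six predictors indistinguishable across classes in the lower-limb
#: screening (dropped there before wrapper selection)
SCREENED_OUT_PREDICTORS: tuple[str, ...] = ("AAV", "DASDV", "FC", "SE", "WAMP", "MYOP")


@dataclass(frozen=True)
class PredictorSpec:
    """One named TD predictor plus its optional parameters
    (e.g. ``PredictorSpec("ZC", {"threshold": 0.01})``)."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise ParameterError(
                f"unknown predictor {self.name!r}; valid names: {sorted(_REGISTRY)}"
            )

    def __hash__(self) -> int:
        return hash((self.name, tuple(sorted(self.params.items()))))


def default_predictors(names: Iterable[str] = PREDICTOR_NAMES) -> list[PredictorSpec]:
    return [PredictorSpec(n) for n in names]


def compute_predictor(window: np.ndarray, p: PredictorSpec | str) -> float:
    """Evaluate one predictor on a single-channel segment (length >= 3)."""
    if isinstance(p, str):
        p = PredictorSpec(p)
    window = np.asarray(window, dtype=float)
    if window.ndim != 1:
        raise ShapeError("compute_predictor expects a 1-D window")
    if window.size < 2:
        raise DataError("window must contain at least 2 samples")
    return float(_REGISTRY[p.name](window, **p.params))


def compute_features(x: np.ndarray, predictors: Sequence[PredictorSpec]) -> np.ndarray:
    """Evaluate predictors over the last axis; returns shape ``x.shape[:-1] + (P,)``."""
    return np.stack([_REGISTRY[p.name](x, **p.params) for p in predictors], axis=-1)


# ---------------------------------------------------------------------------
# FeatureMatrix
# ---------------------------------------------------------------------------

_LABEL_COLS = ("subject", "movement", "repetition", "window")


@dataclass
class FeatureMatrix:
    """Rows = trials or windows; columns = channel × predictor (channel-major).

    ``rows`` is a DataFrame with columns subject, movement, repetition and
    window (window = −1 for unsegmented rows); ``columns`` is a two-level
    (channel, predictor) MultiIndex aligned with ``values``.
    """

    values: np.ndarray
    rows: pd.DataFrame
    columns: pd.MultiIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("values must be 2-D")
        if len(self.rows) != self.values.shape[0]:
            raise ShapeError("row labels do not match values")
        if len(self.columns) != self.values.shape[1]:
            raise ShapeError("column labels do not match values")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature matrix contains non-finite values")

    @property
    def classes(self) -> np.ndarray:
        return self.rows["movement"].to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        labels = self.rows.copy()
        labels.columns = pd.MultiIndex.from_product([["label"], labels.columns])
        feats = pd.DataFrame(self.values, columns=self.columns, index=labels.index)
        return pd.concat([labels, feats], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, header=[0, 1])
        is_label = df.columns.get_level_values(0) == "label"
        rows = df.loc[:, is_label].copy()
        rows.columns = rows.columns.get_level_values(1)
        feats = df.loc[:, ~is_label]
        return cls(
            values=feats.to_numpy(dtype=float),
            rows=rows[list(_LABEL_COLS)],
            columns=pd.MultiIndex.from_tuples(
                list(feats.columns), names=["channel", "predictor"]
            ),
        )

    def select_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(
            values=self.values[mask],
            rows=self.rows.iloc[mask].reset_index(drop=True) if mask.dtype == bool
            else self.rows.iloc[mask].reset_index(drop=True),
            columns=self.columns,
        )


def select_columns(m: FeatureMatrix, mask: Sequence[int] | np.ndarray) -> FeatureMatrix:
    """Keep exactly the columns where the binary mask is 1, preserving order."""
    mask = np.asarray(mask).astype(bool)
    if mask.size != m.values.shape[1]:
        raise ShapeError(f"mask length {mask.size} != {m.values.shape[1]} columns")
    if not mask.any():
        raise DataError("mask selects no columns")
    return FeatureMatrix(
        values=m.values[:, mask],
        rows=m.rows.copy(),
        columns=m.columns[mask],
    )


def _sort_key(class_order: Sequence[str] | None):
    def key(item):
        rec = item.source if isinstance(item, WindowSet) else item
        cls = rec.movement
        c = class_order.index(cls) if class_order is not None else cls
        return (rec.subject, c, rec.repetition)

    return key


def extract_matrix(
    items: Sequence[Recording | WindowSet],
    predictors: Sequence[PredictorSpec] | None = None,
    class_order: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble the labelled feature matrix.

    Unsegmented mode (``items`` are Recordings) yields one row per trial;
    segmented mode (``items`` are WindowSets) yields one row per window.
    Rows are ordered subject-major, then movement (by ``class_order`` when
    given), repetition, window; columns are channel-major
    (ch1·p1, ch1·p2, …, ch2·p1, …).
    """
    if len(items) == 0:
        raise DataError("no recordings to extract from")
    if predictors is None:
        predictors = default_predictors()
    segmented = isinstance(items[0], WindowSet)
    n_channels = (items[0].windows.shape[1] if segmented else items[0].n_channels)
    ordered = sorted(items, key=_sort_key(class_order))

    blocks: list[np.ndarray] = []
    labels: list[dict] = []
    for item in ordered:
        rec = item.source if segmented else item
        if segmented:
            if not isinstance(item, WindowSet):
                raise ShapeError("cannot mix Recordings and WindowSets")
            if item.windows.shape[1] != n_channels:
                raise ShapeError("heterogeneous channel counts")
            feats = compute_features(item.windows, predictors)  # (n_win, ch, P)
            blocks.append(feats.reshape(item.n_windows, -1))
            labels.extend(
                {
                    "subject": rec.subject,
                    "movement": rec.movement,
                    "repetition": rec.repetition,
                    "window": int(w),
                }
                for w in range(item.n_windows)
            )
        else:
            if isinstance(item, WindowSet):
                raise ShapeError("cannot mix Recordings and WindowSets")
            if item.n_channels != n_channels:
                raise ShapeError("heterogeneous channel counts")
            feats = compute_features(item.samples, predictors)  # (ch, P)
            blocks.append(feats.reshape(1, -1))
            labels.append(
                {
                    "subject": rec.subject,
                    "movement": rec.movement,
                    "repetition": rec.repetition,
                    "window": -1,
                }
            )
    columns = pd.MultiIndex.from_tuples(
        [(f"ch{c + 1}", p.name) for c in range(n_channels) for p in predictors],
        names=["channel", "predictor"],
    )
    return FeatureMatrix(
        values=np.vstack(blocks),
        rows=pd.DataFrame(labels, columns=list(_LABEL_COLS)),
        columns=columns,
    )
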