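"""Automated image quality control.

Twelve high-content-screening features computed on the DAPI channel:

- x1  inverse coefficient of variation: mean / SD of image intensity
- x2  focus score: variance / mean of image intensity
- x3  correlation of neighbouring pixels from the 8-level grey-level
      co-occurrence matrix (GLCM)
- x4  power log-log slope (PLLS) over the whole spatial-frequency range:
      gradient of log10 |FFT|^2 against log10 radial frequency
- x5..x12  PLLS within eight spatial-frequency bands (image scales)

Feature vectors feed a plain maximum-likelihood logistic regression
separating good from poor quality images, evaluated by leave-one-out
cross-validation (ROC/AUC).  Population (1/n) variance is used for
x1/x2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

FEATURE_NAMES = ["x1", "x2", "x3", "x4"] + [f"x{i}" for i in range(5, 13)]


class DegenerateImageError(ValueError):
    """The image lacks the variation a QC feature needs."""


# ---------------------------------------------------------------------------
# the four base features


def inverse_cv(channel: np.ndarray) -> float:
    """Mean intensity / population SD of intensity (x1).

    Invariant to positive rescaling of the intensities.
    """
    a = np.asarray(channel, dtype=float)
    sd = a.std()
    if sd == 0:
        raise DegenerateImageError("x1: constant image has zero SD")
    return float(a.mean() / sd)


def focus_score(channel: np.ndarray) -> float:
    """Population variance / mean of intensity (x2); 0 for a constant image."""
    a = np.asarray(channel, dtype=float)
    m = a.mean()
    if m == 0:
        raise DegenerateImageError("x2: zero-mean image")
    return float(a.var() / m)


def quantise_levels(channel: np.ndarray, levels: int = 8) -> np.ndarray:
    """Equal-width quantisation of intensities into ``levels`` grey levels."""
    a = np.asarray(channel, dtype=float)
    rng = np.ptp(a)
    if rng == 0:
        raise DegenerateImageError("GLCM: single grey level after quantisation")
    q = np.floor((a - a.min()) / rng * levels).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm_correlation(channel: np.ndarray, levels: int = 8) -> float:
    """Haralick correlation of the 8-level GLCM at 1-px offset (x3).

    Symmetric accumulation over the horizontal and vertical neighbour
    offsets, averaged; values lie in [-1, 1].
    """
    q = quantise_levels(channel, levels)
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=[0.0, np.pi / 2],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    corr = graycoprops(glcm, "correlation")[0]
    return float(corr.mean())


def _radial_power(channel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(radial frequency, squared FFT magnitude) of all non-DC coefficients."""
    a = np.asarray(channel, dtype=float)
    power = np.abs(np.fft.fft2(a)) ** 2
    fr = np.fft.fftfreq(a.shape[0])
    fc = np.fft.fftfreq(a.shape[1])
    freq = np.hypot(fr[:, None], fc[None, :])
    keep = freq > 0
    return freq[keep], power[keep]


def _slope(logf: np.ndarray, logp: np.ndarray) -> float:
    if np.unique(logf).size < 2:
        raise DegenerateImageError("PLLS: fewer than 2 distinct frequencies")
    return float(np.polyfit(logf, logp, 1)[0])


def plls(channel: np.ndarray, bands: int | None = None) -> float | np.ndarray:
    """Power log-log slope over the full frequency range, or per band.

    Orientation is ignored: every non-DC FFT coefficient contributes one
    point (log10 radial frequency, log10 squared magnitude) and a least
    squares line is fitted.  With ``bands=8`` the frequency axis is cut
    into eight equal-width bins in log10 frequency between the lowest
    non-DC radial frequency and the radial Nyquist, and a slope fitted
    per band (x5..x12); a band with fewer than 2 distinct frequencies
    yields NaN.
    """
    a = np.asarray(channel, dtype=float)
    if min(a.shape) < 16:
        raise ValueError("PLLS needs image side >= 16")
    freq, power = _radial_power(a)
    pos = power > 0
    if pos.sum() < 2 or np.unique(freq[pos]).size < 2:
        raise DegenerateImageError("PLLS: degenerate power spectrum")
    logf = np.log10(freq[pos])
    logp = np.log10(power[pos])
    if bands is None:
        return _slope(logf, logp)
    edges = np.linspace(np.log10(freq[freq > 0].min()), np.log10(freq.max()), bands + 1)
    out = np.full(bands, np.nan)
    for b in range(bands):
        lo, hi = edges[b], edges[b + 1]
        m = (logf >= lo) & (logf <= hi if b == bands - 1 else logf < hi)
        if m.sum() >= 2 and np.unique(logf[m]).size >= 2:
            out[b] = _slope(logf[m], logp[m])
    return out


def qc_features(channel: np.ndarray) -> pd.Series:
    """All twelve QC features (x1..x12) of one channel."""
    values = {}
    for name, fn in (
        ("x1", inverse_cv),
        ("x2", focus_score),
        ("x3", glcm_correlation),
    ):
        try:
            values[name] = fn(channel)
        except (DegenerateImageError, ValueError) as exc:
            raise DegenerateImageError(f"{name}: {exc}") from exc
    try:
        values["x4"] = plls(channel)
        band = plls(channel, bands=8)
    except (DegenerateImageError, ValueError) as exc:
        raise DegenerateImageError(f"x4-x12: {exc}") from exc
    for i, v in enumerate(band, start=5):
        values[f"x{i}"] = float(v)
    return pd.Series(values, index=FEATURE_NAMES)


def qc_feature_table(
    images: dict[str, np.ndarray] | pd.Series,
) -> pd.DataFrame:
    """QC feature vectors for a mapping of image_id -> DAPI channel."""
    rows = {iid: qc_features(ch) for iid, ch in dict(images).items()}
    df = pd.DataFrame(rows).T
    df.index.name = "image_id"
    return df


# ---------------------------------------------------------------------------
# classifier


def _subset_columns(feature_subset: str) -> list[str]:
    if feature_subset == "first4":
        return FEATURE_NAMES[:4]
    if feature_subset == "all12":
        return FEATURE_NAMES
    raise ValueError("feature_subset must be 'first4' or 'all12'")


def train_qc_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    feature_subset: str = "all12",
    ridge_c: float | None = None,
) -> Pipeline:
    """Logistic good/poor classifier on standardised QC features.

    ``labels`` are 'good'/'poor' (or 0/1 with 1 = poor).  Plain maximum
    likelihood by default; pass ``ridge_c`` for ridge regularisation on
    separable data.  Deterministic given the data.
    """
    cols = _subset_columns(feature_subset)
    y = _binary_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both quality classes")
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "logit",
                LogisticRegression(
                    C=np.inf if ridge_c is None else ridge_c,
                    solver="lbfgs",
                    max_iter=2000,
                ),
            ),
        ]
    )
    clf.fit(features[cols].to_numpy(), y)
    clf.feature_columns_ = cols
    return clf


def _binary_labels(labels: pd.Series) -> np.ndarray:
    mapping = {"good": 0, "poor": 1, 0: 0, 1: 1}
    try:
        return np.asarray([mapping[v] for v in labels])
    except KeyError as exc:
        raise ValueError(f"unknown quality label {exc.args[0]!r}") from exc


@dataclass
class LoocvResult:
    """Leave-one-out evaluation: held-out scores, ROC curve and AUC."""

    scores: pd.Series  # held-out P(poor) per image
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def evaluate_loocv(
    features: pd.DataFrame,
    labels: pd.Series,
    feature_subset: str = "all12",
    ridge_c: float | None = None,
) -> LoocvResult:
    """Leave-one-out ROC/AUC of the logistic QC classifier.

    Each image's P(poor) is predicted by a model trained on all other
    images; the ROC is a threshold sweep of those held-out scores and
    the AUC its trapezoid integral.
    """
    if len(features) < 10:
        raise ValueError("need at least 10 images for LOOCV")
    y = _binary_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("both quality classes required")
    cols = _subset_columns(feature_subset)
    X = features[cols]
    scores = np.empty(len(features))
    for i in range(len(features)):
        mask = np.ones(len(features), dtype=bool)
        mask[i] = False
        clf = train_qc_classifier(
            X.iloc[mask], pd.Series(y[mask]), feature_subset, ridge_c
        )
        scores[i] = clf.predict_proba(X.iloc[[i]].to_numpy())[0, 1]
    fpr, tpr, auc = roc_auc(y, scores)
    return LoocvResult(
        scores=pd.Series(scores, index=features.index, name="p_poor"),
        fpr=fpr,
        tpr=tpr,
        auc=auc,
    )


def roc_auc(y: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over the observed scores; AUC by trapezoid."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    pos = y == 1
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    tpr = np.array([(scores >= t)[pos].sum() / n_pos for t in thresholds])
    fpr = np.array([(scores >= t)[~pos].sum() / n_neg for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
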