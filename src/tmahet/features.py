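"""Per-cell compartment features and per-patient distribution encoding.

Each segmented cell yields compartment areas, per-channel total and
mean intensities and log2 nucleus/cytoplasm intensity ratios.  Cells
are stratified by CD99 status (positive: mean cytoplasmic CD99 strictly
above mean nuclear CD99) and a patient-level Ki67 index is the fraction
of CD99-positive cells that are Ki67-positive under log2-ratio
thresholds.  Every patient's cell-feature distribution is encoded as a
Gaussian kernel-density estimate evaluated at 100 equally spaced points
of a cohort-wide grid — the feature vectors consumed by the random
survival forest.  With several biomarkers, mean/total ratio variants
and three CD99 strata, the per-patient feature count is of order
10^3-10^4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

from tmahet.types import CellSegmentation, MultiChannelImage

#: pseudocount (intensity units) added to numerator and denominator of
#: log2 nucleus/cytoplasm ratios so zero compartments stay finite
RATIO_PSEUDOCOUNT = 1.0

STRATA = ("all", "cd99_pos", "cd99_neg")


# ---------------------------------------------------------------------------
# per-cell extraction


def extract_cell_features(
    image: MultiChannelImage,
    seg: CellSegmentation,
    *,
    dapi_channel: str = "DAPI",
    cd99_channel: str = "CD99",
) -> pd.DataFrame:
    """One row per segmented cell with compartment intensity features.

    Totals are sums over compartment pixels, means are totals/area.
    Areas are px^2, plus ``*_um2`` columns when the image carries a
    pixel size.  Ratio columns ``{channel}_log2_nc_mean`` /
    ``_log2_nc_total`` use the pseudocount rule; cells without
    cytoplasm get NaN ratios and ``cytoplasm_missing = True`` rather
    than fabricated values.  ``cd99_positive`` applies the strict
    cytoplasm-over-nucleus rule on CD99 means.
    """
    labels = seg.labels
    n = labels.size
    df = pd.DataFrame(
        {
            "cell_id": labels,
            "image_id": image.image_id,
            "patient_id": image.patient_id,
        }
    )
    nuc_area = (
        ndimage.sum_labels(np.ones(seg.nuclear_labels.shape), seg.nuclear_labels, labels)
        if n
        else np.array([])
    )
    cyt_area = np.zeros(n)
    present = (
        labels[np.isin(labels, np.unique(seg.cytoplasm_labels))] if n else np.array([])
    )
    if len(present):
        cyt_area[np.searchsorted(labels, present)] = ndimage.sum_labels(
            np.ones(seg.cytoplasm_labels.shape), seg.cytoplasm_labels, present
        )
    df["nuclear_area"] = nuc_area
    df["cytoplasm_area"] = cyt_area
    df["cytoplasm_missing"] = cyt_area == 0
    if image.pixel_size is not None:
        df["nuclear_area_um2"] = nuc_area * image.pixel_size**2
        df["cytoplasm_area_um2"] = cyt_area * image.pixel_size**2

    for name in image.channel_names:
        ch = image.channels[name]
        pre = name.lower()  # column prefix, channel-name case-insensitive
        nuc_tot = ndimage.sum_labels(ch, seg.nuclear_labels, labels) if n else np.array([])
        cyt_tot = np.zeros(n)
        if len(present):
            cyt_tot[np.searchsorted(labels, present)] = ndimage.sum_labels(
                ch, seg.cytoplasm_labels, present
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            nuc_mean = np.where(nuc_area > 0, nuc_tot / nuc_area, np.nan)
            cyt_mean = np.where(cyt_area > 0, cyt_tot / cyt_area, np.nan)
        df[f"{pre}_nuclear_total"] = nuc_tot
        df[f"{pre}_nuclear_mean"] = nuc_mean
        df[f"{pre}_cytoplasm_total"] = cyt_tot
        df[f"{pre}_cytoplasm_mean"] = cyt_mean
        df[f"{pre}_log2_nc_mean"] = log2_ratio(nuc_mean, cyt_mean)
        df[f"{pre}_log2_nc_total"] = log2_ratio(
            nuc_tot, np.where(cyt_area > 0, cyt_tot, np.nan)
        )

    cd99 = cd99_channel.lower()
    if f"{cd99}_nuclear_mean" in df:
        df["cd99_positive"] = cd99_status(
            df[f"{cd99}_nuclear_mean"], df[f"{cd99}_cytoplasm_mean"]
        )
    else:
        df["cd99_positive"] = False
    return df


def log2_ratio(nuclear, cytoplasm) -> np.ndarray:
    """log2((nuclear + eps) / (cytoplasm + eps)); NaN where cytoplasm missing."""
    nuc = np.asarray(nuclear, dtype=float)
    cyt = np.asarray(cytoplasm, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.log2((nuc + RATIO_PSEUDOCOUNT) / (cyt + RATIO_PSEUDOCOUNT))


def cd99_status(nuclear_mean, cytoplasm_mean) -> np.ndarray:
    """CD99-positive iff mean cytoplasmic CD99 strictly exceeds nuclear.

    Cells with missing cytoplasm are negative by convention (their
    ``cytoplasm_missing`` flag preserves the distinction).
    """
    nuc = np.asarray(nuclear_mean, dtype=float)
    cyt = np.asarray(cytoplasm_mean, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(cyt), False, cyt > nuc).astype(bool)


class UndefinedIndexError(ValueError):
    """Ki67 index undefined: the patient has no CD99-positive cells."""


def ki67_index(
    cells: pd.DataFrame,
    *,
    rule: str,
    cd99_threshold: float | None = None,
    ki67_threshold: float | None = None,
    cd99_col: str = "cd99_log2_nc_mean",
    ki67_col: str = "ki67_log2_nc_mean",
) -> float:
    """Proportion of CD99-positive cells that are Ki67-positive.

    ``rule='fixed'`` takes CD99 status from the strict
    cytoplasm-over-nucleus rule (``cd99_positive`` column);
    ``rule='centile'`` thresholds the CD99 log2 N/C ratio instead:
    positive cells lie *below* ``cd99_threshold`` (cytoplasm-dominant).
    Ki67-positive cells lie *above* ``ki67_threshold`` on the Ki67 log2
    N/C ratio (nucleus-dominant).  Thresholds are intensity-ratio values
    (typically centiles of the pooled distributions).  Raises
    :class:`UndefinedIndexError` on an empty denominator.
    """
    if rule == "fixed":
        denom = cells["cd99_positive"].to_numpy(dtype=bool)
    elif rule == "centile":
        if cd99_threshold is None:
            raise ValueError("centile rule needs cd99_threshold")
        denom = cells[cd99_col].to_numpy() < cd99_threshold
    else:
        raise ValueError("rule must be 'fixed' or 'centile'")
    if ki67_threshold is None:
        raise ValueError("ki67_threshold is required")
    if not denom.any():
        raise UndefinedIndexError("no CD99-positive cells")
    ki67_pos = cells[ki67_col].to_numpy() > ki67_threshold
    return float((denom & ki67_pos).sum() / denom.sum())


# ---------------------------------------------------------------------------
# patient distribution features


@dataclass
class PatientDistributionFeatures:
    """Per-patient 100-point kernel-density feature vectors.

    ``matrix``: rows = patients, columns = MultiIndex (feature, stratum,
    grid index 0..99); NaN rows mark strata with fewer than
    ``min_cells`` cells.  ``grids`` maps each feature to its fixed
    100-point evaluation grid (identical for every patient).
    """

    matrix: pd.DataFrame
    grids: dict[str, np.ndarray]
    min_cells: int = 5
    bandwidth_rule: str = "scott"

    @property
    def feature_names(self) -> list[str]:
        """Flat names like ``'Ki67_log2_nc_mean|cd99_neg|63'``."""
        return ["|".join(map(str, c)) for c in self.matrix.columns]

    def flat(self) -> pd.DataFrame:
        """Matrix with flat string column names (RSF input form)."""
        out = self.matrix.copy()
        out.columns = self.feature_names
        return out


def patient_distribution_features(
    cells: pd.DataFrame,
    feature_cols: list[str],
    *,
    strata: tuple[str, ...] = STRATA,
    n_grid: int = 100,
    min_cells: int = 5,
    grid_quantiles: tuple[float, float] = (0.005, 0.995),
) -> PatientDistributionFeatures:
    """Encode each patient's cell-feature distributions as KDE vectors.

    Cells from all of a patient's images are pooled.  For every feature
    a common grid of ``n_grid`` equally spaced points spans the pooled
    cross-patient [0.5th, 99.5th] percentile range (robust to
    outliers), fixed before any per-patient evaluation so vectors are
    comparable across patients.  Densities use a Gaussian kernel with
    Scott's-rule bandwidth on each patient's stratum sample; strata
    with fewer than ``min_cells`` cells yield all-NaN vectors.
    """
    if "patient_id" not in cells:
        raise ValueError("cell table must carry patient_id")
    grids: dict[str, np.ndarray] = {}
    for feat in feature_cols:
        vals = cells[feat].dropna().to_numpy()
        if vals.size == 0:
            raise ValueError(f"feature {feat!r} has no finite cells")
        lo, hi = np.quantile(vals, grid_quantiles)
        if lo == hi:  # degenerate pooled distribution: widen minimally
            lo, hi = lo - 0.5, hi + 0.5
        grids[feat] = np.linspace(lo, hi, n_grid)

    stratum_masks = {
        "all": np.ones(len(cells), dtype=bool),
        "cd99_pos": cells.get("cd99_positive", pd.Series(False, index=cells.index))
        .to_numpy(dtype=bool),
    }
    stratum_masks["cd99_neg"] = ~stratum_masks["cd99_pos"]

    patients = cells["patient_id"].unique()
    columns = pd.MultiIndex.from_product(
        [feature_cols, list(strata), range(n_grid)],
        names=["feature", "stratum", "grid_index"],
    )
    mat = np.full((patients.size, len(columns)), np.nan)
    pat_codes = cells["patient_id"].to_numpy()
    for pi, pid in enumerate(patients):
        pmask = pat_codes == pid
        col = 0
        for feat in feature_cols:
            vals_all = cells[feat].to_numpy()
            for stratum in strata:
                m = pmask & stratum_masks[stratum]
                v = vals_all[m]
                v = v[np.isfinite(v)]
                if v.size >= min_cells:
                    mat[pi, col : col + n_grid] = evaluate_kde(v, grids[feat])
                col += n_grid
    return PatientDistributionFeatures(
        matrix=pd.DataFrame(mat, index=pd.Index(patients, name="patient_id"), columns=columns),
        grids=grids,
        min_cells=min_cells,
    )


def evaluate_kde(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Scott's rule) evaluated on ``grid``.

    A zero-variance sample degenerates the covariance estimate; it is
    treated as a near-delta: a Gaussian of bandwidth one grid step.
    """
    values = np.asarray(values, dtype=float)
    scale = max(float(np.abs(values).max(initial=0.0)), 1.0)
    if values.std() > 1e-9 * scale:
        return gaussian_kde(values, bw_method="scott")(grid)
    h = max(grid[1] - grid[0], np.finfo(float).eps)
    z = (grid[:, None] - values[None, :]) / h
    return np.exp(-0.5 * z**2).mean(axis=1) / (h * np.sqrt(2 * np.pi))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    projections: pd.DataFrame
    explained_variance_ratio: np.ndarray
    components: np.ndarray
    dropped_constant: list[str] = field(default_factory=list)


def zscore_pca(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-wise z-scoring then PCA for 2-3 component visualisation.

    All-constant columns are dropped with a warning (their z-score is
    undefined); NaN cells are not allowed.
    """
    import warnings

    from sklearn.decomposition import PCA

    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 patients")
    if n_components > min(len(matrix), matrix.shape[1]):
        raise ValueError("more components requested than patients/features")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN; impute or drop first")
    sd = X.std(axis=0)
    constant = sd == 0
    dropped = [str(c) for c in matrix.columns[constant]]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature(s) before PCA")
    X = X[:, ~constant]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(Z)
    return PCAResult(
        projections=pd.DataFrame(
            proj,
            index=matrix.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
        dropped_constant=dropped,
    )
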