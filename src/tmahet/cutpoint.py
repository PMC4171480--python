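"""Conventional cut-point survival analysis and its multiplicity bias.

Dichotomising a continuous biomarker at the threshold that minimises a
survival p-value inflates type-I error: scanning a 99 x 99 centile grid
of CD99/Ki67 log2 N/C ratio thresholds performs thousands of implicit
tests, so the minimum p is strongly anti-conservative even when survival
is independent of the imaging features.  This module reproduces that
conventional analysis — the Cox p-value heat map over all centile
pairs, the log-rank scan over all dichotomised patient splits, and the
resulting Kaplan-Meier curves — deliberately without any multiple-
testing correction inside the grid (an optional permutation-adjusted
minimum p is provided for honest inference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmahet import survstats
from tmahet.survstats import CoxResult, cox_fit_single, kaplan_meier_curves


def cox_fit(covariate, time, event) -> CoxResult:
    """Single-covariate proportional-hazards fit (coefficient, Wald z, p).

    Efron tie handling; see :func:`tmahet.survstats.cox_fit_single`.
    """
    return cox_fit_single(covariate, time, event)


# ---------------------------------------------------------------------------
# centile threshold grid


@dataclass
class CutpointGrid:
    """Cox results over a CD99 x Ki67 centile threshold grid.

    ``table`` has one row per (centile_cd99, centile_ki67) pair with the
    thresholds on the ratio scale, the Cox coefficient, z and p (NaN
    where the pair was degenerate: undefined or constant Ki67 indices,
    too few events).  ``optimal`` is the valid pair minimising p.
    """

    table: pd.DataFrame
    cd99_centiles: np.ndarray
    ki67_centiles: np.ndarray

    @property
    def optimal(self) -> pd.Series:
        valid = self.table.dropna(subset=["p"])
        if valid.empty:
            raise ValueError("no valid grid cell")
        return valid.loc[valid["p"].idxmin()]

    @property
    def min_p(self) -> float:
        return float(self.optimal["p"])

    def pivot_log10_p(self) -> pd.DataFrame:
        """Heat-map form: rows CD99 centiles, columns Ki67 centiles, log10 p."""
        return self.table.assign(log10_p=np.log10(self.table["p"])).pivot(
            index="centile_cd99", columns="centile_ki67", values="log10_p"
        )


def ki67_index_matrix(
    cells: pd.DataFrame,
    cd99_thresholds: np.ndarray,
    ki67_thresholds: np.ndarray,
    *,
    cd99_col: str = "cd99_log2_nc_mean",
    ki67_col: str = "ki67_log2_nc_mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient Ki67 index for every (CD99, Ki67) threshold pair.

    Returns (patients, index) where ``index`` has shape
    (n_patients, n_cd99, n_ki67); NaN marks undefined indices (patient
    had no CD99-positive cells at that CD99 threshold).  CD99-positive
    cells lie below the CD99 ratio threshold (cytoplasm-dominant);
    Ki67-positive cells lie above the Ki67 ratio threshold.
    """
    sub = cells.dropna(subset=[cd99_col, ki67_col])
    patients, pat_code = np.unique(sub["patient_id"], return_inverse=True)
    cd99 = sub[cd99_col].to_numpy()
    ki67 = sub[ki67_col].to_numpy()
    n_p = patients.size
    n_k = len(ki67_thresholds)
    out = np.full((n_p, len(cd99_thresholds), n_k), np.nan)
    # ki67 bin of each cell: number of thresholds strictly below its ratio
    ki67_sorted = np.sort(ki67_thresholds)
    order = np.argsort(np.argsort(ki67_thresholds))  # map sorted -> input order
    for ci, cthr in enumerate(cd99_thresholds):
        m = cd99 < cthr
        if not m.any():
            continue
        denom = np.bincount(pat_code[m], minlength=n_p).astype(float)
        kbin = np.searchsorted(ki67_sorted, ki67[m], side="left")
        # hist[p, b] = CD99+ cells of patient p with ratio in threshold bin b
        hist = np.zeros((n_p, n_k + 1))
        np.add.at(hist, (pat_code[m], kbin), 1.0)
        # cells above sorted threshold j: suffix sum over bins > j
        above_sorted = hist[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(denom[:, None] > 0, above_sorted / denom[:, None], np.nan)
        out[:, ci, :] = idx[:, order]
    return patients, out


def threshold_grid_cox(
    cells: pd.DataFrame,
    survival: pd.DataFrame,
    *,
    cd99_centiles: np.ndarray | None = None,
    ki67_centiles: np.ndarray | None = None,
    cd99_col: str = "cd99_log2_nc_mean",
    ki67_col: str = "ki67_log2_nc_mean",
) -> CutpointGrid:
    """Exhaustive Cox scan over centile pairs of the pooled ratio scales.

    Thresholds are centiles of the *pooled* (all cells, all patients)
    log2 N/C ratio distributions; for every pair each patient's Ki67
    index is computed and a single-covariate Cox model fitted.  Patients
    with an undefined index at a pair are dropped from that fit.  The
    grid depends on the ratios only through ranks, so any monotone
    transform of the ratio scales leaves it unchanged.
    """
    if cd99_centiles is None:
        cd99_centiles = np.arange(1, 100)
    if ki67_centiles is None:
        ki67_centiles = np.arange(1, 100)
    cd99_centiles = np.asarray(cd99_centiles)
    ki67_centiles = np.asarray(ki67_centiles)

    cd99_thr = np.percentile(cells[cd99_col].dropna(), cd99_centiles)
    ki67_thr = np.percentile(cells[ki67_col].dropna(), ki67_centiles)
    patients, index = ki67_index_matrix(
        cells, cd99_thr, ki67_thr, cd99_col=cd99_col, ki67_col=ki67_col
    )
    surv = survival.set_index("patient_id").loc[patients]
    time = surv["time_days"].to_numpy()
    event = surv["event"].to_numpy()

    rows = []
    for ci, cc in enumerate(cd99_centiles):
        for ki, kc in enumerate(ki67_centiles):
            x = index[:, ci, ki]
            ok = np.isfinite(x)
            row = {
                "centile_cd99": int(cc),
                "centile_ki67": int(kc),
                "threshold_cd99": cd99_thr[ci],
                "threshold_ki67": ki67_thr[ki],
                "n_patients": int(ok.sum()),
                "coef": np.nan,
                "z": np.nan,
                "p": np.nan,
            }
            if ok.sum() >= 3 and event[ok].sum() >= 2 and np.ptp(x[ok]) > 0:
                fit = cox_fit_single(x[ok], time[ok], event[ok])
                row.update(coef=fit.coef, z=fit.z, p=fit.p)
            rows.append(row)
    return CutpointGrid(
        table=pd.DataFrame(rows),
        cd99_centiles=cd99_centiles,
        ki67_centiles=ki67_centiles,
    )


def permutation_adjusted_min_p(
    cells: pd.DataFrame,
    survival: pd.DataFrame,
    *,
    n_permutations: int = 200,
    seed: int = 0,
    **grid_kwargs,
) -> float:
    """Permutation-corrected minimum grid p (honest-inference option).

    Re-runs the grid with survival rows permuted across patients and
    returns the fraction of permutations whose minimum p is at most the
    observed minimum (add-one estimator).
    """
    rng = np.random.default_rng(seed)
    observed = threshold_grid_cox(cells, survival, **grid_kwargs).min_p
    hits = 0
    for _ in range(n_permutations):
        perm = survival.copy()
        perm[["time_days", "event"]] = (
            perm[["time_days", "event"]].sample(frac=1.0, random_state=rng.integers(2**31 - 1)).to_numpy()
        )
        if threshold_grid_cox(cells, perm, **grid_kwargs).min_p <= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# log-rank over all dichotomised splits


def logrank_all_splits(
    index: pd.Series | np.ndarray,
    survival: pd.DataFrame,
    *,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Log-rank over every dichotomised split of patients ordered by index.

    Patients are sorted by the per-patient index (e.g. the Ki67 index);
    each admissible split point (both groups at least
    ``min_group_size``) yields a two-group log-rank statistic and p.
    Returns one row per split with the index value at the cut.
    """
    if isinstance(index, pd.Series):
        surv = survival.set_index("patient_id").loc[index.index]
        values = index.to_numpy(dtype=float)
    else:
        values = np.asarray(index, dtype=float)
        surv = survival
    time = surv["time_days"].to_numpy()
    event = surv["event"].to_numpy()
    n = values.size
    if n < 2 * min_group_size:
        raise ValueError(
            f"need at least {2 * min_group_size} patients for min group size "
            f"{min_group_size}"
        )
    order = np.argsort(values, kind="stable")
    splits = np.arange(min_group_size, n - min_group_size + 1)
    membership = np.zeros((n, splits.size), dtype=bool)
    for j, k in enumerate(splits):
        membership[order[:k], j] = True  # low-index group
    chi2, p = survstats.logrank_statistics(time, event, membership)
    return pd.DataFrame(
        {
            "n_low": splits,
            "n_high": n - splits,
            "index_at_split": values[order][splits - 1],
            "chi2": chi2,
            "p": p,
        }
    )


def kaplan_meier(
    groups, survival: pd.DataFrame, conf: float = 0.95
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier curves with confidence intervals per patient group."""
    if isinstance(groups, pd.Series):
        surv = survival.set_index("patient_id").loc[groups.index]
        labels = groups.to_numpy()
    else:
        labels = np.asarray(groups)
        surv = survival
    return kaplan_meier_curves(
        surv["time_days"].to_numpy(), surv["event"].to_numpy(), labels, conf
    )
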