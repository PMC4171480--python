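"""Random survival forest with variable hunting, written on numpy.

Bagged survival trees are grown with the "log-rank random" splitting
rule: at each node a random subset of features is tested (``mtry``,
default one third of the candidates) and for each a small number of
random split points is drawn; the split maximising the two-group
log-rank statistic wins.  Terminal nodes carry Nelson-Aalen cumulative
hazard estimates over the training event-time grid; a subject's
predicted mortality is the ensemble cumulative hazard summed over that
grid, and out-of-bag (OOB) subjects — those not drawn into a tree's
bootstrap sample — give an internal estimate of the Harrell
concordance error (0 = perfect ranking, 0.5 = chance).

Feature selection follows the variable-hunting recipe: repeated random
80/20 partitions, a minimal-depth ranking of the candidate features on
the 80% part, forward introduction of features while the internal 20%
test error improves, and a selection-frequency ranking aggregated over
the iterations.  Randomised two-thirds/one-third cross-validation
checks that the internal error estimates are unbiased.

All randomness derives from one top-level seed through named
sub-streams, so identical seeds reproduce forests, OOB errors and
selection counts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmahet.survstats import _as_surv_arrays, logrank_statistics

# ---------------------------------------------------------------------------
# concordance


def harrell_concordance_error(predicted_mortality, time, event) -> float:
    """1 - Harrell's concordance index of a mortality-style prediction.

    A pair (i, j) is comparable iff ``t_i < t_j`` with subject i's event
    observed, or ``t_i == t_j`` with i's event observed and j censored.
    A comparable pair is concordant when the shorter-lived subject has
    the higher predicted mortality; prediction ties count 1/2.  Raises
    ``ValueError`` when no pair is comparable.
    """
    pred = np.asarray(predicted_mortality, dtype=float)
    t, e = _as_surv_arrays(time, event)
    if pred.shape != t.shape:
        raise ValueError("prediction and survival arrays must be matched")
    ti, tj = t[:, None], t[None, :]
    ei = (e == 1)[:, None]
    ej = (e == 1)[None, :]
    comparable = (ti < tj) & ei | (ti == tj) & ei & ~ej
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs under this censoring pattern")
    pi, pj = pred[:, None], pred[None, :]
    concordant = np.where(pi > pj, 1.0, np.where(pi == pj, 0.5, 0.0))
    c = float((concordant * comparable).sum() / n_comp)
    return 1.0 - c


# ---------------------------------------------------------------------------
# parameters and model containers


@dataclass(frozen=True)
class RSFParams:
    """Forest hyperparameters.

    ``mtry=None`` means ceil(p/3) candidate features per split;
    ``n_split_points`` random split values are drawn per candidate
    feature ("log-rank random" rule); a node must leave at least
    ``min_terminal_events`` observed events in each child.
    """

    n_trees: int = 1000
    mtry: int | None = None
    n_split_points: int = 10
    min_terminal_events: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolved_mtry(self, n_features: int) -> int:
        m = self.mtry if self.mtry is not None else int(np.ceil(n_features / 3))
        return max(1, min(m, n_features))


@dataclass
class _Tree:
    """One survival tree as parallel node arrays (feature < 0 marks a leaf)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_chf: list[np.ndarray | None]
    oob: np.ndarray  # indices of out-of-bag training subjects
    min_depth: dict[int, int]  # feature -> depth of its first split
    depth: int

    def predict_chf(self, X: np.ndarray) -> np.ndarray:
        """(n, G) cumulative hazard rows for the samples in X."""
        n = X.shape[0]
        leaf_of = np.empty(n, dtype=int)
        stack = [(0, np.arange(n))]
        while stack:
            nd, rows = stack.pop()
            if self.feature[nd] < 0:
                leaf_of[rows] = nd
                continue
            m = X[rows, self.feature[nd]] <= self.threshold[nd]
            stack.append((int(self.left[nd]), rows[m]))
            stack.append((int(self.right[nd]), rows[~m]))
        G = next(c.size for c in self.leaf_chf if c is not None)
        out = np.empty((n, G))
        for nd in np.unique(leaf_of):
            out[leaf_of == nd] = self.leaf_chf[nd]
        return out


@dataclass
class RSFModel:
    """Fitted forest: trees, training grid, OOB error and mortality."""

    trees: list[_Tree]
    feature_names: list[str]
    event_times: np.ndarray
    params: RSFParams
    oob_error: float
    oob_mortality: np.ndarray
    minimal_depth: pd.Series = field(repr=False, default=None)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# fitting


def _node_chf(t: np.ndarray, e: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Nelson-Aalen cumulative hazard of one node, on the global grid."""
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, starts)
    Y = t.size - starts
    ev = d > 0
    if not ev.any():
        return np.zeros(grid.size)
    ut = t[starts][ev]
    cum = np.cumsum(d[ev] / Y[ev])
    pos = np.searchsorted(ut, grid, side="right") - 1
    return np.where(pos >= 0, cum[np.maximum(pos, 0)], 0.0)


def _grow_tree(
    X: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    grid: np.ndarray,
    params: RSFParams,
    rng: np.random.Generator,
) -> _Tree:
    """Grow one bagged tree.  ``X``/``t``/``e`` must be time-sorted so
    node index arrays (kept in sorted order) index time-ordered samples,
    letting the split search share one pass of risk-table sums."""
    n, p = X.shape
    boot = np.sort(rng.integers(0, n, size=n))
    oob = np.setdiff1d(np.arange(n), boot)
    mtry = params.resolved_mtry(p)
    nsplit = params.n_split_points
    min_ev = params.min_terminal_events

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_chf: list[np.ndarray | None] = []
    min_depth: dict[int, int] = {}
    max_depth_seen = 0

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        leaf_chf.append(None)
        return len(feature) - 1

    stack = [(new_node(), boot, 0)]
    while stack:
        nd, idx, depth = stack.pop()
        max_depth_seen = max(max_depth_seen, depth)
        te, ee = t[idx], e[idx]
        n_node = idx.size
        tot_ev = ee.sum()
        # risk-table structure of this node (samples already time-sorted)
        starts = np.flatnonzero(np.r_[True, te[1:] != te[:-1]])
        d = np.add.reduceat(ee, starts)
        Y = n_node - starts
        split = None
        if tot_ev >= 2 * min_ev:
            cand = rng.permutation(p)[:mtry]
            Xn = X[idx][:, cand]
            pick = rng.integers(0, n_node, size=(nsplit, mtry))
            cuts = Xn[pick, np.arange(mtry)[None, :]]
            M = (Xn[:, None, :] <= cuts[None, :, :]).reshape(n_node, -1)
            left_ev = ee @ M
            valid = (left_ev >= min_ev) & (tot_ev - left_ev >= min_ev)
            if valid.any():
                Mv = M[:, valid].astype(float)
                cnt1 = np.add.reduceat(Mv, starts, axis=0)
                d1 = np.add.reduceat(ee[:, None] * Mv, starts, axis=0)
                Y1 = np.cumsum(cnt1[::-1], axis=0)[::-1]
                ev = d > 0
                frac = Y1[ev] / Y[ev, None]
                dm = d[ev, None]
                Ym = Y[ev, None]
                with np.errstate(invalid="ignore", divide="ignore"):
                    var = np.where(
                        Ym > 1, dm * frac * (1 - frac) * (Ym - dm) / (Ym - 1), 0.0
                    ).sum(axis=0)
                ome = (d1[ev] - dm * frac).sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    chi2 = np.where(var > 0, ome**2 / var, 0.0)
                best = int(np.argmax(chi2))
                if chi2[best] > 0:
                    k = np.flatnonzero(valid)[best]
                    f = int(cand[k % mtry])
                    c = float(cuts[k // mtry, k % mtry])
                    split = (f, c, M[:, k])
        if split is None:
            # Nelson-Aalen cumulative hazard on the global event grid
            ev = d > 0
            if ev.any():
                cum = np.cumsum(d[ev] / Y[ev])
                pos = np.searchsorted(te[starts][ev], grid, side="right") - 1
                leaf_chf[nd] = np.where(pos >= 0, cum[np.maximum(pos, 0)], 0.0)
            else:
                leaf_chf[nd] = np.zeros(grid.size)
            continue
        f, c, mask = split
        if f not in min_depth or depth < min_depth[f]:
            min_depth[f] = depth
        feature[nd] = f
        threshold[nd] = c
        ln, rn = new_node(), new_node()
        left[nd], right[nd] = ln, rn
        stack.append((ln, idx[mask], depth + 1))
        stack.append((rn, idx[~mask], depth + 1))

    return _Tree(
        feature=np.asarray(feature),
        threshold=np.asarray(threshold),
        left=np.asarray(left),
        right=np.asarray(right),
        leaf_chf=leaf_chf,
        oob=oob,
        min_depth=min_depth,
        depth=max_depth_seen,
    )


def _coerce_X(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def fit_rsf(
    X,
    time,
    event,
    params: RSFParams | None = None,
    *,
    min_subjects: int = 20,
) -> RSFModel:
    """Fit a random survival forest and estimate its OOB error.

    ``X`` is a patients x features matrix (DataFrame keeps names).
    Requires at least ``min_subjects`` subjects and 5 observed events.
    The OOB mortality of each subject averages the cumulative hazard
    over only the trees for which the subject was out of bag; with 1000
    trees every subject is OOB for some tree with overwhelming
    probability.
    """
    params = params or RSFParams()
    Xa, names = _coerce_X(X)
    t, e = _as_surv_arrays(time, event)
    n, p = Xa.shape
    if n < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects, got {n}")
    if e.sum() < 5:
        raise ValueError("need at least 5 observed events")
    if np.isnan(Xa).any():
        raise ValueError("feature matrix contains NaN")

    grid = np.unique(t[e == 1])
    order = np.argsort(t, kind="stable")  # trees need time-sorted samples
    Xs, ts, es = Xa[order], t[order], e[order]
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_trees)
    trees = [
        _grow_tree(Xs, ts, es, grid, params, np.random.default_rng(s)) for s in seeds
    ]

    chf_sum = np.zeros((n, grid.size))
    counts = np.zeros(n)
    for tree in trees:
        if tree.oob.size:
            chf_sum[tree.oob] += tree.predict_chf(Xs[tree.oob])
            counts[tree.oob] += 1
    covered = counts > 0
    oob_sorted = np.full(n, np.nan)
    oob_sorted[covered] = chf_sum[covered].sum(axis=1) / counts[covered]
    oob_error = harrell_concordance_error(
        oob_sorted[covered], ts[covered], es[covered]
    )
    oob_mort = np.full(n, np.nan)
    oob_mort[order] = oob_sorted

    penalty = max(tr.depth for tr in trees) + 1
    md = np.full((len(trees), p), float(penalty))
    for i, tr in enumerate(trees):
        for f, d in tr.min_depth.items():
            md[i, f] = d
    return RSFModel(
        trees=trees,
        feature_names=names,
        event_times=grid,
        params=params,
        oob_error=float(oob_error),
        oob_mortality=oob_mort,
        minimal_depth=pd.Series(md.mean(axis=0), index=names, name="minimal_depth"),
    )


# ---------------------------------------------------------------------------
# prediction


def predict(model: RSFModel, X) -> tuple[np.ndarray, pd.DataFrame]:
    """Ensemble mortality and survival curves for new patients.

    Returns ``(mortality, curves)``: mortality is the ensemble-averaged
    cumulative hazard summed over the training event times; curves is a
    DataFrame (rows = training event times, one column per patient) of
    ``S(t) = exp(-H(t))``, non-increasing from <= 1, supported only up
    to the last training event time.
    """
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"unknown/missing features: {missing[:5]}")
        Xa = X[model.feature_names].to_numpy(dtype=float)
        index = X.index
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.shape[1] != len(model.feature_names):
            raise ValueError("feature count mismatch with training data")
        index = pd.RangeIndex(Xa.shape[0])
    chf = np.zeros((Xa.shape[0], model.event_times.size))
    for tree in model.trees:
        chf += tree.predict_chf(Xa)
    chf /= len(model.trees)
    curves = pd.DataFrame(
        np.exp(-chf).T, index=pd.Index(model.event_times, name="time"), columns=index
    )
    return chf.sum(axis=1), curves


def mortality_vs_feature(
    model: RSFModel, X, feature: str, n_grid: int = 20
) -> pd.DataFrame:
    """Partial-dependence profile of predicted mortality on one feature.

    The feature column is swept over a quantile grid of its observed
    values while all other features keep their observed values; each
    grid point reports the mean predicted mortality.  A constant column
    yields a single-point (flat) profile.
    """
    if isinstance(X, pd.DataFrame):
        if feature not in X.columns:
            raise ValueError(f"unknown feature {feature!r}")
        Xa = X[model.feature_names].to_numpy(dtype=float)
        fidx = model.feature_names.index(feature)
    else:
        Xa = np.asarray(X, dtype=float)
        fidx = model.feature_names.index(feature)
    values = np.unique(np.quantile(Xa[:, fidx], np.linspace(0, 1, n_grid)))
    rows = []
    for v in values:
        Xm = Xa.copy()
        Xm[:, fidx] = v
        mort, _ = predict(model, pd.DataFrame(Xm, columns=model.feature_names))
        rows.append({"value": v, "mean_mortality": float(mort.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variable hunting


@dataclass
class VariableHuntingResult:
    """Selection counts over VH iterations plus per-iteration details."""

    counts: pd.Series
    ranking: list[str]
    iterations: list[dict]
    n_iter: int


def _forward_select(
    Xtr: np.ndarray,
    ttr: np.ndarray,
    etr: np.ndarray,
    Xte: np.ndarray,
    tte: np.ndarray,
    ete: np.ndarray,
    order: np.ndarray,
    params: RSFParams,
    rng: np.random.Generator,
    max_model_size: int,
) -> tuple[list[int], float]:
    """Introduce ranked features while the held-out error improves."""
    selected = [int(order[0])]
    best = _fit_eval(Xtr, ttr, etr, Xte, tte, ete, selected, params, rng)
    for f in order[1:max_model_size]:
        trial = selected + [int(f)]
        err = _fit_eval(Xtr, ttr, etr, Xte, tte, ete, trial, params, rng)
        if err < best:
            selected, best = trial, err
        else:
            break
    return selected, best


def _fit_eval(Xtr, ttr, etr, Xte, tte, ete, cols, params, rng) -> float:
    sub = RSFParams(
        n_trees=params.n_trees,
        mtry=None,
        n_split_points=params.n_split_points,
        min_terminal_events=params.min_terminal_events,
        seed=int(rng.integers(2**31 - 1)),
    )
    model = fit_rsf(Xtr[:, cols], ttr, etr, sub, min_subjects=2)
    mort, _ = predict(model, Xte[:, cols])
    return harrell_concordance_error(mort, tte, ete)


def variable_hunting(
    X,
    time,
    event,
    params: RSFParams | None = None,
    *,
    n_iter: int = 100,
    train_fraction: float = 0.8,
    max_model_size: int = 20,
    seed: int | None = None,
) -> VariableHuntingResult:
    """Variable-hunting feature selection by repeated 80/20 resampling.

    Each iteration draws a random train/test partition, ranks the
    candidate features by minimal-depth importance of a forest grown on
    the training part, then introduces features in rank order while the
    model's error on the held-out 20% keeps falling (the explicit
    stopping rule standing in for "until no significant features
    remain").  Selection counts aggregate over iterations; the final
    ranking is by descending count with ties broken by feature order.
    """
    params = params or RSFParams()
    Xa, names = _coerce_X(X)
    t, e = _as_surv_arrays(time, event)
    n = Xa.shape[0]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    counts = np.zeros(Xa.shape[1], dtype=int)
    iterations: list[dict] = []
    for it in range(n_iter):
        for _ in range(100):  # redraw until both parts support a fit
            perm = rng.permutation(n)
            n_tr = int(round(train_fraction * n))
            tr, te = perm[:n_tr], perm[n_tr:]
            if e[tr].sum() >= 5 and e[te].sum() >= 1 and te.size >= 2:
                break
        else:
            raise ValueError("could not draw a usable train/test partition")
        rank_params = RSFParams(
            n_trees=params.n_trees,
            mtry=params.mtry,
            n_split_points=params.n_split_points,
            min_terminal_events=params.min_terminal_events,
            seed=int(rng.integers(2**31 - 1)),
        )
        ranking_model = fit_rsf(
            Xa[tr], t[tr], e[tr], rank_params, min_subjects=2
        )
        order = np.argsort(ranking_model.minimal_depth.to_numpy(), kind="stable")
        selected, err = _forward_select(
            Xa[tr], t[tr], e[tr], Xa[te], t[te], e[te],
            order, params, rng, max_model_size,
        )
        counts[selected] += 1
        iterations.append(
            {
                "iteration": it,
                "selected": [names[f] for f in selected],
                "test_error": err,
            }
        )
    count_s = pd.Series(counts, index=names, name="selection_count")
    order = np.lexsort((np.arange(len(names)), -counts))
    return VariableHuntingResult(
        counts=count_s,
        ranking=[names[i] for i in order],
        iterations=iterations,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# randomised cross-validation


@dataclass
class CVResult:
    """Repeated random-partition cross-validation errors."""

    errors: np.ndarray
    mean: float
    sd: float
    repetitions: list[dict]


def cross_validate(
    X,
    time,
    event,
    params: RSFParams | None = None,
    *,
    n_rep: int = 50,
    train_fraction: float = 2 / 3,
    with_vh: bool = False,
    vh_iterations: int = 10,
    seed: int | None = None,
) -> CVResult:
    """Randomised two-thirds/one-third cross-validation of the forest.

    Each repetition fits on a random ``train_fraction`` of patients
    (optionally running variable hunting confined to that training set)
    and scores the Harrell concordance error on the held-out third.
    """
    params = params or RSFParams()
    Xa, names = _coerce_X(X)
    t, e = _as_surv_arrays(time, event)
    n = Xa.shape[0]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    errors = np.empty(n_rep)
    reps: list[dict] = []
    for r in range(n_rep):
        for _ in range(100):
            perm = rng.permutation(n)
            n_tr = int(round(train_fraction * n))
            tr, te = perm[:n_tr], perm[n_tr:]
            if e[tr].sum() >= 5 and e[te].sum() >= 1:
                break
        else:
            raise ValueError("could not draw a usable partition")
        cols = list(range(Xa.shape[1]))
        if with_vh:
            vh = variable_hunting(
                pd.DataFrame(Xa[tr], columns=names),
                t[tr],
                e[tr],
                params,
                n_iter=vh_iterations,
                seed=int(rng.integers(2**31 - 1)),
            )
            top = vh.counts[vh.counts > 0]
            if len(top):
                cols = [names.index(f) for f in vh.ranking if vh.counts[f] > 0]
        sub = RSFParams(
            n_trees=params.n_trees,
            mtry=params.mtry if not with_vh else None,
            n_split_points=params.n_split_points,
            min_terminal_events=params.min_terminal_events,
            seed=int(rng.integers(2**31 - 1)),
        )
        model = fit_rsf(Xa[tr][:, cols], t[tr], e[tr], sub, min_subjects=2)
        mort, _ = predict(model, Xa[te][:, cols])
        errors[r] = harrell_concordance_error(mort, t[te], e[te])
        reps.append(
            {"repetition": r, "n_features": len(cols), "test_error": float(errors[r])}
        )
    return CVResult(
        errors=errors,
        mean=float(errors.mean()),
        sd=float(errors.std(ddof=1)),
        repetitions=reps,
    )
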