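"""Connectome-based predictive modeling (CPM) of a behavioral score.

The protocol: correlate every FC edge with the behavior in the training
subjects; keep edges significant at p < alpha, split by correlation sign into
a positive and a negative network; sum each subject's FC over a network to
get a single network-strength value; fit an ordinary least-squares line of
behavior on strength; predict held-out subjects from their strength.  Model
quality is the Pearson correlation r between predicted and observed scores,
with significance from a permutation test that reruns the entire
cross-validated pipeline on shuffled scores.

Positive and negative networks are modeled and evaluated separately, never
combined.

The estimator :class:`CPMRegressor` exposes one (sign-specific) CPM as a
scikit-learn regressor; :func:`run_loocv`, :func:`run_kfold` and
:func:`permutation_test` implement the cross-validation protocols with a
vectorized leave-one-out path that is algebraically identical to refitting
the estimator per fold (the test suite verifies the equivalence).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io import FCMatrix, SubjectTable, vectorize_edges

logger = logging.getLogger(__name__)

__all__ = [
    "CohortEdgeTable",
    "EdgeSelection",
    "CPMModel",
    "CVResult",
    "PermutationResult",
    "PredictionScore",
    "CPMRegressor",
    "edge_behavior_correlations",
    "select_edges",
    "network_strength",
    "fit_strength_model",
    "predict_scores",
    "evaluate_prediction",
    "run_loocv",
    "run_kfold",
    "permutation_test",
]

SIGNS = ("positive", "negative")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class CohortEdgeTable:
    """Subjects x edges matrix with aligned behavioral scores and covariates."""

    edges: np.ndarray            # (N, P) Fisher-z edge values
    scores: np.ndarray           # (N,)
    subject_ids: list[str] = field(default_factory=list)
    covariates: np.ndarray | None = None  # (N, q)
    n_rois: int | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.edges.ndim != 2:
            raise ValueError("edges must be an N x P matrix")
        n = self.edges.shape[0]
        if self.scores.shape != (n,):
            raise ValueError("scores length must match number of subjects")
        if not self.subject_ids:
            self.subject_ids = [str(i) for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match number of subjects")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise ValueError("covariates rows must match number of subjects")
        for name, arr in (("edges", self.edges), ("scores", self.scores)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    @classmethod
    def from_matrices(
        cls,
        matrices: list[FCMatrix],
        table: SubjectTable,
        covariate_columns: tuple[str, ...] = (),
    ) -> "CohortEdgeTable":
        """Vectorize a cohort of FC matrices aligned to a subject table.

        Subjects present in both sources are kept, in subject-table order.
        ``sex`` is coded 0/1 (first level alphabetically = 0) if requested
        as a covariate.
        """
        by_id = {fc.subject_id: fc for fc in matrices}
        df = table.data[table.data["subject_id"].isin(by_id)].reset_index(drop=True)
        if df.empty:
            raise ValueError("no overlapping subject_ids between matrices and table")
        vecs = np.stack(
            [vectorize_edges(by_id[sid]).values for sid in df["subject_id"]]
        )
        cov = None
        if covariate_columns:
            cols = []
            for c in covariate_columns:
                col = df[c]
                if col.dtype == object:
                    levels = sorted(col.unique())
                    col = col.map({lev: k for k, lev in enumerate(levels)})
                cols.append(col.to_numpy(dtype=float))
            cov = np.column_stack(cols)
        return cls(
            edges=vecs,
            scores=df["rumination"].to_numpy(dtype=float),
            subject_ids=df["subject_id"].tolist(),
            covariates=cov,
            n_rois=matrices[0].n_rois,
        )


@dataclass
class EdgeSelection:
    """Per-edge correlation with the behavior and significance masks."""

    r: np.ndarray
    p: np.ndarray
    alpha: float | None = None
    pos_mask: np.ndarray | None = None
    neg_mask: np.ndarray | None = None


@dataclass
class CPMModel:
    """A fitted strength -> score line for one network sign."""

    intercept: float
    slope: float
    sign: str
    edge_mask: np.ndarray
    degenerate: bool = False


class PredictionScore(NamedTuple):
    """Predicted-vs-observed association: Pearson (or partial) r and p."""

    r: float
    p: float
    degenerate: bool = False


@dataclass
class CVResult:
    """Cross-validated predictions and the consensus network for one sign."""

    sign: str
    predicted: np.ndarray
    observed: np.ndarray
    r_pred: float
    p_pred: float
    consensus_mask: np.ndarray
    iteration_masks: np.ndarray | None = None  # (n_iter, P) bool
    mean_training_r: np.ndarray | None = None  # (P,) mean r across iterations
    per_repeat_r: np.ndarray | None = None     # k-fold only
    per_repeat_p: np.ndarray | None = None

    @property
    def n_consensus_edges(self) -> int:
        return int(self.consensus_mask.sum())


@dataclass
class PermutationResult:
    """Null distribution of predictive r from full pipeline reruns."""

    sign: str
    observed_r: float
    null_r: np.ndarray
    p_perm: float
    n_perm: int


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def _pearson_rows(edges: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r between each edge column and the score vector.

    Constant columns get r = 0.
    """
    xc = edges - edges.mean(axis=0)
    yc = scores - scores.mean()
    ss_x = np.einsum("ij,ij->j", xc, xc)
    ss_y = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.sqrt(ss_x * ss_y)
    r[ss_x <= 0.0] = 0.0
    return np.clip(r, -1.0, 1.0)


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p for Pearson r via t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    df = n - 2
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(r == 0.0, 1.0, p)


def _r_critical(alpha: float, df: int) -> float:
    """|r| threshold equivalent to two-tailed p < alpha at the given df."""
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(np.sqrt(tc**2 / (tc**2 + df)))


def edge_behavior_correlations(tbl: CohortEdgeTable) -> EdgeSelection:
    """Correlate every edge with the behavioral score across subjects.

    Returns per-edge Pearson r and two-tailed p (t transform, N-2 df);
    constant edges get r = 0, p = 1.
    """
    n = tbl.n_subjects
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    if np.var(tbl.scores) == 0.0:
        raise ValueError("behavioral scores have zero variance")
    r = _pearson_rows(tbl.edges, tbl.scores)
    return EdgeSelection(r=r, p=_r_to_p(r, n))


def select_edges(sel: EdgeSelection, alpha: float = 0.01) -> EdgeSelection:
    """Split significant edges (strict p < alpha) into positive and negative masks."""
    sig = sel.p < alpha
    return EdgeSelection(
        r=sel.r,
        p=sel.p,
        alpha=alpha,
        pos_mask=sig & (sel.r > 0),
        neg_mask=sig & (sel.r < 0),
    )


def network_strength(tbl: CohortEdgeTable | np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-subject sum of edge values over a network mask.

    An empty mask yields all-zero strengths (a degenerate network) with a
    logged warning rather than an error, so null-data pipelines complete.
    """
    edges = tbl.edges if isinstance(tbl, CohortEdgeTable) else np.asarray(tbl, float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (edges.shape[1],):
        raise ValueError("mask length must equal the number of edges")
    if not mask.any():
        logger.warning("empty edge mask: network strengths are all zero")
        return np.zeros(edges.shape[0])
    return edges[:, mask].sum(axis=1)


def fit_strength_model(
    strengths: np.ndarray,
    scores: np.ndarray,
    sign: str = "positive",
    edge_mask: np.ndarray | None = None,
) -> CPMModel:
    """OLS of scores on (1, strength).

    Zero-variance strengths give slope 0 and intercept mean(scores), flagged
    degenerate (the training-mean predictor).
    """
    strengths = np.asarray(strengths, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if strengths.shape != scores.shape:
        raise ValueError("strengths and scores must have equal length")
    if strengths.size < 3:
        raise ValueError("need at least 3 observations to fit")
    if edge_mask is None:
        edge_mask = np.zeros(0, dtype=bool)
    sc = strengths - strengths.mean()
    var = float(sc @ sc)
    if var <= 0.0:
        return CPMModel(
            intercept=float(scores.mean()), slope=0.0, sign=sign,
            edge_mask=edge_mask, degenerate=True,
        )
    slope = float(sc @ (scores - scores.mean())) / var
    intercept = float(scores.mean() - slope * strengths.mean())
    return CPMModel(intercept=intercept, slope=slope, sign=sign, edge_mask=edge_mask)


def predict_scores(model: CPMModel, strengths: np.ndarray) -> np.ndarray:
    """Apply a fitted strength model elementwise."""
    return model.intercept + model.slope * np.asarray(strengths, dtype=float)


def evaluate_prediction(
    pred: np.ndarray,
    obs: np.ndarray,
    covariates: np.ndarray | None = None,
) -> PredictionScore:
    """Pearson r (and two-tailed p) between predicted and observed scores.

    With covariates, a partial correlation: both vectors are residualized on
    the covariates (OLS with intercept) and the residuals correlated, with
    N - 2 - q degrees of freedom.  A constant vector (or all-zero residuals)
    yields r = 0, p = 1, flagged degenerate.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    n = pred.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    q = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates rows must match prediction length")
        q = cov.shape[1]
        design = np.column_stack([np.ones(n), cov])
        stacked = np.column_stack([pred, obs])
        orig_ss = ((stacked - stacked.mean(axis=0)) ** 2).sum(axis=0)
        coef, *_ = np.linalg.lstsq(design, stacked, rcond=None)
        resid = stacked - design @ coef
        # residuals that are numerically zero relative to the original
        # variation mean the covariates explain everything: no information
        resid_ss = (resid**2).sum(axis=0)
        resid[:, resid_ss <= 1e-12 * np.maximum(orig_ss, 1e-300)] = 0.0
        pred, obs = resid[:, 0], resid[:, 1]
    pc = pred - pred.mean()
    oc = obs - obs.mean()
    denom = float(pc @ pc) * float(oc @ oc)
    if denom <= 0.0:
        return PredictionScore(r=0.0, p=1.0, degenerate=True)
    r = float(np.clip((pc @ oc) / np.sqrt(denom), -1.0, 1.0))
    df = n - 2 - q
    if abs(r) >= 1.0:
        return PredictionScore(r=r, p=0.0)
    t = r * np.sqrt(df / (1.0 - r**2))
    return PredictionScore(r=r, p=float(2.0 * stats.t.sf(abs(t), df)))


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class CPMRegressor(RegressorMixin, BaseEstimator):
    """One sign-specific CPM as a scikit-learn regressor.

    ``fit(X, y)`` screens the columns of X (edge values) against y, keeps
    edges with the requested correlation sign at p < ``alpha``, and fits an
    OLS line of y on the summed strength over those edges.  ``predict(X)``
    sums the same edges and applies the line.  Composes with sklearn
    model-selection utilities (``cross_val_predict``, ``GridSearchCV`` ...).

    Parameters
    ----------
    alpha : float, default 0.01
        Two-tailed edge-selection threshold (strict p < alpha).
    sign : {"positive", "negative"}, default "negative"
        Which correlation sign forms the prediction network.

    Attributes
    ----------
    r_, p_ : ndarray of shape (P,)
        Training edge-behavior correlations and two-tailed p values.
    edge_mask_ : ndarray of bool, shape (P,)
        Selected edges.
    intercept_, slope_ : float
        Fitted strength -> score line.
    degenerate_ : bool
        True when no edge was selected or strength had zero variance; the
        model then predicts the training mean.
    """

    def __init__(self, alpha: float = 0.01, sign: str = "negative"):
        self.alpha = alpha
        self.sign = sign

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}")
        if X.shape[0] < 4:
            raise ValueError("need at least 4 training subjects")
        tbl = CohortEdgeTable(edges=X, scores=y)
        sel = select_edges(edge_behavior_correlations(tbl), alpha=self.alpha)
        mask = sel.pos_mask if self.sign == "positive" else sel.neg_mask
        strengths = network_strength(tbl, mask)
        model = fit_strength_model(strengths, y, sign=self.sign, edge_mask=mask)
        self.n_features_in_ = X.shape[1]
        self.r_, self.p_ = sel.r, sel.p
        self.edge_mask_ = mask
        self.intercept_, self.slope_ = model.intercept, model.slope
        self.degenerate_ = model.degenerate or not mask.any()
        return self

    def predict(self, X):
        check_is_fitted(self, "edge_mask_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of edges than at fit time")
        strengths = X[:, self.edge_mask_].sum(axis=1)
        return self.intercept_ + self.slope_ * strengths


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------

def _loocv_core(
    edges: np.ndarray,
    scores: np.ndarray,
    alpha: float,
    want_masks: bool,
) -> dict[str, dict]:
    """All N leave-one-out iterations at once.

    Leave-one-out training sums are whole-sample sums minus the held-out
    row, so per-iteration edge correlations, selection masks, strengths and
    OLS fits are computed as dense array expressions; the per-iteration
    strength vectors come from a single edges @ masks.T product per sign.
    Algebraically identical to refitting :class:`CPMRegressor` on each
    training fold.
    """
    n_sub, _ = edges.shape
    n = n_sub - 1  # training size
    r_crit = _r_critical(alpha, n - 2)

    sx = edges.sum(axis=0)[None, :] - edges
    sxx = np.einsum("ij,ij->j", edges, edges)[None, :] - edges**2
    sxy = (edges.T @ scores)[None, :] - edges * scores[:, None]
    sy = (scores.sum() - scores)[:, None]
    syy = (float(scores @ scores) - scores**2)[:, None]

    cov = sxy - sx * sy / n
    var_x = sxx - sx**2 / n
    var_y = syy - sy**2 / n
    denom = var_x * var_y
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(denom)
    r[denom <= 0.0] = 0.0
    np.clip(r, -1.0, 1.0, out=r)

    out: dict[str, dict] = {}
    for sign in SIGNS:
        masks = (r > r_crit) if sign == "positive" else (r < -r_crit)
        strength = edges @ masks.T.astype(float)   # (N, N): [j, i] = subj j, iter i
        held = np.diagonal(strength)
        a_sum = strength.sum(axis=0) - held
        b_sum = np.einsum("ij,ij->j", strength, strength) - held**2
        c_sum = scores @ strength - held * scores
        y_sum = scores.sum() - scores
        var_s = b_sum - a_sum**2 / n
        cov_sy = c_sum - a_sum * y_sum / n
        # relative guard: centered sums of squares lose precision when the
        # strengths are (near-)constant across training subjects
        ok = var_s > np.maximum(b_sum, 1.0) * 1e-12
        slope = np.where(ok, cov_sy / np.where(ok, var_s, 1.0), 0.0)
        intercept = y_sum / n - slope * a_sum / n
        predicted = intercept + slope * held
        entry: dict = {
            "predicted": predicted,
            "consensus_mask": masks.all(axis=0),
            "n_degenerate": int((~ok).sum()),
        }
        if want_masks:
            entry["iteration_masks"] = masks
            entry["mean_training_r"] = r.mean(axis=0)
        out[sign] = entry
    return out


def run_loocv(tbl: CohortEdgeTable, alpha: float = 0.01) -> dict[str, CVResult]:
    """Leave-one-out CPM: one model per held-out subject.

    Each iteration reruns edge selection and the strength GLM on the N-1
    training subjects and predicts the held-out one.  The consensus network
    is the intersection of the N per-iteration masks — the final prediction
    network.  Returns one :class:`CVResult` per network sign; ``r_pred`` /
    ``p_pred`` use the cohort covariates (partial correlation) when present.
    """
    if tbl.n_subjects < 10:
        raise ValueError(f"LOOCV requires at least 10 subjects, got {tbl.n_subjects}")
    core = _loocv_core(tbl.edges, tbl.scores, alpha, want_masks=True)
    results = {}
    for sign, entry in core.items():
        score = evaluate_prediction(entry["predicted"], tbl.scores, tbl.covariates)
        if entry["n_degenerate"]:
            logger.warning(
                "%s network: %d/%d LOOCV folds had a degenerate (empty/constant) "
                "strength model; those folds predict the training mean",
                sign, entry["n_degenerate"], tbl.n_subjects,
            )
        results[sign] = CVResult(
            sign=sign,
            predicted=entry["predicted"],
            observed=tbl.scores.copy(),
            r_pred=score.r,
            p_pred=score.p,
            consensus_mask=entry["consensus_mask"],
            iteration_masks=entry["iteration_masks"],
            mean_training_r=entry["mean_training_r"],
        )
    return results


def _kfold_once(
    edges: np.ndarray,
    scores: np.ndarray,
    k: int,
    alpha: float,
    rng: np.random.Generator,
    collect_masks: bool = False,
):
    """One random k-fold pass; returns predictions (+ per-fold masks)."""
    n_sub = edges.shape[0]
    order = rng.permutation(n_sub)
    folds = np.array_split(order, k)
    predicted = {sign: np.empty(n_sub) for sign in SIGNS}
    fold_masks = {sign: [] for sign in SIGNS} if collect_masks else None
    mean_r = np.zeros(edges.shape[1]) if collect_masks else None
    for fold in folds:
        train = np.setdiff1d(np.arange(n_sub), fold, assume_unique=False)
        r = _pearson_rows(edges[train], scores[train])
        r_crit = _r_critical(alpha, train.size - 2)
        for sign in SIGNS:
            mask = (r > r_crit) if sign == "positive" else (r < -r_crit)
            if mask.any():
                s_train = edges[np.ix_(train, np.flatnonzero(mask))].sum(axis=1)
                s_test = edges[np.ix_(fold, np.flatnonzero(mask))].sum(axis=1)
            else:
                s_train = np.zeros(train.size)
                s_test = np.zeros(fold.size)
            model = fit_strength_model(s_train, scores[train], sign=sign,
                                       edge_mask=mask)
            predicted[sign][fold] = predict_scores(model, s_test)
            if collect_masks:
                fold_masks[sign].append(mask)
        if collect_masks:
            mean_r += r / k
    return predicted, fold_masks, mean_r


def run_kfold(
    tbl: CohortEdgeTable,
    k: int = 10,
    repeats: int = 100,
    alpha: float = 0.01,
    seed: int | None = None,
    r_average: Literal["arithmetic", "fisher"] = "arithmetic",
) -> dict[str, CVResult]:
    """Repeated k-fold CPM with averaged predictive r and p.

    Subjects are randomly partitioned into k near-equal folds; each fold is
    predicted from a model trained on the other k-1.  The whole process is
    repeated ``repeats`` times with fresh random partitions (a child seed per
    repeat) and the per-repeat r and p are averaged arithmetically — the
    averaged p is descriptive only; inference comes from
    :func:`permutation_test`.  The consensus mask intersects every fold of
    every repeat.  ``predicted`` holds the per-subject mean across repeats.
    """
    n_sub = tbl.n_subjects
    if k > n_sub:
        raise ValueError(f"k={k} exceeds the {n_sub} subjects")
    if k < 2:
        raise ValueError("k must be at least 2")
    seq = np.random.SeedSequence(seed)
    child_seeds = seq.spawn(repeats)
    per_r = {sign: np.empty(repeats) for sign in SIGNS}
    per_p = {sign: np.empty(repeats) for sign in SIGNS}
    pred_sum = {sign: np.zeros(n_sub) for sign in SIGNS}
    consensus = {sign: np.ones(tbl.n_edges, dtype=bool) for sign in SIGNS}
    all_masks = {sign: [] for sign in SIGNS}
    mean_r_acc = {sign: np.zeros(tbl.n_edges) for sign in SIGNS}
    for rep in range(repeats):
        rng = np.random.default_rng(child_seeds[rep])
        predicted, fold_masks, mean_r = _kfold_once(
            tbl.edges, tbl.scores, k, alpha, rng, collect_masks=True
        )
        for sign in SIGNS:
            score = evaluate_prediction(predicted[sign], tbl.scores, tbl.covariates)
            per_r[sign][rep] = score.r
            per_p[sign][rep] = score.p
            pred_sum[sign] += predicted[sign]
            for mask in fold_masks[sign]:
                consensus[sign] &= mask
            all_masks[sign].append(np.stack(fold_masks[sign]))
            mean_r_acc[sign] += mean_r / repeats
    results = {}
    for sign in SIGNS:
        if r_average == "fisher":
            z = np.arctanh(np.clip(per_r[sign], -1 + 1e-15, 1 - 1e-15))
            r_mean = float(np.tanh(z.mean()))
        else:
            r_mean = float(per_r[sign].mean())
        results[sign] = CVResult(
            sign=sign,
            predicted=pred_sum[sign] / repeats,
            observed=tbl.scores.copy(),
            r_pred=r_mean,
            p_pred=float(per_p[sign].mean()),
            consensus_mask=consensus[sign],
            iteration_masks=np.concatenate(all_masks[sign], axis=0),
            mean_training_r=mean_r_acc[sign],
            per_repeat_r=per_r[sign],
            per_repeat_p=per_p[sign],
        )
    return results


def permutation_test(
    tbl: CohortEdgeTable,
    cv: Literal["loocv", "kfold"] = "loocv",
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.01,
    k: int = 10,
    repeats: int = 100,
    mode: Literal["full", "shuffle_only"] = "full",
    counting: Literal["plugin", "add_one"] = "plugin",
) -> dict[str, PermutationResult]:
    """Permutation significance of the cross-validated predictive r.

    For each permutation the behavioral scores are shuffled and, in the
    default ``full`` mode, the entire pipeline — edge selection, strength
    GLM, cross-validated prediction, evaluation — is rerun to yield one null
    r per network sign.  ``p_perm`` is the fraction of null r values strictly
    greater than the observed r (``counting="plugin"``); the
    ``(count+1)/(n_perm+1)`` variant is available but not the default.

    ``mode="shuffle_only"`` re-correlates the fixed observed predictions
    against shuffled scores — cheap, exploratory, never the reported p.
    The observed k-fold statistic uses ``repeats`` partitions, but each
    permutation uses a single repeat for tractability.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if tbl.n_subjects < 10:
        raise ValueError("permutation test requires at least 10 subjects")
    rng = np.random.default_rng(seed)

    if cv == "loocv":
        observed = run_loocv(tbl, alpha=alpha)
    else:
        observed = run_kfold(tbl, k=k, repeats=repeats, alpha=alpha,
                             seed=int(rng.integers(2**31 - 1)))

    null_r = {sign: np.empty(n_perm) for sign in SIGNS}
    for b in range(n_perm):
        perm_scores = rng.permutation(tbl.scores)
        if mode == "shuffle_only":
            for sign in SIGNS:
                null_r[sign][b] = evaluate_prediction(
                    observed[sign].predicted, perm_scores, tbl.covariates
                ).r
            continue
        if cv == "loocv":
            core = _loocv_core(tbl.edges, perm_scores, alpha, want_masks=False)
            preds = {sign: core[sign]["predicted"] for sign in SIGNS}
        else:
            preds, _, _ = _kfold_once(
                tbl.edges, perm_scores, k, alpha,
                np.random.default_rng(rng.integers(2**31 - 1)),
            )
        for sign in SIGNS:
            null_r[sign][b] = evaluate_prediction(
                preds[sign], perm_scores, tbl.covariates
            ).r

    results = {}
    for sign in SIGNS:
        obs_r = observed[sign].r_pred
        count = int((null_r[sign] > obs_r).sum())
        if counting == "add_one":
            p_perm = (count + 1) / (n_perm + 1)
        else:
            p_perm = count / n_perm
        results[sign] = PermutationResult(
            sign=sign,
            observed_r=obs_r,
            null_r=null_r[sign],
            p_perm=float(p_perm),
            n_perm=n_perm,
        )
    return results
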