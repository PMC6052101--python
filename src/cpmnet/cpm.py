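"""The CPM estimator: edge selection, network strengths, and cross-validated
trait prediction.

Connectome-based predictive modeling (CPM) predicts a behavioral trait from
a subject's functional connectome in three steps, repeated inside a
cross-validation loop so that every subject is predicted from models that
never saw their data:

1. **Edge selection.** In the training subjects, every edge's strength is
   correlated with the trait (Pearson, or partial correlation given
   covariates). Edges surviving a threshold — by correlation p-value or by
   sparsity (top fraction of edges) — with positive correlation form the
   correlated network (CN); those with negative correlation form the
   anti-correlated network (AN).
2. **Network strength.** For each subject, CN strength is the sum of that
   subject's Fisher-z values over CN edges (each undirected edge counted
   once); AN strength likewise; combined strength = CN - AN.
3. **Model fit and prediction.** A first-degree polynomial (ordinary least
   squares, optionally with additional binary covariates) maps training
   strength to trait; the held-out subject's strength is plugged in.

Performance is the Spearman correlation ``r_s`` between predicted and
observed trait across all held-out predictions, also expressed as percent
variance explained ``100 * r_s**2``, clamped to 0 when ``r_s < 0`` (a model
that anti-predicts explains nothing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .edges import n_edges, vec_to_sym
from .io import ConnectivityStack

NETWORKS = ("cn", "an", "combined")


@dataclass(frozen=True)
class ThresholdSpec:
    """Edge-selection rule: ``method`` is ``"p"`` (correlation p-value below
    ``level``) or ``"sparsity"`` (top ``level`` fraction of edges by r)."""

    method: str
    level: float

    def __post_init__(self) -> None:
        if self.method not in ("p", "sparsity"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if not 0 < self.level < 1:
            raise ValueError(f"threshold level must lie in (0, 1), got {self.level}")

    @classmethod
    def parse(cls, text: str) -> "ThresholdSpec":
        """Parse ``"p:0.01"`` or ``"sparsity:0.05"``."""
        try:
            method, level = text.split(":")
            return cls(method.strip(), float(level))
        except ValueError as exc:
            raise ValueError(f"cannot parse threshold spec {text!r}") from exc

    def __str__(self) -> str:
        return f"{self.method}:{self.level:g}"


@dataclass
class EdgeMaskPair:
    """Binary CN (positive) and AN (negative) edge sets over the strict
    upper triangle of an ``n_nodes`` connectome."""

    pos: np.ndarray  # bool (n_edges,)
    neg: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, bool)
        self.neg = np.asarray(self.neg, bool)
        e = n_edges(self.n_nodes)
        if self.pos.shape != (e,) or self.neg.shape != (e,):
            raise ValueError(f"masks must have length {e} for {self.n_nodes} nodes")
        if (self.pos & self.neg).any():
            raise ValueError("CN and AN masks overlap")

    def pos_square(self) -> np.ndarray:
        return vec_to_sym(self.pos.astype(int), self.n_nodes)

    def neg_square(self) -> np.ndarray:
        return vec_to_sym(self.neg.astype(int), self.n_nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeMaskPair):
            return NotImplemented
        return (
            self.n_nodes == other.n_nodes
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.neg, other.neg)
        )


@dataclass
class NetworkStrengths:
    """Per-subject summed edge strengths; ``combined = cn - an`` exactly."""

    cn: np.ndarray
    an: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.cn - self.an

    def by_network(self, network: str) -> np.ndarray:
        if network not in NETWORKS:
            raise KeyError(network)
        return getattr(self, network) if network != "combined" else self.combined


@dataclass
class NetworkScore:
    """Spearman performance of one network's predictions."""

    r_s: float
    r_s_squared: float  # percent, clamped to 0 for negative r_s
    flagged: bool = False  # constant predictions: correlation undefined


@dataclass
class CPMModel:
    """Fitted strength-to-trait polynomials for CN / AN / combined."""

    mask_pair: EdgeMaskPair
    coef: dict[str, np.ndarray]  # network -> [intercept, slope, *covariates]
    threshold_spec: ThresholdSpec

    def predict(
        self, network: str, strength: np.ndarray, covariates: np.ndarray | None = None
    ) -> np.ndarray:
        c = self.coef[network]
        out = c[0] + c[1] * np.asarray(strength, float)
        if len(c) > 2:
            if covariates is None:
                raise ValueError("model was fit with covariates; none supplied")
            out = out + np.atleast_2d(covariates.T).T @ c[2:]
        return out


@dataclass
class PredictionResult:
    """Held-out predictions and Spearman performance per network."""

    observed: np.ndarray
    predicted: dict[str, np.ndarray]
    scores: dict[str, NetworkScore]
    fold_masks: list[EdgeMaskPair] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Edge selection
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of y (columns) on a design matrix including intercept."""
    q, _ = np.linalg.qr(design)
    return y - q @ (q.T @ y)


def edge_trait_association(
    edge_matrix: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge Pearson (or partial) correlation with the trait and
    two-sided p-values.

    Parameters
    ----------
    edge_matrix
        Subjects x edges strengths (a ``ConnectivityStack.edge_matrix()``).
    trait
        Trait value per subject; must be non-constant.
    covariates
        Optional subjects x k matrix. When given, both each edge and the
        trait are residualized on the covariates (plus intercept) and the
        correlation of the residuals is returned, with ``k`` degrees of
        freedom removed.

    Returns
    -------
    r, p
        Correlation and two-sided p per edge, from the t transform
        ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - k``. Constant
        edges get ``r = 0, p = 1`` with a warning.
    """
    x = np.asarray(edge_matrix, float)
    y = np.asarray(trait, float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects for edge-trait association")
    if y.shape != (n,):
        raise ValueError("trait length does not match subject count")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant; correlations undefined")

    n_cov = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariates do not match subject count")
        n_cov = cov.shape[1]
        design = np.column_stack([np.ones(n), cov])
        x = _residualize(x, design)
        y = _residualize(y[:, None], design)[:, 0]

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    # relative tolerance: residualizing on a collinear covariate leaves only
    # floating-point noise, which must not masquerade as variance
    x_scale = np.sqrt((np.asarray(edge_matrix, float) ** 2).sum(axis=0)) + 1e-300
    y_scale = np.sqrt((np.asarray(trait, float) ** 2).sum()) + 1e-300
    flat = sx <= 1e-9 * x_scale
    if sy <= 1e-9 * y_scale:
        warnings.warn("trait residual is (near-)zero after covariate removal")
        return np.zeros(x.shape[1]), np.ones(x.shape[1])
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant edge(s): r set to 0, p to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r[flat] = 0.0
    r = np.clip(r, -1.0, 1.0)

    df = n - 2 - n_cov
    if df <= 0:
        raise ValueError("not enough subjects for the covariate count")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isnan(p)] = 0.0  # |r| == 1 -> infinite t
    p[flat] = 1.0
    return r, p


def select_edges(r: np.ndarray, p: np.ndarray, spec: ThresholdSpec) -> EdgeMaskPair:
    """Threshold edgewise correlations into a CN/AN mask pair.

    P-value mode: CN = {r > 0, p < level}, AN = {r < 0, p < level}.
    Sparsity mode: CN = the top ``round(level * n_edges)`` edges by r
    descending, AN = the same count by r ascending, ties broken by
    ascending edge index.
    """
    r = np.asarray(r, float)
    p = np.asarray(p, float)
    if r.shape != p.shape:
        raise ValueError("r and p must have the same length")
    e = r.shape[0]
    n_nodes = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(n_nodes) != e:
        raise ValueError(f"{e} is not a valid edge-universe size")
    if spec.method == "p":
        pos = (r > 0) & (p < spec.level)
        neg = (r < 0) & (p < spec.level)
    else:
        k = int(round(spec.level * e))
        if 2 * k > e:
            raise ValueError("sparsity level too high: CN and AN would overlap")
        order_desc = np.lexsort((np.arange(e), -r))
        order_asc = np.lexsort((np.arange(e), r))
        pos = np.zeros(e, bool)
        neg = np.zeros(e, bool)
        pos[order_desc[:k]] = True
        neg[order_asc[:k]] = True
    return EdgeMaskPair(pos, neg, n_nodes)


# ---------------------------------------------------------------------------
# Strengths and models
# ---------------------------------------------------------------------------

def network_strength(
    matrix_or_edges: np.ndarray, masks: EdgeMaskPair
) -> NetworkStrengths:
    """Summed CN and AN edge strengths.

    Accepts a single node x node matrix, a subjects x nodes x nodes stack,
    or a subjects x edges matrix; each undirected edge contributes once.
    """
    arr = np.asarray(matrix_or_edges, float)
    e = n_edges(masks.n_nodes)
    if arr.ndim >= 2 and arr.shape[-1] == arr.shape[-2] == masks.n_nodes:
        from .edges import sym_to_vec

        arr = sym_to_vec(arr)
    if arr.shape[-1] != e:
        raise ValueError("matrix does not match the mask's node universe")
    if np.isnan(arr[..., masks.pos | masks.neg]).any():
        raise ValueError("mask references an uncovered (NaN) edge")
    cn = arr[..., masks.pos].sum(axis=-1) if masks.pos.any() else np.zeros(arr.shape[:-1])
    an = arr[..., masks.neg].sum(axis=-1) if masks.neg.any() else np.zeros(arr.shape[:-1])
    return NetworkStrengths(np.asarray(cn, float), np.asarray(an, float))


def fit_strength_model(
    strengths: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares coefficients ``[intercept, slope, *covariates]`` of the
    first-degree polynomial fitting trait to network strength."""
    s = np.asarray(strengths, float)
    y = np.asarray(trait, float)
    n = s.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects to fit")
    if np.ptp(s) == 0:
        raise ValueError("strength vector is constant; slope unidentifiable")
    cols = [np.ones(n), s]
    names = ["intercept", "strength"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"covariate_{j}")
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = [
            names[j]
            for j in range(design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def score_performance(
    predicted: np.ndarray, observed: np.ndarray
) -> NetworkScore:
    """Spearman ``r_s`` (midranks for ties) and percent variance explained
    ``100 * r_s^2``, set to 0 when ``r_s < 0``. A constant prediction vector
    leaves the correlation undefined: reported as 0 and flagged."""
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("predicted/observed must be equal-length vectors (n >= 3)")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return NetworkScore(0.0, 0.0, flagged=True)
    r_s = float(stats.spearmanr(pred, obs).statistic)
    return NetworkScore(r_s, 100.0 * r_s**2 if r_s >= 0 else 0.0)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_folds(
    n: int, cv: str = "loo", k: int = 10, seed: int | None = None
) -> list[np.ndarray]:
    """Fold index lists: ``"loo"`` yields singleton folds in subject order;
    ``"kfold"`` randomly permutes subjects (seed required) into k groups
    whose sizes differ by at most one."""
    if cv == "loo":
        return [np.array([i]) for i in range(n)]
    if cv == "kfold":
        if seed is None:
            raise ValueError("k-fold assignment requires a seed")
        if not 2 <= k <= n:
            raise ValueError(f"k must lie in [2, n]; got k={k}, n={n}")
        perm = np.random.default_rng(seed).permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    raise ValueError(f"unknown cv scheme {cv!r}")


def _cv_loop(
    train_edges: np.ndarray,
    test_edges: np.ndarray,
    trait: np.ndarray,
    threshold: ThresholdSpec,
    folds: Sequence[np.ndarray],
    covariates: np.ndarray | None,
    covariate_mode: str,
) -> PredictionResult:
    """Shared CV engine: select and fit on train-source matrices of the
    training subjects, predict from test-source matrices of held-out
    subjects. ``train_edges`` and ``test_edges`` coincide for ordinary CPM
    and differ for cross-condition validation."""
    if covariate_mode not in ("none", "select", "model", "both"):
        raise ValueError(f"unknown covariate mode {covariate_mode!r}")
    n = train_edges.shape[0]
    cov = None
    if covariates is not None and covariate_mode != "none":
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
    sel_cov = cov if covariate_mode in ("select", "both") else None
    mod_cov = cov if covariate_mode in ("model", "both") else None

    predicted = {net: np.full(n, np.nan) for net in NETWORKS}
    fold_masks: list[EdgeMaskPair] = []
    seen = np.zeros(n, bool)
    for fold in folds:
        fold = np.asarray(fold, int)
        if seen[fold].any():
            raise ValueError("folds overlap: a subject would be predicted twice")
        seen[fold] = True
        tr = np.setdiff1d(np.arange(n), fold)
        if np.ptp(trait[tr]) == 0:
            raise ValueError("constant trait in a training fold")
        r, p = edge_trait_association(
            train_edges[tr], trait[tr], sel_cov[tr] if sel_cov is not None else None
        )
        masks = select_edges(r, p, threshold)
        fold_masks.append(masks)
        s_tr = network_strength(train_edges[tr], masks)
        s_te = network_strength(test_edges[fold], masks)
        for net in NETWORKS:
            str_tr = s_tr.by_network(net)
            if np.ptp(str_tr) == 0:
                # Empty or degenerate network in this fold: predict the mean.
                predicted[net][fold] = trait[tr].mean()
                continue
            coef = fit_strength_model(
                str_tr, trait[tr], mod_cov[tr] if mod_cov is not None else None
            )
            pred = coef[0] + coef[1] * s_te.by_network(net)
            if len(coef) > 2:
                pred = pred + mod_cov[fold] @ coef[2:]
            predicted[net][fold] = pred
    if not seen.all():
        raise ValueError("folds do not cover every subject")

    scores = {net: score_performance(predicted[net], trait) for net in NETWORKS}
    return PredictionResult(trait.copy(), predicted, scores, fold_masks)


def batched_cpm_combined(
    edges: np.ndarray,
    traits: np.ndarray,
    threshold: ThresholdSpec,
    folds: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Combined-network CPM predictions for many trait vectors at once.

    Equivalent to running the combined-network arm of the CV loop once per
    column of ``traits`` (subjects x B), but with the edge-trait
    correlations and strength sums of all B columns batched into matrix
    products — the workhorse behind permutation inference, where the same
    connectome stack is re-analyzed under hundreds of permuted traits.
    P-value thresholding is applied as the equivalent critical |r| bound.

    Returns
    -------
    r_s : (B,) Spearman correlation of held-out predictions vs each trait.
    predictions : (n, B) held-out combined-network predictions.
    """
    x = np.asarray(edges, float)
    t_mat = np.asarray(traits, float)
    if t_mat.ndim == 1:
        t_mat = t_mat[:, None]
    n, e = x.shape
    n_b = t_mat.shape[1]
    preds = np.empty((n, n_b))
    all_idx = np.arange(n)
    for fold in folds:
        fold = np.asarray(fold, int)
        tr = np.setdiff1d(all_idx, fold)
        nt = len(tr)
        xt, tt = x[tr], t_mat[tr]
        xc = xt - xt.mean(axis=0)
        tc = tt - tt.mean(axis=0)
        sx = np.sqrt((xc**2).sum(axis=0))
        sy = np.sqrt((tc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc.T @ tc) / (sx[:, None] * sy[None, :])
        r[~np.isfinite(r)] = 0.0
        if threshold.method == "p":
            df = nt - 2
            t_crit = stats.t.isf(threshold.level / 2.0, df)
            r_crit = np.sqrt(t_crit**2 / (df + t_crit**2))
            mask = (r > r_crit).astype(float) - (r < -r_crit)
        else:
            k_sel = int(round(threshold.level * e))
            mask = np.zeros_like(r)
            if k_sel > 0:
                top = np.argpartition(-r, k_sel - 1, axis=0)[:k_sel]
                bot = np.argpartition(r, k_sel - 1, axis=0)[:k_sel]
                cols = np.arange(n_b)
                mask[top, cols[None, :]] = 1.0
                mask[bot, cols[None, :]] = -1.0
        strength = x @ mask  # combined = CN - AN in one product
        s_tr = strength[tr]
        sm = s_tr.mean(axis=0)
        s_c = s_tr - sm
        var = (s_c**2).sum(axis=0)
        cov = (s_c * tc).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(var > 0, cov / var, 0.0)
        intercept = tt.mean(axis=0) - slope * sm
        preds[fold] = intercept[None, :] + slope[None, :] * strength[fold]
    # column-wise Spearman of predictions vs their own trait vector
    pr = stats.rankdata(preds, axis=0)
    tr_r = stats.rankdata(t_mat, axis=0)
    pc = pr - pr.mean(axis=0)
    oc = tr_r - tr_r.mean(axis=0)
    denom = np.sqrt((pc**2).sum(axis=0) * (oc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_s = (pc * oc).sum(axis=0) / denom
    r_s[~np.isfinite(r_s)] = 0.0
    return r_s, preds


def run_cpm_cv(
    stack: ConnectivityStack | np.ndarray,
    trait: np.ndarray,
    threshold: ThresholdSpec | str = ThresholdSpec("p", 0.01),
    cv: str = "loo",
    k: int = 10,
    seed: int | None = None,
    covariates: np.ndarray | None = None,
    covariate_mode: str = "none",
) -> PredictionResult:
    """Cross-validated CPM for one condition.

    Parameters
    ----------
    stack
        A ``ConnectivityStack`` or a subjects x edges matrix.
    trait
        Trait per subject (subjects with missing trait must be dropped
        upstream).
    threshold
        Edge-selection rule (``ThresholdSpec`` or parseable string).
    cv, k, seed
        ``"loo"`` (default) or ``"kfold"`` with ``k`` groups; the random
        fold assignment requires ``seed``.
    covariates, covariate_mode
        Covariate matrix and where it enters: ``"select"`` (partial
        correlation in edge selection), ``"model"`` (extra regressors in
        the strength model), ``"both"``, or ``"none"``.

    Returns
    -------
    PredictionResult
        Held-out predictions, per-network Spearman scores, and the
        per-fold edge masks (for intersection networks).
    """
    if isinstance(threshold, str):
        threshold = ThresholdSpec.parse(threshold)
    edges = stack.edge_matrix() if isinstance(stack, ConnectivityStack) else np.asarray(stack, float)
    trait = np.asarray(trait, float)
    if np.isnan(trait).any():
        raise ValueError("trait contains missing values; drop those subjects first")
    folds = make_folds(edges.shape[0], cv, k, seed)
    return _cv_loop(edges, edges, trait, threshold, folds, covariates, covariate_mode)
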