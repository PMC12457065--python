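"""Cross-lagged panel network estimation.

For one trajectory group and one pair of consecutive waves (t, t+1), each of
the six symptom-cluster scores at wave t+1 is regressed on all six
standardized scores at wave t (L1-penalized, lambda chosen by 10-fold
cross-validation per outcome) plus the three baseline covariates (gender,
age, trauma count; unpenalized by default — they are adjustment variables,
not network members).  The 6x6 matrix of node coefficients W, with
W[i, j] = effect of node i at t on node j at t+1, is the directed network.

The L1 solver is scikit-learn coordinate descent; partially-penalized
designs are handled exactly by profiling out the unpenalized block
(Frisch-Waugh residualization), which leaves the penalized subproblem an
ordinary lasso.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from ._solver import lasso_gram_path, lasso_gram_path_from_moments
from .simulate import COVARIATES, NODES


class ZeroVarianceError(ValueError):
    """A variable is constant within the analysis subset."""


@dataclass(frozen=True)
class LassoConfig:
    """Penalized-regression settings for network estimation."""

    n_folds: int = 10
    lambda_rule: str = "min"  # or "1se"
    fold_seed: int = 0
    covariates: tuple[str, ...] = COVARIATES
    covariate_penalized: bool = False
    n_lambda: int = 100
    lambda_decades: float = 4.0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_rule not in {"min", "1se"}:
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class CLPNetwork:
    """Directed signed network for one group x wave pair.

    ``W[i, j]`` is the standardized coefficient of node i at wave t
    predicting node j at wave t+1; the diagonal holds autoregressive
    effects.  Covariate coefficients are stored separately and are never
    part of the network.
    """

    group: str
    wave_pair: tuple[int, int]
    nodes: tuple[str, ...]
    W: np.ndarray  # (6, 6)
    covariate_coefs: np.ndarray  # (n_covariates, 6)
    lambdas: np.ndarray  # per-outcome penalty
    n: int
    config: LassoConfig = field(default_factory=LassoConfig)
    display_thresholded: bool = False

    @property
    def autoregressive(self) -> np.ndarray:
        return np.diag(self.W)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i, src in enumerate(self.nodes):
            for j, tgt in enumerate(self.nodes):
                rows.append(
                    {
                        "group": self.group,
                        "wave_from": self.wave_pair[0],
                        "wave_to": self.wave_pair[1],
                        "source": src,
                        "target": tgt,
                        "weight": self.W[i, j],
                        "lambda_outcome": self.lambdas[j],
                    }
                )
        return pd.DataFrame(rows)

    def matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=list(self.nodes), columns=list(self.nodes))

    def to_graph(self):
        """networkx DiGraph of nonzero edges (weights as attributes)."""
        import networkx as nx

        g = nx.DiGraph(group=self.group, wave_pair=str(self.wave_pair))
        g.add_nodes_from(self.nodes)
        for i, src in enumerate(self.nodes):
            for j, tgt in enumerate(self.nodes):
                if self.W[i, j] != 0.0:
                    g.add_edge(src, tgt, weight=float(self.W[i, j]))
        return g


@dataclass
class StandardizedBlock:
    """Z-scored analysis matrices for one group x wave pair."""

    X_t: np.ndarray  # (n, 6) nodes at wave t
    X_t1: np.ndarray  # (n, 6) nodes at wave t+1
    C: np.ndarray  # (n, n_covariates)
    nodes: tuple[str, ...]
    covariates: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    ids: np.ndarray


def standardize_block(
    panel: pd.DataFrame,
    group_ids: Sequence,
    waves: tuple[int, int],
    covariates: Sequence[str] = COVARIATES,
    nodes: Sequence[str] = NODES,
) -> StandardizedBlock:
    """Z-score every node variable at both waves and every covariate within
    the subject subset. Raises :class:`ZeroVarianceError` naming the first
    constant variable."""
    ids = np.asarray(group_ids)
    if ids.size == 0:
        raise ValueError("empty group")
    sub = panel[panel["id"].isin(ids)]
    means: dict[str, float] = {}
    sds: dict[str, float] = {}

    def z(col: str) -> np.ndarray:
        v = sub[col].to_numpy(float)
        m, s = v.mean(), v.std(ddof=0)
        if s <= 0:
            raise ZeroVarianceError(f"variable {col!r} has zero variance in this subset")
        means[col], sds[col] = float(m), float(s)
        return (v - m) / s

    t0, t1 = waves
    X_t = np.column_stack([z(f"{n}_{t0}") for n in nodes])
    X_t1 = np.column_stack([z(f"{n}_{t1}") for n in nodes])
    C = np.column_stack([z(c) for c in covariates]) if covariates else np.empty((len(sub), 0))
    return StandardizedBlock(
        X_t=X_t,
        X_t1=X_t1,
        C=C,
        nodes=tuple(nodes),
        covariates=tuple(covariates),
        means=means,
        sds=sds,
        ids=sub["id"].to_numpy(),
    )


def _split_design(X: np.ndarray, penalty_free: Sequence[int]):
    free = np.asarray(sorted(penalty_free), dtype=int)
    pen = np.asarray([j for j in range(X.shape[1]) if j not in set(free.tolist())], dtype=int)
    return pen, free


def _residualize(Xp, Xf, y):
    """Project out the unpenalized block (exact profiling of the objective)."""
    if Xf.shape[1] == 0:
        return Xp, y, None
    coef_p, *_ = np.linalg.lstsq(Xf, Xp, rcond=None)
    coef_y, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    return Xp - Xf @ coef_p, y - Xf @ coef_y, None


def lasso_path_fit(
    X: np.ndarray,
    y: np.ndarray,
    penalty_free: Sequence[int] = (),
    lam: float = 0.0,
) -> np.ndarray:
    """Minimize (1/2n)||y - Xb||^2 + lam * sum_{j penalized} |b_j|.

    Columns listed in ``penalty_free`` are unpenalized.  lam = 0 reduces to
    least squares.  Returns the full coefficient vector in input column
    order (no intercept; inputs are assumed centered/standardized).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in design or outcome")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = X.shape[1]
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    pen, free = _split_design(X, penalty_free)
    Xp, Xf = X[:, pen], X[:, free]
    Xp_r, y_r, _ = _residualize(Xp, Xf, y)
    model = Lasso(alpha=lam, fit_intercept=False, tol=1e-10, max_iter=200_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xp_r, y_r)
    bp = model.coef_
    out = np.zeros(p)
    out[pen] = bp
    if free.size:
        bf, *_ = np.linalg.lstsq(Xf, y - Xp @ bp, rcond=None)
        out[free] = bf
    return out


def lambda_max(X: np.ndarray, y: np.ndarray, penalty_free: Sequence[int] = ()) -> float:
    """Smallest lambda at which every penalized coefficient is zero (KKT bound),
    computed after profiling out the unpenalized block."""
    pen, free = _split_design(np.asarray(X, float), penalty_free)
    Xp_r, y_r, _ = _residualize(X[:, pen], X[:, free], np.asarray(y, float))
    return float(np.max(np.abs(Xp_r.T @ y_r)) / X.shape[0])


def _lambda_grid(lmax: float, cfg: LassoConfig) -> np.ndarray:
    lmax = max(lmax, 1e-12)
    return np.logspace(np.log10(lmax), np.log10(lmax) - cfg.lambda_decades, cfg.n_lambda)


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LassoConfig = LassoConfig(),
    penalty_free: Sequence[int] = (),
) -> float:
    """Choose lambda by K-fold cross-validation over a log grid spanning four
    decades below the full-sample lambda_max (100 points).

    ``min`` returns the CV-MSE minimizer; ``1se`` the largest lambda whose
    CV error is within one standard error of the minimum.  The fold split is
    a seeded simple random partition, so the selection is deterministic in
    (data, config).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < cfg.n_folds:
        raise ValueError(
            f"n={n} < n_folds={cfg.n_folds}; reduce n_folds to at most {n}"
        )
    grid = _lambda_grid(lambda_max(X, y, penalty_free), cfg)
    pen, free = _split_design(X, penalty_free)
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.fold_seed % (2**31))
    sq_err = np.zeros((cfg.n_folds, grid.size))
    for f, (tr, te) in enumerate(kf.split(X)):
        Xp_tr, Xf_tr = X[np.ix_(tr, pen)], X[np.ix_(tr, free)]
        Xp_r, y_r, _ = _residualize(Xp_tr, Xf_tr, y[tr])
        # Gram coordinate descent: same objective/solution as sklearn's
        # lasso_path, but cheap enough to re-run inside every bootstrap
        # replicate (see _solver)
        coefs = lasso_gram_path(Xp_r, y_r, grid)
        # coefs: (n_pen, n_lambda) aligned with grid (descending)
        if free.size:
            bf, *_ = np.linalg.lstsq(Xf_tr, y[tr][:, None] - Xp_tr @ coefs, rcond=None)
            pred = X[np.ix_(te, pen)] @ coefs + X[np.ix_(te, free)] @ bf
        else:
            pred = X[np.ix_(te, pen)] @ coefs
        sq_err[f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
    mean_err = sq_err.mean(axis=0)
    if cfg.lambda_rule == "min":
        return float(grid[int(np.argmin(mean_err))])
    se = sq_err.std(axis=0, ddof=1) / np.sqrt(cfg.n_folds)
    i_min = int(np.argmin(mean_err))
    cutoff = mean_err[i_min] + se[i_min]
    ok = np.nonzero(mean_err <= cutoff)[0]
    return float(grid[ok.min()])  # grid is descending: smallest index = largest lambda


def _cv_lambdas_block(
    X: np.ndarray,
    Ys: np.ndarray,
    cfg: LassoConfig,
    penalty_free: Sequence[int] = (),
) -> np.ndarray:
    """Per-outcome CV lambda selection sharing fold splits, residualization
    and Gram matrices across outcomes.  Identical selections to calling
    :func:`cv_select_lambda` per outcome (same folds, grid and objective),
    just batched for speed inside bootstrap loops."""
    n = X.shape[0]
    if n < cfg.n_folds:
        raise ValueError(
            f"n={n} < n_folds={cfg.n_folds}; reduce n_folds to at most {n}"
        )
    pen, free = _split_design(X, penalty_free)
    Xp, Xf = X[:, pen], X[:, free]
    n_out = Ys.shape[1]
    grids = [
        _lambda_grid(lambda_max(X, Ys[:, j], penalty_free), cfg) for j in range(n_out)
    ]
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.fold_seed % (2**31))
    errs = np.zeros((n_out, cfg.n_folds, cfg.n_lambda))
    for f, (tr, te) in enumerate(kf.split(X)):
        Xp_tr, Xf_tr = Xp[tr], Xf[tr]
        if free.size:
            Qp, *_ = np.linalg.lstsq(Xf_tr, Xp_tr, rcond=None)
            Xp_r = Xp_tr - Xf_tr @ Qp
        else:
            Xp_r = Xp_tr
        G = Xp_r.T @ Xp_r / len(tr)
        for j in range(n_out):
            y_tr = Ys[tr, j]
            if free.size:
                qy, *_ = np.linalg.lstsq(Xf_tr, y_tr, rcond=None)
                y_r = y_tr - Xf_tr @ qy
            else:
                y_r = y_tr
            c = Xp_r.T @ y_r / len(tr)
            coefs = lasso_gram_path_from_moments(G, c, grids[j])
            if free.size:
                bf, *_ = np.linalg.lstsq(Xf_tr, y_tr[:, None] - Xp_tr @ coefs, rcond=None)
                pred = Xp[te] @ coefs + Xf[te] @ bf
            else:
                pred = Xp[te] @ coefs
            errs[j, f] = ((pred - Ys[te, j][:, None]) ** 2).mean(axis=0)
    out = np.empty(n_out)
    for j in range(n_out):
        mean_err = errs[j].mean(axis=0)
        if cfg.lambda_rule == "min":
            out[j] = grids[j][int(np.argmin(mean_err))]
        else:
            se = errs[j].std(axis=0, ddof=1) / np.sqrt(cfg.n_folds)
            i_min = int(np.argmin(mean_err))
            ok = np.nonzero(mean_err <= mean_err[i_min] + se[i_min])[0]
            out[j] = grids[j][ok.min()]
    return out


def fit_clpn(
    panel: pd.DataFrame,
    group_ids: Sequence,
    wave_pair: tuple[int, int] = (1, 2),
    cfg: LassoConfig = LassoConfig(),
    group: str = "all",
    lambdas: Sequence[float] | None = None,
) -> CLPNetwork:
    """Estimate the cross-lagged network for one group and wave pair.

    ``lambdas`` (length 6) skips per-outcome cross-validation and reuses the
    given penalties — used by the fast bootstrap mode.
    """
    block = standardize_block(panel, group_ids, wave_pair, cfg.covariates)
    n = block.X_t.shape[0]
    if n < 50:
        warnings.warn(f"only {n} subjects in group {group!r}; estimates will be unstable")
    X = np.hstack([block.X_t, block.C])
    n_nodes = len(block.nodes)
    penalty_free: tuple[int, ...] = ()
    if not cfg.covariate_penalized and block.C.shape[1]:
        penalty_free = tuple(range(n_nodes, n_nodes + block.C.shape[1]))
    W = np.zeros((n_nodes, n_nodes))
    cov_coefs = np.zeros((block.C.shape[1], n_nodes))
    if lambdas is not None:
        lams = np.asarray(lambdas, float).copy()
    else:
        lams = _cv_lambdas_block(X, block.X_t1, cfg, penalty_free)
    for j in range(n_nodes):
        y = block.X_t1[:, j]
        coef = lasso_path_fit(X, y, penalty_free, lams[j])
        W[:, j] = coef[:n_nodes]
        cov_coefs[:, j] = coef[n_nodes:]
    return CLPNetwork(
        group=group,
        wave_pair=tuple(wave_pair),
        nodes=block.nodes,
        W=W,
        covariate_coefs=cov_coefs,
        lambdas=lams,
        n=n,
        config=cfg,
    )


def apply_display_threshold(net: CLPNetwork, threshold: float) -> CLPNetwork:
    """Display copy with |W| < threshold zeroed (strict inequality); the
    estimation copy is untouched and downstream statistics must never
    consume the thresholded copy."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = copy.deepcopy(net)
    out.W = np.where(np.abs(net.W) < threshold, 0.0, net.W)
    out.display_thresholded = True
    return out
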