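"""The MultiDA fitting engine.

The model maximizes a weighted sum of squared covariances between
one-dimensional latent variables ``v_j = chi_j alpha_j`` of the blocks,

    sum_{j != k} d_jk (alpha_j' chi_j' chi_k alpha_k)^2 ,

subject to the latent-norm constraint ``||chi_j alpha_j||^2 = N`` and an
elastic-net penalty on each loading.  ``chi_j`` equals the block ``X_j``
except for the class block, which carries the slack augmentation
``chi_J = X_J + b (*) m``.

Optimization is cyclic (Wold's procedure): each block's loading is
refreshed in turn from its *inner component* -- the weighted sum of the
neighbouring latent vectors, each scaled by its current covariance with
the block's own latent vector -- via a univariate soft-threshold (UST)
update followed by renormalization.  The squared-covariance objective is
convex in each covariance, so the linearized (inner-component) update is
a minorize-maximize step; a cheap guard additionally rejects any block
update that would decrease the objective, making the per-rank trace
non-decreasing by construction.

Sparsity is controlled per block by a shrinkage fraction
``lambda in [0, 1)``: the soft-threshold applied to the gradient
``chi_j' upsilon_j`` is ``lambda * max|chi_j' upsilon_j|``, so ``0``
means no shrinkage and values near one zero out all but the strongest
coordinates.  The fraction is chosen by K-fold cross-validation on the
regression of the inner component onto the block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .data import BlockGraph, MultiblockData
from .discriminant import (
    SlackState,
    augmented_class_block,
    update_discriminant_loading,
    update_slack,
)

__all__ = [
    "FitOptions",
    "RankFit",
    "LoadingSet",
    "objective_value",
    "inner_component",
    "ust_update",
    "normalize_loading",
    "select_lambda_cv",
    "fit_rank",
    "deflate",
    "fit",
]

_AUTO_GRID_SIZE = 20
_AUTO_GRID_MAX = 0.95


@dataclass
class FitOptions:
    """Tuning knobs of the fitting engine.

    Parameters
    ----------
    n_ranks
        Number of latent dimensions (components) to extract sequentially.
    max_iter
        Maximum Wold sweeps per rank.
    tol
        Relative objective-change convergence threshold per sweep.
    cv_folds
        K for the K-fold cross-validation of the shrinkage fractions.
    lambda_grid
        Candidate shrinkage fractions in ``[0, 1)``, or ``"auto"`` for
        ``0`` plus 19 log-spaced values up to 0.95.
    seed
        Seed for loading initialization and CV fold shuffling; required
        for reproducibility.
    discriminant
        Enable the slack-variable discriminant step on the block linked
        to the class block.
    sgcca_mode
        Ablation: replace the weight matrix ``D`` by the binary ``C``
        and disable the discriminant slack, which reduces the model to
        sparse generalized canonical correlation analysis.
    freeze_slack_at_zero
        Run the discriminant update path but pin ``m = 0`` (diagnostic;
        makes the fit identical to the plain correlation model).
    norm_convention
        ``"n"``: ``||chi alpha||^2 = N`` (default); ``"unit"``:
        ``||chi alpha||^2 = 1``.  The two differ by a constant factor
        that cancels in covariance rankings.
    reselect_lambda
        Re-run CV at every sweep instead of once per rank.
    monotone_guard
        Reject any block update that would decrease the objective.
    """

    n_ranks: int = 2
    max_iter: int = 100
    tol: float = 1e-6
    cv_folds: int = 3
    lambda_grid: Sequence[float] | str = "auto"
    seed: int = 0
    discriminant: bool = True
    sgcca_mode: bool = False
    freeze_slack_at_zero: bool = False
    norm_convention: str = "n"
    reselect_lambda: bool = False
    monotone_guard: bool = True

    def __post_init__(self) -> None:
        if self.n_ranks < 1 or self.max_iter < 1:
            raise ValueError("n_ranks and max_iter must be positive")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.norm_convention not in ("n", "unit"):
            raise ValueError("norm_convention must be 'n' or 'unit'")
        if not isinstance(self.lambda_grid, str):
            grid = [float(v) for v in self.lambda_grid]
            if not grid:
                raise ValueError("lambda_grid must not be empty")
            if any(v < 0 for v in grid):
                raise ValueError("every shrinkage fraction must be nonnegative")
            self.lambda_grid = grid
        elif self.lambda_grid != "auto":
            raise ValueError("lambda_grid must be a sequence or 'auto'")

    @property
    def slack_enabled(self) -> bool:
        return self.discriminant and not self.sgcca_mode and not self.freeze_slack_at_zero

    @property
    def discriminant_path(self) -> bool:
        """Whether block updates route through the discriminant step."""
        return self.discriminant and not self.sgcca_mode

    def to_dict(self) -> dict:
        grid = self.lambda_grid if isinstance(self.lambda_grid, str) else list(self.lambda_grid)
        return {
            "n_ranks": self.n_ranks,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "cv_folds": self.cv_folds,
            "lambda_grid": grid,
            "seed": self.seed,
            "discriminant": self.discriminant,
            "sgcca_mode": self.sgcca_mode,
            "freeze_slack_at_zero": self.freeze_slack_at_zero,
            "norm_convention": self.norm_convention,
            "reselect_lambda": self.reselect_lambda,
            "monotone_guard": self.monotone_guard,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "FitOptions":
        return cls(**obj)


def auto_lambda_grid() -> np.ndarray:
    """Default shrinkage-fraction grid: 0 plus 19 log-spaced values to 0.95."""
    return np.r_[0.0, np.geomspace(_AUTO_GRID_MAX / 100.0, _AUTO_GRID_MAX, _AUTO_GRID_SIZE - 1)]


# ---------------------------------------------------------------------------
# elementary updates


def ust_update(X: np.ndarray, upsilon: np.ndarray, lam: float) -> np.ndarray:
    """Univariate soft-threshold update (unnormalized loading).

    Element-wise ``sign(g) (|g| - lam)_+`` with ``g = X' upsilon``:
    the closed-form elastic-net solution when the Gram matrix is treated
    as diagonal.  ``lam`` is an absolute threshold on the scale of ``g``.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    g = X.T @ np.asarray(upsilon, dtype=float)
    return np.sign(g) * np.maximum(np.abs(g) - lam, 0.0)


def normalize_loading(
    alpha: np.ndarray, chi: np.ndarray, convention: str = "n"
) -> tuple[np.ndarray, bool]:
    """Rescale a loading to the latent-norm contract.

    Returns ``(alpha_scaled, degenerate)``.  Convention ``"n"`` enforces
    ``||chi alpha||^2 = N``; ``"unit"`` enforces ``||chi alpha||^2 = 1``.
    An identically zero loading (or one whose latent vector is zero) is
    returned unchanged with ``degenerate=True``.
    """
    alpha = np.asarray(alpha, dtype=float)
    norm = float(np.linalg.norm(chi @ alpha))
    if norm == 0.0:
        return alpha.copy(), True
    target = math.sqrt(chi.shape[0]) if convention == "n" else 1.0
    return alpha * (target / norm), False


def _regression_coef(X: np.ndarray, upsilon: np.ndarray, thr: float) -> np.ndarray:
    """Soft-thresholded regression coefficients on the prediction scale.

    The UST solution divided by the per-column squared norms (the
    diagonal-Gram approximation of the normal equation), so that
    ``X @ coef`` approximates ``upsilon``.
    """
    g = X.T @ upsilon
    colnorm2 = np.einsum("ij,ij->j", X, X)
    coef = np.sign(g) * np.maximum(np.abs(g) - thr, 0.0)
    nz = colnorm2 > 0
    coef[nz] /= colnorm2[nz]
    coef[~nz] = 0.0
    return coef


def select_lambda_cv(
    X: np.ndarray,
    upsilon: np.ndarray,
    K: int,
    grid: Sequence[float],
    rng: np.random.Generator,
) -> float:
    """Choose the shrinkage fraction by K-fold cross-validation.

    For each candidate fraction the UST regression of ``upsilon`` on
    ``X`` is fitted on K-1 folds (threshold = fraction times the largest
    absolute training gradient) and scored by the mean squared error of
    predicting the held-out entries of ``upsilon``.  The fraction with
    the smallest mean error wins; ties go to the larger fraction (the
    sparser model).
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must not be empty")
    if grid.size == 1:
        return float(grid[0])
    if K < 2:
        raise ValueError("K must be at least 2")
    n = X.shape[0]
    if n < K:
        raise ValueError("need at least K samples for K-fold CV")
    upsilon = np.asarray(upsilon, dtype=float)
    splitter = KFold(n_splits=K, shuffle=True, random_state=int(rng.integers(2**31)))
    errs = np.zeros(grid.size)
    for tr, te in splitter.split(X):
        Xtr, Xte = X[tr], X[te]
        utr, ute = upsilon[tr], upsilon[te]
        g = Xtr.T @ utr
        gmax = float(np.abs(g).max(initial=0.0))
        colnorm2 = np.einsum("ij,ij->j", Xtr, Xtr)
        nz = colnorm2 > 0
        for i, frac in enumerate(grid):
            coef = np.sign(g) * np.maximum(np.abs(g) - frac * gmax, 0.0)
            coef[nz] /= colnorm2[nz]
            coef[~nz] = 0.0
            resid = ute - Xte @ coef
            errs[i] += float(resid @ resid) / len(te)
    errs /= K
    tol = 1e-12 * max(1.0, float(errs.min()))
    best = grid[errs <= errs.min() + tol]
    return float(best.max())


# ---------------------------------------------------------------------------
# objective and inner components


def _chi_blocks(
    data: MultiblockData, slack: SlackState | None
) -> list[np.ndarray]:
    chi = list(data.blocks)
    if slack is not None:
        chi[data.class_index] = augmented_class_block(
            data.blocks[data.class_index], slack.b, slack.m
        )
    return chi


def _objective_from_scores(W: np.ndarray, scores: list[np.ndarray]) -> float:
    J = len(scores)
    total = 0.0
    for j in range(J):
        for k in range(J):
            if k == j or W[j, k] == 0:
                continue
            cov = float(scores[j] @ scores[k])
            total += W[j, k] * cov * cov
    return total


def objective_value(
    data: MultiblockData,
    graph: BlockGraph,
    loadings: Sequence[np.ndarray],
    slack: SlackState | None = None,
    *,
    sgcca_mode: bool = False,
) -> float:
    """Weighted sum of squared latent covariances (the model objective)."""
    chi = _chi_blocks(data, slack if not sgcca_mode else None)
    if len(loadings) != len(chi):
        raise ValueError("one loading vector per block is required")
    scores = []
    for X, a in zip(chi, loadings):
        a = np.asarray(a, dtype=float)
        if a.shape[0] != X.shape[1]:
            raise ValueError("loading length does not match block width")
        scores.append(X @ a)
    return _objective_from_scores(graph.weights(sgcca_mode), scores)


def inner_component(
    j: int,
    data: MultiblockData,
    graph: BlockGraph,
    loadings: Sequence[np.ndarray],
    slack: SlackState | None = None,
    *,
    sgcca_mode: bool = False,
) -> np.ndarray:
    """Inner component of block ``j``: the weighted neighbour signal.

    ``upsilon_j = sum_{k != j} d_jk (v_j' v_k) v_k`` with
    ``v_k = chi_k alpha_k``.
    """
    chi = _chi_blocks(data, slack if not sgcca_mode else None)
    scores = [X @ np.asarray(a, dtype=float) for X, a in zip(chi, loadings)]
    return _inner_from_scores(j, graph.weights(sgcca_mode), scores)


def _inner_from_scores(j: int, W: np.ndarray, scores: list[np.ndarray]) -> np.ndarray:
    up = np.zeros_like(scores[j])
    for k in range(len(scores)):
        if k == j or W[j, k] == 0:
            continue
        up += W[j, k] * float(scores[j] @ scores[k]) * scores[k]
    return up


# ---------------------------------------------------------------------------
# per-rank fit


@dataclass
class RankFit:
    """One extracted rank: loadings, scores, slack and diagnostics."""

    loadings: list[np.ndarray]
    scores: list[np.ndarray]
    lambdas: list[float]
    slack: SlackState | None
    trace: list[float]
    converged: bool
    degenerate: list[bool]
    n_sweeps: int

    @property
    def all_zero(self) -> bool:
        return all(not np.any(a) for a in self.loadings)


def _discriminant_block_index(graph: BlockGraph, class_index: int) -> int:
    linked = [j for j in range(graph.n_blocks) if j != class_index and graph.C[j, class_index] > 0]
    if not linked:
        raise ValueError("no block is linked to the class block")
    return linked[-1]


def fit_rank(
    data: MultiblockData,
    graph: BlockGraph,
    options: FitOptions,
    rng: np.random.Generator,
) -> RankFit:
    """Extract one rank by cyclic block updates (Wold's procedure).

    Each sweep refreshes every block's loading from its inner component
    by soft-thresholding and renormalization; the block linked to the
    class block additionally runs the slack-variable discriminant step.
    Sweeps stop when the relative objective change falls below
    ``options.tol`` or after ``options.max_iter`` sweeps.
    """
    J = data.n_blocks
    if graph.n_blocks != J:
        raise ValueError("graph size does not match number of blocks")
    N = data.n_samples
    cls = data.class_index
    W = graph.weights(options.sgcca_mode)
    conv = options.norm_convention

    disc = options.discriminant_path
    disc_j = _discriminant_block_index(graph, cls) if disc else -1
    slack = SlackState.zeros(data.labels) if disc else None

    chi = list(data.blocks)
    if slack is not None:
        chi[cls] = augmented_class_block(data.blocks[cls], slack.b, slack.m)

    # seeded random initialization, normalized to the latent-norm contract
    alphas: list[np.ndarray] = []
    degenerate = [False] * J
    for j in range(J):
        a = rng.standard_normal(data.blocks[j].shape[1])
        a, bad = normalize_loading(a, chi[j], conv)
        degenerate[j] = bad
        alphas.append(a)
    scores = [chi[j] @ alphas[j] for j in range(J)]

    lambdas: list[float | None] = [None] * J
    grid = auto_lambda_grid() if isinstance(options.lambda_grid, str) else np.asarray(
        options.lambda_grid, dtype=float
    )

    # the block coupled to the class goes first: its sweep-1 target
    # contains the class latent, which does not depend on the random
    # initialization, so every later block cross-validates its
    # shrinkage against an informed latent rather than the initial noise
    anchor = disc_j if disc else _discriminant_block_index(graph, cls)
    order = [anchor, cls] + [j for j in range(J) if j != cls and j != anchor]

    obj = _objective_from_scores(W, scores)
    trace: list[float] = []  # objective after each full sweep
    converged = False
    terminated = False
    sweeps = 0

    for sweeps in range(1, options.max_iter + 1):
        sweep_start = obj
        for j in order:
            class_scale = 0.0
            if disc and j == disc_j:
                # discriminant step: the regression target is the class
                # block's message, i.e. the slack-augmented class latent
                # scaled by its weighted covariance with this block
                class_scale = W[j, cls] * float(scores[j] @ scores[cls]) * alphas[cls][0]
                target = W[j, cls] * float(scores[j] @ scores[cls]) * scores[cls]
            else:
                target = _inner_from_scores(j, W, scores)
            if lambdas[j] is None or options.reselect_lambda:
                if data.blocks[j].shape[1] == 1:
                    lambdas[j] = 0.0  # nothing to select in a single column
                else:
                    lambdas[j] = select_lambda_cv(
                        chi[j], target, options.cv_folds, grid, rng
                    )
            g = chi[j].T @ target
            gmax = float(np.abs(g).max(initial=0.0))
            thr = lambdas[j] * gmax
            if disc and j == disc_j:
                cand = update_discriminant_loading(chi[j], target, thr)
            else:
                cand = ust_update(chi[j], target, thr)
            if not np.any(cand):
                # all coefficients shrunk away: the block carries no
                # information at this rank; terminate the rank (during
                # the first sweep nothing has been fitted yet, so the
                # whole rank is void)
                if sweeps == 1:
                    for k in range(J):
                        alphas[k] = np.zeros_like(alphas[k])
                        scores[k] = np.zeros(N)
                        degenerate[k] = True
                else:
                    alphas[j] = np.zeros_like(alphas[j])
                    scores[j] = np.zeros(N)
                    degenerate[j] = True
                terminated = True
                break

            old_alpha, old_score = alphas[j], scores[j]
            new_alpha, bad = normalize_loading(cand, chi[j], conv)
            alphas[j] = new_alpha
            scores[j] = chi[j] @ new_alpha
            reverts: list = []
            if disc and j == disc_j and options.slack_enabled:
                # slack step (the DLSR alternation): bring the regression
                # coefficients back to the label scale and take the
                # positive part of the class-directed residual vs the raw
                # labels; the slack then enters every covariance term
                # through the augmented class block
                if class_scale != 0.0:
                    reverts = [
                        (slack.m.copy(), chi[cls], alphas[cls].copy(), scores[cls])
                    ]
                    coef = _regression_coef(chi[j], target, thr)
                    # the diagonal-Gram solution loses overall scale when
                    # predictor columns are correlated; calibrate the
                    # prediction by its least-squares scalar before
                    # moving to the label scale
                    pred = chi[j] @ coef
                    pp = float(pred @ pred)
                    cal = float(pred @ target) / pp if pp > 0 else 0.0
                    coef = coef * (cal / class_scale)
                    slack.m = update_slack(
                        chi[j], coef, data.blocks[cls][:, 0], slack.b
                    )
                    chi[cls] = augmented_class_block(
                        data.blocks[cls], slack.b, slack.m
                    )
                    a5, bad5 = normalize_loading(alphas[cls], chi[cls], conv)
                    if not bad5:
                        alphas[cls] = a5
                    scores[cls] = chi[cls] @ alphas[cls]

            new_obj = _objective_from_scores(W, scores)
            # the first sweep always replaces the random initialization;
            # from the second sweep on, reject any objective decrease
            if options.monotone_guard and sweeps > 1 and new_obj < obj:
                alphas[j], scores[j] = old_alpha, old_score
                if reverts:
                    slack.m, chi[cls], alphas[cls], scores[cls] = reverts[0]
            else:
                obj = new_obj
        trace.append(obj)
        if terminated:
            break
        if abs(obj - sweep_start) < options.tol * max(1.0, abs(sweep_start)):
            converged = True
            break

    return RankFit(
        loadings=alphas,
        scores=scores,
        lambdas=[0.0 if l is None else float(l) for l in lambdas],
        slack=slack,
        trace=trace,
        converged=converged,
        degenerate=degenerate,
        n_sweeps=sweeps,
    )


# ---------------------------------------------------------------------------
# deflation and multi-rank extraction


def deflate(
    data: MultiblockData,
    loadings: "RankFit | Sequence[np.ndarray]",
    *,
    deflate_class: bool = False,
) -> MultiblockData:
    """Residualize each block against its own latent score.

    ``X_j <- X_j - v_j (v_j' v_j)^{-1} v_j' X_j`` with ``v_j = X_j a_j``;
    blocks with an all-zero loading pass through unchanged.  The class
    block is left intact by default: its single +/-1 column is the
    supervision signal, not structure to be explained away.
    """
    if isinstance(loadings, RankFit):
        loadings = loadings.loadings
    out = data.copy()
    for j, a in enumerate(loadings):
        if j == data.class_index and not deflate_class:
            continue
        a = np.asarray(a, dtype=float)
        if not np.any(a):
            continue
        v = out.blocks[j] @ a
        denom = float(v @ v)
        # a numerically vanished score (e.g. an already-deflated block)
        # carries no direction to remove
        scale = float(np.sum(out.blocks[j] ** 2)) * float(a @ a)
        if denom <= 1e-18 * max(scale, 1.0):
            continue
        out.blocks[j] = out.blocks[j] - np.outer(v / denom, v @ out.blocks[j])
    return out


@dataclass
class LoadingSet:
    """Accumulated multi-rank fit result.

    ``loadings[r][j]`` is block ``j``'s loading vector at rank ``r``
    (normalized to the latent-norm contract, or identically zero and
    flagged in ``degenerate[r][j]``); ``scores[r][j]`` the corresponding
    latent vector on the (deflated) data the rank was fitted to.
    """

    loadings: list[list[np.ndarray]] = field(default_factory=list)
    scores: list[list[np.ndarray]] = field(default_factory=list)
    lambdas: list[list[float]] = field(default_factory=list)
    objective_traces: list[list[float]] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    degenerate: list[list[bool]] = field(default_factory=list)
    slacks: list[SlackState | None] = field(default_factory=list)
    block_names: list[str] = field(default_factory=list)
    feature_names: list[list[str]] = field(default_factory=list)
    options: FitOptions | None = None

    @property
    def n_ranks(self) -> int:
        """Number of effective (stored) ranks."""
        return len(self.loadings)

    @property
    def n_blocks(self) -> int:
        return len(self.loadings[0]) if self.loadings else 0

    def block_loadings(self, j: int) -> np.ndarray:
        """Stacked (n_ranks x P_j) loading matrix of block ``j``."""
        return np.vstack([self.loadings[r][j] for r in range(self.n_ranks)])


def fit(
    data: MultiblockData,
    graph: BlockGraph,
    options: FitOptions | None = None,
) -> LoadingSet:
    """Fit the full multi-rank model: fit a rank, deflate, repeat.

    Extraction stops early when a rank yields all-zero loadings (the
    multiblock carries no further information) or when any single block
    degenerates to zero.
    """
    if options is None:
        options = FitOptions()
    rng = np.random.default_rng(options.seed)
    result = LoadingSet(
        block_names=list(data.block_names),
        feature_names=[list(f) for f in data.feature_names],
        options=options,
    )
    current = data
    for _ in range(options.n_ranks):
        rank = fit_rank(current, graph, options, rng)
        if rank.all_zero:
            break
        result.loadings.append(rank.loadings)
        result.scores.append(rank.scores)
        result.lambdas.append(rank.lambdas)
        result.objective_traces.append(rank.trace)
        result.converged.append(rank.converged)
        result.degenerate.append(rank.degenerate)
        result.slacks.append(rank.slack)
        if any(rank.degenerate):
            break  # a block ran out of information; stop extracting
        current = deflate(current, rank)
    return result
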