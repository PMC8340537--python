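"""Angle-based joint and individual variation explained (aJIVE).

Each centered block ``X_k`` (p_k features x n samples) is decomposed as

    X_k = J_k + I_k + E_k

where the rows of every ``J_k`` span a common *joint* sample-space basis
``V_J`` shared across blocks, ``I_k`` is block-specific low-rank structure
orthogonal to ``V_J``, and ``E_k`` is residual. The algorithm runs in three
phases:

1. per-block truncated SVD at a chosen initial rank r_k, keeping the first
   discarded singular value as that block's noise threshold;
2. SVD of the vertically stacked row-basis matrices. By principal-angle
   analysis the squared singular values of this stack equal sums of squared
   cosines of the canonical angles between block row spaces, so a direction
   shared by all K blocks scores close to K. Directions are kept as joint
   when their squared singular value exceeds both a Wedin-perturbation
   threshold and a random-direction (Monte Carlo null) threshold;
3. projection of each block onto the joint basis gives J_k; the individual
   component is recovered from the remainder by SVD, keeping directions
   above the block's noise threshold.

The row bases are scale-free, so the decomposition is insensitive to
heterogeneous block scales: no variance scaling of the inputs is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .blocks import MultiOmicsCollection, OmicsBlock
from .ranks import RankSelectionResult, select_initial_ranks

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSVD",
    "JointStructure",
    "BlockDecomposition",
    "AjiveResult",
    "truncated_block_svd",
    "stacked_basis_svd",
    "wedin_bound",
    "random_direction_bound",
    "select_joint_rank",
    "extract_joint",
    "extract_individual",
    "variance_explained",
    "ajive",
    "AJIVE",
]

_TIE_TOL = 1e-10  # exceedance slack for the noiseless case (see select_joint_rank)


@dataclass
class BlockSVD:
    """Phase-1 truncated SVD of one block."""

    name: str
    rank: int
    left_basis: np.ndarray  # p_k x r_k
    singular_values: np.ndarray  # length r_k, descending
    row_basis: np.ndarray  # n x r_k, orthonormal columns
    noise_threshold: float  # first discarded singular value (0 if none)
    residual: np.ndarray  # X - rank-r_k approximation, p_k x n

    @property
    def n_samples(self) -> int:
        return self.row_basis.shape[0]


@dataclass
class JointStructure:
    """Phase-2 output: the shared sample-space basis and its diagnostics."""

    joint_rank: int
    joint_basis: np.ndarray  # n x r_J ("common normalized scores")
    squared_singular_values: np.ndarray
    wedin_threshold: float
    random_threshold: float


@dataclass
class BlockDecomposition:
    """Phase-3 output for one block."""

    name: str
    joint: np.ndarray  # J_k, p_k x n
    individual: np.ndarray  # I_k, p_k x n
    residual: np.ndarray  # E_k, p_k x n
    initial_rank: int
    individual_rank: int
    noise_threshold: float
    joint_loadings: np.ndarray  # p_k x r_J
    individual_scores: np.ndarray  # n x individual_rank (right factors * svals)
    individual_loadings: np.ndarray  # p_k x individual_rank


@dataclass
class AjiveResult:
    """Full decomposition: joint structure, per-block parts, diagnostics."""

    joint: JointStructure
    blocks: list[BlockDecomposition]
    variance_explained: pd.DataFrame  # rows = blocks; columns joint/individual/residual
    provenance: dict = field(default_factory=dict)

    @property
    def joint_rank(self) -> int:
        return self.joint.joint_rank

    @property
    def joint_scores(self) -> np.ndarray:
        return self.joint.joint_basis

    @property
    def individual_ranks(self) -> list[int]:
        return [b.individual_rank for b in self.blocks]

    def block(self, name: str) -> BlockDecomposition:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


def _fix_signs(basis: np.ndarray, partner: np.ndarray | None = None):
    """Make each column's largest-magnitude entry positive (reproducible sign)."""
    if basis.size == 0:
        return (basis, partner) if partner is not None else basis
    flips = np.sign(basis[np.abs(basis).argmax(axis=0), np.arange(basis.shape[1])])
    flips[flips == 0] = 1.0
    out = basis * flips
    if partner is not None:
        return out, partner * flips
    return out


def truncated_block_svd(block: OmicsBlock, r_k: int) -> BlockSVD:
    """Phase 1: rank-``r_k`` SVD of a centered, fully observed block.

    The (r_k+1)-th singular value is kept as the block's noise threshold
    (0 when r_k exhausts the spectrum).
    """
    X = block.values
    if np.isnan(X).any():
        raise ValueError(f"block {block.name!r} has missing entries")
    p, n = X.shape
    if not (1 <= r_k < min(p, n)) and r_k != min(p, n):
        if r_k < 1 or r_k > min(p, n):
            raise ValueError(f"initial rank {r_k} out of range for block {block.name!r} ({p}x{n})")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    noise = float(s[r_k]) if r_k < s.size else 0.0
    V, U_r = _fix_signs(Vt[:r_k].T, U[:, :r_k])
    approx = (U_r * s[:r_k]) @ V.T
    return BlockSVD(
        name=block.name,
        rank=r_k,
        left_basis=U_r,
        singular_values=s[:r_k].copy(),
        row_basis=V,
        noise_threshold=noise,
        residual=X - approx,
    )


def stacked_basis_svd(svds: Sequence[BlockSVD]) -> tuple[np.ndarray, np.ndarray]:
    """Phase 2: SVD of the stacked transposed row bases (sum r_k x n).

    Returns the squared singular values (each in [0, K]) and the right
    singular vectors as candidate joint directions, in decreasing order.
    """
    if len(svds) < 2:
        raise ValueError("need at least 2 blocks to define joint structure")
    n = svds[0].n_samples
    for sv in svds[1:]:
        if sv.n_samples != n:
            raise ValueError(
                f"block {sv.name!r} has {sv.n_samples} samples, expected {n}"
            )
    M = np.vstack([sv.row_basis.T for sv in svds])
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    return s**2, Vt.T


def wedin_bound(
    svds: Sequence[BlockSVD],
    n_resample: int = 400,
    seed: int = 0,
    percentile: float = 5.0,
) -> float:
    """Wedin-style perturbation threshold on stacked squared singular values.

    For each block the sine of the largest principal angle between the
    estimated and underlying signal row space is bounded by
    ``max(||E^T U||, ||E V||) / sigma_min`` with ``E`` the discarded part of
    the block; the operator norms are estimated by projecting ``E`` onto
    ``n_resample`` random rank-r_k orthonormal bases. Each draw yields a
    threshold sample ``K - sum_k sin^2(theta_k)``; the given lower
    ``percentile`` of these samples is returned (conservative), clipped to
    [0, K]. Noiseless blocks give exactly K.
    """
    if n_resample < 2:
        raise ValueError("n_resample must be >= 2")
    rng = np.random.default_rng(seed)
    K = len(svds)
    sin2 = np.zeros((n_resample, K))
    for k, sv in enumerate(svds):
        E = sv.residual
        if np.linalg.norm(E) == 0:
            continue
        p, n = E.shape
        r = sv.rank
        sigma_min = sv.singular_values[-1]
        for d in range(n_resample):
            Vr, _ = np.linalg.qr(rng.standard_normal((n, r)))
            Ur, _ = np.linalg.qr(rng.standard_normal((p, r)))
            term_v = np.linalg.norm(E @ Vr, 2)
            term_u = np.linalg.norm(E.T @ Ur, 2)
            sin_hat = min(1.0, max(term_u, term_v) / sigma_min)
            sin2[d, k] = sin_hat**2
    samples = K - sin2.sum(axis=1)
    return float(np.clip(np.percentile(samples, percentile), 0.0, K))


def random_direction_bound(
    ranks: Sequence[int],
    n: int,
    n_draws: int = 400,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Monte-Carlo null threshold for the top stacked squared singular value.

    Draws K independent uniformly-random orthonormal bases of the given
    ranks in dimension ``n``, stacks them and records the largest squared
    singular value; returns the requested quantile over ``n_draws`` draws.
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must lie in (0, 1)")
    for r in ranks:
        if r >= n:
            raise ValueError(f"rank {r} must be < n={n}")
    rng = np.random.default_rng(seed)
    tops = np.empty(n_draws)
    for d in range(n_draws):
        mats = []
        for r in ranks:
            if r == 0:
                continue
            Q, _ = np.linalg.qr(rng.standard_normal((n, r)))
            mats.append(Q.T)
        if not mats:
            tops[d] = 0.0
            continue
        s = np.linalg.svd(np.vstack(mats), compute_uv=False)
        tops[d] = s[0] ** 2
    return float(np.quantile(tops, quantile))


def select_joint_rank(
    squared_svs: np.ndarray,
    t_wedin: float,
    t_random: float,
    rank_cap: int | None = None,
) -> int:
    """Count stacked squared singular values exceeding both thresholds.

    Exceedance is strict, except when the Wedin threshold sits exactly at K
    (noiseless blocks, zero perturbation): perfectly shared directions then
    attain exactly K, so exceedance is evaluated as >= K - 1e-10 there.
    The result is capped at ``rank_cap`` (min of the initial ranks).
    """
    sq = np.asarray(squared_svs, dtype=float)
    threshold = max(t_wedin, t_random)
    r = int((sq > threshold).sum())
    if t_wedin >= t_random:
        # noiseless-tie escape: a zero-perturbation Wedin threshold sits at
        # exactly K, which perfectly shared directions attain but never
        # strictly exceed
        r = max(r, int((sq >= t_wedin - _TIE_TOL).sum()))
    if rank_cap is not None:
        r = min(r, rank_cap)
    return r


def extract_joint(
    blocks: Sequence[OmicsBlock], joint_basis: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Phase 3a: project each block onto the joint basis.

    Returns per block ``(J_k, joint_loadings)`` with ``J_k = X_k V_J V_J^T``
    and loadings ``X_k V_J`` (p_k x r_J).
    """
    out = []
    for b in blocks:
        X = b.values
        if X.shape[1] != joint_basis.shape[0]:
            raise ValueError(
                f"block {b.name!r} has {X.shape[1]} samples, joint basis has "
                f"{joint_basis.shape[0]}"
            )
        loadings = X @ joint_basis
        J = loadings @ joint_basis.T
        out.append((J, loadings))
    return out


def extract_individual(
    X: np.ndarray,
    J: np.ndarray,
    noise_threshold: float,
    joint_basis: np.ndarray,
    max_rank: int | None = None,
) -> tuple[np.ndarray, int, np.ndarray, np.ndarray]:
    """Phase 3b: individual component from the joint-removed remainder.

    ``R = X - J`` is decomposed by SVD; directions with singular value
    strictly above the block's phase-1 noise threshold (floored by a
    machine-precision rank tolerance) form ``I``. The result is re-projected
    off the joint basis so orthogonality holds to machine precision.

    Returns ``(I, individual_rank, scores, loadings)`` with scores the right
    singular vectors scaled by singular values (sample-indexed, ordered by
    decreasing singular value).
    """
    R = X - J
    p, n = R.shape
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    # zero cutoff is relative to the block's scale, not the remainder's: a
    # numerically-zero remainder must yield individual rank 0
    tol = max(p, n) * np.finfo(float).eps * np.linalg.norm(X)
    cut = max(noise_threshold, tol)
    r_i = int((s > cut).sum())
    if max_rank is not None:
        r_i = min(r_i, max_rank)
    if r_i == 0:
        return np.zeros_like(R), 0, np.zeros((n, 0)), np.zeros((p, 0))
    V, U_r = _fix_signs(Vt[:r_i].T, U[:, :r_i])
    I = (U_r * s[:r_i]) @ V.T
    if joint_basis.shape[1]:
        I = I - (I @ joint_basis) @ joint_basis.T
    scores = V * s[:r_i]
    loadings = U_r
    return I, r_i, scores, loadings


def variance_explained(
    decomps: Sequence[BlockDecomposition], originals: Sequence[OmicsBlock]
) -> pd.DataFrame:
    """Per-block proportions ||J||_F^2 / ||X||_F^2 etc.; rows sum to 1."""
    rows = {}
    for d, b in zip(decomps, originals):
        total = float(np.linalg.norm(b.values) ** 2)
        if total == 0:
            raise ValueError(f"block {b.name!r} has zero norm")
        j = float(np.linalg.norm(d.joint) ** 2) / total
        i = float(np.linalg.norm(d.individual) ** 2) / total
        rows[d.name] = {"joint": j, "individual": i, "residual": 1.0 - j - i}
    return pd.DataFrame.from_dict(rows, orient="index")[["joint", "individual", "residual"]]


def ajive(
    collection: MultiOmicsCollection,
    initial_ranks: RankSelectionResult | Sequence[int] | None = None,
    joint_rank: int | None = None,
    n_wedin_samples: int = 400,
    n_random_draws: int = 400,
    random_quantile: float = 0.95,
    wedin_percentile: float = 5.0,
    seed: int = 0,
) -> AjiveResult:
    """Run the full three-phase decomposition on a centered collection.

    Parameters
    ----------
    collection : centered, fully observed blocks on identical samples (K >= 2).
    initial_ranks : per-block phase-1 ranks; ``None`` selects them by profile
        likelihood.
    joint_rank : manual override of the threshold-based joint-rank choice.
    n_wedin_samples, n_random_draws, random_quantile, wedin_percentile, seed :
        threshold estimation controls; the decomposition is deterministic
        given the seed.
    """
    if collection.n_blocks < 2:
        raise ValueError("joint structure undefined for a single block; need K >= 2")
    for b in collection.blocks:
        if b.has_missing:
            raise ValueError(f"block {b.name!r} has missing entries; impute first")

    if initial_ranks is None:
        initial_ranks = select_initial_ranks(collection)
    if isinstance(initial_ranks, RankSelectionResult):
        ranks = list(initial_ranks.initial_ranks)
    else:
        ranks = [int(r) for r in initial_ranks]
    if len(ranks) != collection.n_blocks:
        raise ValueError("one initial rank per block required")

    svds = [truncated_block_svd(b, r) for b, r in zip(collection.blocks, ranks)]
    sq_svs, candidates = stacked_basis_svd(svds)
    t_wedin = wedin_bound(svds, n_resample=n_wedin_samples, seed=seed, percentile=wedin_percentile)
    t_random = random_direction_bound(
        ranks, collection.n_samples, n_draws=n_random_draws, quantile=random_quantile, seed=seed + 1
    )
    rank_cap = min(ranks)
    if joint_rank is None:
        r_J = select_joint_rank(sq_svs, t_wedin, t_random, rank_cap=rank_cap)
    else:
        r_J = min(int(joint_rank), rank_cap)
    V_J = _fix_signs(candidates[:, :r_J])

    joint_parts = extract_joint(collection.blocks, V_J)
    decomps: list[BlockDecomposition] = []
    for b, sv, (J, loadings) in zip(collection.blocks, svds, joint_parts):
        I, r_i, scores, iload = extract_individual(
            b.values, J, sv.noise_threshold, V_J, max_rank=sv.rank
        )
        E = b.values - J - I
        decomps.append(
            BlockDecomposition(
                name=b.name,
                joint=J,
                individual=I,
                residual=E,
                initial_rank=sv.rank,
                individual_rank=r_i,
                noise_threshold=sv.noise_threshold,
                joint_loadings=loadings,
                individual_scores=scores,
                individual_loadings=iload,
            )
        )
    ve = variance_explained(decomps, collection.blocks)
    joint = JointStructure(
        joint_rank=r_J,
        joint_basis=V_J,
        squared_singular_values=sq_svs,
        wedin_threshold=t_wedin,
        random_threshold=t_random,
    )
    logger.info(
        "ajive: initial ranks %s, joint rank %d (wedin %.4f, random %.4f), "
        "individual ranks %s",
        ranks,
        r_J,
        t_wedin,
        t_random,
        [d.individual_rank for d in decomps],
    )
    return AjiveResult(
        joint=joint,
        blocks=decomps,
        variance_explained=ve,
        provenance={
            "initial_ranks": ranks,
            "joint_rank": r_J,
            "wedin_threshold": t_wedin,
            "random_threshold": t_random,
            "seed": seed,
            "n_wedin_samples": n_wedin_samples,
            "n_random_draws": n_random_draws,
            "random_quantile": random_quantile,
            "wedin_percentile": wedin_percentile,
        },
    )


class AJIVE(BaseEstimator):
    """Scikit-learn style estimator for the angle-based JIVE decomposition.

    ``fit`` takes a list of views ``Xs``, each shaped (n_samples,
    n_features_k) on the same samples. Views are feature-mean centered by
    default, then decomposed into joint, individual and residual parts.

    Parameters
    ----------
    initial_ranks : sequence of int or None
        Per-view phase-1 ranks; ``None`` selects them by profile likelihood
        of each view's singular-value scree.
    joint_rank : int or None
        Manual joint-rank override; ``None`` uses the Wedin/random-direction
        thresholds.
    center : bool, default True
        Feature-mean center each view before decomposition.
    random_state : int, default 0
        Seed for the resampling-based thresholds.

    Attributes
    ----------
    joint_rank_ : int
    joint_scores_ : ndarray (n_samples, joint_rank_), orthonormal columns
    individual_ranks_ : list of int
    individual_scores_ : list of ndarray (n_samples, individual_rank_k)
    variance_explained_ : DataFrame with joint/individual/residual proportions
    result_ : AjiveResult with full matrices and provenance
    """

    def __init__(
        self,
        initial_ranks: Sequence[int] | None = None,
        joint_rank: int | None = None,
        center: bool = True,
        n_wedin_samples: int = 400,
        n_random_draws: int = 400,
        random_quantile: float = 0.95,
        wedin_percentile: float = 5.0,
        random_state: int = 0,
    ):
        self.initial_ranks = initial_ranks
        self.joint_rank = joint_rank
        self.center = center
        self.n_wedin_samples = n_wedin_samples
        self.n_random_draws = n_random_draws
        self.random_quantile = random_quantile
        self.wedin_percentile = wedin_percentile
        self.random_state = random_state

    def fit(self, Xs: Sequence[np.ndarray], y=None) -> "AJIVE":
        if len(Xs) < 2:
            raise ValueError("joint structure undefined for a single view; need K >= 2")
        n = np.asarray(Xs[0]).shape[0]
        blocks = []
        for k, X in enumerate(Xs):
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != n:
                raise ValueError(f"view {k} must be 2-D with {n} rows")
            V = X.T.copy()  # store features x samples
            if self.center:
                V = V - V.mean(axis=1, keepdims=True)
            blocks.append(
                OmicsBlock(
                    values=V,
                    feature_ids=[f"v{k}_f{j}" for j in range(V.shape[0])],
                    sample_ids=[str(i) for i in range(n)],
                    name=f"view{k}",
                )
            )
        coll = MultiOmicsCollection(blocks=blocks)
        self.result_ = ajive(
            coll,
            initial_ranks=self.initial_ranks,
            joint_rank=self.joint_rank,
            n_wedin_samples=self.n_wedin_samples,
            n_random_draws=self.n_random_draws,
            random_quantile=self.random_quantile,
            wedin_percentile=self.wedin_percentile,
            seed=self.random_state,
        )
        self.joint_rank_ = self.result_.joint_rank
        self.joint_scores_ = self.result_.joint_scores
        self.individual_ranks_ = self.result_.individual_ranks
        self.individual_scores_ = [b.individual_scores for b in self.result_.blocks]
        self.variance_explained_ = self.result_.variance_explained
        return self

    def fit_transform(self, Xs: Sequence[np.ndarray], y=None) -> np.ndarray:
        """Fit and return concatenated joint and individual sample scores."""
        self.fit(Xs)
        parts = [self.joint_scores_] + self.individual_scores_
        return np.hstack([p for p in parts if p.size] or [np.zeros((len(Xs[0]), 0))])
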