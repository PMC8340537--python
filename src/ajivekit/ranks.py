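"""Initial-rank selection by profile likelihood on the singular-value scree.

For a candidate rank q, the scree ``d_1 >= ... >= d_L`` is split into a
signal group (first q values) and a noise group (the rest). Both groups are
modelled as Gaussian with their own means and a pooled maximum-likelihood
variance; the selected rank maximizes the summed log-density over all
values. This is the automated stand-in for eyeballing a scree-plot elbow:
the likelihood is largest when the split point sits at the biggest, most
consistent gap.

Applied to singular values (not their squares), matching scree-plot
practice. Selection is invariant to rescaling the whole scree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .blocks import MultiOmicsCollection

logger = logging.getLogger(__name__)

__all__ = ["RankSelectionResult", "profile_likelihood_rank", "select_initial_ranks"]


class DegenerateScreeWarning(UserWarning):
    pass


@dataclass
class RankSelectionResult:
    """Chosen initial ranks with the underlying screes and likelihood curves."""

    initial_ranks: list[int]
    block_names: list[str]
    singular_values: list[np.ndarray] = field(default_factory=list)
    profile_loglik: list[np.ndarray] = field(default_factory=list)
    overrides: dict[str, int] = field(default_factory=dict)

    def rank_of(self, name: str) -> int:
        return self.initial_ranks[self.block_names.index(name)]


def profile_likelihood_rank(
    values: Sequence[float], max_rank: int
) -> tuple[int, np.ndarray]:
    """Rank maximizing the two-group pooled-variance Gaussian profile likelihood.

    Parameters
    ----------
    values : descending non-negative singular values, length >= 3.
    max_rank : largest candidate rank, < len(values).

    Returns
    -------
    (rank, curve) where ``curve[q-1]`` is the profile log-likelihood of
    candidate q. Ties go to the smallest q. A flat scree (zero pooled
    variance everywhere) returns rank 1 with a :class:`DegenerateScreeWarning`.
    """
    d = np.asarray(values, dtype=float)
    L = d.size
    if L < 3:
        raise ValueError(f"need at least 3 singular values, got {L}")
    if max_rank < 1 or max_rank >= L:
        raise ValueError(f"max_rank must be in [1, {L - 1}], got {max_rank}")
    if np.any(np.diff(d) > 1e-9 * max(1.0, abs(d[0]))):
        raise ValueError("singular values must be non-increasing")

    curve = np.empty(max_rank)
    degenerate = True
    for q in range(1, max_rank + 1):
        g1, g2 = d[:q], d[q:]
        m1, m2 = g1.mean(), g2.mean()
        ss = ((g1 - m1) ** 2).sum() + ((g2 - m2) ** 2).sum()
        var = ss / L  # pooled MLE variance
        if var <= 0:
            curve[q - 1] = np.inf  # degenerate: perfect two-level fit
            continue
        degenerate = False
        curve[q - 1] = -0.5 * L * (np.log(2 * np.pi * var) + 1.0)
    if not np.isfinite(curve).all():
        finite = np.isfinite(curve)
        if not finite.any() or np.all(d == d[0]):
            warnings.warn(
                "all singular values equal; returning rank 1", DegenerateScreeWarning
            )
            return 1, curve
        # a perfect two-level scree: the infinite-likelihood split wins
        rank = int(np.argmax(curve) + 1)
        return rank, curve
    if degenerate:
        warnings.warn("degenerate scree; returning rank 1", DegenerateScreeWarning)
        return 1, curve
    rank = int(np.argmax(curve) + 1)  # argmax takes the first (smallest q) on ties
    return rank, curve


def select_initial_ranks(
    collection: MultiOmicsCollection,
    max_rank_frac: float = 0.5,
    overrides: Mapping[str, int] | None = None,
) -> RankSelectionResult:
    """Profile-likelihood initial rank for every block of a centered collection.

    ``max_rank`` per block is ``floor(max_rank_frac * min(p_k, n)) - 1``.
    ``overrides`` maps block names to manually fixed ranks (used for
    sensitivity analyses); overridden blocks still report their scree.
    """
    if not (0 < max_rank_frac <= 1):
        raise ValueError("max_rank_frac must lie in (0, 1]")
    overrides = dict(overrides or {})
    unknown = set(overrides) - {b.name for b in collection.blocks}
    if unknown:
        raise KeyError(f"override for unknown block(s): {sorted(unknown)}")

    ranks: list[int] = []
    names: list[str] = []
    svs: list[np.ndarray] = []
    curves: list[np.ndarray] = []
    for block in collection.blocks:
        if block.has_missing:
            raise ValueError(f"block {block.name!r} has missing entries; impute first")
        d = np.linalg.svd(block.values, compute_uv=False)
        max_rank = int(np.floor(max_rank_frac * min(block.values.shape))) - 1
        max_rank = max(1, min(max_rank, d.size - 1))
        try:
            rank, curve = profile_likelihood_rank(d, max_rank)
        except ValueError as exc:
            raise ValueError(f"block {block.name!r}: {exc}") from exc
        if block.name in overrides:
            logger.info(
                "select_initial_ranks: block %r overridden to %d (profile likelihood chose %d)",
                block.name,
                overrides[block.name],
                rank,
            )
            rank = int(overrides[block.name])
        names.append(block.name)
        ranks.append(rank)
        svs.append(d)
        curves.append(curve)
    return RankSelectionResult(
        initial_ranks=ranks,
        block_names=names,
        singular_values=svs,
        profile_loglik=curves,
        overrides=dict(overrides),
    )
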