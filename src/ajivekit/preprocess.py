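"""Per-block filtering, transformation, imputation and centering.

Implements the preprocessing rules of a blood-sample multi-omics workflow:
variance and gene-location feature selection, a missingness filter, the
beta-to-M-value transform with an extreme-M exclusion for methylation,
counts-per-million filtering for sequencing counts, log2 transforms,
iterative-SVD imputation of missing values, and per-feature mean centering
(no variance scaling — the downstream decomposition is insensitive to block
scale heterogeneity).

Every filter is a pure feature-subset operation: the sample set and the
observed values of surviving features are untouched, and each returns a
:class:`FilterReport` whose per-rule counts telescope exactly.

Threshold conventions (all strict): a feature is dropped when its missing
fraction is *more than* ``max_missing_frac``, when its mean CPM is *less
than* ``min_cpm``, and when it has zero counts in *more than*
``max_zero_samples`` samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .blocks import OmicsBlock

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "FilterReport",
    "variance_filter",
    "gene_location_union_filter",
    "missingness_filter",
    "beta_to_mvalue",
    "extreme_mvalue_filter",
    "cpm_filter",
    "log2_transform",
    "svdmiss_impute",
    "SVDImputer",
    "center_features",
    "preprocess_methylation",
    "preprocess_counts",
    "PreprocessError",
    "EmptySelectionError",
]


class PreprocessError(ValueError):
    pass


class EmptySelectionError(PreprocessError):
    """A filter removed every feature."""


@dataclass
class FilterSpec:
    """Filtering thresholds for one block (defaults follow common practice:
    40% missingness cap, |M| bound 3, 1 count-per-million, 5 zero samples)."""

    top_n_variance: int | None = None
    gene_location_set: frozenset[str] | None = None
    max_missing_frac: float = 0.40
    m_value_bound: float = 3.0
    min_cpm: float = 1.0
    max_zero_samples: int = 5
    filter_variant: str = "location_and_variance"

    def __post_init__(self) -> None:
        if self.max_missing_frac < 0 or self.max_missing_frac > 1:
            raise PreprocessError("max_missing_frac must lie in [0, 1]")
        for name in ("m_value_bound", "min_cpm"):
            if getattr(self, name) <= 0:
                raise PreprocessError(f"{name} must be positive")
        if self.max_zero_samples < 0:
            raise PreprocessError("max_zero_samples must be non-negative")
        if self.filter_variant not in ("location_and_variance", "location_only", "variance_only"):
            raise PreprocessError(f"unknown filter_variant {self.filter_variant!r}")


@dataclass
class FilterReport:
    """Ordered record of applied rules; counts telescope at every step."""

    block_name: str
    steps: list[dict] = field(default_factory=list)

    def add(self, rule: str, n_in: int, n_removed: int, **extra) -> None:
        step = {"rule": rule, "n_in": n_in, "n_removed": n_removed, "n_out": n_in - n_removed}
        step.update(extra)
        if self.steps and self.steps[-1]["n_out"] != n_in:
            raise PreprocessError(
                f"filter report for {self.block_name!r}: counts do not telescope at {rule!r}"
            )
        self.steps.append(step)
        logger.info(
            "%s | %s: %d -> %d (-%d)", self.block_name, rule, n_in, n_in - n_removed, n_removed
        )

    @property
    def final_count(self) -> int:
        return self.steps[-1]["n_out"] if self.steps else 0

    def merged(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport(self.block_name, list(self.steps))
        for s in other.steps:
            out.add(s["rule"], s["n_in"], s["n_removed"])
        return out


def _observed_variance(values: np.ndarray) -> np.ndarray:
    """Per-feature sample variance over observed entries (ddof=1)."""
    with np.errstate(invalid="ignore"):
        return np.asarray(np.nanvar(values, axis=1, ddof=1))


def variance_filter(block: OmicsBlock, top_n: int) -> tuple[OmicsBlock, FilterReport]:
    """Keep the ``top_n`` features with highest sample variance.

    Variance is computed over observed entries; ties for the last slot go to
    the lexicographically smaller feature id. Original sample order is kept.
    """
    p = block.n_features
    if top_n > p:
        raise PreprocessError(f"top_n={top_n} exceeds feature count {p}")
    var = _observed_variance(block.values)
    order = sorted(range(p), key=lambda i: (-var[i], block.feature_ids[i]))
    keep = {block.feature_ids[i] for i in order[:top_n]}
    out = block.subset_features(keep)
    report = FilterReport(block.name)
    report.add("variance_top_n", p, p - top_n, top_n=top_n)
    return out, report


def gene_location_union_filter(
    cpg_block: OmicsBlock,
    cpg_to_gene: Mapping[str, Iterable[str] | str],
    selected_genes: Iterable[str],
    extra_top_n: int,
    variant: str = "location_and_variance",
) -> tuple[OmicsBlock, FilterReport]:
    """Select CpGs by gene location, by variance, or by the union of both.

    ``location_and_variance`` keeps the union of CpGs mapped to
    ``selected_genes`` and the ``extra_top_n`` highest-variance CpGs;
    ``location_only`` and ``variance_only`` keep one set alone. CpGs absent
    from the mapping count as not located on any selected gene.
    """
    genes = set(selected_genes)
    p = cpg_block.n_features

    def mapped_genes(cpg: str) -> set[str]:
        g = cpg_to_gene.get(cpg)
        if g is None:
            return set()
        if isinstance(g, str):
            return {g}
        return set(g)

    loc_set = {f for f in cpg_block.feature_ids if mapped_genes(f) & genes}
    var_set: set[str] = set()
    if variant in ("location_and_variance", "variance_only"):
        n_var = min(extra_top_n, p)
        var = _observed_variance(cpg_block.values)
        order = sorted(range(p), key=lambda i: (-var[i], cpg_block.feature_ids[i]))
        var_set = {cpg_block.feature_ids[i] for i in order[:n_var]}

    if variant == "location_and_variance":
        keep = loc_set | var_set
    elif variant == "location_only":
        keep = loc_set
    elif variant == "variance_only":
        keep = var_set
    else:
        raise PreprocessError(f"unknown variant {variant!r}")
    if not keep:
        raise EmptySelectionError(
            f"gene_location_union_filter({variant}) selected no CpGs in block {cpg_block.name!r}"
        )
    out = cpg_block.subset_features(keep)
    report = FilterReport(cpg_block.name)
    report.add(
        f"gene_location_union[{variant}]",
        p,
        p - len(keep),
        n_location=len(loc_set),
        n_variance=len(var_set),
        n_overlap=len(loc_set & var_set),
    )
    return out, report


def missingness_filter(
    block: OmicsBlock, max_missing_frac: float = 0.40
) -> tuple[OmicsBlock, FilterReport]:
    """Drop features missing in strictly more than ``max_missing_frac`` of samples."""
    p, n = block.values.shape
    miss = np.isnan(block.values).sum(axis=1) / n
    keep = [f for f, m in zip(block.feature_ids, miss) if m <= max_missing_frac]
    out = block.subset_features(keep)
    report = FilterReport(block.name)
    report.add("missingness", p, p - len(keep), max_missing_frac=max_missing_frac)
    return out, report


def beta_to_mvalue(block: OmicsBlock, clip: float = 1e-6) -> OmicsBlock:
    """Entrywise M = log2(beta / (1 - beta)); betas at exactly 0/1 are clipped.

    Strictly monotone in beta and antisymmetric about beta = 0.5. Missing
    entries stay missing.
    """
    if block.assay_kind != "methylation_beta":
        raise PreprocessError(f"beta_to_mvalue expects methylation_beta, got {block.assay_kind!r}")
    v = block.values
    obs = ~np.isnan(v)
    if ((v[obs] < 0) | (v[obs] > 1)).any():
        raise PreprocessError(f"block {block.name!r}: beta values outside [0, 1]")
    b = np.clip(v, clip, 1.0 - clip)
    m = np.where(obs, np.log2(b / (1.0 - b)), np.nan)
    return replace(block, values=m, assay_kind="methylation_m")


def extreme_mvalue_filter(
    block: OmicsBlock, bound: float = 3.0, rule: str = "mean_abs"
) -> tuple[OmicsBlock, FilterReport]:
    """Drop CpGs with extreme M-values (|M| above ``bound``).

    ``rule="mean_abs"`` (default) excludes a CpG when the mean of |M| over
    its observed samples exceeds the bound; ``rule="any"`` excludes when any
    observed |M| exceeds it.
    """
    if block.assay_kind != "methylation_m":
        raise PreprocessError(
            f"extreme_mvalue_filter expects methylation_m, got {block.assay_kind!r}"
        )
    absm = np.abs(block.values)
    with np.errstate(invalid="ignore"):
        if rule == "mean_abs":
            stat = np.nanmean(absm, axis=1)
        elif rule == "any":
            stat = np.nanmax(absm, axis=1)
        else:
            raise PreprocessError(f"unknown extreme-M rule {rule!r}")
    p = block.n_features
    keep = [f for f, s in zip(block.feature_ids, stat) if not (s > bound)]
    out = block.subset_features(keep)
    report = FilterReport(block.name)
    report.add(f"extreme_mvalue[{rule}]", p, p - len(keep), bound=bound)
    return out, report


def cpm_filter(
    block: OmicsBlock, min_cpm: float = 1.0, max_zero_samples: int = 5
) -> tuple[OmicsBlock, FilterReport]:
    """Counts-per-million filter for sequencing-count blocks.

    CPM of an entry is its count divided by the sample's library size times
    1e6. A feature is removed when its mean CPM across samples is strictly
    below ``min_cpm``, then remaining features with zero counts in strictly
    more than ``max_zero_samples`` samples are removed.
    """
    if block.assay_kind != "counts":
        raise PreprocessError(f"cpm_filter expects counts, got {block.assay_kind!r}")
    v = block.values
    lib = np.nansum(v, axis=0)
    if (lib <= 0).any():
        bad = block.sample_ids[int(np.argmax(lib <= 0))]
        raise PreprocessError(f"sample {bad!r} has zero library size")
    cpm = v / lib[np.newaxis, :] * 1e6
    with np.errstate(invalid="ignore"):
        mean_cpm = np.nanmean(cpm, axis=1)
    p = block.n_features
    keep1 = [f for f, c in zip(block.feature_ids, mean_cpm) if not (c < min_cpm)]
    step1 = block.subset_features(keep1)
    report = FilterReport(block.name)
    report.add("cpm_min", p, p - len(keep1), min_cpm=min_cpm)

    zeros = np.nansum(step1.values == 0, axis=1)
    keep2 = [f for f, z in zip(step1.feature_ids, zeros) if z <= max_zero_samples]
    out = step1.subset_features(keep2)
    report.add("zero_samples", len(keep1), len(keep1) - len(keep2), max_zero_samples=max_zero_samples)
    return out, report


def log2_transform(block: OmicsBlock, offset: float = 1.0) -> OmicsBlock:
    """Entrywise log2(value + offset); result is tagged ``expression_log``."""
    v = block.values
    obs = ~np.isnan(v)
    if ((v[obs] + offset) <= 0).any():
        raise PreprocessError(
            f"block {block.name!r}: non-positive value at offset {offset}; cannot log2"
        )
    out = np.where(obs, np.log2(np.where(obs, v, 1.0) + offset), np.nan)
    return replace(block, values=out, assay_kind="expression_log")


def svdmiss_impute(
    block: OmicsBlock, rank: int = 10, tol: float = 1e-6, max_iter: int = 200
) -> OmicsBlock:
    """Iterative truncated-SVD imputation of missing entries.

    Missing entries are initialized with feature means, then repeatedly
    overwritten by a rank-``rank`` SVD approximation of the completed matrix
    until the relative Frobenius change of the imputed entries drops below
    ``tol``. Observed entries are never altered. Non-convergence logs a
    warning and returns the last iterate.
    """
    imputer = SVDImputer(rank=rank, tol=tol, max_iter=max_iter)
    completed = imputer.fit_transform(block.values)
    if imputer.n_iter_ >= max_iter and not imputer.converged_:
        logger.warning(
            "svdmiss_impute: block %r did not converge in %d iterations (last change %.3g)",
            block.name,
            max_iter,
            imputer.last_change_,
        )
    else:
        logger.info(
            "svdmiss_impute: block %r converged in %d iterations", block.name, imputer.n_iter_
        )
    return replace(block, values=completed)


class SVDImputer:
    """Scikit-learn style transformer for iterative-SVD matrix completion.

    Parameters
    ----------
    rank : int
        Truncation rank of the SVD approximation (clamped to matrix dims).
    tol : float
        Convergence tolerance on the relative Frobenius change of the
        imputed entries between successive iterations.
    max_iter : int
        Iteration cap.

    Attributes
    ----------
    n_iter_ : int
        Iterations performed (0 when the input had no missing entries).
    converged_ : bool
    last_change_ : float
    """

    def __init__(self, rank: int = 10, tol: float = 1e-6, max_iter: int = 200):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"rank": self.rank, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "SVDImputer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "SVDImputer":
        self.fit_transform(X)
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        self.n_iter_ = 0
        self.converged_ = True
        self.last_change_ = 0.0
        if not mask.any():
            return X.copy()
        if mask.all(axis=1).any():
            raise PreprocessError("a row has no observed entries; cannot impute")
        if mask.all(axis=0).any():
            raise PreprocessError("a column has no observed entries; cannot impute")
        r = int(min(self.rank, min(X.shape)))
        row_means = np.nanmean(X, axis=1)
        filled = np.where(mask, row_means[:, None], X)
        prev = filled[mask]
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            U, s, Vt = np.linalg.svd(filled, full_matrices=False)
            approx = (U[:, :r] * s[:r]) @ Vt[:r]
            filled = np.where(mask, approx, X)
            cur = filled[mask]
            denom = np.linalg.norm(cur)
            change = np.linalg.norm(cur - prev) / (denom if denom > 0 else 1.0)
            self.n_iter_ = it
            self.last_change_ = float(change)
            prev = cur
            if change < self.tol:
                self.converged_ = True
                break
        return filled


def center_features(block: OmicsBlock) -> OmicsBlock:
    """Subtract each feature's mean; no variance scaling. Idempotent."""
    if block.has_missing:
        raise PreprocessError(
            f"block {block.name!r} has missing entries; impute before centering"
        )
    v = block.values
    return replace(block, values=v - v.mean(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# Canonical per-assay pipelines. Order fixed as: feature selection ->
# missingness filter -> M-value transform -> extreme-M filter -> imputation
# -> centering (methylation); CPM filter -> log2 -> centering (counts).
# ---------------------------------------------------------------------------

def preprocess_methylation(
    block: OmicsBlock,
    spec: FilterSpec,
    cpg_to_gene: Mapping[str, Iterable[str] | str] | None = None,
    selected_genes: Iterable[str] | None = None,
    impute_rank: int = 10,
) -> tuple[OmicsBlock, FilterReport]:
    """Full methylation path from beta values to centered M-values."""
    report = FilterReport(block.name)
    if cpg_to_gene is not None and selected_genes is not None:
        block, rep = gene_location_union_filter(
            block,
            cpg_to_gene,
            selected_genes,
            extra_top_n=spec.top_n_variance or 0,
            variant=spec.filter_variant,
        )
        report = report.merged(rep)
    elif spec.top_n_variance is not None:
        block, rep = variance_filter(block, spec.top_n_variance)
        report = report.merged(rep)
    block, rep = missingness_filter(block, spec.max_missing_frac)
    report = report.merged(rep)
    if block.assay_kind == "methylation_beta":
        block = beta_to_mvalue(block)
    block, rep = extreme_mvalue_filter(block, spec.m_value_bound)
    report = report.merged(rep)
    if block.has_missing:
        block = svdmiss_impute(block, rank=impute_rank)
    return center_features(block), report


def preprocess_counts(
    block: OmicsBlock, spec: FilterSpec, log_offset: float = 1.0
) -> tuple[OmicsBlock, FilterReport]:
    """Counts path: CPM filter, log2(count + offset), centering."""
    block, report = cpm_filter(block, spec.min_cpm, spec.max_zero_samples)
    block = log2_transform(block, offset=log_offset)
    if block.has_missing:
        block = svdmiss_impute(block)
    return center_features(block), report
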