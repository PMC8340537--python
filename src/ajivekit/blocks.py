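"""Multi-omics data containers and TSV input/output.

A *block* is one omics measurement matrix, stored features x samples: rows
are variables (CpGs, transcripts, miRNAs), columns are study subjects. All
blocks in a collection share one ordered sample set, so subspace comparisons
across blocks happen in the common sample-indexed space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSAY_KINDS = frozenset(
    {"methylation_beta", "methylation_m", "expression_log", "expression_raw", "counts"}
)


class BlockValidationError(ValueError):
    """Raised when a block violates its structural invariants."""


class AlignmentError(ValueError):
    """Raised when blocks/covariates cannot be placed on a common sample set."""


@dataclass
class OmicsBlock:
    """One feature-by-sample omics matrix.

    Parameters
    ----------
    values : ndarray of shape (p, n)
        Measurements, features as rows. ``NaN`` marks a missing entry.
    feature_ids, sample_ids : sequences of unique strings
        Row and column identifiers.
    name : str
        Human-readable block name (e.g. ``"methylation"``).
    assay_kind : str
        One of ``methylation_beta``, ``methylation_m``, ``expression_log``,
        ``expression_raw``, ``counts``. Counts blocks must hold non-negative
        integers wherever observed.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    name: str = "block"
    assay_kind: str = "expression_log"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise BlockValidationError(f"block {self.name!r}: values must be 2-D")
        p, n = self.values.shape
        if len(self.feature_ids) != p:
            raise BlockValidationError(
                f"block {self.name!r}: {len(self.feature_ids)} feature ids for {p} rows"
            )
        if len(self.sample_ids) != n:
            raise BlockValidationError(
                f"block {self.name!r}: {len(self.sample_ids)} sample ids for {n} columns"
            )
        dup_f = _first_duplicate(self.feature_ids)
        if dup_f is not None:
            raise BlockValidationError(f"block {self.name!r}: duplicate feature id {dup_f!r}")
        dup_s = _first_duplicate(self.sample_ids)
        if dup_s is not None:
            raise BlockValidationError(f"block {self.name!r}: duplicate sample id {dup_s!r}")
        if self.assay_kind not in ASSAY_KINDS:
            raise BlockValidationError(
                f"block {self.name!r}: unknown assay_kind {self.assay_kind!r}"
            )
        if self.assay_kind == "counts":
            obs = self.values[~np.isnan(self.values)]
            if obs.size and ((obs < 0).any() or (obs != np.round(obs)).any()):
                raise BlockValidationError(
                    f"block {self.name!r}: counts block has negative or non-integer entries"
                )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_features(self, keep_ids: Sequence[str]) -> "OmicsBlock":
        """Return a new block restricted to ``keep_ids``, in original row order."""
        keep = set(keep_ids)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep]
        return replace(
            self,
            values=self.values[idx, :].copy(),
            feature_ids=[self.feature_ids[i] for i in idx],
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise AlignmentError(
                f"block {self.name!r}: sample {exc.args[0]!r} not present"
            ) from None
        return replace(
            self, values=self.values[:, idx].copy(), sample_ids=[str(s) for s in sample_ids]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class MultiOmicsCollection:
    """K blocks on an identical ordered sample set plus covariates and outcome.

    ``covariates`` is a samples x covariates table indexed by sample id;
    ``outcome`` is a sample-indexed series (binary 0/1 or small-cardinality
    categorical labels).
    """

    blocks: list[OmicsBlock]
    covariates: pd.DataFrame | None = None
    outcome: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise BlockValidationError("collection needs at least one block")
        ref = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if b.sample_ids != ref:
                raise AlignmentError(
                    f"block {b.name!r} sample ids differ from block {self.blocks[0].name!r}; "
                    "use align_samples first"
                )
        if self.covariates is not None:
            if list(map(str, self.covariates.index)) != ref:
                raise AlignmentError("covariate table index differs from block sample ids")
        if self.outcome is not None:
            if list(map(str, self.outcome.index)) != ref:
                raise AlignmentError("outcome index differs from block sample ids")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.blocks[0].n_samples

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


# ---------------------------------------------------------------------------
# TSV input/output. Canonical on-disk format: features as rows, first column
# holds the feature id, header row holds sample ids. Empty cells are missing.
# ---------------------------------------------------------------------------

def read_block(path: str | Path, assay_kind: str, name: str | None = None) -> OmicsBlock:
    """Read a TSV/CSV matrix into a validated :class:`OmicsBlock`.

    Raises a parse error with row/column coordinates for non-numeric cells,
    and rejects duplicate feature or sample ids.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise BlockValidationError(f"{path}: duplicate sample id {dup!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise BlockValidationError(f"{path}: duplicate feature id {dup!r}")
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        raw = df[col]
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise BlockValidationError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}"
            )
        values[:, j] = parsed.to_numpy()
    return OmicsBlock(
        values=values,
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        name=name or path.stem,
        assay_kind=assay_kind,
    )


def write_block(block: OmicsBlock, path: str | Path) -> None:
    """Write a block as TSV (features x samples); missing entries as empty cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    block.to_frame().to_csv(path, sep="\t", index_label="feature_id", na_rep="")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sample-indexed covariate/outcome table (first column = sample id)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.map(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise BlockValidationError(f"{path}: duplicate sample id {dup!r}")
    return df


def align_samples(
    blocks: Sequence[OmicsBlock],
    covariates: pd.DataFrame | None = None,
    outcome: pd.Series | None = None,
) -> MultiOmicsCollection:
    """Restrict blocks (and covariates/outcome) to their common samples.

    The intersection of sample ids is taken across all inputs and placed in
    canonical sorted order; dropped samples are logged per source. An empty
    intersection raises :class:`AlignmentError`.
    """
    common: set[str] = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    if covariates is not None:
        common &= set(map(str, covariates.index))
    if outcome is not None:
        common &= set(map(str, outcome.index))
    if not common:
        raise AlignmentError("no samples shared by all inputs")
    order = sorted(common)
    for b in blocks:
        dropped = set(b.sample_ids) - common
        if dropped:
            logger.info("align_samples: dropped %d samples from block %r", len(dropped), b.name)
    aligned = [b.reorder_samples(order) for b in blocks]
    cov = None
    if covariates is not None:
        cov = covariates.copy()
        cov.index = cov.index.map(str)
        cov = cov.loc[order]
    out = None
    if outcome is not None:
        out = outcome.copy()
        out.index = out.index.map(str)
        out = out.loc[order]
    return MultiOmicsCollection(blocks=aligned, covariates=cov, outcome=out)
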