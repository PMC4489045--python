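"""Normalization, log-scale variance propagation, count conversion and the
coefficient-of-variation filter.

FPKM estimates are depth-normalized with median-of-ratios size factors, zeros
are offset before the natural-log transform, and the per-sample estimation
uncertainty is carried to the log scale by the delta method:
``Var[log Y] ~= se(Y)^2 / Y^2``.  Isoforms whose normalized FPKM is too
variable within either group (CV > 0.4 by default) are excluded because the
delta approximation degrades when the SE is large relative to the estimate.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ExpressionTable


@dataclass(frozen=True)
class FilterConfig:
    """CV-filter threshold and the offset added to zero FPKM before log."""

    cv_threshold: float = 0.4
    zero_offset: float = 1e-4

    def __post_init__(self) -> None:
        if not self.cv_threshold > 0:
            raise ValueError("cv_threshold must be positive")
        if not self.zero_offset > 0:
            raise ValueError("zero_offset must be positive")


@dataclass
class MetaRegressionProblem:
    """One isoform's log-expression observations with known within-sample
    variances and a fixed-effects design matrix.

    ``design`` has a leading all-ones intercept column; ``coef_of_interest``
    indexes the column being tested (normally the group indicator).
    """

    log_y: np.ndarray
    within_var: np.ndarray
    design: np.ndarray
    coef_of_interest: int = 1

    def __post_init__(self) -> None:
        self.log_y = np.asarray(self.log_y, dtype=float)
        self.within_var = np.asarray(self.within_var, dtype=float)
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        n, p = self.design.shape
        if self.log_y.shape != (n,) or self.within_var.shape != (n,):
            raise ValueError("log_y, within_var and design rows must all have length n")
        if not np.all(np.isfinite(self.log_y)):
            raise ValueError("log_y contains non-finite values")
        if not np.all(np.isfinite(self.within_var)) or np.any(self.within_var < 0):
            raise ValueError("within_var must be finite and non-negative")
        if not np.allclose(self.design[:, 0], 1.0):
            raise ValueError("design must have a leading all-ones intercept column")
        if n <= p:
            raise ValueError(f"need n > p, got n={n}, p={p}")
        if np.linalg.matrix_rank(self.design) < p:
            raise ValueError("design matrix is rank deficient")
        if not 0 <= self.coef_of_interest < p:
            raise ValueError("coef_of_interest out of range")

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def p(self) -> int:
        return self.design.shape[1]


def compute_size_factors(fpkm: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factor per sample.

    The reference for isoform *i* is its geometric mean across samples; the
    size factor for sample *j* is the median of ``fpkm[i, j] / ref_i`` over
    isoforms with all-positive values (rows containing a zero are excluded
    because their geometric mean vanishes).
    """
    fpkm = np.atleast_2d(np.asarray(fpkm, dtype=float))
    positive = np.all(fpkm > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no isoform has positive FPKM in every sample; size factors are "
            "undefined - skip normalization for this dataset"
        )
    sub = fpkm[positive]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    return np.median(sub / ref[:, None], axis=0)


def normalize_expression(table: ExpressionTable, size_factors: np.ndarray) -> ExpressionTable:
    """Divide FPKM and SE columns by per-sample size factors.

    SEs scale linearly because dividing an estimate by a constant divides its
    standard error by the same constant.
    """
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape != (table.n_samples,):
        raise ValueError("need exactly one size factor per sample")
    if np.any(size_factors <= 0) or not np.all(np.isfinite(size_factors)):
        raise ValueError("size factors must be positive and finite")
    return ExpressionTable(
        isoform_ids=list(table.isoform_ids),
        fpkm=table.fpkm / size_factors,
        fpkm_se=table.fpkm_se / size_factors,
        transcript_length=table.transcript_length.copy(),
        mapped_reads=table.mapped_reads.copy(),
        sample_ids=list(table.sample_ids),
    )


def fpkm_to_count(fpkm, mapped_reads, length):
    """Expected fragment count implied by an FPKM value.

    ``count = round(FPKM * N * L / 1e9)`` with N the sample's mapped reads and
    L the transcript length in bp; rounded to the nearest integer for
    count-based consumers.
    """
    fpkm = np.asarray(fpkm, dtype=float)
    if np.any(~np.isfinite(fpkm)) or np.any(fpkm < 0):
        raise ValueError("fpkm must be finite and non-negative")
    if np.any(np.asarray(mapped_reads) <= 0) or np.any(np.asarray(length) <= 0):
        raise ValueError("mapped_reads and length must be positive")
    count = np.rint(fpkm * np.asarray(mapped_reads) * np.asarray(length) / 1e9)
    out = count.astype(np.int64)
    return out if out.ndim else int(out)


def apply_zero_offset(fpkm, zero_offset: float = 1e-4):
    """Replace exact zeros by ``zero_offset``; positive values pass through."""
    if not zero_offset > 0:
        raise ValueError("zero_offset must be positive")
    fpkm = np.asarray(fpkm, dtype=float)
    return np.where(fpkm == 0, zero_offset, fpkm)


def log_transform(fpkm, zero_offset: float = 1e-4):
    """Natural log of FPKM, with exact zeros replaced by ``zero_offset``."""
    fpkm = np.asarray(fpkm, dtype=float)
    if np.any(fpkm < 0):
        raise ValueError("fpkm must be non-negative")
    out = np.log(apply_zero_offset(fpkm, zero_offset))
    return out if out.ndim else float(out)


def delta_method_log_variance(fpkm_se, fpkm):
    """Delta-method variance of log(Y): ``se(Y)^2 / Y^2``.

    The observed (normalized, offset-adjusted) value stands in for E(Y); the
    offset must have been applied first so Y > 0.
    """
    fpkm = np.asarray(fpkm, dtype=float)
    fpkm_se = np.asarray(fpkm_se, dtype=float)
    if np.any(fpkm <= 0):
        raise ValueError("fpkm must be positive (apply the zero offset first)")
    if np.any(fpkm_se < 0):
        raise ValueError("fpkm_se must be non-negative")
    out = (fpkm_se / fpkm) ** 2
    return out if out.ndim else float(out)


@dataclass
class CVFilterResult:
    """Keep flags plus the per-group CVs behind them.

    ``cv`` has shape ``(n_isoforms, 2)`` with columns ordered by group code
    (0, 1); entries are NaN where the group mean is zero.
    """

    keep: np.ndarray
    cv: np.ndarray


def cv_filter(
    normalized_fpkm: np.ndarray,
    group: np.ndarray,
    config: FilterConfig = FilterConfig(),
) -> CVFilterResult:
    """Flag isoforms whose within-group CV exceeds the threshold.

    CV = sample SD (n-1 denominator) / mean of normalized FPKM, computed
    separately in each group; an isoform is kept iff CV <= threshold in BOTH
    groups.  Isoforms with zero mean in either group are dropped (CV
    undefined).
    """
    fpkm = np.atleast_2d(np.asarray(normalized_fpkm, dtype=float))
    group = np.asarray(group, dtype=int)
    if group.shape != (fpkm.shape[1],):
        raise ValueError("group must have one entry per sample")
    cv = np.full((fpkm.shape[0], 2), np.nan)
    keep = np.ones(fpkm.shape[0], dtype=bool)
    for g in (0, 1):
        sub = fpkm[:, group == g]
        if sub.shape[1] < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        ok = mean > 0
        cv[ok, g] = sd[ok] / mean[ok]
        keep &= ok & (np.where(ok, cv[:, g], np.inf) <= config.cv_threshold)
    return CVFilterResult(keep=keep, cv=cv)
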