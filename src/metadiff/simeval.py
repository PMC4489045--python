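"""Synthetic expression-estimate data and evaluation metrics.

The generator emulates a two-group RNA-seq isoform study at the level of the
expression estimates themselves: per-isoform baseline abundance from a
log-normal law, a 1.25-fold group effect for 30 % of isoforms (half up, half
down in cases), optional covariate/confounder structure, biological
replicate noise e ~ N(0, tau^2), and estimation noise u ~ N(0, sigma2_i)
whose variance shrinks with the isoform's expected fragment count.  Reported
FPKM is exp(truth + e + u) and the reported SE is the value the delta method
inverts back to sigma_i, so the statistical structure the meta-regression
assumes holds exactly on the log scale.

Three scenarios:

* I   - no covariate.
* II  - a covariate (uniform 18-60 in both groups, think "age") raises
        expression of 10 % of isoforms by 1.35-fold per covariate SD.
* III - same effect, but the covariate is a confounder: uniform(40, 85) in
        cases vs uniform(18, 60) in controls.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionTable, PhenotypeTable


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults follow the simulated study design: 16 cases vs 16 controls,
    30 % DE at 1.25-fold (half up / half down), sequencing depth uniform on
    8-12 million reads, 10 % of isoforms covariate-affected at 1.35-fold per
    covariate SD in Scenarios II/III.
    """

    n_cases: int = 16
    n_controls: int = 16
    n_isoforms: int = 2000
    frac_de: float = 0.30
    fold_change: float = 1.25
    scenario: str = "I"
    frac_cov_affected: float = 0.10
    cov_fold_per_sd: float = 1.35
    cov_range_controls: tuple[float, float] = (18.0, 60.0)
    cov_range_cases: tuple[float, float] | None = None
    depth_range: tuple[float, float] = (8e6, 12e6)
    tau_range: tuple[float, float] = (0.1, 0.4)
    uncertainty_scale: float = 1.0
    log_fpkm_mean: float = math.log(20.0)
    log_fpkm_sd: float = 1.0
    length_log_mean: float = math.log(1800.0)
    length_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("I", "II", "III"):
            raise ValueError("scenario must be 'I', 'II' or 'III'")
        if min(self.n_cases, self.n_controls, self.n_isoforms) <= 0:
            raise ValueError("sample and isoform counts must be positive")
        for name in ("frac_de", "frac_cov_affected"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fold_change <= 0 or self.cov_fold_per_sd <= 0:
            raise ValueError("fold changes must be positive")
        if self.cov_range_cases is None:
            self.cov_range_cases = (
                (40.0, 85.0) if self.scenario == "III" else self.cov_range_controls
            )
        for name in ("cov_range_controls", "cov_range_cases", "depth_range", "tau_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered interval")
        if self.uncertainty_scale <= 0:
            raise ValueError("uncertainty_scale must be positive")


@dataclass
class SimulatedDataset:
    """Expression + phenotype tables plus the per-isoform ground truth."""

    expr: ExpressionTable
    pheno: PhenotypeTable
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def covariate_per_unit_effect(fold_per_sd: float, range_lo: float, range_hi: float) -> float:
    """Percent expression increase per covariate unit implied by a
    fold-per-SD effect, for a uniform(range_lo, range_hi) covariate.

    The uniform SD is (hi - lo)/sqrt(12); e.g. 1.35-fold per SD over
    uniform(18, 60) is a 2.5 % increase per unit.
    """
    if not range_hi > range_lo:
        raise ValueError("range_hi must exceed range_lo")
    if fold_per_sd <= 0:
        raise ValueError("fold_per_sd must be positive")
    sd = (range_hi - range_lo) / math.sqrt(12.0)
    return 100.0 * (fold_per_sd ** (1.0 / sd) - 1.0)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one synthetic dataset; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_isoforms
    n_samples = config.n_controls + config.n_cases
    # controls first; cases carry the fold-change (group coded control=0)
    x = np.concatenate(
        [np.zeros(config.n_controls), np.ones(config.n_cases)]
    )
    sample_ids = [f"ctrl{j + 1:03d}" for j in range(config.n_controls)] + [
        f"case{j + 1:03d}" for j in range(config.n_cases)
    ]

    # -- truth bookkeeping: DE flags, directions, covariate-affected flags
    n_de = round(config.frac_de * n)
    n_up = n_de // 2
    order = rng.permutation(n)
    de_idx = order[:n_de]
    direction = np.zeros(n, dtype=int)
    direction[de_idx[:n_up]] = 1
    direction[de_idx[n_up:]] = -1
    de = direction != 0

    cov_affected = np.zeros(n, dtype=bool)
    has_covariate = config.scenario in ("II", "III")
    if has_covariate:
        n_cov = round(config.frac_cov_affected * n)
        n_cov_de = n_cov // 2
        non_de_idx = order[n_de:]
        cov_affected[rng.choice(de_idx, size=min(n_cov_de, de_idx.size), replace=False)] = True
        cov_affected[
            rng.choice(non_de_idx, size=min(n_cov - n_cov_de, non_de_idx.size), replace=False)
        ] = True

    # -- covariate values and the per-unit log slope (anchored to the
    #    control range so II and III share the same effect size)
    if has_covariate:
        z = np.empty(n_samples)
        z[x == 0] = rng.uniform(*config.cov_range_controls, size=config.n_controls)
        z[x == 1] = rng.uniform(*config.cov_range_cases, size=config.n_cases)
        lo, hi = config.cov_range_controls
        slope = math.log(config.cov_fold_per_sd) / ((hi - lo) / math.sqrt(12.0))
    else:
        z = np.zeros(n_samples)
        slope = 0.0

    lengths = np.clip(
        np.rint(rng.lognormal(config.length_log_mean, config.length_log_sd, size=n)),
        200, 50_000,
    ).astype(np.int64)
    depths = rng.integers(
        int(config.depth_range[0]), int(config.depth_range[1]), size=n_samples
    )

    baseline = rng.normal(config.log_fpkm_mean, config.log_fpkm_sd, size=n)
    tau = rng.uniform(*config.tau_range, size=n)
    beta1 = direction * math.log(config.fold_change)
    cov_slope = np.where(cov_affected, slope, 0.0)

    mean_log = (
        baseline[:, None]
        + beta1[:, None] * x[None, :]
        + cov_slope[:, None] * z[None, :]
    )
    e = rng.standard_normal((n, n_samples)) * tau[:, None]
    true_log = mean_log + e
    expected_count = np.exp(true_log) * depths[None, :] * lengths[:, None] / 1e9
    sigma2 = np.clip(config.uncertainty_scale / (expected_count + 1.0), 1e-6, 4.0)
    u = rng.standard_normal((n, n_samples)) * np.sqrt(sigma2)
    fpkm = np.exp(true_log + u)
    fpkm_se = fpkm * np.sqrt(sigma2)  # delta method inverts this exactly

    isoform_ids = [f"iso{k + 1:05d}" for k in range(n)]
    expr = ExpressionTable(
        isoform_ids=isoform_ids,
        fpkm=fpkm,
        fpkm_se=fpkm_se,
        transcript_length=lengths,
        mapped_reads=depths,
        sample_ids=sample_ids,
    )
    covariates = pd.DataFrame(index=sample_ids)
    if has_covariate:
        covariates["z"] = z
    pheno = PhenotypeTable(
        sample_ids=sample_ids,
        group=x.astype(int),
        covariates=covariates,
        group_labels={"control": 0, "case": 1},
    )
    truth = pd.DataFrame(
        {
            "isoform_id": isoform_ids,
            "de": de,
            "direction": direction,
            "cov_affected": cov_affected,
            "baseline_log_fpkm": baseline,
            "tau": tau,
            "beta1": beta1,
            "cov_slope": cov_slope,
        }
    )
    return SimulatedDataset(expr=expr, pheno=pheno, truth=truth, config=config)


# ---------------------------------------------------------------------------
# evaluation metrics


def _as_bool(a, name: str) -> np.ndarray:
    return np.asarray(a, dtype=bool)


def empirical_fdr(calls, truth) -> float:
    """Fraction of truly non-DE isoforms among those called DE.

    Returns 0.0 when nothing is called (documented convention).
    """
    calls = _as_bool(calls, "calls")
    truth = _as_bool(truth, "truth")
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    positives = int(calls.sum())
    false_pos = int((calls & ~truth).sum())
    return false_pos / max(1, positives)


def power_estimate(calls, truth, restrict_to=None) -> float:
    """Fraction of true DE isoforms called DE, optionally within a mask
    (e.g. only covariate-affected true DE isoforms)."""
    calls = _as_bool(calls, "calls")
    truth = _as_bool(truth, "truth")
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    mask = np.ones_like(truth) if restrict_to is None else _as_bool(restrict_to, "restrict_to")
    if mask.shape != truth.shape:
        raise ValueError("restrict_to must have equal length")
    denom = int((truth & mask).sum())
    if denom == 0:
        raise ValueError("no true DE isoforms in the evaluation set")
    return int((calls & truth & mask).sum()) / denom


def roc_points(pvalues, truth) -> list[tuple[float, float]]:
    """(sensitivity, specificity) pairs over all distinct p-value cutoffs.

    A call is p <= cutoff.  The no-call endpoint (0, 1) and the all-call
    endpoint (1, 0) are always included.
    """
    p = np.asarray(pvalues, dtype=float)
    truth = _as_bool(truth, "truth")
    if p.shape != truth.shape:
        raise ValueError("pvalues and truth must have equal length")
    if np.isnan(p).any():
        raise ValueError("pvalues contain NaN")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both classes")
    points = [(0.0, 1.0)]
    for cut in np.unique(p):
        calls = p <= cut
        sens = int((calls & truth).sum()) / n_pos
        spec = int((~calls & ~truth).sum()) / n_neg
        points.append((sens, spec))
    if points[-1] != (1.0, 0.0):
        points.append((1.0, 0.0))
    # drop consecutive duplicates while keeping threshold order
    out = [points[0]]
    for pt in points[1:]:
        if pt != out[-1]:
            out.append(pt)
    return out
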