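"""Per-isoform differential-expression orchestration.

normalize -> offset/log -> delta-method variances -> CV filter -> per-isoform
ML fit with the requested tests -> Benjamini-Hochberg adjustment over the
tested isoforms (each test type adjusted separately).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import metareg
from .io import DEResultTable, ExpressionTable, PhenotypeTable, RESULT_COLUMNS
from .preprocess import (
    FilterConfig,
    MetaRegressionProblem,
    apply_zero_offset,
    compute_size_factors,
    cv_filter,
    delta_method_log_variance,
    log_transform,
    normalize_expression,
)

logger = logging.getLogger(__name__)

_TEST_CHOICES = ("t", "bclr", "both")


@dataclass
class AnalysisConfig:
    """Knobs for one differential-expression run.

    ``test`` selects the Wald t-test, the Bartlett-corrected LR test, or
    both; ``fdr_level`` is the nominal FDR for the strict ``q < level`` DE
    call; ``n_boot`` sizes the parametric bootstrap behind the Bartlett
    correction factor; ``seed`` makes the bootstrap deterministic.
    """

    test: str = "both"
    fdr_level: float = 0.05
    cv_threshold: float = 0.4
    zero_offset: float = 1e-4
    normalize: bool = True
    covariate_cols: tuple[str, ...] = ()
    bcf_method: str = "bootstrap"
    n_boot: int = 1000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.test not in _TEST_CHOICES:
            raise ValueError(f"test must be one of {_TEST_CHOICES}")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")
        self.covariate_cols = tuple(self.covariate_cols)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def declare_de(qvalues, level: float) -> np.ndarray:
    """DE flags: q-value strictly below the nominal FDR level."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    q = np.asarray(qvalues, dtype=float)
    return q < level


def _isoform_seed(base_seed: int, index: int) -> int:
    # deterministic per-isoform stream for the bootstrap, independent of
    # which other isoforms were filtered
    return int((base_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1))


def run_differential_analysis(
    expr: ExpressionTable,
    pheno: PhenotypeTable,
    config: AnalysisConfig = AnalysisConfig(),
) -> DEResultTable:
    """Test every isoform for differential expression between two groups.

    Isoforms failing the CV filter carry a filter flag and no statistics;
    isoforms whose fit does not converge are flagged and excluded from the
    BH adjustment.  Fully deterministic for fixed inputs and config.
    """
    pheno = pheno.reordered(expr.sample_ids)
    group = pheno.group
    for g in (0, 1):
        if (group == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    missing = [c for c in config.covariate_cols if c not in pheno.covariates.columns]
    if missing:
        raise ValueError(f"covariate columns not in phenotype table: {missing}")
    Z = pheno.covariates[list(config.covariate_cols)].to_numpy(dtype=float)
    n = expr.n_samples
    p = 2 + Z.shape[1]
    if n <= p:
        raise ValueError(f"need more than {p} samples to fit {p} coefficients, got {n}")
    design = np.column_stack([np.ones(n), group.astype(float), Z])

    if config.normalize:
        factors = compute_size_factors(expr.fpkm)
        table = normalize_expression(expr, factors)
    else:
        table = expr

    fpkm_adj = apply_zero_offset(table.fpkm, config.zero_offset)
    log_y = log_transform(table.fpkm, config.zero_offset)
    within_var = delta_method_log_variance(table.fpkm_se, fpkm_adj)

    filt = cv_filter(table.fpkm, group, FilterConfig(config.cv_threshold, config.zero_offset))
    if not filt.keep.any():
        logger.warning("CV filter removed every isoform; returning empty result")

    want_t = config.test in ("t", "both")
    want_bclr = config.test in ("bclr", "both")

    rows: list[dict] = []
    for i, iso in enumerate(expr.isoform_ids):
        row: dict = {c: np.nan for c in RESULT_COLUMNS}
        row["isoform_id"] = iso
        row["filtered"] = False
        row["filter_reason"] = np.nan
        row["converged"] = np.nan
        if not filt.keep[i]:
            row["filtered"] = True
            if np.isnan(filt.cv[i]).any():
                row["filter_reason"] = "zero group mean"
            else:
                row["filter_reason"] = (
                    f"CV>{config.cv_threshold:g} "
                    f"(group0={filt.cv[i, 0]:.3f}, group1={filt.cv[i, 1]:.3f})"
                )
            rows.append(row)
            continue
        problem = MetaRegressionProblem(
            log_y=log_y[i], within_var=within_var[i], design=design, coef_of_interest=1
        )
        try:
            full = metareg.fit_random_effects_ml(problem)
            if not full.converged:
                raise metareg.ConvergenceError("full fit did not converge")
            row["converged"] = True
            row["beta1_hat"] = float(full.beta_hat[1])
            row["tau2_hat"] = full.tau2_hat
            if want_t:
                t_res = metareg.t_test(full, 1)
                row["t_stat"] = t_res.statistic
                row["t_pvalue"] = t_res.pvalue
            if want_bclr:
                null = metareg.fit_random_effects_ml(metareg._null_problem(problem, 1))
                if not null.converged:
                    raise metareg.ConvergenceError("null fit did not converge")
                lr = 2.0 * (full.loglik - null.loglik)
                if lr < -1e-6:
                    raise metareg.ConvergenceError("negative LR beyond tolerance")
                lr = max(lr, 0.0)
                bcf = metareg.bartlett_correction_factor(
                    problem,
                    tau2_hat=null.tau2_hat,
                    coef_index=1,
                    method=config.bcf_method,
                    n_boot=config.n_boot,
                    seed=_isoform_seed(config.seed, i),
                )
                bclr = metareg.bclr_test(lr, bcf)
                row["bclr_stat"] = bclr.statistic
                row["bclr_pvalue"] = bclr.pvalue
                row["bcf"] = bcf
        except (metareg.ConvergenceError, metareg.SingularDesignError) as exc:
            logger.warning("isoform %s: fit failed (%s); excluded from FDR", iso, exc)
            row["converged"] = False
            for col in (
                "beta1_hat", "tau2_hat", "t_stat", "t_pvalue", "bclr_stat",
                "bclr_pvalue", "bcf",
            ):
                row[col] = np.nan
        rows.append(row)

    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    for dcol in ("t_de", "bclr_de"):
        df[dcol] = df[dcol].astype(object)
    for test, on in (("t", want_t), ("bclr", want_bclr)):
        pcol, qcol, dcol = f"{test}_pvalue", f"{test}_qvalue", f"{test}_de"
        tested = df[pcol].notna()
        if on and tested.any():
            q = bh_adjust(df.loc[tested, pcol].to_numpy())
            df.loc[tested, qcol] = q
            df.loc[tested, dcol] = list(declare_de(q, config.fdr_level))
    df["filtered"] = df["filtered"].astype(bool)
    return DEResultTable(df)
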