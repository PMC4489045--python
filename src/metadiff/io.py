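"""Tabular data model and file I/O.

Expression estimates arrive either as a pair of generic isoforms-by-samples
TSV matrices (FPKM values and their standard errors) or as per-sample
Cufflinks ``isoforms.fpkm_tracking`` files.  Phenotype information is a TSV
with one row per sample.  Results are written as a flat TSV that round-trips
losslessly through :func:`read_results`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: two-sided 95 % normal quantile used to convert CI half-widths to SEs
Z95 = 1.959964


class ValidationError(ValueError):
    """An in-memory table violates one of its invariants."""


class ParseError(ValueError):
    """A file could not be interpreted as the declared dialect."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ExpressionTable:
    """Isoforms-by-samples FPKM matrix with matching standard errors.

    Parameters
    ----------
    isoform_ids : unique isoform/transcript identifiers (rows).
    fpkm : non-negative matrix of estimated FPKM values, shape
        ``(n_isoforms, n_samples)``.
    fpkm_se : standard errors of the FPKM estimates, same shape.
    transcript_length : transcript length in bp per isoform.
    mapped_reads : total mapped reads per sample.
    sample_ids : unique sample identifiers (columns).
    """

    isoform_ids: list[str]
    fpkm: np.ndarray
    fpkm_se: np.ndarray
    transcript_length: np.ndarray
    mapped_reads: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.isoform_ids = _check_unique(self.isoform_ids, "isoform ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.fpkm = np.atleast_2d(np.asarray(self.fpkm, dtype=float))
        self.fpkm_se = np.atleast_2d(np.asarray(self.fpkm_se, dtype=float))
        self.transcript_length = np.asarray(self.transcript_length)
        self.mapped_reads = np.asarray(self.mapped_reads)
        ni, ns = len(self.isoform_ids), len(self.sample_ids)
        if self.fpkm.shape != (ni, ns):
            raise ValidationError(
                f"fpkm matrix shape {self.fpkm.shape} does not match "
                f"{ni} isoforms x {ns} samples"
            )
        if self.fpkm_se.shape != self.fpkm.shape:
            raise ValidationError(
                f"fpkm_se shape {self.fpkm_se.shape} differs from fpkm "
                f"shape {self.fpkm.shape}"
            )
        for name, mat in (("fpkm", self.fpkm), ("fpkm_se", self.fpkm_se)):
            bad = ~np.isfinite(mat) | (mat < 0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"{name} contains a non-finite or negative entry at "
                    f"isoform {self.isoform_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {mat[i, j]!r}"
                )
        if self.transcript_length.shape != (ni,):
            raise ValidationError("transcript_length must have one entry per isoform")
        if self.mapped_reads.shape != (ns,):
            raise ValidationError("mapped_reads must have one entry per sample")
        if not np.all(np.isfinite(self.transcript_length.astype(float))) or np.any(
            self.transcript_length <= 0
        ):
            raise ValidationError("transcript_length entries must be positive")
        if not np.all(np.isfinite(self.mapped_reads.astype(float))) or np.any(
            self.mapped_reads <= 0
        ):
            raise ValidationError("mapped_reads entries must be positive")
        self.transcript_length = self.transcript_length.astype(np.int64)
        self.mapped_reads = self.mapped_reads.astype(np.int64)

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class PhenotypeTable:
    """Per-sample group indicator and optional real-valued covariates."""

    sample_ids: list[str]
    group: np.ndarray
    covariates: pd.DataFrame
    group_labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.group = np.asarray(self.group, dtype=int)
        if self.group.shape != (len(self.sample_ids),):
            raise ValidationError("group must have one entry per sample")
        if not set(np.unique(self.group)) <= {0, 1}:
            raise ValidationError("group must be coded 0/1")
        if len(np.unique(self.group)) != 2:
            raise ValidationError("group must take exactly two values")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=self.sample_ids)
        if len(self.covariates) != len(self.sample_ids):
            raise ValidationError("covariates must have one row per sample")
        if self.covariates.shape[1] and not np.isfinite(
            self.covariates.to_numpy(dtype=float)
        ).all():
            raise ValidationError("covariates contain missing or non-finite values")

    def reordered(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        """Return a copy with rows aligned to ``sample_ids``."""
        if set(sample_ids) != set(self.sample_ids):
            missing = sorted(set(sample_ids) - set(self.sample_ids))
            raise ValidationError(f"phenotype is missing samples: {missing[:5]}")
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        order = [pos[s] for s in sample_ids]
        return PhenotypeTable(
            sample_ids=list(sample_ids),
            group=self.group[order],
            covariates=self.covariates.iloc[order],
            group_labels=dict(self.group_labels),
        )


RESULT_COLUMNS = [
    "isoform_id",
    "filtered",
    "filter_reason",
    "converged",
    "beta1_hat",
    "tau2_hat",
    "t_stat",
    "t_pvalue",
    "t_qvalue",
    "t_de",
    "bclr_stat",
    "bclr_pvalue",
    "bclr_qvalue",
    "bclr_de",
    "bcf",
]

_FLOAT_RESULT_COLS = [
    "beta1_hat",
    "tau2_hat",
    "t_stat",
    "t_pvalue",
    "t_qvalue",
    "bclr_stat",
    "bclr_pvalue",
    "bclr_qvalue",
    "bcf",
]
_STAT_RESULT_COLS = [c for c in _FLOAT_RESULT_COLS] + ["t_de", "bclr_de"]


@dataclass
class DEResultTable:
    """Per-isoform differential-expression results.

    ``table`` has the fixed column order :data:`RESULT_COLUMNS`; filtered rows
    carry only the filter flag/reason, all statistic columns are NA.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"result table is missing columns: {missing}")
        self.table = self.table[RESULT_COLUMNS].reset_index(drop=True)
        _check_unique(self.table["isoform_id"], "isoform ids")
        for test in ("t", "bclr"):
            for col in (f"{test}_pvalue", f"{test}_qvalue"):
                vals = self.table[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValidationError(f"{col} outside [0, 1]")
            both = self.table[[f"{test}_pvalue", f"{test}_qvalue"]].dropna()
            if (both[f"{test}_qvalue"] < both[f"{test}_pvalue"] - 1e-12).any():
                raise ValidationError(f"{test} q-values must be >= p-values")
        filt = self.table["filtered"].astype(bool)
        if filt.any() and self.table.loc[filt, _STAT_RESULT_COLS].notna().any().any():
            raise ValidationError("filtered rows must not carry test statistics")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers


def _read_matrix_tsv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{what} matrix at {path} has no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{what} matrix at {path} is not numeric: {exc}") from exc
    return df


def _read_two_column(path: str | Path, what: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{what} file at {path} needs id and value columns")
    ser = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    return ser


def _read_cufflinks_tracking(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["tracking_id", "length", "FPKM", "FPKM_conf_lo", "FPKM_conf_hi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path} lacks tracking columns {missing}")
    df = df[required].copy()
    df["tracking_id"] = df["tracking_id"].astype(str)
    if df["tracking_id"].duplicated().any():
        dup = df.loc[df["tracking_id"].duplicated(), "tracking_id"].iloc[0]
        raise ParseError(f"{path} has duplicate tracking_id {dup!r}")
    if (df["FPKM_conf_hi"] < df["FPKM_conf_lo"]).any():
        bad = df.loc[df["FPKM_conf_hi"] < df["FPKM_conf_lo"], "tracking_id"].iloc[0]
        raise ParseError(f"{path}: FPKM_conf_hi < FPKM_conf_lo for {bad!r}")
    # symmetric 95% normal CI assumption; asymmetric bounds are averaged
    df["se"] = (df["FPKM_conf_hi"] - df["FPKM_conf_lo"]) / (2.0 * Z95)
    upper = df["FPKM_conf_hi"] - df["FPKM"]
    lower = df["FPKM"] - df["FPKM_conf_lo"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lower > 0, upper / lower, 1.0)
    worst = float(np.nanmax(np.abs(np.log(np.where(ratio > 0, ratio, 1.0)))))
    if worst > 0.01:
        logger.info(
            "%s: confidence bounds asymmetric (max |log hi/lo half-width "
            "ratio| = %.3f); half-widths averaged", path, worst
        )
    return df.set_index("tracking_id")


def _cufflinks_sample_files(fpkm_path: str | Path) -> list[tuple[str, Path]]:
    p = Path(fpkm_path)
    if p.is_dir():
        files = sorted(p.glob("*.fpkm_tracking"))
        if not files:
            raise ParseError(f"no *.fpkm_tracking files found in {p}")
        return [(f.name[: -len(".fpkm_tracking")], f) for f in files]
    manifest = pd.read_csv(p, sep="\t")
    if manifest.shape[1] < 2:
        raise ParseError(
            f"{p} is neither a directory nor a two-column manifest "
            "(sample_id, tracking file path)"
        )
    return [
        (str(row.iloc[0]), Path(str(row.iloc[1])))
        for _, row in manifest.iterrows()
    ]


def read_expression_table(
    fpkm_path: str | Path,
    se_path: str | Path | None,
    lengths_path: str | Path | None,
    reads_path: str | Path,
    dialect: str = "generic_tsv",
) -> ExpressionTable:
    """Read an :class:`ExpressionTable` from disk.

    ``dialect="generic_tsv"``: ``fpkm_path`` and ``se_path`` are
    isoforms-by-samples TSV matrices (first column = isoform id, header =
    sample ids) with identical labels; ``lengths_path`` maps isoform id to
    transcript length; ``reads_path`` maps sample id to mapped-read total.

    ``dialect="cufflinks_tracking"``: ``fpkm_path`` is a directory of
    ``<sample>.fpkm_tracking`` files (or a manifest TSV of sample id, path);
    SEs are recovered from the 95 % confidence bounds as
    ``(conf_hi - conf_lo) / (2 * 1.959964)`` and lengths come from the
    tracking files, so ``se_path``/``lengths_path`` must be None.
    """
    if dialect == "generic_tsv":
        if se_path is None or lengths_path is None:
            raise ParseError("generic_tsv requires se_path and lengths_path")
        fpkm = _read_matrix_tsv(fpkm_path, "FPKM")
        se = _read_matrix_tsv(se_path, "SE")
        if list(se.columns) != list(fpkm.columns):
            raise ParseError(
                "FPKM and SE sample columns differ "
                f"(first mismatch: {sorted(set(fpkm.columns) ^ set(se.columns))[:3]})"
            )
        if list(se.index) != list(fpkm.index):
            raise ParseError(
                "FPKM and SE isoform rows differ "
                f"(first mismatch: {sorted(set(fpkm.index) ^ set(se.index))[:3]})"
            )
        lengths = _read_two_column(lengths_path, "lengths")
        missing = [i for i in fpkm.index if i not in lengths.index]
        if missing:
            raise ParseError(f"isoforms missing a transcript length: {missing[:5]}")
        lengths = lengths.loc[fpkm.index]
    elif dialect == "cufflinks_tracking":
        if se_path is not None:
            raise ParseError("cufflinks_tracking derives SEs itself; se_path must be None")
        samples = _cufflinks_sample_files(fpkm_path)
        per_sample = {sid: _read_cufflinks_tracking(path) for sid, path in samples}
        first_sid = samples[0][0]
        index = per_sample[first_sid].index
        for sid, df in per_sample.items():
            if not df.index.equals(index):
                extra = sorted(set(df.index) ^ set(index))
                raise ParseError(
                    f"sample {sid!r} tracks different isoforms than "
                    f"{first_sid!r} (e.g. {extra[:3]})"
                )
        fpkm = pd.DataFrame({sid: per_sample[sid]["FPKM"] for sid, _ in samples})
        se = pd.DataFrame({sid: per_sample[sid]["se"] for sid, _ in samples})
        lengths = per_sample[first_sid]["length"]
        if lengths.isna().any():
            missing = list(lengths.index[lengths.isna()])
            raise ParseError(f"isoforms missing a transcript length: {missing[:5]}")
    else:
        raise ParseError(f"unknown dialect {dialect!r}")

    reads = _read_two_column(reads_path, "mapped reads")
    missing = [s for s in fpkm.columns if s not in reads.index]
    if missing:
        raise ParseError(f"samples missing a mapped-read total: {missing[:5]}")
    reads = reads.loc[list(fpkm.columns)]

    return ExpressionTable(
        isoform_ids=list(fpkm.index),
        fpkm=fpkm.to_numpy(),
        fpkm_se=se.to_numpy(),
        transcript_length=lengths.to_numpy(),
        mapped_reads=reads.to_numpy(),
        sample_ids=list(fpkm.columns),
    )


def read_phenotype_table(
    path: str | Path,
    group_col: str,
    covariate_cols: Sequence[str] = (),
    group_levels: tuple[str, str] | None = None,
) -> PhenotypeTable:
    """Read sample phenotype/covariate data.

    The first column is the sample id.  The group column must take exactly
    two values; by default the lexicographically smaller label is coded 0
    (logged), which ``group_levels=(ref, alt)`` overrides.
    """
    df = pd.read_csv(path, sep="\t")
    if group_col not in df.columns:
        raise ParseError(f"group column {group_col!r} not found in {path}")
    missing_cov = [c for c in covariate_cols if c not in df.columns]
    if missing_cov:
        raise ParseError(f"covariate columns not found: {missing_cov}")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    group_raw = df[group_col].astype(str)
    if group_raw.isna().any() or df[list(covariate_cols)].isna().any().any():
        raise ValidationError(f"{path} contains missing values")
    levels = sorted(group_raw.unique())
    if len(levels) != 2:
        raise ValidationError(
            f"group column {group_col!r} must have exactly 2 levels, got {levels}"
        )
    if group_levels is not None:
        if sorted(group_levels) != levels:
            raise ValidationError(
                f"group_levels {group_levels} do not match observed levels {levels}"
            )
        levels = list(group_levels)
    mapping = {levels[0]: 0, levels[1]: 1}
    logger.info("group coding for %r: %s", group_col, mapping)
    covariates = df[list(covariate_cols)].astype(float)
    covariates.index = sample_ids
    return PhenotypeTable(
        sample_ids=sample_ids,
        group=group_raw.map(mapping).to_numpy(),
        covariates=covariates,
        group_labels=mapping,
    )


# ---------------------------------------------------------------------------
# writers


def write_results(results: DEResultTable, path: str | Path) -> None:
    """Write a result table as TSV with NA for missing statistics."""
    results.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def _parse_bool(col: pd.Series) -> pd.Series:
    return col.map({"True": True, "False": False, True: True, False: False})


def read_results(path: str | Path) -> DEResultTable:
    """Read back a TSV produced by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    df["isoform_id"] = df["isoform_id"].astype(str)
    df["filtered"] = _parse_bool(df["filtered"]).astype(bool)
    df["converged"] = _parse_bool(df["converged"]).astype("boolean")
    for col in ("t_de", "bclr_de"):
        df[col] = _parse_bool(df[col]).astype("boolean")
    df["filter_reason"] = df["filter_reason"].replace("", np.nan)
    for col in _FLOAT_RESULT_COLS:
        df[col] = pd.to_numeric(df[col])
    return DEResultTable(df)


def write_expression_table(
    table: ExpressionTable,
    fpkm_path: str | Path,
    se_path: str | Path,
    lengths_path: str | Path,
    reads_path: str | Path,
) -> None:
    """Write a table in the generic TSV dialect (inverse of the reader)."""
    idx = pd.Index(table.isoform_ids, name="isoform_id")
    pd.DataFrame(table.fpkm, index=idx, columns=table.sample_ids).to_csv(
        fpkm_path, sep="\t"
    )
    pd.DataFrame(table.fpkm_se, index=idx, columns=table.sample_ids).to_csv(
        se_path, sep="\t"
    )
    pd.DataFrame(
        {"isoform_id": table.isoform_ids, "length": table.transcript_length}
    ).to_csv(lengths_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": table.sample_ids, "mapped_reads": table.mapped_reads}
    ).to_csv(reads_path, sep="\t", index=False)


def write_phenotype_table(
    pheno: PhenotypeTable, path: str | Path, group_col: str = "status"
) -> None:
    inverse = {v: k for k, v in pheno.group_labels.items()} or {0: "0", 1: "1"}
    df = pd.DataFrame({"sample_id": pheno.sample_ids})
    df[group_col] = [inverse[g] for g in pheno.group]
    for col in pheno.covariates.columns:
        df[col] = pheno.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)
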