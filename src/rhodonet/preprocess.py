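"""Normalization and aggregation applied before network construction.

The transcriptomics route is: probe aggregation -> log2 -> replicate
averaging -> robust z-scores (MADs from the median).  The proteomics route
is: central-tendency (column median) normalization -> z-scores -> removal
of proteins with too many missing values.  Robust z uses the unscaled MAD
(no 1.4826 consistency factor): the score is literally the number of median
absolute deviations away from the median.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import ExprMatrix, SampleSheet, ValidationError


class StandardizedResult(NamedTuple):
    matrix: ExprMatrix
    degenerate_genes: list  # zero-MAD / zero-sd rows, zeroed and flagged


class FilterResult(NamedTuple):
    matrix: ExprMatrix
    removed_genes: list


class AggregationResult(NamedTuple):
    matrix: ExprMatrix
    dropped_multi_probes: list  # probes hitting >1 gene, discarded


def aggregate_probes(values: pd.DataFrame, sheet: SampleSheet) -> AggregationResult:
    """Collapse a probe-by-sample matrix to gene level.

    Probes mapping to more than one gene are discarded; genes measured by
    several remaining probes get the per-sample mean across those probes.
    """
    if sheet.probe_map is None:
        raise ValidationError("aggregate_probes requires a probe->gene map")
    pm = sheet.probe_map
    counts = pm.groupby("probe")["gene"].nunique()
    multi = sorted(counts.index[counts > 1])
    keep = pm[~pm["probe"].isin(multi)]
    keep = keep[keep["probe"].isin(values.index)]
    if keep.empty:
        raise ValidationError("no probes left after discarding multi-gene probes")
    sub = values.loc[keep["probe"]]
    sub.index = pd.Index(keep["gene"].to_numpy(), name="gene")
    agg = sub.groupby(level=0, sort=True).mean()
    return AggregationResult(ExprMatrix(agg, standardization="raw"), multi)


def log2_and_average(expr: ExprMatrix, sheet: SampleSheet) -> ExprMatrix:
    """log2-transform (if still on linear scale) and average replicates.

    Columns are grouped by the sample sheet's condition assignment; the
    output has one column per condition, tagged ``averaged``.  Already
    log2-scaled input is not transformed a second time.
    """
    data = expr.data
    if expr.standardization == "raw":
        bad = data.le(0) | ~np.isfinite(data)
        if bad.to_numpy().any():
            g = data.index[bad.any(axis=1)][0]
            s = data.columns[bad.loc[g]][0]
            raise ValidationError(
                f"non-positive value for gene {g!r}, sample {s!r}: cannot log2"
            )
        data = np.log2(data)
    elif expr.standardization not in ("log2",):
        raise ValidationError(
            f"log2_and_average expects raw or log2 input, got {expr.standardization!r}"
        )
    missing = [s for s in data.columns if s not in sheet.samples.index]
    if missing:
        raise ValidationError(f"samples absent from sample sheet: {missing[:5]}")
    cond = data.columns.map(sheet.samples["condition"])
    averaged = data.T.groupby(cond.to_numpy()).mean().T
    # keep condition order of first appearance in the sheet
    order = [c for c in sheet.conditions if c in averaged.columns]
    averaged = averaged[order]
    return ExprMatrix(averaged, standardization="averaged")


def _check_min_observed(data: pd.DataFrame, min_obs: int = 3) -> None:
    obs = data.notna().sum(axis=1)
    bad = sorted(data.index[obs < min_obs])
    if bad:
        raise ValidationError(
            f"rows with fewer than {min_obs} observed values: {bad}"
        )


def robust_z(expr: ExprMatrix) -> StandardizedResult:
    """Per-gene robust z-score: (x - median) / MAD with unscaled MAD.

    Rows whose MAD is zero carry no usable scale and are set to all-zero;
    their ids are returned (and warned about) so downstream correlation can
    treat them specially rather than dropping them from the gene universe.
    """
    data = expr.data
    _check_min_observed(data)
    X = data.to_numpy(dtype=float)
    med = np.nanmedian(X, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(X - med), axis=1, keepdims=True)
    zero = (mad == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - med) / mad
    Z[zero] = 0.0
    Z[np.isnan(X)] = np.nan
    flagged = sorted(data.index[zero])
    if flagged:
        warnings.warn(
            f"{len(flagged)} gene(s) with MAD=0 zeroed: {flagged[:5]}",
            stacklevel=2,
        )
    out = pd.DataFrame(Z, index=data.index, columns=data.columns)
    return StandardizedResult(ExprMatrix(out, standardization="robust_z"), flagged)


def zscore(expr: ExprMatrix) -> StandardizedResult:
    """Per-gene z-score over observed entries (sample sd, divisor n-1)."""
    data = expr.data
    _check_min_observed(data)
    X = data.to_numpy(dtype=float)
    mean = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    zero = (sd == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - mean) / sd
    Z[zero] = 0.0
    Z[np.isnan(X)] = np.nan
    flagged = sorted(data.index[zero])
    if flagged:
        warnings.warn(
            f"{len(flagged)} gene(s) with sd=0 zeroed: {flagged[:5]}", stacklevel=2
        )
    out = pd.DataFrame(Z, index=data.index, columns=data.columns)
    return StandardizedResult(ExprMatrix(out, standardization="z"), flagged)


def central_tendency_normalize(expr: ExprMatrix) -> ExprMatrix:
    """Subtract each condition column's median (central-tendency normalization).

    Missing entries are ignored when computing the median and preserved in
    the output.  Intended for log-scale abundance matrices.
    """
    data = expr.data
    all_missing = sorted(data.columns[data.isna().all(axis=0)])
    if all_missing:
        raise ValidationError(f"all-missing condition column(s): {all_missing}")
    centered = data - data.median(axis=0, skipna=True)
    return ExprMatrix(centered, standardization=expr.standardization)


def filter_missing(expr: ExprMatrix, max_missing: int = 2) -> FilterResult:
    """Drop rows with more than ``max_missing`` missing entries.

    The boundary is strict ("more than"): a row with exactly ``max_missing``
    missing values is retained.  Retained values are never altered.
    """
    data = expr.data
    n_missing = data.isna().sum(axis=1)
    keep = n_missing <= max_missing
    removed = sorted(data.index[~keep])
    if not keep.any():
        warnings.warn("filter_missing removed every row", stacklevel=2)
    out = replace(expr, data=data.loc[keep].copy())
    return FilterResult(out, removed)
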