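"""LOWESS intensity normalization and two-group differential expression.

The expression matrix holds log2 net signals (probes x samples, missing
allowed where a probe was not detectable).  Normalization removes the
intensity-dependent bias of each sample against a reference signal — by
default the per-probe mean across all samples ("mean-array"), which reduces
the two-channel design of spotted arrays to a channel-agnostic multi-sample
scheme.  For each sample a LOWESS curve of M = sample - reference on
A = (sample + reference)/2 is fitted over the probes shared with the
reference and subtracted, the classic MA-plot detrending.

Differential expression is a per-probe two-sample t-test on log2 values with
a deliberately relaxed significance cutoff (default p <= 0.1) and no
multiple-testing gate, so that true positives are not excluded at the cost
of a known ~10% false-positive rate among null probes; a Benjamini-Hochberg
FDR column is emitted for reference but never drives the up/down calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

MIN_SHARED_PROBES = 20


class NormalizationError(ValueError):
    """Raised when a sample cannot be normalized; names the sample."""


def expression_from_summaries(probe_summaries: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Build a log2 expression matrix from QC probe summaries.

    A cell is filled with log2(mean good-spot net signal) where the probe
    was detectable on that sample, and left missing otherwise.  Returns the
    matrix and a sample -> group label mapping.
    """
    det = probe_summaries[probe_summaries["detectable"] & probe_summaries["mean_signal"].notna()]
    mat = det.pivot(index="probe_id", columns="sample_id", values="mean_signal")
    mat = np.log2(mat)
    all_samples = probe_summaries[["sample_id", "group"]].drop_duplicates()
    groups = all_samples.set_index("sample_id")["group"]
    mat = mat.reindex(columns=groups.index.tolist())
    return mat, groups


def lowess_normalize(
    matrix: pd.DataFrame,
    span: float = 0.3,
    reference: str = "mean-array",
) -> pd.DataFrame:
    """Remove per-sample intensity-dependent bias by LOWESS detrending.

    Parameters
    ----------
    matrix
        Probes x samples log2 matrix; NaN marks undetectable cells.
    span
        LOWESS smoothing fraction (fraction of shared probes in each local
        fit window).
    reference
        ``"mean-array"`` (per-probe mean over all samples) or the name of a
        sample column to normalize against.
    """
    if matrix.shape[1] < 2:
        raise NormalizationError("need at least two samples to normalize")
    if reference == "mean-array":
        ref = matrix.mean(axis=1, skipna=True)
    elif reference in matrix.columns:
        ref = matrix[reference]
    else:
        raise NormalizationError(f"unknown reference {reference!r}")
    out = matrix.copy()
    for sample in matrix.columns:
        col = matrix[sample]
        shared = col.notna() & ref.notna()
        if int(shared.sum()) < MIN_SHARED_PROBES:
            raise NormalizationError(
                f"sample {sample!r} shares only {int(shared.sum())} probes with the "
                f"reference (need >= {MIN_SHARED_PROBES})")
        m = (col[shared] - ref[shared]).to_numpy()
        a = ((col[shared] + ref[shared]) / 2.0).to_numpy()
        trend = lowess(m, a, frac=span, return_sorted=False)
        out.loc[shared, sample] = col[shared].to_numpy() - trend
    return out


@dataclass
class DESummary:
    """Up/down/total counts of significant probes."""

    n_up: int
    n_down: int

    @property
    def n_total_de(self) -> int:
        return self.n_up + self.n_down


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    p_cutoff: float = 0.1,
    equal_var: bool = False,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-probe two-group t-test on log2 values with direction calls.

    Parameters
    ----------
    matrix
        Probes x samples log2 expression, missing allowed.
    groups
        Sample -> group label mapping; exactly two labels.
    p_cutoff
        Significance threshold for calling a direction (default 0.1).
    equal_var
        ``False`` (default) for the Welch unequal-variance test, ``True``
        for the pooled-variance Student test.
    group_order
        (baseline, comparison); log2_ratio is comparison minus baseline.
        Defaults to sorted label order, which puts "immature" before
        "mature" under the default labels.

    Returns a DataFrame with one row per probe: group means, log2_ratio,
    p_value, BH-adjusted q_value, direction in {up, down, ns, untestable}
    and the sample counts used.  Probes with fewer than two non-missing
    values in either group are reported untestable, not silently dropped.
    """
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"groups must have exactly two labels, got {labels}")
    if group_order is not None:
        if sorted(group_order) != labels:
            raise ValueError(f"group_order {group_order} does not match labels {labels}")
        base, comp = group_order
    else:
        base, comp = labels
    cols_base = groups.index[groups == base]
    cols_comp = groups.index[groups == comp]

    rows = []
    for probe_id, row in matrix.iterrows():
        x = row[cols_base].dropna().to_numpy(dtype=float)
        y = row[cols_comp].dropna().to_numpy(dtype=float)
        rec = {
            "probe_id": probe_id,
            f"mean_log2_{base}": x.mean() if len(x) else np.nan,
            f"mean_log2_{comp}": y.mean() if len(y) else np.nan,
            "n_used_base": len(x), "n_used_comp": len(y),
        }
        if len(x) < 2 or len(y) < 2:
            rec.update(log2_ratio=np.nan, p_value=np.nan, direction="untestable")
        else:
            ratio = y.mean() - x.mean()
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                p = 1.0  # identical constant groups: no evidence at all
            else:
                with warnings.catch_warnings():
                    # near-identical replicates trip scipy's precision
                    # warning; the limiting p-values (0 or 1) are correct
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = float(stats.ttest_ind(y, x, equal_var=equal_var).pvalue)
                if np.isnan(p):
                    p = 1.0  # zero within-group variance in both groups
            direction = "ns"
            if p <= p_cutoff:
                direction = "up" if ratio > 0 else "down" if ratio < 0 else "ns"
            rec.update(log2_ratio=ratio, p_value=p, direction=direction)
        rows.append(rec)
    res = pd.DataFrame(rows)
    testable = res["p_value"].notna()
    res["q_value"] = np.nan
    if testable.any():
        res.loc[testable, "q_value"] = multipletests(
            res.loc[testable, "p_value"], method="fdr_bh")[1]
    return res


def de_summary(results: pd.DataFrame) -> DESummary:
    """Count up- and down-regulated probes among the direction calls."""
    if results.empty:
        return DESummary(0, 0)
    counts = results["direction"].value_counts()
    return DESummary(int(counts.get("up", 0)), int(counts.get("down", 0)))
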