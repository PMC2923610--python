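"""Diagnostic plots: MA trend before/after normalization, concordance scatter."""

from __future__ import annotations

import numpy as np
import pandas as pd


def ma_plot(matrix: pd.DataFrame, sample: str, ax=None, reference: str = "mean-array"):
    """MA scatter of one sample against the reference signal."""
    import matplotlib.pyplot as plt

    ref = matrix.mean(axis=1) if reference == "mean-array" else matrix[reference]
    col = matrix[sample]
    shared = col.notna() & ref.notna()
    m = col[shared] - ref[shared]
    a = (col[shared] + ref[shared]) / 2.0
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(a, m, s=6, alpha=0.5)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("A = (sample + reference) / 2 [log2]")
    ax.set_ylabel("M = sample - reference [log2]")
    ax.set_title(f"MA plot: {sample}")
    return ax


def concordance_plot(neg_dct: pd.Series, array_log2: pd.Series, ax=None):
    """-dCt against log2 array signal with the fitted line and Pearson r."""
    import matplotlib.pyplot as plt
    from scipy import stats

    paired = neg_dct.dropna().index.intersection(array_log2.dropna().index)
    x = array_log2.loc[paired].to_numpy(dtype=float)
    y = neg_dct.loc[paired].to_numpy(dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(x, y)
    if len(paired) >= 3 and np.ptp(x) > 0:
        fit = stats.linregress(x, y)
        xs = np.linspace(x.min(), x.max(), 20)
        ax.plot(xs, fit.intercept + fit.slope * xs, color="crimson", lw=1)
        ax.set_title(f"R = {fit.rvalue:.3f}")
    ax.set_xlabel("log2 microarray signal")
    ax.set_ylabel("-dCt (qRT-PCR)")
    return ax
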