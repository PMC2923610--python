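"""Relative quantification of qPCR Ct data and cross-platform concordance.

Ct is the PCR cycle at which fluorescence crosses threshold; one extra cycle
means half the starting template, so Ct is inversely and (at efficiency 2)
linearly related to log2 expression.  Technical replicates are collapsed
first (replicates beyond the detectability ceiling, Ct > 35 by default, are
dropped; a sample x assay with no surviving replicate is undetectable).
Quantification is relative:

* delta-Ct: target mean Ct minus the reference assay's mean Ct in the same
  sample (18S rRNA for miRNA runs, beta-actin for mRNA runs);
* delta-delta-Ct: a sample's delta-Ct minus the calibrator group's mean
  delta-Ct, so the calibrator group averages zero by construction and a
  *smaller* ddCt means *higher* expression.

Concordance with the microarray plots -dCt against log2 array signal per
sample and reports the Pearson correlation, alongside each platform's
two-group t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "group", "assay_id", "role", "replicate", "ct"]


class CtTableError(ValueError):
    """Raised for schema problems in a Ct table."""


def read_ct_table(path) -> pd.DataFrame:
    """Read a tab-delimited Ct table and validate its schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise CtTableError(f"{path}: missing required column(s) {missing}")
    bad_roles = set(df["role"].unique()) - {"target", "reference"}
    if bad_roles:
        raise CtTableError(f"{path}: unknown role value(s) {sorted(bad_roles)}")
    if (pd.to_numeric(df["ct"], errors="coerce") <= 0).any() or df["ct"].isna().any():
        raise CtTableError(f"{path}: ct values must be positive numbers")
    return df[CT_COLUMNS]


def collapse_replicates(cts, ct_max: float = 35.0) -> float:
    """Mean Ct of one sample x assay's technical replicates, or NaN.

    Replicates whose Ct exceeds ``ct_max`` are treated as failed
    amplification and dropped; when none survive the sample x assay is
    undetectable (NaN).
    """
    cts = np.asarray(cts, dtype=float)
    if cts.size == 0:
        raise ValueError("collapse_replicates requires at least one replicate")
    ok = cts <= ct_max
    return float(cts[ok].mean()) if ok.any() else float("nan")


def delta_ct_table(ct_table: pd.DataFrame, ct_max: float = 35.0) -> pd.DataFrame:
    """Per-sample delta-Ct for every target assay against the reference.

    Technical replicates are collapsed first.  Multiple reference assays,
    if present, are averaged on the Ct scale.  Rows where either the target
    or the reference is undetectable carry delta_ct = NaN and
    undetectable = True.
    """
    collapsed = (
        ct_table.groupby(["sample_id", "group", "assay_id", "role"])["ct"]
        .apply(lambda s: collapse_replicates(s.to_numpy(), ct_max=ct_max))
        .reset_index(name="mean_ct")
    )
    refs = collapsed[collapsed["role"] == "reference"]
    if refs.empty:
        raise CtTableError("Ct table contains no reference assay (role=reference)")
    ref_ct = refs.groupby("sample_id")["mean_ct"].mean()
    targets = collapsed[collapsed["role"] == "target"].copy()
    targets["ref_ct"] = targets["sample_id"].map(ref_ct)
    targets["delta_ct"] = targets["mean_ct"] - targets["ref_ct"]
    targets["undetectable"] = targets["delta_ct"].isna()
    return targets[["sample_id", "group", "assay_id", "mean_ct", "ref_ct",
                    "delta_ct", "undetectable"]]


def delta_ct(target_mean_ct: float, reference_mean_ct: float) -> float:
    """Single-sample delta-Ct; NaN if either side is undetectable."""
    return float(target_mean_ct) - float(reference_mean_ct)


@dataclass
class DdCtAssayResult:
    """Group comparison of one assay on the delta-Ct scale."""

    assay_id: str
    per_sample_ddct: pd.Series  # indexed by sample_id
    mean_ddct: dict[str, float]  # per group
    p_value: float
    log2_fold_change: float  # comparison vs calibrator; equals -ddCt difference

    @property
    def fold_change(self) -> float:
        return float(2.0 ** self.log2_fold_change)


def delta_delta_ct(
    delta_cts: pd.DataFrame,
    calibrator_group: str,
    equal_var: bool = False,
) -> list[DdCtAssayResult]:
    """Per-assay ddCt relative to the calibrator group's mean delta-Ct.

    The calibrator group's mean ddCt is zero by construction.  Groups are
    compared with a two-tailed t-test on the delta-Ct values (Welch by
    default); at amplification efficiency 2 the group ddCt difference is
    minus the log2 fold change.  Assays with a group entirely undetectable
    are reported untestable via a NaN p-value.
    """
    if calibrator_group not in set(delta_cts["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} not present")
    out = []
    for assay_id, grp in delta_cts.groupby("assay_id", sort=True):
        ok = grp[~grp["undetectable"]]
        cal = ok.loc[ok["group"] == calibrator_group, "delta_ct"].to_numpy()
        other_label = [g for g in grp["group"].unique() if g != calibrator_group]
        oth = ok.loc[ok["group"] != calibrator_group, "delta_ct"].to_numpy()
        if len(cal) == 0 or len(oth) == 0:
            out.append(DdCtAssayResult(assay_id, pd.Series(dtype=float),
                                       {}, float("nan"), float("nan")))
            continue
        ddct = ok.set_index("sample_id")["delta_ct"] - cal.mean()
        means = {calibrator_group: 0.0}
        for g in other_label:
            means[g] = float(oth.mean() - cal.mean())
        if len(cal) >= 2 and len(oth) >= 2:
            if np.ptp(cal) == 0 and np.ptp(oth) == 0:
                p = 1.0 if cal.mean() == oth.mean() else 0.0
            else:
                p = float(stats.ttest_ind(oth, cal, equal_var=equal_var).pvalue)
        else:
            p = float("nan")
        out.append(DdCtAssayResult(
            assay_id, ddct, means, p, log2_fold_change=-(oth.mean() - cal.mean())))
    return out


@dataclass
class ConcordanceResult:
    """Agreement between qPCR and microarray for one assay."""

    assay_id: str
    pearson_r: float
    n_pairs: int
    p_qpcr: float  # two-group t-test on -dCt
    p_array: float  # two-group t-test on log2 array signal


def concordance(
    delta_cts: pd.DataFrame,
    array_log2: pd.Series,
    groups: pd.Series,
    assay_id: str | None = None,
) -> ConcordanceResult:
    """Pearson correlation of -dCt against log2 microarray signal.

    ``delta_cts`` is the per-sample delta-Ct table restricted to one assay
    (or pass ``assay_id`` to select it); ``array_log2`` maps sample_id to
    the matching probe's log2 mean signal.  Requires at least three paired
    samples.  Also reports the two-group two-tailed t-test of each platform
    over the same samples.
    """
    d = delta_cts if assay_id is None else delta_cts[delta_cts["assay_id"] == assay_id]
    if assay_id is None:
        ids = d["assay_id"].unique()
        if len(ids) != 1:
            raise ValueError("pass assay_id when the delta-Ct table holds several assays")
        assay_id = str(ids[0])
    d = d[~d["undetectable"]].set_index("sample_id")
    paired = d.index.intersection(array_log2.dropna().index)
    if len(paired) < 3:
        raise ValueError(
            f"assay {assay_id!r}: only {len(paired)} paired samples, need >= 3")
    neg_dct = -d.loc[paired, "delta_ct"].to_numpy()
    arr = array_log2.loc[paired].to_numpy(dtype=float)
    if np.ptp(neg_dct) == 0 or np.ptp(arr) == 0:
        r = float("nan")  # correlation undefined on a constant platform
    else:
        r = float(stats.pearsonr(neg_dct, arr).statistic)
    g = groups.loc[paired]
    labels = sorted(g.unique())

    def _group_p(values: np.ndarray) -> float:
        if len(labels) != 2:
            return float("nan")
        a = values[(g == labels[0]).to_numpy()]
        b = values[(g == labels[1]).to_numpy()]
        if len(a) < 2 or len(b) < 2:
            return float("nan")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)

    return ConcordanceResult(assay_id, r, int(len(paired)),
                             _group_p(neg_dct), _group_p(arr))
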