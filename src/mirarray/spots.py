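"""Spot-level quality control and detection calling for replicate-spotted arrays.

Each probe is deposited several times on an array (here triplicate).  The QC
rules operate per probe per sample on background-subtracted net signals:

* a *bad spot* deviates from the replicate-set mean by more than 50% of that
  mean; if the replicate-set CV itself exceeds 0.5 the whole probe is
  discarded for that sample;
* a spot is *detected* when its net signal exceeds ``k_sd`` times the local
  background standard deviation (default 3);
* a probe is *detectable* on a sample only when at least ``frac_required``
  (default 50%) of its repeating spots are detected and the CV over the
  surviving good spots stays below ``cv_max`` (default 0.5).

CV is standard deviation over mean of the replicate-spot net signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import percent

SPOT_COLUMNS = ["sample_id", "group", "probe_id", "spot_index", "fg", "bg_mean", "bg_sd"]
_NUMERIC_COLUMNS = ["spot_index", "fg", "bg_mean", "bg_sd"]


class SpotTableError(ValueError):
    """Raised for schema or parse problems in a spot-level table."""


def read_spot_table(path) -> pd.DataFrame:
    """Read a tab-delimited spot table into a validated DataFrame.

    The file must carry a header naming at least the columns in
    :data:`SPOT_COLUMNS`; column order is irrelevant.  Malformed numeric
    fields are reported with their 1-based file line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SpotTableError(f"{path}: missing required column(s) {missing}")
    df = df[SPOT_COLUMNS].copy()
    for col in _NUMERIC_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +1 header, +1 one-based
            raise SpotTableError(
                f"{path}: non-numeric value in column '{col}' at line(s) {lines}"
            )
        df[col] = values
    df["spot_index"] = df["spot_index"].astype(int)
    if (df["bg_sd"] < 0).any():
        raise SpotTableError(f"{path}: negative bg_sd encountered")
    return df


def subtract_background(fg, bg_mean, floor: float = 1.0):
    """Net signal ``fg - bg_mean``, floored at a small positive value.

    The floor (default 1 intensity unit) keeps the log2 transform defined for
    spots whose foreground does not exceed the local background.
    """
    return np.maximum(np.asarray(fg, dtype=float) - np.asarray(bg_mean, dtype=float), floor)


def _cv(values: np.ndarray) -> float:
    """Sample CV (SD/mean, ddof=1); 0.0 for a single value."""
    if len(values) < 2:
        return 0.0
    m = values.mean()
    return float(values.std(ddof=1) / m) if m > 0 else np.inf


def flag_bad_spots(nets: np.ndarray, cv_max: float = 0.5) -> np.ndarray:
    """Good/bad flags for one probe's replicate spots on one sample.

    Returns a boolean array, ``True`` where the spot is good.  Evaluation is
    a single pass against the mean of *all* replicate spots: a spot is bad
    when it deviates from that mean by more than half of it.  If the CV over
    the surviving spots still exceeds ``cv_max`` the replicate set is
    unusable as a whole and every spot is flagged bad.
    """
    nets = np.asarray(nets, dtype=float)
    if nets.size == 0:
        raise ValueError("flag_bad_spots requires at least one spot")
    mean = nets.mean()
    good = np.abs(nets - mean) <= 0.5 * mean
    if not good.any() or _cv(nets[good]) > cv_max:
        return np.zeros(nets.shape, dtype=bool)
    return good


def detection_call(
    nets: np.ndarray,
    bg_sds: np.ndarray,
    good: np.ndarray | None = None,
    k_sd: float = 3.0,
    cv_max: float = 0.5,
    frac_required: float = 0.5,
) -> dict:
    """Per-probe per-sample detection summary from replicate-spot net signals.

    ``good`` marks spots that survived :func:`flag_bad_spots`; when omitted
    the flags are computed here.  A spot counts as detected when its net
    signal exceeds ``k_sd`` times its background SD; the probe is detectable
    when detected good spots reach ``frac_required`` of *all* repeating spots
    and the CV over good spots is below ``cv_max``.  With zero good spots the
    probe is not detectable and its mean signal is missing (NaN).
    """
    nets = np.asarray(nets, dtype=float)
    bg_sds = np.asarray(bg_sds, dtype=float)
    if good is None:
        good = flag_bad_spots(nets, cv_max=cv_max)
    good = np.asarray(good, dtype=bool)
    n_total = int(nets.size)
    n_good = int(good.sum())
    detected = good & (nets > k_sd * bg_sds)
    n_detected = int(detected.sum())
    if n_good == 0:
        mean_signal, cv, detectable = np.nan, np.nan, False
    else:
        mean_signal = float(nets[good].mean())
        cv = _cv(nets[good])
        detectable = (n_detected >= frac_required * n_total) and (cv < cv_max)
    return {
        "n_spots_total": n_total,
        "n_spots_good": n_good,
        "n_spots_detected": n_detected,
        "mean_signal": mean_signal,
        "cv": cv,
        "detectable": bool(detectable),
    }


def summarize_probes(
    spots: pd.DataFrame,
    floor: float = 1.0,
    k_sd: float = 3.0,
    cv_max: float = 0.5,
    frac_required: float = 0.5,
) -> pd.DataFrame:
    """Apply background subtraction, bad-spot flagging and detection calling.

    Parameters
    ----------
    spots
        Spot-level table with the :data:`SPOT_COLUMNS` schema.
    floor, k_sd, cv_max, frac_required
        QC rule parameters, see the module docstring.

    Returns
    -------
    DataFrame with one row per (sample_id, probe_id) carrying the group
    label, spot counts, mean net signal over good spots, the replicate CV
    and the detectable flag.
    """
    spots = spots.copy()
    spots["net"] = subtract_background(spots["fg"], spots["bg_mean"], floor=floor)
    rows = []
    for (sample_id, probe_id), grp in spots.groupby(["sample_id", "probe_id"], sort=True):
        nets = grp["net"].to_numpy()
        good = flag_bad_spots(nets, cv_max=cv_max)
        rec = detection_call(
            nets, grp["bg_sd"].to_numpy(), good,
            k_sd=k_sd, cv_max=cv_max, frac_required=frac_required,
        )
        rec.update(sample_id=sample_id, probe_id=probe_id, group=grp["group"].iloc[0])
        rows.append(rec)
    cols = ["sample_id", "group", "probe_id", "n_spots_total", "n_spots_good",
            "n_spots_detected", "mean_signal", "cv", "detectable"]
    return pd.DataFrame(rows)[cols]


@dataclass
class DetectionReport:
    """Cross-sample detection bookkeeping for a whole experiment."""

    per_sample_detected: dict[str, int]
    mean_detected: float
    sd_detected: float
    union: int
    intersection: int
    n_probes: int
    intersection_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.intersection_pct = percent(self.intersection, self.n_probes)


def summarize_detection(probe_summaries: pd.DataFrame, n_probes: int | None = None) -> DetectionReport:
    """Detection counts per sample, their mean +/- SD, union and intersection.

    ``n_probes`` defaults to the number of distinct probes in the input; the
    intersection ("present in all samples") is also reported as a percentage
    of that total.
    """
    if probe_summaries.empty:
        raise ValueError("no probe summaries to report on")
    if n_probes is None:
        n_probes = probe_summaries["probe_id"].nunique()
    det = probe_summaries[probe_summaries["detectable"]]
    samples = sorted(probe_summaries["sample_id"].unique())
    counts = {s: int((det["sample_id"] == s).sum()) for s in samples}
    vals = np.array(list(counts.values()), dtype=float)
    detected_sets = [set(det.loc[det["sample_id"] == s, "probe_id"]) for s in samples]
    union = set().union(*detected_sets)
    inter = set.intersection(*detected_sets) if detected_sets else set()
    return DetectionReport(
        per_sample_detected=counts,
        mean_detected=float(vals.mean()),
        sd_detected=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        union=len(union),
        intersection=len(inter),
        n_probes=int(n_probes),
    )
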