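"""Spot-level QC: parsing, background subtraction, bad-spot and detection rules."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirarray as ma
from mirarray.spots import SpotTableError, flag_bad_spots, detection_call


# ---------------------------------------------------------------- parsing

def test_read_spot_table_preserves_rows_and_ignores_column_order(tmp_path, small_dataset):
    spot_table, _ = small_dataset
    path = tmp_path / "spots.tsv"
    spot_table.to_csv(path, sep="\t", index=False)
    df = ma.read_spot_table(path)
    assert len(df) == len(spot_table)  # n_samples x n_probes x 3

    shuffled = tmp_path / "shuffled.tsv"
    spot_table[list(reversed(spot_table.columns))].to_csv(shuffled, sep="\t", index=False)
    df2 = ma.read_spot_table(shuffled)
    pd.testing.assert_frame_equal(df, df2)


def test_read_spot_table_reports_malformed_rows(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "sample_id\tgroup\tprobe_id\tspot_index\tfg\tbg_mean\tbg_sd\n"
        "s1\ta\tp1\t1\t100\t10\t2\n"
        "s1\ta\tp2\t1\t100\t10\n"  # truncated row
    )
    with pytest.raises(SpotTableError, match="line.*3"):
        ma.read_spot_table(path)


def test_read_spot_table_missing_column(tmp_path):
    path = tmp_path / "nocol.tsv"
    path.write_text("sample_id\tgroup\tprobe_id\tspot_index\tfg\tbg_mean\ns\ta\tp\t1\t5\t1\n")
    with pytest.raises(SpotTableError, match="bg_sd"):
        ma.read_spot_table(path)


# ------------------------------------------------- background subtraction

@pytest.mark.parametrize("fg,bg,floor,expected", [
    (500.0, 100.0, 1.0, 400.0),
    (50.0, 100.0, 1.0, 1.0),
    (100.0, 100.0, 1.0, 1.0),
    (100.0, 99.9, 0.5, 0.5),
])
def test_subtract_background(fg, bg, floor, expected):
    assert ma.subtract_background(fg, bg, floor=floor) == pytest.approx(expected)


# ------------------------------------------------------------- bad spots

def test_flag_bad_spots_uniform_replicates_all_good():
    assert flag_bad_spots([100.0, 100.0, 100.0]).tolist() == [True, True, True]


def test_flag_bad_spots_single_outlier():
    # mean 166.7, threshold 83.3: only the 300 spot exceeds it
    good = flag_bad_spots([100.0, 100.0, 300.0])
    assert good.tolist() == [True, True, False]


def test_flag_bad_spots_unusable_probe():
    # every spot deviates by more than half the mean: nothing survives
    good = flag_bad_spots([10.0, 100.0, 1000.0])
    assert not good.any()


# -------------------------------------------------------- detection call

def test_detection_call_detectable_probe():
    rec = detection_call([400.0, 410.0, 390.0], [50.0, 50.0, 50.0])
    assert rec["n_spots_detected"] == 3
    assert rec["cv"] == pytest.approx(0.025, abs=0.005)
    assert rec["detectable"]
    assert rec["mean_signal"] == pytest.approx(400.0)


def test_detection_call_signals_below_threshold():
    rec = detection_call([120.0, 130.0, 125.0], [50.0, 50.0, 50.0])
    assert rec["n_spots_detected"] == 0 and not rec["detectable"]


def test_detection_call_minority_detected_is_not_detectable():
    # one of three spots above 3x background SD: 1/3 < 50%
    rec = detection_call([400.0, 10.0, 20.0], [50.0, 50.0, 50.0],
                         good=np.array([True, True, True]))
    assert rec["n_spots_detected"] == 1 and not rec["detectable"]


def test_detection_call_zero_good_spots_flags_missing_signal():
    rec = detection_call([10.0, 100.0, 1000.0], [5.0, 5.0, 5.0])
    assert rec["n_spots_good"] == 0
    assert not rec["detectable"]
    assert np.isnan(rec["mean_signal"])


# ------------------------------------------------------------- summaries

def test_summarize_probes_count_conservation(small_dataset):
    spot_table, _ = small_dataset
    summaries = ma.summarize_probes(spot_table)
    bad = summaries["n_spots_total"] - summaries["n_spots_good"]
    assert ((summaries["n_spots_good"] + bad) == summaries["n_spots_total"]).all()
    assert (summaries["n_spots_detected"] <= summaries["n_spots_good"]).all()
    assert len(summaries) == spot_table.groupby(["sample_id", "probe_id"]).ngroups


def test_summarize_detection_extremes():
    rows = []
    for s in ("s1", "s2"):
        for p in ("p1", "p2"):
            rows.append({"sample_id": s, "group": "g", "probe_id": p,
                         "n_spots_total": 3, "n_spots_good": 3, "n_spots_detected": 3,
                         "mean_signal": 100.0, "cv": 0.01, "detectable": True})
    rep = ma.summarize_detection(pd.DataFrame(rows))
    assert rep.union == rep.intersection == 2 and rep.intersection_pct == 100.0

    # disjoint detection across samples -> empty intersection
    df = pd.DataFrame(rows)
    df.loc[(df.sample_id == "s1") & (df.probe_id == "p1"), "detectable"] = False
    df.loc[(df.sample_id == "s2") & (df.probe_id == "p2"), "detectable"] = False
    rep = ma.summarize_detection(df)
    assert rep.intersection == 0 and rep.union == 2


# ----------------------------------------------------- rule-oracle checks

def _oracle(nets, bg_sds, k_sd=3.0, cv_max=0.5, frac_required=0.5):
    """Independent brute-force evaluation of the three textual QC rules,
    using the statistics module rather than numpy."""
    mean_all = statistics.fmean(nets)
    good = [abs(n - mean_all) <= 0.5 * mean_all for n in nets]
    survivors = [n for n, g in zip(nets, good) if g]
    if survivors:
        sd = statistics.stdev(survivors) if len(survivors) > 1 else 0.0
        if statistics.fmean(survivors) <= 0 or sd / statistics.fmean(survivors) > cv_max:
            good = [False] * len(nets)
            survivors = []
    if not survivors:
        return good, False
    detected = sum(1 for n, b, g in zip(nets, bg_sds, good) if g and n > k_sd * b)
    cv = (statistics.stdev(survivors) / statistics.fmean(survivors)
          if len(survivors) > 1 else 0.0)
    detectable = detected >= frac_required * len(nets) and cv < cv_max
    return good, detectable


def test_qc_rules_match_brute_force_oracle():
    """Implementation decisions agree with a from-scratch evaluation of the
    deviation, CV and detection-fraction rules on randomized fixtures."""
    rng = np.random.default_rng(11)
    for _ in range(1000):
        n = int(rng.integers(1, 6))
        nets = np.round(rng.lognormal(5, 2, n) + 1.0, 3)
        bg_sds = np.round(rng.uniform(1, 200, n), 3)
        good = ma.flag_bad_spots(nets)
        rec = detection_call(nets, bg_sds, good)
        o_good, o_detectable = _oracle(list(nets), list(bg_sds))
        assert good.tolist() == o_good
        assert rec["detectable"] == o_detectable


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    nets=st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=1, max_size=6),
    scale=st.integers(min_value=-10, max_value=10).map(lambda k: 2.0 ** k),
)
def test_bad_spot_rule_is_scale_invariant(nets, scale):
    """Both QC ratios (deviation/mean and SD/mean) are dimensionless, so
    rescaling every net signal leaves the good/bad flags unchanged.
    Power-of-two scales keep the float arithmetic exact."""
    base = flag_bad_spots(np.asarray(nets))
    scaled = flag_bad_spots(np.asarray(nets) * scale)
    assert base.tolist() == scaled.tolist()


def test_detection_monotone_in_thresholds():
    """Raising k_sd can only lose detections; raising cv_max only gain them."""
    rng = np.random.default_rng(3)
    fixtures = [(rng.lognormal(5, 1.5, 3) + 1, rng.uniform(5, 150, 3))
                for _ in range(300)]

    def n_detectable(k_sd, cv_max):
        return sum(detection_call(n, b, k_sd=k_sd, cv_max=cv_max)["detectable"]
                   for n, b in fixtures)

    counts_k = [n_detectable(k, 0.5) for k in (1, 2, 3, 5, 10)]
    assert counts_k == sorted(counts_k, reverse=True)
    counts_cv = [n_detectable(3, c) for c in (0.05, 0.2, 0.5, 1.0)]
    assert counts_cv == sorted(counts_cv)
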