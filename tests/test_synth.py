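"""Synthetic-data generators: determinism, planted structure, configuration."""

import numpy as np
import pytest

import mirarray as ma
from mirarray.synth import SynthConfigError


def test_generators_are_deterministic(tmp_path):
    cfg = ma.SynthConfig(n_probes=50, frac_de=0.2, frac_bad_spots=0.05,
                         frac_absent=0.1, seed=123)
    a1, t1 = ma.generate_array_dataset(cfg)
    a2, t2 = ma.generate_array_dataset(cfg)
    ma.synth.write_tables(a1, t1, tmp_path / "r1")
    ma.synth.write_tables(a2, t2, tmp_path / "r2")
    assert (tmp_path / "r1" / "spots.tsv").read_bytes() == \
           (tmp_path / "r2" / "spots.tsv").read_bytes()

    q1 = ma.generate_qpcr_dataset(t1, t1.de_probe_ids()[:3], seed=5)
    q2 = ma.generate_qpcr_dataset(t2, t2.de_probe_ids()[:3], seed=5)
    assert q1.equals(q2)

    s1, d1 = ma.generate_target_table(t1, seed=9)
    s2, d2 = ma.generate_target_table(t2, seed=9)
    assert s1.equals(s2) and d1.equals(d2)


@pytest.mark.parametrize("field,value,match", [
    ("frac_de", 1.5, "frac_de"),
    ("frac_bad_spots", -0.1, "frac_bad_spots"),
    ("n_spot_replicates", 0, "n_spot_replicates"),
    ("log2fc_range", (0.0, 2.0), "log2fc_range"),
    ("spot_cv", -1.0, "spot_cv"),
])
def test_invalid_config_names_the_field(field, value, match):
    cfg = ma.SynthConfig(n_probes=10, **{field: value})
    with pytest.raises(SynthConfigError, match=match):
        ma.generate_array_dataset(cfg)


def test_planted_bad_spot_count_matches_binomial_expectation():
    # 0.1 x 100 probes x 3 spots x 6 samples = 180 expected corrupted spots
    cfg = ma.SynthConfig(n_probes=100, frac_bad_spots=0.1, frac_de=0.0,
                         frac_absent=0.0, seed=4)
    _, truth = ma.generate_array_dataset(cfg)
    n_bad = int(truth.spots["bad"].sum())
    sd = np.sqrt(1800 * 0.1 * 0.9)  # ~12.7
    assert abs(n_bad - 180) < 5 * sd


def test_ground_truth_invariants(small_dataset):
    _, truth = small_dataset
    de = truth.probes[truth.probes["log2fc"] != 0]
    assert (de["log2fc"].abs() >= truth.config.log2fc_range[0]).all()
    assert (truth.probes.loc[truth.probes["absent"], "log2fc"] == 0).all()


def test_absent_probes_stay_below_detection(small_dataset):
    spot_table, truth = small_dataset
    summaries = ma.summarize_probes(spot_table)
    absent = set(truth.probes.loc[truth.probes["absent"], "probe_id"])
    called = summaries[summaries["detectable"]]
    assert absent.isdisjoint(set(called["probe_id"]))


def test_spot_table_row_count(small_dataset):
    spot_table, truth = small_dataset
    cfg = truth.config
    expected = cfg.n_probes * cfg.n_spot_replicates * 2 * cfg.n_samples_per_group
    assert len(spot_table) == expected


# --------------------------------------------------------------- qPCR data

def _copy_truth(truth):
    return ma.GroundTruth(truth.probes.copy(), truth.spots.copy(), truth.config)


def test_noise_free_qpcr_closed_forms(clean_dataset):
    """With slope 1 and no noise, a planted 2-fold increase gives a group
    ddCt difference of exactly -1, and the reference assay is constant."""
    _, truth = clean_dataset
    truth = _copy_truth(truth)
    # overwrite one probe's truth with an exact 2-fold change
    truth.probes.loc[0, ["log2fc", "absent"]] = [1.0, False]
    assay = truth.probes.loc[0, "probe_id"]
    ct = ma.generate_qpcr_dataset(truth, [assay], ct_slope=1.0, ct_noise_sd=0.0, seed=0)
    ref = ct[ct["role"] == "reference"]
    assert ref["ct"].nunique() == 1
    dct = ma.delta_ct_table(ct)
    res = ma.delta_delta_ct(dct[dct["assay_id"] == assay], "immature")[0]
    assert res.mean_ddct["mature"] == pytest.approx(-1.0, abs=1e-12)


def test_qpcr_unknown_assay_raises(clean_dataset):
    _, truth = clean_dataset
    with pytest.raises(KeyError, match="no-such-mir"):
        ma.generate_qpcr_dataset(truth, ["no-such-mir"])


def test_qpcr_noise_power(clean_dataset):
    """Planted log2fc=2 with Ct noise 0.2 and n=3/group is detected by the
    ddCt t-test in the vast majority of replicate simulations."""
    _, truth = clean_dataset
    truth = _copy_truth(truth)
    truth.probes.loc[1, ["log2fc", "absent"]] = [2.0, False]
    assay = truth.probes.loc[1, "probe_id"]
    hits = 0
    for rep in range(200):
        ct = ma.generate_qpcr_dataset(truth, [assay], ct_noise_sd=0.2, seed=1000 + rep)
        dct = ma.delta_ct_table(ct)
        res = ma.delta_delta_ct(dct[dct["assay_id"] == assay], "immature")[0]
        hits += res.p_value <= 0.05
    assert hits >= 160  # >= 80% power


# -------------------------------------------------------------- target data

def test_target_table_fully_anticorrelated(clean_dataset):
    _, truth = clean_dataset
    sites, gene_dir = ma.generate_target_table(truth, frac_anticorrelated=1.0, seed=2)
    de = truth.probes[truth.probes["log2fc"] != 0]
    mirna_dir = de.set_index("probe_id")["log2fc"].map(
        lambda v: "up" if v > 0 else "down")
    report = ma.anticorrelation_filter(sites, mirna_dir, gene_dir.set_index("id")["direction"])
    for gene in report.per_gene:
        assert gene.positive_percentage == 1.0


def test_target_table_half_anticorrelated_converges(clean_dataset):
    _, truth = clean_dataset
    sites, gene_dir = ma.generate_target_table(
        truth, n_genes=200, sites_per_gene_mean=30, frac_anticorrelated=0.5, seed=3)
    de = truth.probes[truth.probes["log2fc"] != 0]
    mirna_dir = de.set_index("probe_id")["log2fc"].map(
        lambda v: "up" if v > 0 else "down")
    report = ma.anticorrelation_filter(sites, mirna_dir, gene_dir.set_index("id")["direction"])
    assert report.overall_positive_percentage == pytest.approx(0.5, abs=0.05)


def test_target_table_region_weights_respected(clean_dataset):
    _, truth = clean_dataset
    weights = (0.05, 0.77, 0.18)
    sites, _ = ma.generate_target_table(
        truth, n_genes=100, sites_per_gene_mean=50, region_weights=weights, seed=6)
    counts = ma.count_sites_by_region(sites)
    n = counts.total
    for region, w in zip(("5UTR", "CDS", "3UTR"), weights):
        sd = np.sqrt(n * w * (1 - w))
        assert abs(counts.counts[region] - n * w) < 5 * sd


def test_target_table_bad_region_weights(clean_dataset):
    _, truth = clean_dataset
    with pytest.raises(SynthConfigError, match="region_weights"):
        ma.generate_target_table(truth, region_weights=(0.5, 0.5, 0.5))
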