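import pandas as pd
import pytest

import mirarray as ma


@pytest.fixture(scope="session")
def small_dataset():
    """A compact noisy dataset with planted DE, bad spots and absent probes."""
    cfg = ma.SynthConfig(
        n_probes=120, frac_de=0.2, log2fc_range=(1.5, 3.0), spot_cv=0.1,
        frac_bad_spots=0.05, frac_absent=0.1, seed=20260928,
    )
    spot_table, truth = ma.generate_array_dataset(cfg)
    return spot_table, truth


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset: zero spot CV, no bad spots, nothing absent."""
    cfg = ma.SynthConfig(
        n_probes=60, frac_de=0.3, log2fc_range=(1.0, 3.0), spot_cv=0.0,
        frac_bad_spots=0.0, frac_absent=0.0, seed=7,
    )
    spot_table, truth = ma.generate_array_dataset(cfg)
    return spot_table, truth


@pytest.fixture
def spot_file(tmp_path, small_dataset):
    spot_table, _ = small_dataset
    path = tmp_path / "spots.tsv"
    spot_table.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def run_qc_de(spot_table: pd.DataFrame, p_cutoff: float = 0.1,
              equal_var: bool = False, normalize: bool = True) -> pd.DataFrame:
    """QC -> (optional) LOWESS -> DE on an in-memory spot table."""
    summaries = ma.summarize_probes(spot_table)
    mat, groups = ma.expression_from_summaries(summaries)
    if normalize:
        mat = ma.lowess_normalize(mat)
    return ma.differential_expression(mat, groups, p_cutoff=p_cutoff,
                                      equal_var=equal_var)
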