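"""Synthetic spot-level array data, matched qPCR Ct tables and target tables.

The generator emulates a replicate-spotted two-group miRNA microarray study:
1260 unique probes spotted in triplicate per array, three biological
replicates per group (sexually immature vs mature testis), a planted subset
of differentially expressed probes with known log2 fold changes,
multiplicative lognormal spot noise, additive Gaussian background, a
fraction of deliberately corrupted ("bad") spots and a fraction of probes
expressed below the detection level.  Every dataset ships with its ground
truth so downstream stages can be scored against what was planted.

A single signal column per sample is emitted: the dual-dye design of real
two-color chips is abstracted to per-sample signals, which is the form the
data takes after channel balancing anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATURE_DEFAULT = ("immature", "mature")

# Corruption factors for planted bad spots.  With triplicate spots a single
# corrupted replicate at factor f deviates from the replicate mean by more
# than 50% of that mean only for f > 2 or f < 0.4, and inflation beyond
# f = 4 would drag the *good* spots over the deviation threshold too; the
# ranges below keep planted bad spots unambiguously flaggable.
_INFLATE = (2.2, 3.8)
_DEFLATE = (0.05, 0.35)


class SynthConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic array experiment.

    Defaults mirror the emulated study design: triplicate spots, three
    biological replicates per group, planted absolute log2 fold changes
    between 1 and 3, spot-level CV 0.1 and an additive background around
    100 intensity units.
    """

    n_probes: int = 1260
    n_spot_replicates: int = 3
    n_samples_per_group: int = 3
    group_labels: tuple[str, str] = MATURE_DEFAULT
    frac_de: float = 0.1
    log2fc_range: tuple[float, float] = (1.0, 3.0)
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.5
    spot_cv: float = 0.1
    bg_mean: float = 100.0
    bg_sd: float = 15.0
    frac_bad_spots: float = 0.0
    frac_absent: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_de", "frac_bad_spots", "frac_absent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_spot_replicates < 1:
            raise SynthConfigError(f"n_spot_replicates must be >= 1, got {self.n_spot_replicates}")
        if self.n_probes < 1:
            raise SynthConfigError(f"n_probes must be >= 1, got {self.n_probes}")
        if self.n_samples_per_group < 1:
            raise SynthConfigError(
                f"n_samples_per_group must be >= 1, got {self.n_samples_per_group}")
        lo, hi = self.log2fc_range
        if lo <= 0 or hi < lo:
            raise SynthConfigError(f"log2fc_range must satisfy 0 < lo <= hi, got {self.log2fc_range}")
        if self.spot_cv < 0:
            raise SynthConfigError(f"spot_cv must be >= 0, got {self.spot_cv}")
        if self.bg_sd < 0:
            raise SynthConfigError(f"bg_sd must be >= 0, got {self.bg_sd}")
        if len(self.group_labels) != 2 or self.group_labels[0] == self.group_labels[1]:
            raise SynthConfigError(f"group_labels must be two distinct labels, got {self.group_labels}")


@dataclass
class GroundTruth:
    """What was planted: per-probe expression truth and per-spot bad flags.

    ``probes`` has columns probe_id, baseline_log2, log2fc (0 for non-DE),
    absent; ``spots`` has sample_id, probe_id, spot_index, bad.  ``config``
    keeps the generating parameters for provenance.
    """

    probes: pd.DataFrame
    spots: pd.DataFrame
    config: SynthConfig

    def expression_log2(self) -> pd.DataFrame:
        """True per-sample log2 expression (probes x samples)."""
        cfg = self.config
        imm, mat = cfg.group_labels
        samples = [f"{g}_{i+1}" for g in (imm, mat) for i in range(cfg.n_samples_per_group)]
        out = pd.DataFrame(index=self.probes["probe_id"], columns=samples, dtype=float)
        for s in samples:
            shift = self.probes["log2fc"].to_numpy() if s.startswith(mat) else 0.0
            out[s] = self.probes["baseline_log2"].to_numpy() + shift
        return out

    def de_probe_ids(self) -> list[str]:
        return list(self.probes.loc[self.probes["log2fc"] != 0, "probe_id"])


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_array_dataset(cfg: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a spot-level table plus its ground truth.

    One row per (sample x probe x spot replicate).  Foreground is the local
    background plus the true linear signal under multiplicative lognormal
    noise; planted bad spots have that signal multiplied by a corruption
    factor; absent probes emit foreground within 2 background SDs of the
    background so the 3xSD detection rule classifies them undetected.
    Fixing ``cfg.seed`` makes the output byte-identical across runs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    imm, mat = cfg.group_labels

    probe_ids = np.array([f"miR-{i:04d}" for i in range(1, cfg.n_probes + 1)])
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_probes)
    is_de = rng.random(cfg.n_probes) < cfg.frac_de
    mag = rng.uniform(cfg.log2fc_range[0], cfg.log2fc_range[1], cfg.n_probes)
    sign = rng.choice([-1.0, 1.0], cfg.n_probes)
    log2fc = np.where(is_de, sign * mag, 0.0)
    absent = rng.random(cfg.n_probes) < cfg.frac_absent
    log2fc = np.where(absent, 0.0, log2fc)

    samples = [(f"{imm}_{i+1}", imm) for i in range(cfg.n_samples_per_group)] + \
              [(f"{mat}_{i+1}", mat) for i in range(cfg.n_samples_per_group)]

    rows, truth_rows = [], []
    for sample_id, group in samples:
        expr_log2 = baseline + (log2fc if group == mat else 0.0)
        signal = np.power(2.0, expr_log2)
        for spot in range(1, cfg.n_spot_replicates + 1):
            noise = _lognormal_multiplier(rng, cfg.spot_cv, cfg.n_probes)
            bad = rng.random(cfg.n_probes) < cfg.frac_bad_spots
            factor = np.where(
                rng.random(cfg.n_probes) < 0.5,
                rng.uniform(*_INFLATE, cfg.n_probes),
                rng.uniform(*_DEFLATE, cfg.n_probes),
            )
            true_sig = signal * noise * np.where(bad, factor, 1.0)
            bg = np.maximum(rng.normal(cfg.bg_mean, cfg.bg_sd, cfg.n_probes), 0.0)
            fg = bg + true_sig
            # absent probes sit within 2 background SDs of their background
            fg = np.where(absent, bg + rng.uniform(0.0, 2.0 * cfg.bg_sd, cfg.n_probes), fg)
            for j in range(cfg.n_probes):
                rows.append((sample_id, group, probe_ids[j], spot,
                             fg[j], bg[j], cfg.bg_sd))
                truth_rows.append((sample_id, probe_ids[j], spot, bool(bad[j] and not absent[j])))

    spot_table = pd.DataFrame(
        rows, columns=["sample_id", "group", "probe_id", "spot_index", "fg", "bg_mean", "bg_sd"])
    truth = GroundTruth(
        probes=pd.DataFrame({
            "probe_id": probe_ids, "baseline_log2": baseline,
            "log2fc": log2fc, "absent": absent,
        }),
        spots=pd.DataFrame(truth_rows, columns=["sample_id", "probe_id", "spot_index", "bad"]),
        config=cfg,
    )
    return spot_table, truth


def generate_qpcr_dataset(
    truth: GroundTruth,
    assays: list[str],
    ct_slope: float = 1.0,
    ct_intercept: float = 38.0,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    n_replicates: int = 3,
    reference_id: str = "ref-18S",
    reference_log2: float = 18.0,
) -> pd.DataFrame:
    """Ct table matched to the array ground truth.

    Ct = intercept - slope * log2(true expression) + Gaussian noise, per
    technical replicate (triplicate by default).  A stable reference assay
    with zero fold change is always included, so delta-Ct normalization has
    its anchor.
    """
    known = set(truth.probes["probe_id"])
    unknown = [a for a in assays if a not in known]
    if unknown:
        raise KeyError(f"assay id(s) not present in ground truth: {unknown}")
    rng = np.random.default_rng(seed)
    expr = truth.expression_log2()
    rows = []
    imm, mat = truth.config.group_labels
    for sample_id in expr.columns:
        group = mat if sample_id.startswith(mat) else imm
        for assay in assays:
            true_ct = ct_intercept - ct_slope * float(expr.loc[assay, sample_id])
            for rep in range(1, n_replicates + 1):
                ct = true_ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append((sample_id, group, assay, "target", rep, ct))
        ref_ct = ct_intercept - ct_slope * reference_log2
        for rep in range(1, n_replicates + 1):
            ct = ref_ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            rows.append((sample_id, group, reference_id, "reference", rep, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "assay_id", "role", "replicate", "ct"])


REGIONS = ("5UTR", "CDS", "3UTR")


def generate_target_table(
    truth: GroundTruth,
    n_genes: int = 20,
    sites_per_gene_mean: float = 10.0,
    region_weights: tuple[float, float, float] = (0.05, 0.77, 0.18),
    frac_anticorrelated: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy predicted miRNA-target site table with a known anticorrelated share.

    Each gene receives a Poisson number of sites (at least one).  Genes get a
    random up/down direction; each site's miRNA is drawn from the planted DE
    probes with the opposite direction with probability
    ``frac_anticorrelated`` (else the same direction), so the expected
    positive percentage under the anticorrelation filter is known by
    construction.

    Returns (site table, gene direction table).
    """
    w = np.asarray(region_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise SynthConfigError(f"region_weights must sum to 1, got {tuple(region_weights)}")
    de = truth.probes[truth.probes["log2fc"] != 0]
    if de.empty:
        raise SynthConfigError("ground truth contains no DE probes to build target sites from")
    up = de.loc[de["log2fc"] > 0, "probe_id"].to_numpy()
    down = de.loc[de["log2fc"] < 0, "probe_id"].to_numpy()
    if len(up) == 0 or len(down) == 0:
        raise SynthConfigError("need planted DE probes in both directions")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene-{i:03d}" for i in range(1, n_genes + 1)]
    gene_dir = rng.choice(["up", "down"], n_genes)
    site_rows = []
    for gid, gdir in zip(gene_ids, gene_dir):
        n_sites = max(1, int(rng.poisson(sites_per_gene_mean)))
        anti_pool, same_pool = (down, up) if gdir == "up" else (up, down)
        for _ in range(n_sites):
            pool = anti_pool if rng.random() < frac_anticorrelated else same_pool
            mirna = str(rng.choice(pool))
            region = str(rng.choice(REGIONS, p=w))
            start = int(rng.integers(0, 2000))
            site_rows.append((mirna, gid, region, start))
    sites = pd.DataFrame(site_rows, columns=["mirna_id", "gene_id", "region", "start"])
    directions = pd.DataFrame({"id": gene_ids, "direction": gene_dir})
    return sites, directions


def write_tables(spot_table: pd.DataFrame, truth: GroundTruth, outdir) -> None:
    """Write the spot table and truth tables as UTF-8 tab-delimited files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spot_table.to_csv(outdir / "spots.tsv", sep="\t", index=False, lineterminator="\n")
    truth.probes.to_csv(outdir / "truth_probes.tsv", sep="\t", index=False, lineterminator="\n")
    truth.spots.to_csv(outdir / "truth_spots.tsv", sep="\t", index=False, lineterminator="\n")
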