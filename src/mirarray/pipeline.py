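"""End-to-end orchestration: QC -> normalize/DE -> qPCR -> integration.

Stages run from a single config (YAML or an in-memory
:class:`PipelineConfig`); every output is a tab-delimited table plus a
manifest recording parameters and input checksums, so identical config and
inputs give byte-identical outputs.  A stage failure aborts the run, names
the stage, and removes partial outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import normalize, qpcr, spots, targets


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and cause."""


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run.

    Defaults follow the standard rule set: 3x background-SD detection,
    CV < 0.5, >= 50% of repeating spots detected, LOWESS span 0.3, relaxed
    p-cutoff 0.1, Ct ceiling 35.
    """

    spot_table: str | None = None
    ct_table: str | None = None
    site_table: str | None = None
    gene_directions: str | None = None
    mirna_directions: str | None = None  # optional override of the DE calls
    outdir: str = "mirarray_out"
    floor: float = 1.0
    k_sd: float = 3.0
    cv_max: float = 0.5
    frac_required: float = 0.5
    lowess_span: float = 0.3
    p_cutoff: float = 0.1
    equal_var: bool = False
    ct_max: float = 35.0
    calibrator_group: str | None = None  # default: lexicographically first group
    g_total: int = 19977
    m_total: int = 1200
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.p_cutoff <= 1.0:
            raise PipelineError(f"config: p_cutoff must be in (0, 1], got {self.p_cutoff}")
        if self.ct_max <= 0:
            raise PipelineError(f"config: ct_max must be positive, got {self.ct_max}")
        for name in ("spot_table", "ct_table", "site_table", "gene_directions",
                     "mirna_directions"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    probe_summaries: pd.DataFrame | None = None
    detection: spots.DetectionReport | None = None
    expression: pd.DataFrame | None = None
    de_results: pd.DataFrame | None = None
    de_counts: normalize.DESummary | None = None
    delta_cts: pd.DataFrame | None = None
    ddct: list | None = None
    integration: targets.IntegrationReport | None = None
    extrapolation: targets.ExtrapolationResult | None = None
    outputs: list[Path] = field(default_factory=list)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage the config provides inputs for.

    Requires at least a spot table.  The qPCR and integration stages run
    only when their input tables are configured.  miRNA directions for the
    anticorrelation filter default to this run's own DE calls unless an
    override table is given.
    """
    config.validate()
    if config.spot_table is None:
        raise PipelineError("config: spot_table is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    def _emit(name: str, frame: pd.DataFrame) -> Path:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n",
                     float_format="%.10g")
        result.outputs.append(path)
        return path

    try:
        # --- spot QC and detection -------------------------------------
        try:
            spot_df = spots.read_spot_table(config.spot_table)
            result.probe_summaries = spots.summarize_probes(
                spot_df, floor=config.floor, k_sd=config.k_sd,
                cv_max=config.cv_max, frac_required=config.frac_required)
            result.detection = spots.summarize_detection(result.probe_summaries)
            _emit("probe_summaries.tsv", result.probe_summaries)
            det = result.detection
            _emit("detection_summary.tsv", pd.DataFrame([{
                "n_probes": det.n_probes, "union_detected": det.union,
                "present_in_all": det.intersection,
                "present_in_all_pct": det.intersection_pct,
                "mean_detected": det.mean_detected, "sd_detected": det.sd_detected,
                **{f"detected_{s}": n for s, n in det.per_sample_detected.items()},
            }]))
        except Exception as exc:
            raise PipelineError(f"stage qc failed: {exc}") from exc

        # --- normalization and DE --------------------------------------
        try:
            mat, groups = normalize.expression_from_summaries(result.probe_summaries)
            result.expression = normalize.lowess_normalize(mat, span=config.lowess_span)
            result.de_results = normalize.differential_expression(
                result.expression, groups,
                p_cutoff=config.p_cutoff, equal_var=config.equal_var)
            result.de_counts = normalize.de_summary(result.de_results)
            _emit("de_results.tsv", result.de_results)
        except Exception as exc:
            raise PipelineError(f"stage de failed: {exc}") from exc

        # --- qPCR -------------------------------------------------------
        if config.ct_table is not None:
            try:
                ct = qpcr.read_ct_table(config.ct_table)
                result.delta_cts = qpcr.delta_ct_table(ct, ct_max=config.ct_max)
                calibrator = config.calibrator_group or sorted(ct["group"].unique())[0]
                result.ddct = qpcr.delta_delta_ct(result.delta_cts, calibrator)
                _emit("delta_ct.tsv", result.delta_cts)
                _emit("ddct_summary.tsv", pd.DataFrame([{
                    "assay_id": r.assay_id, "p_value": r.p_value,
                    "log2_fold_change": r.log2_fold_change,
                    **{f"mean_ddct_{g}": v for g, v in r.mean_ddct.items()},
                } for r in result.ddct]))
            except Exception as exc:
                raise PipelineError(f"stage qpcr failed: {exc}") from exc

        # --- target integration ----------------------------------------
        if config.site_table is not None:
            try:
                if config.gene_directions is None:
                    raise ValueError("integration needs a gene_directions table")
                sites = targets.read_site_table(config.site_table)
                gene_dir = targets.read_direction_table(config.gene_directions)
                if config.mirna_directions is not None:
                    mirna_dir = targets.read_direction_table(config.mirna_directions)
                else:
                    mirna_dir = result.de_results.set_index("probe_id")["direction"]
                    mirna_dir = mirna_dir.replace("untestable", "ns")
                result.integration = targets.anticorrelation_filter(
                    sites, mirna_dir, gene_dir)
                _emit("integration.tsv", result.integration.to_frame())
                regions = targets.count_sites_by_region(sites)
                de_mirnas = sites["mirna_id"].nunique()
                spec = targets.ExtrapolationSpec(
                    observed=regions.counts, observed_total=regions.total,
                    g_obs=sites["gene_id"].nunique(), m_obs=de_mirnas,
                    g_total=config.g_total, m_total=config.m_total)
                result.extrapolation = targets.extrapolate_genome_wide(spec)
                _emit("region_counts.tsv", pd.DataFrame([{
                    **regions.counts, "total": regions.total,
                    **{f"{r}_pct": p for r, p in (regions.percentages or {}).items()},
                }]))
            except Exception as exc:
                raise PipelineError(f"stage integrate failed: {exc}") from exc

        _write_manifest(config, result, outdir)
    except PipelineError:
        for path in result.outputs:
            path.unlink(missing_ok=True)
        raise
    return result


def _write_manifest(config: PipelineConfig, result: PipelineResult, outdir: Path) -> None:
    lines = ["[parameters]"]
    for key, value in asdict(config).items():
        lines.append(f"{key} = {value}")
    lines.append("[inputs]")
    for name in ("spot_table", "ct_table", "site_table", "gene_directions",
                 "mirna_directions"):
        p = getattr(config, name)
        if p is not None:
            lines.append(f"{name} = {p} sha256:{_sha256(p)}")
    lines.append("[outputs]")
    for path in result.outputs:
        lines.append(f"{path.name} sha256:{_sha256(path)}")
    manifest = outdir / "manifest.txt"
    manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
    result.outputs.append(manifest)
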