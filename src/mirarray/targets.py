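"""miRNA-target site bookkeeping, anticorrelation filtering and extrapolation.

Predicted miRNA binding sites fall in one of three mRNA regions (5'UTR, CDS,
3'UTR).  Integration with expression data keeps, for each gene, only the
distinct binding miRNAs whose differential-expression direction is opposite
to the gene's own — a miRNA represses its target, so a genuine interaction
should show anticorrelated expression.  The retained share of a gene's
predicted miRNAs is its *positive percentage*.

Genome-wide extrapolation scales the observed site counts linearly in both
the gene catalogue (analyzed genes -> genome gene count) and the miRNA
catalogue (analyzed miRNAs -> assumed species total):

    scaled = observed * (g_total / g_obs) * (m_total / m_obs)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import round_half_up

REGIONS = ("5UTR", "CDS", "3UTR")
DIRECTIONS = ("up", "down", "ns")


class SiteTableError(ValueError):
    """Raised for schema or content problems in a site table."""


class IntegrationError(ValueError):
    """Raised when direction entries are missing for sites under filtering."""


def read_site_table(path) -> pd.DataFrame:
    """Read a tab-delimited site table (mirna_id, gene_id, region, start).

    Duplicate (mirna, gene, region, start) rows are collapsed; the number of
    duplicates dropped is stored in ``df.attrs["n_duplicates_dropped"]``.
    Unknown region labels raise with the offending 1-based line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str, "region": str})
    required = ["mirna_id", "gene_id", "region", "start"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SiteTableError(f"{path}: missing required column(s) {missing}")
    df = df[required]
    starts = pd.to_numeric(df["start"], errors="coerce")
    bad = df.index[starts.isna() | (starts < 0)]
    if len(bad):
        raise SiteTableError(
            f"{path}: malformed start at line(s) {[int(i) + 2 for i in bad[:5]]}")
    df["start"] = starts.astype(int)
    unknown = df.index[~df["region"].isin(REGIONS)]
    if len(unknown):
        labels = df.loc[unknown, "region"].unique().tolist()
        raise SiteTableError(
            f"{path}: unknown region label(s) {labels} at line(s) "
            f"{[int(i) + 2 for i in unknown[:5]]}")
    before = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    df.attrs["n_duplicates_dropped"] = before - len(df)
    return df


def read_direction_table(path) -> pd.Series:
    """Read an id -> direction table (direction in {up, down, ns})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "direction"}.issubset(df.columns):
        raise SiteTableError(f"{path}: direction tables need columns id, direction")
    bad = set(df["direction"]) - set(DIRECTIONS)
    if bad:
        raise SiteTableError(f"{path}: unknown direction value(s) {sorted(bad)}")
    return df.set_index("id")["direction"]


@dataclass
class RegionCounts:
    """Site counts and shares per mRNA region."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float] | None  # None when total == 0


def count_sites_by_region(sites: pd.DataFrame) -> RegionCounts:
    """Count sites per region; percentages rounded to two decimals.

    The per-region counts always partition the input.  Unknown region
    labels raise, naming the offending rows.
    """
    unknown = sites.index[~sites["region"].isin(REGIONS)] if len(sites) else []
    if len(unknown):
        raise SiteTableError(
            f"unknown region label(s) at row(s) {[int(i) for i in unknown[:5]]}")
    counts = {r: int((sites["region"] == r).sum()) if len(sites) else 0 for r in REGIONS}
    total = sum(counts.values())
    pct = None
    if total > 0:
        pct = {r: round_half_up(100.0 * c / total, 2) for r, c in counts.items()}
    return RegionCounts(counts=counts, total=total, percentages=pct)


@dataclass
class IntegrationResult:
    """Per-gene retention of predicted binding miRNAs after filtering."""

    gene_id: str
    gene_direction: str
    n_predicted_mirnas: int
    n_retained_mirnas: int
    positive_percentage: float = field(init=False)

    def __post_init__(self) -> None:
        self.positive_percentage = (
            self.n_retained_mirnas / self.n_predicted_mirnas
            if self.n_predicted_mirnas else 0.0)


@dataclass
class IntegrationReport:
    """Per-gene results plus the overall retained share."""

    per_gene: list[IntegrationResult]
    overall_predicted: int
    overall_retained: int

    @property
    def overall_positive_percentage(self) -> float:
        return (self.overall_retained / self.overall_predicted
                if self.overall_predicted else 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "gene_id": r.gene_id,
            "gene_direction": r.gene_direction,
            "n_predicted_mirnas": r.n_predicted_mirnas,
            "n_retained_mirnas": r.n_retained_mirnas,
            "positive_percentage": r.positive_percentage,
        } for r in self.per_gene]
        rows.append({
            "gene_id": "TOTAL", "gene_direction": "",
            "n_predicted_mirnas": self.overall_predicted,
            "n_retained_mirnas": self.overall_retained,
            "positive_percentage": self.overall_positive_percentage,
        })
        return pd.DataFrame(rows)


_OPPOSITE = {("up", "down"), ("down", "up")}


def anticorrelation_filter(
    sites: pd.DataFrame,
    mirna_directions: pd.Series,
    gene_directions: pd.Series,
) -> IntegrationReport:
    """Retain miRNA-gene pairs with strictly opposite expression directions.

    Counting is over *distinct* binding miRNAs per gene, not raw site rows;
    a pair survives only when one member is up and the other down — a
    non-significant call on either side drops it.  Every miRNA and gene
    appearing in ``sites`` must have a direction entry.
    """
    pairs = sites[["mirna_id", "gene_id"]].drop_duplicates()
    missing_m = sorted(set(pairs["mirna_id"]) - set(mirna_directions.index))
    missing_g = sorted(set(pairs["gene_id"]) - set(gene_directions.index))
    if missing_m or missing_g:
        raise IntegrationError(
            f"missing direction entries; miRNAs: {missing_m[:10]}, genes: {missing_g[:10]}")
    per_gene = []
    for gene_id, grp in pairs.groupby("gene_id", sort=True):
        gdir = gene_directions[gene_id]
        mirnas = grp["mirna_id"]
        retained = sum(
            1 for m in mirnas if (mirna_directions[m], gdir) in _OPPOSITE)
        per_gene.append(IntegrationResult(
            gene_id=str(gene_id), gene_direction=str(gdir),
            n_predicted_mirnas=len(mirnas), n_retained_mirnas=int(retained)))
    return IntegrationReport(
        per_gene=per_gene,
        overall_predicted=sum(r.n_predicted_mirnas for r in per_gene),
        overall_retained=sum(r.n_retained_mirnas for r in per_gene),
    )


def integration_report_from_counts(
    predicted: dict[str, int],
    retained: dict[str, int],
    gene_directions: dict[str, str] | None = None,
) -> IntegrationReport:
    """Build an integration report directly from per-gene count pairs.

    Useful for re-deriving positive percentages from published predicted /
    retained binding-miRNA counts without the underlying site table.
    """
    if set(predicted) != set(retained):
        raise IntegrationError("predicted and retained must cover the same genes")
    per_gene = [
        IntegrationResult(
            gene_id=g,
            gene_direction=(gene_directions or {}).get(g, "ns"),
            n_predicted_mirnas=int(predicted[g]),
            n_retained_mirnas=int(retained[g]),
        )
        for g in predicted
    ]
    return IntegrationReport(
        per_gene=per_gene,
        overall_predicted=sum(predicted.values()),
        overall_retained=sum(retained.values()),
    )


@dataclass
class ExtrapolationSpec:
    """Observed site counts and the catalogue sizes to scale between."""

    observed: dict[str, int]  # per region
    observed_total: int
    g_obs: int
    m_obs: int
    g_total: int
    m_total: int

    def validate(self) -> None:
        for name in ("g_obs", "m_obs", "g_total", "m_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if sum(self.observed.values()) != self.observed_total:
            raise ValueError("per-region observed counts must sum to the total")


@dataclass
class ExtrapolationResult:
    """Genome-wide scaled site counts, in raw units and in millions."""

    scaled: dict[str, float]  # per region plus "total"
    scaled_millions: dict[str, float]  # rounded to two decimals
    per_gene_average_sites: float  # scaled total / g_total
    observed_per_gene: float  # observed total / g_obs


def extrapolate_genome_wide(spec: ExtrapolationSpec) -> ExtrapolationResult:
    """Scale observed site counts to genome-wide totals.

    scaled = observed * (g_total/g_obs) * (m_total/m_obs); million-scale
    figures are rounded half-up to two decimals.  Also reports the average
    sites per gene on both the observed and the scaled footing.
    """
    spec.validate()
    factor = (spec.g_total / spec.g_obs) * (spec.m_total / spec.m_obs)
    scaled = {r: c * factor for r, c in spec.observed.items()}
    scaled["total"] = spec.observed_total * factor
    millions = {r: round_half_up(v / 1e6, 2) for r, v in scaled.items()}
    return ExtrapolationResult(
        scaled=scaled,
        scaled_millions=millions,
        per_gene_average_sites=scaled["total"] / spec.g_total,
        observed_per_gene=spec.observed_total / spec.g_obs,
    )
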