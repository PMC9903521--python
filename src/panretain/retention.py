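"""Gene retention rate (GRR) statistics over pangenome presence/absence panels.

GRR of an orthogroup in a species panel is the percentage of pangenome lines
carrying the gene: GRR = 100 * n_present / n_lines. Built on top of it are
the monotone dosage-pattern filter (keep orthogroups whose GRR decreases
strictly along a ploidy-ordered species list), the R_bw = GRR_a/GRR_b
species-preference categorisation, and the correlation of mean per-orthogroup
GRR with gene family size that diagnoses the gene dosage constraint effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import HogRecord, PresenceAbsenceMatrix

logger = logging.getLogger("panretain")


# ---------------------------------------------------------------------------
# Core statistic
# ---------------------------------------------------------------------------

def grr(
    presence_column: np.ndarray,
    nodata_column: np.ndarray | None = None,
    exclude_nodata: bool = False,
) -> float:
    """Gene retention rate in percent for one gene over one species panel.

    With ``exclude_nodata`` the denominator drops lines whose call carries no
    evidence; otherwise no-data calls count as absent (matching published
    pangenome practice, where an unassembled gene is reported missing).
    Returns NaN when no countable line remains.
    """
    presence = np.asarray(presence_column, dtype=bool)
    if presence.ndim != 1 or presence.size == 0:
        raise ValueError("presence_column must be a non-empty 1-D vector")
    if nodata_column is not None and exclude_nodata:
        nodata = np.asarray(nodata_column, dtype=bool)
        countable = ~nodata
        if not countable.any():
            return math.nan
        return 100.0 * presence[countable].sum() / countable.sum()
    return 100.0 * presence.sum() / presence.size


@dataclass
class RetentionTable:
    """Per-HOG retention rates across species panels.

    ``data`` is a DataFrame indexed by hog_id with columns
    ``(species, 'n_present')``, ``(species, 'n_lines')``, ``(species, 'grr')``;
    GRR is kept at full precision (exactly 100*n_present/n_lines) and only
    rounded in rendered reports.
    """

    data: pd.DataFrame
    species: list[str]
    og_by_hog: dict[str, str] = field(default_factory=dict)

    def grr_frame(self) -> pd.DataFrame:
        return self.data.loc[:, [(sp, "grr") for sp in self.species]].droplevel(1, axis=1)

    def to_tsv(self, path: str | Path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{sp}_{what}" for sp, what in flat.columns]
        flat.insert(0, "og_id", [self.og_by_hog.get(h, "") for h in flat.index])
        flat.to_csv(path, sep="\t", index_label="hog_id", float_format="%.10g")


def hog_gene_presence(
    hog: HogRecord, pav: PresenceAbsenceMatrix
) -> tuple[np.ndarray, np.ndarray | None]:
    """Presence of a HOG in each line of one species panel.

    A HOG is present in a line when at least one of its member genes for that
    species is present. Genes of the HOG missing from the PAV matrix are
    ignored; a HOG with no genotyped gene yields an all-no-data column.
    """
    genes = [g for g in hog.genes_by_species.get(pav.species, []) if g in set(pav.gene_ids)]
    if not genes:
        n = len(pav.line_ids)
        return np.zeros(n, dtype=bool), np.ones(n, dtype=bool)
    idx = [pav.gene_ids.index(g) for g in genes]
    presence = pav.calls[:, idx].any(axis=1)
    nodata = None
    if pav.nodata is not None:
        nodata = pav.nodata[:, idx].all(axis=1) & ~presence
    return presence, nodata


def retention_table(
    hogs: list[HogRecord],
    pavs: dict[str, PresenceAbsenceMatrix],
    exclude_nodata: bool = False,
    require_any_gene: bool = True,
) -> RetentionTable:
    """Compute GRR for every HOG in every species panel.

    A species' GRR is NaN for HOGs without any genotyped gene in that species'
    panel. With ``require_any_gene`` (default) a HOG must carry at least one
    gene in at least one of the panels to be retained in the table.
    """
    species = list(pavs)
    rows = {}
    for hog in hogs:
        if require_any_gene and not any(
            hog.genes_by_species.get(sp) for sp in species
        ):
            continue
        row: dict[tuple[str, str], float] = {}
        for sp in species:
            pav = pavs[sp]
            if not hog.genes_by_species.get(sp):
                row[(sp, "n_present")] = math.nan
                row[(sp, "n_lines")] = len(pav.line_ids)
                row[(sp, "grr")] = math.nan
                continue
            presence, nodata = hog_gene_presence(hog, pav)
            if exclude_nodata and nodata is not None:
                countable = int((~nodata).sum())
                n_present = int(presence[~nodata].sum())
            else:
                countable = presence.size
                n_present = int(presence.sum())
            row[(sp, "n_present")] = n_present
            row[(sp, "n_lines")] = countable
            row[(sp, "grr")] = (
                100.0 * n_present / countable if countable else math.nan
            )
        rows[hog.hog_id] = row
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return RetentionTable(
        data=data,
        species=species,
        og_by_hog={h.hog_id: h.og_id for h in hogs},
    )


# ---------------------------------------------------------------------------
# Dosage-pattern filter
# ---------------------------------------------------------------------------

@dataclass
class PatternGeneSet:
    """HOGs whose GRR decreases along the species order, plus the gene ids
    they contribute in the reference (first-listed) species."""

    hog_ids: list[str]
    reference_species: str
    reference_genes: dict[str, list[str]]  # hog_id -> gene ids
    n_skipped_missing: int = 0

    @property
    def genes(self) -> list[str]:
        return [g for hog in self.hog_ids for g in self.reference_genes[hog]]


def pattern_filter(
    retention: RetentionTable,
    species_order: list[str],
    hogs: list[HogRecord] | None = None,
    strict: bool = True,
) -> PatternGeneSet:
    """Keep HOGs with monotonically decreasing GRR along ``species_order``.

    Strict mode (default) requires GRR[s1] > GRR[s2] > ... exactly as a
    decreasing chain; the relaxed mode accepts >= with at least one strict
    drop. HOGs missing a GRR for any species in the order are skipped and
    counted.
    """
    for sp in species_order:
        if sp not in retention.species:
            raise ValueError(f"species {sp!r} not in retention table")
    grr_cols = retention.grr_frame()[species_order]
    values = grr_cols.to_numpy()
    ok = ~np.isnan(values).any(axis=1)
    n_skipped = int((~ok).sum())
    diffs = -np.diff(values, axis=1)  # positive where decreasing
    if strict:
        passing = ok & (diffs > 0).all(axis=1)
    else:
        passing = ok & (diffs >= 0).all(axis=1) & (diffs > 0).any(axis=1)
    hog_ids = list(grr_cols.index[passing])
    ref = species_order[0]
    genes_by_hog = {h.hog_id: h.genes_by_species.get(ref, []) for h in hogs or []}
    reference_genes = {hid: list(genes_by_hog.get(hid, [])) for hid in hog_ids}
    logger.info(
        "pattern filter: %d/%d HOGs pass (%d skipped for missing GRR)",
        len(hog_ids), len(grr_cols), n_skipped,
    )
    return PatternGeneSet(hog_ids, ref, reference_genes, n_skipped)


# ---------------------------------------------------------------------------
# R_bw categorisation
# ---------------------------------------------------------------------------

class RbwCategory(str, Enum):
    BARLEY_PREFERENTIAL = "barley_preferential"
    NEUTRAL = "neutral"
    WHEAT_PREFERENTIAL = "wheat_preferential"
    UNASSIGNED = "unassigned"
    UNDEFINED = "undefined"


@dataclass
class RbwRecord:
    hog_id: str
    r_bw: float  # may be +inf; NaN when undefined
    category: RbwCategory


def rbw_categorize(grr_a: float, grr_b: float, hog_id: str = "") -> RbwRecord:
    """Categorise species-preferential retention from the ratio of two GRRs.

    r = GRR_a/GRR_b; r >= 1.2 is a-preferential (barley in the reference
    comparison), 0.9 < r < 1.1 neutral, r <= 0.8 b-preferential (wheat). The
    published cutoffs deliberately leave gaps ((0.8, 0.9] and [1.1, 1.2));
    ratios falling there are labeled unassigned rather than merged into a
    neighbouring category. GRR_b = 0 with GRR_a > 0 gives r = +inf, the
    extreme a-preferential case; both zero is undefined.
    """
    if grr_a < 0 or grr_b < 0:
        raise ValueError("GRR cannot be negative")
    if math.isnan(grr_a) or math.isnan(grr_b):
        return RbwRecord(hog_id, math.nan, RbwCategory.UNDEFINED)
    if grr_b == 0.0:
        if grr_a == 0.0:
            return RbwRecord(hog_id, math.nan, RbwCategory.UNDEFINED)
        return RbwRecord(hog_id, math.inf, RbwCategory.BARLEY_PREFERENTIAL)
    r = grr_a / grr_b
    if r >= 1.2:
        cat = RbwCategory.BARLEY_PREFERENTIAL
    elif 0.9 < r < 1.1:
        cat = RbwCategory.NEUTRAL
    elif r <= 0.8:
        cat = RbwCategory.WHEAT_PREFERENTIAL
    else:
        cat = RbwCategory.UNASSIGNED
    return RbwRecord(hog_id, r, cat)


def rbw_table(
    retention: RetentionTable, species_a: str, species_b: str
) -> pd.DataFrame:
    """R_bw record per HOG with both GRRs defined; plus category counts."""
    g = retention.grr_frame()
    records = [
        rbw_categorize(row[species_a], row[species_b], hog_id=hid)
        for hid, row in g.iterrows()
        if not (math.isnan(row[species_a]) or math.isnan(row[species_b]))
    ]
    return pd.DataFrame(
        {
            "hog_id": [r.hog_id for r in records],
            "r_bw": [r.r_bw for r in records],
            "category": [r.category.value for r in records],
        }
    ).set_index("hog_id")


# ---------------------------------------------------------------------------
# Family size vs retention
# ---------------------------------------------------------------------------

def pearson(x, y) -> float:
    """Product-moment correlation; raises on constant or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class FamilySizeResult:
    correlation: float
    slope: float
    intercept: float
    per_og: pd.DataFrame  # og_id -> family_size, mean_grr


def family_size_table(
    retention: RetentionTable, hogs: list[HogRecord], species: str
) -> pd.DataFrame:
    """Per parent-OG family size (number of member HOGs) and unweighted mean
    GRR over those members, for one species."""
    g = retention.grr_frame()[species]
    rows: dict[str, list[float]] = {}
    sizes: dict[str, int] = {}
    for hog in hogs:
        if hog.hog_id not in g.index:
            continue
        sizes[hog.og_id] = sizes.get(hog.og_id, 0) + 1
        val = g.loc[hog.hog_id]
        if not math.isnan(val):
            rows.setdefault(hog.og_id, []).append(float(val))
    out = pd.DataFrame(
        {
            "family_size": {og: sizes[og] for og in rows},
            "mean_grr": {og: float(np.mean(v)) for og, v in rows.items()},
        }
    )
    out.index.name = "og_id"
    return out


def family_size_correlation(
    retention: RetentionTable, hogs: list[HogRecord], species: str
) -> FamilySizeResult:
    """Pearson correlation (and least-squares slope) between gene family size
    and mean per-OG retention rate — negative under dosage-constrained loss."""
    table = family_size_table(retention, hogs, species)
    if len(table) < 2:
        raise ValueError("need at least 2 orthogroups")
    if table["family_size"].nunique() < 2:
        raise ValueError("constant family size: correlation undefined")
    r = pearson(table["family_size"], table["mean_grr"])
    slope, intercept = np.polyfit(table["family_size"], table["mean_grr"], 1)
    return FamilySizeResult(r, float(slope), float(intercept), table)


def tpm_log_transform(tpm_matrix) -> np.ndarray:
    """Elementwise log10(TPM + 0.01), the transform used for expression
    heatmaps; zero TPM maps to -2."""
    tpm = np.asarray(tpm_matrix, dtype=float)
    if np.any(tpm < 0):
        raise ValueError("TPM values must be non-negative")
    return np.log10(tpm + 0.01)
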