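"""End-to-end retention study orchestration: configuration, staging, report.

``run_study`` strings the stages together — read orthogroups and
presence/absence panels, compute retention rates, apply the monotone
dosage-pattern filter, categorise R_bw preference, optionally classify
duplication types, compute pairwise Ka/Ks, and run per-category GO
enrichment — and emits a StudyReport (JSON + TSV bundle) with a provenance
block (config hash, seed, version). Stages log their in/out counts and a
stage failure aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dupclass, enrichment, kaks, retention
from .io import read_fasta, read_gff_gene_loci, read_hog_table, read_pav_matrix

logger = logging.getLogger("panretain")

__version__ = "0.1.0"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


_CONFIG_DEFAULTS: dict = {
    "hog_table": None,
    "pav": None,              # map species -> path
    "species_order": None,
    "exclude_nodata": False,
    "pattern_strict": True,
    "gff": None,
    "hits": None,
    "proximal_window": 10,
    "e_cutoff": 1e-5,
    "top_n_hits": 5,
    "min_block_size": 5,
    "max_gap_genes": 25,
    "annotation": None,
    "enrichment_threshold": 0.05,
    "cds": None,
    "kaks_pairs": None,       # TSV: gene_a, gene_b, og_id
    "missingness_threshold": 0.8,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    hog_table: str
    pav: dict[str, str]
    species_order: list[str]
    exclude_nodata: bool = False
    pattern_strict: bool = True
    gff: str | None = None
    hits: str | None = None
    proximal_window: int = 10
    e_cutoff: float = 1e-5
    top_n_hits: int = 5
    min_block_size: int = 5
    max_gap_genes: int = 25
    annotation: str | None = None
    enrichment_threshold: float = 0.05
    cds: str | None = None
    kaks_pairs: str | None = None
    missingness_threshold: float = 0.8
    seed: int = 0

    def canonical(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path_or_mapping) -> PipelineConfig:
    """Load and validate a declarative YAML config.

    Unknown keys are rejected by name; ``hog_table``, ``pav`` and
    ``species_order`` are required; defaults are applied for the rest.
    """
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text())
    else:
        raw = dict(path_or_mapping)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    merged = {**_CONFIG_DEFAULTS, **raw}
    for key in ("hog_table", "pav", "species_order"):
        if not merged[key]:
            raise ValueError(f"config missing required key {key!r}")
    if not set(merged["species_order"]) <= set(merged["pav"]):
        raise ValueError("species_order contains species without a PAV matrix")
    return PipelineConfig(**merged)


@dataclass
class StudyReport:
    provenance: dict
    n_hogs: int
    retention_summary: dict
    pattern: dict
    rbw_counts: dict
    dup_composition: dict | None
    kaks_summary: dict | None
    enrichment_by_category: dict | None
    tables: dict = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        payload = {
            k: v for k, v in self.__dict__.items() if k != "tables"
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonify)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        for name, frame in self.tables.items():
            frame.to_csv(out / f"{name}.tsv", sep="\t")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_study(config: PipelineConfig) -> StudyReport:
    """Run the full retention study defined by ``config``.

    Deterministic given config + seed; every stage logs counts in/out.
    """
    # --- stage: read inputs -------------------------------------------------
    try:
        hogs = read_hog_table(config.hog_table)
        pavs = {
            sp: read_pav_matrix(path, species=sp)
            for sp, path in config.pav.items()
        }
    except Exception as exc:
        raise StageError("read_inputs", str(exc)) from exc
    logger.info("read %d HOGs, %d PAV panels", len(hogs), len(pavs))

    # --- stage: retention ---------------------------------------------------
    try:
        table = retention.retention_table(
            hogs, pavs, exclude_nodata=config.exclude_nodata
        )
    except Exception as exc:
        raise StageError("retention", str(exc)) from exc
    grr_frame = table.grr_frame()
    summary = {
        sp: {
            "mean_grr": float(np.nanmean(grr_frame[sp])),
            "n_defined": int(grr_frame[sp].notna().sum()),
        }
        for sp in table.species
    }
    logger.info("retention: %d HOGs scored", len(grr_frame))

    # --- stage: pattern filter ----------------------------------------------
    try:
        pattern = retention.pattern_filter(
            table, config.species_order, hogs=hogs, strict=config.pattern_strict
        )
    except Exception as exc:
        raise StageError("pattern_filter", str(exc)) from exc

    # --- stage: R_bw --------------------------------------------------------
    sp_a, sp_b = config.species_order[0], config.species_order[-1]
    try:
        rbw = retention.rbw_table(table, sp_a, sp_b)
    except Exception as exc:
        raise StageError("rbw", str(exc)) from exc
    rbw_counts = rbw["category"].value_counts().to_dict()
    for cat in retention.RbwCategory:
        rbw_counts.setdefault(cat.value, 0)

    tables = {"retention": grr_frame, "rbw": rbw}

    # --- stage: duplication classification (optional) -----------------------
    dup_comp = None
    dup_table: dict[str, dupclass.DupClass] = {}
    if config.gff and config.hits:
        try:
            loci = read_gff_gene_loci(config.gff)
            raw_hits = dupclass.read_hit_table(config.hits)
            hits = dupclass.filter_hits(
                raw_hits, e_cutoff=config.e_cutoff, top_n=config.top_n_hits
            )
            anchors = _anchors_from_hits(loci, hits)
            blocks = dupclass.detect_collinear_blocks(
                anchors,
                min_block_size=config.min_block_size,
                max_gap_genes=config.max_gap_genes,
            )
            dup_table = dupclass.classify_duplicates(
                loci, hits, blocks, proximal_window=config.proximal_window
            )
        except Exception as exc:
            raise StageError("classify_dups", str(exc)) from exc
        pattern_classes = {
            g: dup_table[g] for g in pattern.genes if g in dup_table
        }
        dup_comp = (
            dupclass.class_composition(pattern_classes)
            if pattern_classes
            else dupclass.class_composition(dup_table)
        )
        logger.info("classified %d genes", len(dup_table))

    # --- stage: pairwise Ka/Ks (optional) ------------------------------------
    kaks_summary = None
    if config.cds and config.kaks_pairs:
        try:
            cds = read_fasta(config.cds)
            pairs = pd.read_csv(config.kaks_pairs, sep="\t", dtype=str)
            omegas: dict[str, dict[str, float]] = {}
            rows = []
            for _, row in pairs.iterrows():
                res = kaks.ng86(cds[row["gene_a"]], cds[row["gene_b"]])
                rows.append(
                    {
                        "gene_a": row["gene_a"],
                        "gene_b": row["gene_b"],
                        "og_id": row.get("og_id", ""),
                        "Ka": res.Ka, "Ks": res.Ks, "omega": res.omega,
                    }
                )
                omegas.setdefault(row.get("og_id", ""), {})[row["gene_a"]] = res.omega
            frame = pd.DataFrame(rows)
            rel = []
            for og, group in omegas.items():
                for gene in group:
                    try:
                        rel.append(kaks.relative_kaks(group, gene))
                    except (ValueError, KeyError):
                        pass
            defined = frame["omega"].dropna()
            kaks_summary = {
                "n_pairs": int(len(frame)),
                "mean_omega": float(defined.mean()) if len(defined) else None,
                "bins": kaks.kaks_bins(frame["omega"]),
                "mean_relative_kaks": float(np.mean(rel)) if rel else None,
            }
            tables["kaks"] = frame.set_index("gene_a")
        except Exception as exc:
            raise StageError("kaks", str(exc)) from exc

    # --- stage: enrichment (optional) ----------------------------------------
    enrich_by_cat = None
    if config.annotation:
        try:
            ann = enrichment.read_annotation_table(config.annotation)
            gene_by_hog = {h.hog_id: h.genes_by_species.get(sp_a, []) for h in hogs}
            enrich_by_cat = {}
            query_sets = {"pattern": list(pattern.genes)}
            for cat in (
                retention.RbwCategory.BARLEY_PREFERENTIAL,
                retention.RbwCategory.NEUTRAL,
                retention.RbwCategory.WHEAT_PREFERENTIAL,
            ):
                hog_ids = rbw.index[rbw["category"] == cat.value]
                query_sets[cat.value] = [
                    g for hid in hog_ids for g in gene_by_hog.get(hid, [])
                ]
            for name, query in query_sets.items():
                results = enrichment.enrich(
                    query, ann, threshold=config.enrichment_threshold
                )
                enrich_by_cat[name] = {
                    "n_query": len(query),
                    "n_significant": sum(r.significant for r in results),
                    "top_terms": [
                        {"term_id": r.term_id, "p": r.p_value, "score": r.enrichment_score}
                        for r in results[:5]
                    ],
                }
        except Exception as exc:
            raise StageError("enrichment", str(exc)) from exc

    provenance = {
        "config_hash": PipelineConfig.config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "config": config.canonical(),
    }
    return StudyReport(
        provenance=provenance,
        n_hogs=len(hogs),
        retention_summary=summary,
        pattern={
            "n_hogs_passing": len(pattern.hog_ids),
            "n_genes": len(pattern.genes),
            "reference_species": pattern.reference_species,
            "n_skipped_missing": pattern.n_skipped_missing,
            "hog_ids": pattern.hog_ids,
        },
        rbw_counts=rbw_counts,
        dup_composition=dup_comp,
        kaks_summary=kaks_summary,
        enrichment_by_category=enrich_by_cat,
        tables=tables,
    )


def _anchors_from_hits(loci, hits):
    """Turn same-direction hit pairs into rank anchors per chromosome pair."""
    by_id = {l.gene_id: l for l in loci}
    anchors: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        a, b = by_id[h.query], by_id[h.subject]
        if a.chrom == b.chrom and a.rank == b.rank:
            continue
        if (a.chrom, a.rank) > (b.chrom, b.rank):
            a, b = b, a
        anchors.setdefault((a.chrom, b.chrom), []).append((a.rank, b.rank))
    return anchors
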