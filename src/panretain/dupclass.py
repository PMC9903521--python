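"""Gene duplication typing: singleton / dispersed / proximal / tandem /
WGD-segmental, from homology hits and gene order.

The classifier mirrors the semantics of the widely used synteny-based
duplicate classifiers: each gene receives the highest-precedence class
supported by any of its retained homology hits, with precedence
WGD/segmental > tandem > proximal > dispersed, and genes with no retained
hit are singletons. Segmental evidence comes from a collinear-block detector
that chains homology anchors by dynamic programming on gene ranks; chain
length is the chain score (no e-value scoring).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .io import FormatError, GeneLocus


class DupClass(str, Enum):
    SINGLETON = "singleton"
    DISPERSED = "dispersed"
    PROXIMAL = "proximal"
    TANDEM = "tandem"
    WGD_SEGMENTAL = "wgd_segmental"


#: classification precedence, highest first
PRECEDENCE = (
    DupClass.WGD_SEGMENTAL,
    DupClass.TANDEM,
    DupClass.PROXIMAL,
    DupClass.DISPERSED,
)


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value cannot be negative")


@dataclass
class CollinearBlock:
    """A chained run of homology anchors collinear between two chromosomes."""

    chrom_pair: tuple[str, str]
    anchors: list[tuple[int, int]]  # (rank in A, rank in B)
    orientation: str  # "same" | "inverted"

    @property
    def size(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------
# Hit filtering
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column tabular (blast outfmt-6 dialect) hit table: only the
    query, subject, e-value and bit-score columns are used."""
    hits = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns")
            hits.append(
                HomologyHit(cells[0], cells[1], float(cells[10]), float(cells[11]))
            )
    return hits


def write_hit_table(hits: list[HomologyHit], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            cells = [h.query, h.subject, "100.0", "0", "0", "0", "0", "0",
                     "0", "0", f"{h.e_value:g}", f"{h.bit_score:g}"]
            fh.write("\t".join(cells) + "\n")


def filter_hits(
    raw_hits: list[HomologyHit], e_cutoff: float = 1e-5, top_n: int = 5
) -> list[HomologyHit]:
    """Drop self-hits, apply the e-value cutoff, and keep the top_n hits per
    query (best e-value, ties broken by bit score then subject id)."""
    by_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in raw_hits:
        if h.query == h.subject or h.e_value > e_cutoff:
            continue
        by_query[h.query].append(h)
    out: list[HomologyHit] = []
    for query in sorted(by_query):
        ranked = sorted(
            by_query[query], key=lambda h: (h.e_value, -h.bit_score, h.subject)
        )
        out.extend(ranked[:top_n])
    return out


# ---------------------------------------------------------------------------
# Collinear block detection
# ---------------------------------------------------------------------------

def _best_chain(
    anchors: list[tuple[int, int]], direction: int, max_gap_genes: int
) -> list[int]:
    """Longest chain (indices into ``anchors``) monotone in both ranks, with
    consecutive anchors within max_gap_genes in both genomes; direction +1
    chains increasing second-genome ranks, -1 decreasing. Classic O(n^2) DP;
    ties broken toward the lexicographically earliest anchor sequence."""
    order = sorted(range(len(anchors)), key=lambda i: anchors[i])
    best_len = [1] * len(anchors)
    prev = [-1] * len(anchors)
    for oi, i in enumerate(order):
        ai, bi = anchors[i]
        for j in order[:oi]:
            aj, bj = anchors[j]
            if aj >= ai:
                continue
            if direction * (bi - bj) <= 0:
                continue
            if ai - aj > max_gap_genes or abs(bi - bj) > max_gap_genes:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(len(anchors)), key=lambda i: (best_len[i], -anchors[i][0]))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def detect_collinear_blocks(
    anchors_by_chrom_pair: dict[tuple[str, str], list[tuple[int, int]]],
    min_block_size: int = 5,
    max_gap_genes: int = 25,
) -> list[CollinearBlock]:
    """Chain homology anchors into collinear blocks per chromosome pair.

    Blocks are extracted greedily best-chain-first (same and inverted
    orientations competing), each anchor joining at most one block; chains
    shorter than min_block_size are dropped.
    """
    blocks: list[CollinearBlock] = []
    for pair in sorted(anchors_by_chrom_pair):
        remaining = sorted(set(anchors_by_chrom_pair[pair]))
        while remaining:
            candidates = []
            for direction, name in ((1, "same"), (-1, "inverted")):
                idx = _best_chain(remaining, direction, max_gap_genes)
                candidates.append(([remaining[i] for i in idx], name))
            chain, orientation = max(candidates, key=lambda c: len(c[0]))
            if len(chain) < min_block_size:
                break
            blocks.append(CollinearBlock(pair, chain, orientation))
            taken = set(chain)
            remaining = [a for a in remaining if a not in taken]
    return blocks


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_duplicates(
    loci: list[GeneLocus],
    hits: list[HomologyHit],
    blocks: list[CollinearBlock] | None = None,
    proximal_window: int = 10,
) -> dict[str, DupClass]:
    """Assign one duplication class per gene.

    Hits are treated as undirected: both partners of a hit receive evidence.
    A gene that is an anchor of any collinear block is WGD/segmental; a hit
    partner at adjacent rank on the same chromosome makes both tandem; within
    2..proximal_window ranks, proximal; any other retained hit, dispersed;
    no retained hit at all, singleton.
    """
    by_id = {l.gene_id: l for l in loci}
    for h in hits:
        for g in (h.query, h.subject):
            if g not in by_id:
                raise ValueError(f"hit references unknown gene {g!r}")

    anchor_genes: set[str] = set()
    if blocks:
        rank_index: dict[tuple[str, int], str] = {
            (l.chrom, l.rank): l.gene_id for l in loci
        }
        for block in blocks:
            ca, cb = block.chrom_pair
            for ra, rb in block.anchors:
                for key in ((ca, ra), (cb, rb)):
                    gene = rank_index.get(key)
                    if gene is not None:
                        anchor_genes.add(gene)

    result: dict[str, DupClass] = {l.gene_id: DupClass.SINGLETON for l in loci}

    def upgrade(gene: str, cls: DupClass) -> None:
        current = result[gene]
        if current is DupClass.SINGLETON or PRECEDENCE.index(cls) < PRECEDENCE.index(current):
            result[gene] = cls

    for h in hits:
        a, b = by_id[h.query], by_id[h.subject]
        if a.chrom == b.chrom:
            delta = abs(a.rank - b.rank)
            if delta == 1:
                cls = DupClass.TANDEM
            elif 2 <= delta <= proximal_window:
                cls = DupClass.PROXIMAL
            else:
                cls = DupClass.DISPERSED
        else:
            cls = DupClass.DISPERSED
        upgrade(h.query, cls)
        upgrade(h.subject, cls)

    for gene, cls in result.items():
        if cls is not DupClass.SINGLETON and gene in anchor_genes:
            result[gene] = DupClass.WGD_SEGMENTAL
    return result


def class_composition(table: dict[str, DupClass]) -> dict[str, float]:
    """Percentage of genes per duplication class (sums to 100)."""
    if not table:
        raise ValueError("empty classification table")
    counts: dict[str, int] = defaultdict(int)
    for cls in table.values():
        counts[cls.value] += 1
    total = len(table)
    return {name: 100.0 * n / total for name, n in sorted(counts.items())}


def write_dup_classes(table: dict[str, DupClass], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(table), "dup_class": [c.value for c in table.values()]}
    ).to_csv(path, sep="\t", index=False)
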