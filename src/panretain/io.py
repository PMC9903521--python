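"""Readers, writers and validation for the formats the retention pipeline consumes.

Formats handled here: the hierarchical-orthogroup (HOG) table dialect
(tab-separated; columns ``HOG``, ``OG``, ``Gene Tree Parent Clade``, then one
gene-list column per species), presence/absence matrices over pangenome lines
(CSV/TSV, cells 0/1 or absent/present), GFF3 gene coordinates, FASTA sequence
sets, Newick trees with ``#k`` branch labels marking foreground lineages, and
pre-tabulated per-gene genotype-missingness counts used to call gene absence
from SNP data.

Internal coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import STOP_CODONS, translate

logger = logging.getLogger("panretain")

HOG_FIXED_COLUMNS = ("HOG", "OG", "Gene Tree Parent Clade")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A parsed file violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HogRecord:
    """One hierarchical orthologous group: nested inside a parent orthogroup
    (OG) and carrying one gene list per species (possibly empty — a gene
    family absent from one species' reference is a legitimate record)."""

    hog_id: str
    og_id: str
    genes_by_species: dict[str, list[str]]
    clade: str = ""

    def all_genes(self) -> list[str]:
        return [g for genes in self.genes_by_species.values() for g in genes]


@dataclass
class PresenceAbsenceMatrix:
    """Boolean lines x genes presence/absence calls for one species panel.

    ``nodata`` optionally marks calls with no usable evidence (e.g. a gene
    with zero genotyped SNPs in a line); such calls can be excluded from
    retention-rate denominators.
    """

    species: str
    line_ids: list[str]
    gene_ids: list[str]
    calls: np.ndarray  # bool, shape (n_lines, n_genes)
    nodata: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.shape != (len(self.line_ids), len(self.gene_ids)):
            raise ValidationError(
                f"{self.species}: matrix shape {self.calls.shape} does not "
                f"match {len(self.line_ids)} lines x {len(self.gene_ids)} genes"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError(f"{self.species}: duplicate line ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"{self.species}: duplicate gene ids")
        if self.nodata is not None:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.calls.shape:
                raise ValidationError(f"{self.species}: nodata shape mismatch")

    def column(self, gene_id: str) -> np.ndarray:
        return self.calls[:, self.gene_ids.index(gene_id)]


@dataclass
class GeneLocus:
    """A gene's genomic interval (0-based half-open) plus its rank along the
    chromosome when genes are ordered by start position."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")


@dataclass
class GenotypeMissingness:
    """Per-gene, per-line SNP genotyping counts (total markers and missing
    calls) used to infer gene absence from dense missingness."""

    line_ids: list[str]
    gene_ids: list[str]
    total: np.ndarray    # int, (n_lines, n_genes)
    missing: np.ndarray  # int, (n_lines, n_genes)

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=int)
        self.missing = np.asarray(self.missing, dtype=int)
        if self.total.shape != self.missing.shape:
            raise ValidationError("total/missing shape mismatch")
        if np.any(self.missing > self.total):
            raise ValidationError("missing count exceeds total count")
        if np.any(self.total < 0) or np.any(self.missing < 0):
            raise ValidationError("negative SNP counts")


@dataclass
class LabeledTree:
    """A phylogeny with branch lengths and integer branch labels: label 0 is
    background, labels k >= 1 are foreground classes (Newick ``#k`` suffix
    convention)."""

    tree: dendropy.Tree
    n_resolved_polytomies: int = 0

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def labels_present(self) -> set[int]:
        return {
            getattr(e, "branch_class", 0)
            for e in self.tree.preorder_edge_iter()
            if e.tail_node is not None
        }


# ---------------------------------------------------------------------------
# Hierarchical orthogroup tables
# ---------------------------------------------------------------------------

def _split_gene_cell(cell: str) -> list[str]:
    cell = cell.strip()
    if not cell:
        return []
    sep = ", " if ", " in cell else ","
    return [g.strip() for g in cell.split(sep) if g.strip()]


def read_hog_table(path: str | Path) -> list[HogRecord]:
    """Parse a tab-separated hierarchical-orthogroup table.

    Header must start with ``HOG``, ``OG``, ``Gene Tree Parent Clade``;
    every further column is a species whose cells hold comma-separated gene
    ids (empty cells allowed). Duplicate HOG ids are a format error; a gene
    id appearing in two HOGs is a validation error naming both.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:3]) != HOG_FIXED_COLUMNS:
            raise FormatError(
                f"{path}: expected leading columns {HOG_FIXED_COLUMNS}, got {header[:3]}"
            )
        species = header[3:]
        if not species:
            raise FormatError(f"{path}: no species columns")
        records: list[HogRecord] = []
        seen_hogs: set[str] = set()
        gene_owner: dict[str, str] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            cells += [""] * (3 + len(species) - len(cells))
            hog_id, og_id, clade = cells[0], cells[1], cells[2]
            if hog_id in seen_hogs:
                raise FormatError(f"{path}:{lineno}: duplicated HOG id {hog_id!r}")
            seen_hogs.add(hog_id)
            genes_by_species: dict[str, list[str]] = {}
            for sp, cell in zip(species, cells[3:]):
                genes = _split_gene_cell(cell)
                for g in genes:
                    if g in gene_owner:
                        raise ValidationError(
                            f"gene {g!r} appears in both HOG {gene_owner[g]!r} "
                            f"and HOG {hog_id!r}"
                        )
                    gene_owner[g] = hog_id
                genes_by_species[sp] = genes
            records.append(HogRecord(hog_id, og_id, genes_by_species, clade))
    return records


def write_hog_table(records: list[HogRecord], path: str | Path) -> None:
    """Write HOG records in the same tab-separated dialect read_hog_table reads."""
    species: list[str] = []
    for rec in records:
        for sp in rec.genes_by_species:
            if sp not in species:
                species.append(sp)
    with Path(path).open("w") as fh:
        fh.write("\t".join(HOG_FIXED_COLUMNS + tuple(species)) + "\n")
        for rec in records:
            cells = [rec.hog_id, rec.og_id, rec.clade]
            cells += [", ".join(rec.genes_by_species.get(sp, [])) for sp in species]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Presence/absence matrices
# ---------------------------------------------------------------------------

_PAV_TRUE = {"1", "present"}
_PAV_FALSE = {"0", "absent"}


def read_pav_matrix(path: str | Path, species: str | None = None) -> PresenceAbsenceMatrix:
    """Read a delimited presence/absence matrix (lines x genes).

    First column holds line ids; the header row holds gene ids. Cells must be
    ``0``/``1`` or ``absent``/``present`` (case-insensitive); anything else is
    a format error reported with its row/column coordinates. Delimiter is
    sniffed between comma and tab.
    """
    path = Path(path)
    text = path.read_text().strip("\n")
    if not text:
        raise FormatError(f"{path}: empty file")
    lines = text.split("\n")
    delim = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(delim)
    gene_ids = [c.strip() for c in header[1:]]
    if not gene_ids:
        raise FormatError(f"{path}: no gene columns")
    if len(lines) < 2:
        raise FormatError(f"{path}: empty data section")
    line_ids: list[str] = []
    rows: list[list[bool]] = []
    for rowno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(delim)]
        if len(cells) != len(gene_ids) + 1:
            raise FormatError(f"{path}:{rowno}: expected {len(gene_ids) + 1} cells")
        line_ids.append(cells[0])
        row: list[bool] = []
        for colno, cell in enumerate(cells[1:], start=2):
            low = cell.lower()
            if low in _PAV_TRUE:
                row.append(True)
            elif low in _PAV_FALSE:
                row.append(False)
            else:
                raise FormatError(
                    f"{path}: non-binary cell {cell!r} at row {rowno}, column {colno}"
                )
        rows.append(row)
    return PresenceAbsenceMatrix(
        species=species or path.stem,
        line_ids=line_ids,
        gene_ids=gene_ids,
        calls=np.array(rows, dtype=bool),
    )


def write_pav_matrix(pav: PresenceAbsenceMatrix, path: str | Path, delim: str = ",") -> None:
    with Path(path).open("w") as fh:
        fh.write(delim.join(["line_id"] + pav.gene_ids) + "\n")
        for i, lid in enumerate(pav.line_ids):
            fh.write(delim.join([lid] + [str(int(v)) for v in pav.calls[i]]) + "\n")


def pav_from_missingness(
    gm: GenotypeMissingness,
    max_missing_fraction: float = 0.8,
    species: str = "panel",
) -> PresenceAbsenceMatrix:
    """Call gene absence from SNP genotype missingness.

    A gene is called absent in a line iff missing/total exceeds
    ``max_missing_fraction``. Calls with total = 0 carry no evidence: they are
    flagged no-data so retention-rate denominators can exclude them.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    nodata = gm.total == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(nodata, 0.0, gm.missing / np.maximum(gm.total, 1))
    present = ~(frac > max_missing_fraction) & ~nodata
    return PresenceAbsenceMatrix(
        species=species,
        line_ids=list(gm.line_ids),
        gene_ids=list(gm.gene_ids),
        calls=present,
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# GFF3 gene loci
# ---------------------------------------------------------------------------

def _gff_attributes(field9: str) -> dict[str, str]:
    attrs = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff_gene_loci(path: str | Path, feature_type: str = "gene") -> list[GeneLocus]:
    """Extract gene loci from a GFF3 file and assign per-chromosome ranks.

    Only rows of ``feature_type`` are used; the gene id is the ``ID``
    attribute. Ranks are 0-based along each chromosome after sorting by
    (chrom, start, gene_id) — the gene_id tie-break makes rank assignment
    deterministic for tied starts.
    """
    loci: list[GeneLocus] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cells[2] != feature_type:
                continue
            attrs = _gff_attributes(cells[8])
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: {feature_type} row without ID")
            start1, end1 = int(cells[3]), int(cells[4])
            loci.append(
                GeneLocus(
                    gene_id=gene_id,
                    chrom=cells[0],
                    start=start1 - 1,  # GFF3 is 1-based inclusive
                    end=end1,
                    strand=cells[6] if cells[6] in "+-" else "+",
                )
            )
    return assign_ranks(loci)


def assign_ranks(loci: list[GeneLocus]) -> list[GeneLocus]:
    """Assign 0-based per-chromosome ranks ordered by (start, gene_id)."""
    out = sorted(loci, key=lambda l: (l.chrom, l.start, l.gene_id))
    counters: dict[str, int] = {}
    for locus in out:
        locus.rank = counters.get(locus.chrom, 0)
        counters[locus.chrom] = locus.rank + 1
    return out


def write_gff_gene_loci(loci: list[GeneLocus], path: str | Path, source: str = "panretain") -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            fh.write(
                "\t".join(
                    [l.chrom, source, "gene", str(l.start + 1), str(l.end), ".",
                     l.strand, ".", f"ID={l.gene_id}"]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path),
        "fasta",
    )


def validate_cds(seqs: dict[str, str], allow_internal_stops: bool = False) -> None:
    """Check CDS records: length divisible by 3, no internal stop codons."""
    for name, seq in seqs.items():
        if len(seq) % 3:
            raise ValidationError(f"CDS {name!r}: length {len(seq)} not divisible by 3")
        aa = translate(seq)
        internal = aa[:-1]
        if "*" in internal and not allow_internal_stops:
            pos = internal.index("*")
            raise ValidationError(
                f"CDS {name!r}: internal stop codon at codon {pos + 1}"
            )


# ---------------------------------------------------------------------------
# Newick trees with "#k" branch labels
# ---------------------------------------------------------------------------

def read_newick_labeled(path_or_string: str | Path) -> LabeledTree:
    """Read a Newick tree, interpreting ``#k`` label suffixes as foreground
    branch classes (the convention of the common codon-selection tools).

    A ``#k`` suffix on a tip or internal node marks the branch above that
    node with class k; unlabeled branches are class 0 (background).
    Polytomies are arbitrarily resolved to make the tree binary (with
    zero-length inserted branches); the number of resolutions is recorded.
    """
    text = str(path_or_string)
    if "(" not in text:
        text = Path(path_or_string).read_text()
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for node in tree.preorder_node_iter():
        label_holder = node.taxon if node.taxon is not None else node
        raw = label_holder.label or ""
        cls = 0
        if "#" in raw:
            base, _, suffix = raw.rpartition("#")
            try:
                cls = int(suffix)
            except ValueError as exc:
                raise FormatError(f"bad branch label suffix {raw!r}") from exc
            label_holder.label = base
        if node.edge is not None:
            node.edge.branch_class = cls

    n_resolved = sum(
        max(0, len(n.child_nodes()) - 2) for n in tree.preorder_node_iter()
    )
    if n_resolved:
        tree.resolve_polytomies(limit=2)
        for node in tree.preorder_node_iter():
            if not hasattr(node.edge, "branch_class"):
                node.edge.branch_class = 0
            if node.edge.length is None and node.parent_node is not None:
                node.edge.length = 0.0
        logger.info("resolved %d polytomy branch(es) arbitrarily", n_resolved)
    return LabeledTree(tree=tree, n_resolved_polytomies=n_resolved)


def write_newick_labeled(lt: LabeledTree, path: str | Path | None = None) -> str:
    """Serialise a labeled tree back to Newick with ``#k`` suffixes."""

    def render(node) -> str:
        cls = getattr(node.edge, "branch_class", 0)
        suffix = f"#{cls}" if cls else ""
        length = f":{node.edge.length:g}" if node.edge.length is not None else ""
        if node.is_leaf():
            return f"{node.taxon.label}{suffix}{length}"
        inner = ",".join(render(c) for c in node.child_nodes())
        label = node.label or ""
        return f"({inner}){label}{suffix}{length}"

    text = render(lt.tree.seed_node) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
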