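"""Seeded generators for every input the retention pipeline consumes.

Each generator is a pure function of (configuration, seed) and returns both
the synthetic data and its ground truth, so every pipeline stage can be
tested end-to-end without external genome downloads:

* ``gen_pangenome`` — a three-species panel (diploid/tetraploid/hexaploid,
  20/20/15 lines by default) with hierarchical orthogroups nested in parent
  orthogroups and per-line gene loss following a logistic dosage model:
  retention probability decreases with gene family size and with ploidy,
  the minimal monotone form of the gene-dosage-constraint hypothesis.
* ``gen_genome_layout`` — a gene layout with planted, non-overlapping
  tandem/proximal/dispersed/segmental duplication events and the homology
  hits they would produce.
* ``evolve_codons`` — codon alignments evolved along a labeled tree under
  branch-specific omega or a branch-site class mixture (no stop codons by
  construction, states live on the 61 sense codons).
* ``gen_go`` — gene->GO annotation tables with one term planted at a chosen
  fold enrichment in a designated query set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import SENSE_CODONS
from .codonmodel import SiteClassMix, TransitionCache, flatten_tree, model_a_caches
from .dupclass import DupClass, HomologyHit
from .io import GeneLocus, HogRecord, LabeledTree, PresenceAbsenceMatrix, assign_ranks


# ---------------------------------------------------------------------------
# Panel and loss-model configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    ploidy: int
    n_lines: int


@dataclass(frozen=True)
class PanelSpec:
    """Default panel mirrors the published study conditions: a diploid
    panel of 20 lines, a tetraploid panel of 20, a hexaploid panel of 15."""

    species: tuple[SpeciesSpec, ...] = (
        SpeciesSpec("barley", 2, 20),
        SpeciesSpec("emmer", 4, 20),
        SpeciesSpec("wheat", 6, 15),
    )

    def __post_init__(self) -> None:
        if any(s.n_lines < 1 for s in self.species):
            raise ValueError("every species needs at least one line")
        if any(s.ploidy not in (2, 4, 6) for s in self.species):
            raise ValueError("ploidy must be 2, 4 or 6")


@dataclass(frozen=True)
class LossModel:
    """Logistic gene-retention model.

    Retention probability of a gene from a family of f HOGs in a species of
    given ploidy:

        p = logistic(beta0 - b_f * (f - 1) - beta_ploidy * (ploidy/2 - 1))
        b_f = beta_family + beta_interact * (ploidy/2 - 1)

    beta_family and beta_ploidy are >= 0 so larger families and higher
    ploidy can only lower retention; beta_interact > 0 makes the
    family-size effect steeper at higher ploidy (the observed
    dosage-constraint-increases-with-ploidy pattern).
    """

    beta0: float = 4.0
    beta_family: float = 0.4
    beta_ploidy: float = 0.5
    beta_interact: float = 0.2

    def __post_init__(self) -> None:
        if self.beta_family < 0 or self.beta_ploidy < 0 or self.beta_interact < 0:
            raise ValueError("dosage coefficients must be non-negative")

    def retention_prob(self, family_size: int, ploidy: int) -> float:
        extra_sets = ploidy / 2.0 - 1.0
        slope = self.beta_family + self.beta_interact * extra_sets
        logit = self.beta0 - slope * (family_size - 1) - self.beta_ploidy * extra_sets
        return 1.0 / (1.0 + np.exp(-logit))


@dataclass
class TruthBundle:
    """Ground truth attached to generated data."""

    retention_prob: dict[tuple[str, str], float] = field(default_factory=dict)
    family_size: dict[str, int] = field(default_factory=dict)  # og_id -> n HOGs
    dup_class: dict[str, DupClass] = field(default_factory=dict)
    site_class: np.ndarray | None = None  # per-site simulated class index
    planted_term: str | None = None


# ---------------------------------------------------------------------------
# Pangenome generator
# ---------------------------------------------------------------------------

def _truncated_geometric_sizes(rng, n, p=0.5, truncate_at=12) -> np.ndarray:
    """Family sizes >= 1 from a geometric(p) (mean 1/p = 2) truncated at 12."""
    sizes = rng.geometric(p, size=n)
    return np.minimum(sizes, truncate_at)


def gen_pangenome(
    panel: PanelSpec = PanelSpec(),
    n_ogs: int = 500,
    loss: LossModel = LossModel(),
    seed: int = 0,
    family_size_p: float = 0.5,
    family_size_max: int = 12,
):
    """Generate HOG table + per-species PAV matrices + truth.

    Each parent OG holds a geometric number of HOGs (mean 2, truncated);
    each HOG carries exactly one gene per species; each pangenome line
    carries the gene independently with the loss-model retention
    probability. Fully reproducible under the seed.

    Returns (hogs, pavs, truth).
    """
    rng = np.random.default_rng(seed)
    sizes = _truncated_geometric_sizes(rng, n_ogs, family_size_p, family_size_max)
    hogs: list[HogRecord] = []
    truth = TruthBundle()
    for og_i, fam in enumerate(sizes):
        og_id = f"OG{og_i:05d}"
        truth.family_size[og_id] = int(fam)
        for h in range(int(fam)):
            hog_id = f"{og_id}.H{h}"
            genes = {
                sp.name: [f"{sp.name}_{og_i:05d}_{h}"] for sp in panel.species
            }
            hogs.append(HogRecord(hog_id, og_id, genes, clade="N1"))
            for sp in panel.species:
                truth.retention_prob[(hog_id, sp.name)] = loss.retention_prob(
                    int(fam), sp.ploidy
                )
    pavs: dict[str, PresenceAbsenceMatrix] = {}
    for sp in panel.species:
        gene_ids = [h.genes_by_species[sp.name][0] for h in hogs]
        probs = np.array([truth.retention_prob[(h.hog_id, sp.name)] for h in hogs])
        calls = rng.random((sp.n_lines, len(gene_ids))) < probs[None, :]
        pavs[sp.name] = PresenceAbsenceMatrix(
            species=sp.name,
            line_ids=[f"{sp.name}_line{i:03d}" for i in range(sp.n_lines)],
            gene_ids=gene_ids,
            calls=calls,
        )
    return hogs, pavs, truth


# ---------------------------------------------------------------------------
# Genome layout generator
# ---------------------------------------------------------------------------

_GENE_SPAN = 600
_GENE_SPACING = 1000


def gen_genome_layout(
    n_chrom: int = 4,
    genes_per_chrom: int = 60,
    events: dict[DupClass, int] | None = None,
    proximal_window: int = 10,
    min_block_size: int = 5,
    seed: int = 0,
):
    """Plant non-overlapping duplication events in a fresh gene layout.

    Every gene starts as a singleton; each planted event marks its genes
    with the corresponding truth class and emits homology hits (e-value
    1e-30) between the duplicate partners. Segmental events pair
    ``min_block_size`` consecutive genes on two chromosomes so the anchors
    chain into a collinear block.

    Returns (loci, hits, truth_classes).
    """
    if events is None:
        events = {
            DupClass.TANDEM: 2,
            DupClass.PROXIMAL: 2,
            DupClass.DISPERSED: 2,
            DupClass.WGD_SEGMENTAL: 1,
        }
    rng = np.random.default_rng(seed)
    free: dict[str, set[int]] = {
        f"chr{c + 1}": set(range(genes_per_chrom)) for c in range(n_chrom)
    }
    chroms = sorted(free)
    truth: dict[str, DupClass] = {}
    hits: list[HomologyHit] = []

    def gene_name(chrom: str, rank: int) -> str:
        return f"{chrom}g{rank:04d}"

    def claim(chrom: str, ranks) -> None:
        free[chrom] -= set(ranks)

    def add_hit(g1: str, g2: str) -> None:
        hits.append(HomologyHit(g1, g2, 1e-30, 500.0))

    def pick_run(length: int, margin: int = 1) -> tuple[str, int]:
        """A chromosome and start rank with `length` consecutive free ranks,
        separated from used ranks by `margin` to keep events non-overlapping."""
        order = rng.permutation(len(chroms))
        for ci in order:
            chrom = chroms[ci]
            candidates = [
                s
                for s in range(genes_per_chrom - length + 1)
                if all(
                    r in free[chrom]
                    for r in range(max(0, s - margin), min(genes_per_chrom, s + length + margin))
                )
            ]
            if candidates:
                return chrom, int(rng.choice(candidates))
        raise ValueError("layout too small for the requested events")

    for cls in (DupClass.WGD_SEGMENTAL, DupClass.TANDEM,
                DupClass.PROXIMAL, DupClass.DISPERSED):
        for _ in range(events.get(cls, 0)):
            if cls is DupClass.TANDEM:
                chrom, s = pick_run(2)
                g1, g2 = gene_name(chrom, s), gene_name(chrom, s + 1)
                claim(chrom, (s, s + 1))
                truth[g1] = truth[g2] = cls
                add_hit(g1, g2)
            elif cls is DupClass.PROXIMAL:
                gap = int(rng.integers(2, proximal_window + 1))
                chrom, s = pick_run(gap + 1)
                g1, g2 = gene_name(chrom, s), gene_name(chrom, s + gap)
                claim(chrom, (s, s + gap))
                truth[g1] = truth[g2] = cls
                add_hit(g1, g2)
            elif cls is DupClass.DISPERSED:
                c1, s1 = pick_run(1)
                c2, s2 = pick_run(1)
                while c2 == c1:
                    c2, s2 = pick_run(1)
                g1, g2 = gene_name(c1, s1), gene_name(c2, s2)
                claim(c1, (s1,))
                claim(c2, (s2,))
                truth[g1] = truth[g2] = cls
                add_hit(g1, g2)
            else:  # segmental block
                c1, s1 = pick_run(min_block_size)
                claim(c1, range(s1, s1 + min_block_size))
                c2, s2 = pick_run(min_block_size)
                claim(c2, range(s2, s2 + min_block_size))
                for k in range(min_block_size):
                    g1 = gene_name(c1, s1 + k)
                    g2 = gene_name(c2, s2 + k)
                    truth[g1] = truth[g2] = cls
                    add_hit(g1, g2)

    loci = [
        GeneLocus(
            gene_id=gene_name(chrom, r),
            chrom=chrom,
            start=r * _GENE_SPACING,
            end=r * _GENE_SPACING + _GENE_SPAN,
            strand="+" if (r % 2 == 0) else "-",
        )
        for chrom in chroms
        for r in range(genes_per_chrom)
    ]
    loci = assign_ranks(loci)
    for locus in loci:
        truth.setdefault(locus.gene_id, DupClass.SINGLETON)
    return loci, hits, truth


# ---------------------------------------------------------------------------
# Codon alignment evolution
# ---------------------------------------------------------------------------

def _sample_states(rng, p_matrix: np.ndarray, parent_states: np.ndarray) -> np.ndarray:
    cum = np.cumsum(p_matrix, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.size)
    rows = cum[parent_states]
    return (rows < u[:, None]).sum(axis=1)


def evolve_codons(
    lt: LabeledTree,
    kappa: float,
    omega_by_label: dict[int, float] | None,
    pi: np.ndarray,
    n_codons: int,
    seed: int = 0,
    site_mix: SiteClassMix | None = None,
):
    """Evolve a codon alignment along a labeled tree.

    Either ``omega_by_label`` (branch model: one omega per branch class) or
    ``site_mix`` (branch-site Model A classes) must be given. Root codons
    are drawn from pi; each branch applies the transition matrix of its
    scaled rate matrix over its length. Returns (alignment, truth) where
    truth.site_class holds the simulated class per site (all zeros for a
    pure branch model).
    """
    if (omega_by_label is None) == (site_mix is None):
        raise ValueError("give exactly one of omega_by_label or site_mix")
    rng = np.random.default_rng(seed)
    flat = flatten_tree(lt)
    pi = np.asarray(pi, dtype=float)

    if site_mix is not None:
        props = site_mix.proportions
        site_class = rng.choice(4, size=n_codons, p=props / props.sum())
        mix_caches = model_a_caches(site_mix)
    else:
        site_class = np.zeros(n_codons, dtype=int)
        mix_caches = None

    states: dict[int, np.ndarray] = {
        flat.root: rng.choice(len(SENSE_CODONS), size=n_codons, p=pi / pi.sum())
    }
    cache: dict[float, TransitionCache] = {}

    def transition(omega: float) -> TransitionCache:
        if omega not in cache:
            cache[omega] = TransitionCache(kappa, omega, pi)
        return cache[omega]

    # preorder over nodes: parents before children
    preorder: list[int] = []
    stack = [flat.root]
    while stack:
        node = stack.pop()
        preorder.append(node)
        stack.extend(reversed(flat.children.get(node, [])))

    for node in preorder:
        for child in flat.children.get(node, []):
            btype = "fg" if flat.bclass[child] >= 1 else "bg"
            t = flat.blen[child]
            child_states = np.empty(n_codons, dtype=int)
            if site_mix is not None:
                for cls in range(4):
                    mask = site_class == cls
                    if not mask.any():
                        continue
                    p = mix_caches[(btype, cls)].p_matrix(t)
                    child_states[mask] = _sample_states(rng, p, states[node][mask])
            else:
                w = omega_by_label.get(flat.bclass[child], omega_by_label.get(0))
                p = transition(w).p_matrix(t)
                child_states[:] = _sample_states(rng, p, states[node])
            states[child] = child_states

    tip_ids = [i for i in range(flat.n_nodes) if i not in flat.children]
    nodes = list(lt.tree.preorder_node_iter())
    alignment = {}
    for i in tip_ids:
        name = nodes[i].taxon.label
        alignment[name] = "".join(SENSE_CODONS[s] for s in states[i])
    truth = TruthBundle(site_class=site_class)
    return alignment, truth


# ---------------------------------------------------------------------------
# GO annotation generator
# ---------------------------------------------------------------------------

def gen_go(
    universe_size: int = 20000,
    n_terms: int = 50,
    query_size: int = 300,
    planted_fold: float = 5.0,
    planted_term_size: int = 100,
    term_size_range: tuple[int, int] = (20, 200),
    seed: int = 0,
):
    """Generate a gene->GO annotation table with one planted enriched term.

    Unplanted terms draw their genes uniformly from the universe; the
    planted term's overlap with the designated query set is
    planted_fold x the null expectation (capped at the term size).
    Returns (annotation DataFrame, query gene list, truth).
    """
    if planted_fold < 0:
        raise ValueError("fold must be non-negative")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:06d}" for i in range(universe_size)])
    query = list(rng.choice(genes, size=query_size, replace=False))
    query_set = set(query)
    namespaces = np.array(["MF", "BP", "CC"])

    rows = []
    for t in range(n_terms):
        term_id = f"GO:{t + 1:07d}"
        ns = namespaces[t % 3]
        if t == 0:
            expected = planted_term_size * query_size / universe_size
            k = min(planted_term_size, int(round(planted_fold * expected)))
            in_query = rng.choice(sorted(query_set), size=k, replace=False)
            outside = rng.choice(
                sorted(set(genes) - query_set),
                size=planted_term_size - k,
                replace=False,
            )
            members = list(in_query) + list(outside)
        else:
            size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
            members = list(rng.choice(genes, size=size, replace=False))
        rows.extend(
            {
                "gene_id": g,
                "term_id": term_id,
                "term_name": f"term {t + 1}",
                "namespace": ns,
            }
            for g in members
        )
    annotation = pd.DataFrame(rows)
    # every universe gene appears so the default universe is complete
    annotated = set(annotation["gene_id"])
    rest = [g for g in genes if g not in annotated]
    if rest:
        filler = pd.DataFrame(
            {
                "gene_id": rest,
                "term_id": "GO:9999999",
                "term_name": "background bucket",
                "namespace": "BP",
            }
        )
        annotation = pd.concat([annotation, filler], ignore_index=True)
    truth = TruthBundle(planted_term="GO:0000001")
    return annotation, query, truth


def gen_go_for_pangenome(
    hogs,
    truth: TruthBundle,
    species: str = "barley",
    other_species: str = "wheat",
    n_terms: int = 30,
    planted_term_size: int = 60,
    planted_bias: float = 0.9,
    term_size_range: tuple[int, int] = (15, 80),
    seed: int = 0,
):
    """GO annotation for a generated pangenome with function-linked bias.

    The universe is the reference species' genes. One planted term draws
    ``planted_bias`` of its members from genes whose true retention is
    dosage-biased toward the reference species (true retention ratio >=
    1.2), emulating a functional category preferentially retained in the
    lower-ploidy species; all other terms are uniform. Enrichment on the
    observed preferential category should recover the planted term while
    the neutral category should not.
    """
    rng = np.random.default_rng(seed)
    universe, biased = [], []
    for h in hogs:
        genes = h.genes_by_species.get(species, [])
        universe.extend(genes)
        pa = truth.retention_prob.get((h.hog_id, species))
        pb = truth.retention_prob.get((h.hog_id, other_species))
        if pa is not None and pb is not None and pb > 0 and pa / pb >= 1.2:
            biased.extend(genes)
    if not universe:
        raise ValueError(f"no genes for species {species!r}")
    unbiased = sorted(set(universe) - set(biased))
    rows = []
    namespaces = ("MF", "BP", "CC")
    for t in range(n_terms):
        term_id = f"GO:{t + 1:07d}"
        if t == 0 and biased:
            size = min(planted_term_size, len(universe))
            k = min(len(biased), int(round(planted_bias * size)))
            members = list(rng.choice(biased, size=k, replace=False))
            if size - k > 0 and unbiased:
                members += list(
                    rng.choice(unbiased, size=min(size - k, len(unbiased)), replace=False)
                )
        else:
            size = int(rng.integers(*term_size_range))
            members = list(rng.choice(universe, size=min(size, len(universe)), replace=False))
        rows.extend(
            {"gene_id": g, "term_id": term_id, "term_name": f"term {t + 1}",
             "namespace": namespaces[t % 3]}
            for g in members
        )
    annotated = {r["gene_id"] for r in rows}
    rows.extend(
        {"gene_id": g, "term_id": "GO:9999999", "term_name": "background bucket",
         "namespace": "BP"}
        for g in universe
        if g not in annotated
    )
    out_truth = TruthBundle(
        retention_prob=dict(truth.retention_prob),
        family_size=dict(truth.family_size),
        planted_term="GO:0000001",
    )
    return pd.DataFrame(rows), out_truth
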