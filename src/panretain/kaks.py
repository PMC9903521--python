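"""Pairwise Ka/Ks by the Nei–Gojobori (1986) counting method.

The estimator counts, per codon, the fraction of single-nucleotide changes
that are synonymous (synonymous "sites"), averages difference counts over
all mutational pathways between diverged codons, and applies the
Jukes–Cantor correction d = -(3/4) ln(1 - (4/3) p) to the raw proportions.
Conventions (documented because published variants differ):

* site fractions are computed among non-stop single-nucleotide changes and
  each codon contributes exactly 3 sites (s + n = 3), so S + N = 3·codons;
* pathways through stop codons are discarded before averaging; in the
  pathological case where every pathway is blocked, all pathways are used
  with each step classified by its actual synonymy;
* omega = Ka/Ks is reported as NaN when Ks = 0 (optionally +inf when Ka > 0).

Also here: codon back-translation of protein alignments (the usual route
from a protein aligner to a codon alignment), relative Ka/Ks versus the
orthogroup mean, histogram binning of omega and thin t-test wrappers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from ._codons import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, NUCLEOTIDES, translate

GAP_CODON = "---"


@dataclass
class KaKsResult:
    S: float      # synonymous sites
    N: float      # nonsynonymous sites
    Sd: float     # synonymous differences (pathway-averaged)
    Nd: float     # nonsynonymous differences
    pS: float
    pN: float
    Ks: float     # Jukes-Cantor corrected dS (NaN when saturated)
    Ka: float     # corrected dN
    omega: float  # Ka/Ks; NaN when undefined
    n_codons: int


# ---------------------------------------------------------------------------
# Back-translation
# ---------------------------------------------------------------------------

def backtranslate(
    protein_alignment: dict[str, str], cds_by_id: dict[str, str]
) -> dict[str, str]:
    """Expand an aligned protein set to a codon alignment using each
    sequence's CDS; every residue becomes its codon, every gap ``---``.

    The ungapped protein must translate exactly from the CDS (standard code,
    a trailing stop codon on the CDS is tolerated and dropped).
    """
    out: dict[str, str] = {}
    lengths = {len(s) for s in protein_alignment.values()}
    if len(lengths) > 1:
        raise ValueError("protein alignment rows have unequal lengths")
    for name, prot in protein_alignment.items():
        if name not in cds_by_id:
            raise ValueError(f"no CDS for aligned sequence {name!r}")
        cds = cds_by_id[name]
        if len(cds) % 3:
            raise ValueError(f"CDS {name!r}: length not divisible by 3")
        aa = translate(cds)
        if aa.endswith("*"):
            aa = aa[:-1]
            cds = cds[:-3]
        ungapped = prot.replace("-", "")
        if aa != ungapped:
            pos = next(
                (i for i, (x, y) in enumerate(zip(aa, ungapped)) if x != y),
                min(len(aa), len(ungapped)),
            )
            raise ValueError(
                f"CDS/protein mismatch for {name!r} at residue {pos + 1}"
            )
        codons, k = [], 0
        for residue in prot:
            if residue == "-":
                codons.append(GAP_CODON)
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        out[name] = "".join(codons)
    return out


# ---------------------------------------------------------------------------
# NG86 counting tables (precomputed over the 61 sense codons)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; sums to 3."""
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two sense codons."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diffs)]
    valid = [r for r in results if r is not None]
    if not valid:
        # all pathways blocked by stops: classify stop-passing steps as-is
        def walk_any(order):
            sd = nd = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            return sd, nd

        valid = [walk_any(order) for order in itertools.permutations(diffs)]
    sd = sum(r[0] for r in valid) / len(valid)
    nd = sum(r[1] for r in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Pairwise NG86
# ---------------------------------------------------------------------------

def _iter_codon_pairs(seq1: str, seq2: str):
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length not divisible by 3")
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if "-" in c1 or "-" in c2:
            if c1 != GAP_CODON and "-" in c1 or c2 != GAP_CODON and "-" in c2:
                raise ValueError(f"partial gap codon at alignment codon {i // 3 + 1}")
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"stop codon at alignment codon {i // 3 + 1}")
        yield c1, c2


def ng86(seq1: str, seq2: str, inf_omega: bool = False) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for one aligned CDS pair (symmetric in order).

    S is the mean of the two sequences' per-codon synonymous site sums;
    pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected into Ks and Ka.
    """
    s1 = s2 = sd = nd = 0.0
    n_codons = 0
    for c1, c2 in _iter_codon_pairs(seq1.upper(), seq2.upper()):
        n_codons += 1
        s1 += _codon_sites(c1)[0]
        s2 += _codon_sites(c2)[0]
        d = _pair_differences(c1, c2)
        sd += d[0]
        nd += d[1]
    if n_codons == 0:
        raise ValueError("no shared ungapped codon")
    S = (s1 + s2) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else math.nan
    pN = nd / N if N > 0 else math.nan
    Ks = jukes_cantor(pS) if not math.isnan(pS) else math.nan
    Ka = jukes_cantor(pN) if not math.isnan(pN) else math.nan
    if math.isnan(Ks) or Ks == 0.0:
        omega = math.nan
        if Ks == 0.0 and Ka == 0.0:
            omega = math.nan
        elif Ks == 0.0 and inf_omega:
            omega = math.inf
    else:
        omega = Ka / Ks
    return KaKsResult(S, N, sd, nd, pS, pN, Ks, Ka, omega, n_codons)


# ---------------------------------------------------------------------------
# Derived statistics
# ---------------------------------------------------------------------------

def relative_kaks(omega_by_gene: dict[str, float], gene: str) -> float:
    """Gene omega divided by its orthogroup's mean omega (genes with
    undefined omega excluded from the mean); > 1 flags elevated Ka/Ks."""
    if gene not in omega_by_gene:
        raise KeyError(gene)
    defined = [v for v in omega_by_gene.values() if not math.isnan(v) and math.isfinite(v)]
    if not defined:
        raise ValueError("no defined omega in orthogroup")
    mean = float(np.mean(defined))
    if mean <= 0:
        raise ValueError("orthogroup mean omega must be positive")
    return omega_by_gene[gene] / mean


def kaks_bins(omegas, edges=(0.0, 0.5, 1.0, 2.2)) -> dict[str, int]:
    """Histogram of defined omega values over half-open bins
    [e0,e1), ..., [e_last, inf); NaN values are dropped."""
    vals = [v for v in omegas if not math.isnan(v)]
    edges = list(edges)
    labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
    labels.append(f"[{edges[-1]:g},inf)")
    counts = dict.fromkeys(labels, 0)
    for v in vals:
        for i in range(len(edges) - 1):
            if edges[i] <= v < edges[i + 1]:
                counts[labels[i]] += 1
                break
        else:
            if v >= edges[-1]:
                counts[labels[-1]] += 1
    return counts


def two_sample_ttest(a, b) -> tuple[float, float]:
    """Two-tailed two-sample t test (equal-variance); returns (t, p)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def one_sample_ttest(a, popmean: float) -> tuple[float, float]:
    """Two-tailed one-sample t test against ``popmean``; returns (t, p)."""
    res = stats.ttest_1samp(np.asarray(a, float), popmean)
    return float(res.statistic), float(res.pvalue)
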