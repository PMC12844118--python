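"""Molecular-evolution statistics.

Implements the Nei-Gojobori (1986) codon-based estimator of synonymous and
nonsynonymous substitution rates (Ks, Ka): fractional synonymous-site
counting, pathway-averaged difference counting, and Jukes-Cantor multiple-
hit correction.  Also provides the Welch t contrast of Ks between genomic
regions, ancestral gene-content reconstruction from ortholog/orphan counts,
and gene-loss rates.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "KsEstimate",
    "LossSummary",
    "RegionContrast",
    "syn_site_fraction",
    "codon_path_differences",
    "nei_gojobori",
    "codon_align",
    "welch_t",
    "ancestral_gene_count",
    "loss_rate",
    "region_contrast",
    "jukes_cantor",
]

_BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

# codon -> amino acid for the standard genetic code; stops excluded
_CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)

MIN_CODONS = 10  # below this an estimate is flagged "short" and suppressed


def _is_sense(codon: str) -> bool:
    return codon in _CODON_AA


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); ValueError if saturated."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise ValueError(f"proportion p={p} is saturated under Jukes-Cantor")
    return -0.75 * math.log(arg)


@functools.cache
def syn_site_fraction(codon: str) -> float:
    """Fractional number of synonymous sites in one sense codon.

    Each of the three positions contributes (synonymous single-base
    changes)/3; mutations producing a stop codon count as nonsynonymous,
    following the classic Nei-Gojobori convention.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    aa = _CODON_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _is_sense(mutant) and _CODON_AA[mutant] == aa:
                syn += 1.0
    return syn / 3.0


@functools.cache
def codon_path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) step counts between codons.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded from the average.  If every
    pathway is excluded the fallback counts all steps as nonsynonymous.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if len(c) != 3 or any(x not in _BASES for x in c):
            raise ValueError(f"invalid codon {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c!r} not allowed")
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return (0.0, 0.0)

    path_counts: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        current = a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if _CODON_AA[current] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            path_counts.append((sd, nd))
    if not path_counts:
        return (0.0, float(len(diff_positions)))
    sd_mean = sum(s for s, _ in path_counts) / len(path_counts)
    nd_mean = sum(n for _, n in path_counts) / len(path_counts)
    return (sd_mean, nd_mean)


@dataclass
class KsEstimate:
    """Nei-Gojobori site and difference counts with corrected rates."""

    gene_a: str
    gene_b: str
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    pS: float | None = None
    pN: float | None = None
    Ks: float | None = None
    Ka: float | None = None
    n_codons_used: int = 0
    flags: set[str] = field(default_factory=set)


_PROTEIN_ALIGNER: PairwiseAligner | None = None


def _protein_aligner() -> PairwiseAligner:
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        aligner.mode = "global"
        _PROTEIN_ALIGNER = aligner
    return _PROTEIN_ALIGNER


def _translate(cds: str) -> str:
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            aa.append("*")
        elif all(b in _BASES for b in codon):
            aa.append(_CODON_AA[codon])
        else:
            aa.append("X")
    return "".join(aa)


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Codon-aware pairwise alignment of two coding sequences.

    Translations are globally aligned at the protein level and the gaps are
    back-projected onto codons, which keeps all alignment gaps frame-
    preserving.  Terminal stop codons are trimmed first.  Returns the list
    of aligned codon pairs with gap codons as '---'.
    """
    a, b = cds_a.upper(), cds_b.upper()
    a = a[: len(a) - len(a) % 3]
    b = b[: len(b) - len(b) % 3]
    if a[-3:] in STOP_CODONS:
        a = a[:-3]
    if b[-3:] in STOP_CODONS:
        b = b[:-3]
    if not a or not b:
        return []
    prot_a, prot_b = _translate(a), _translate(b)
    # internal stops / ambiguity become 'X' for alignment purposes
    safe_a, safe_b = prot_a.replace("*", "X"), prot_b.replace("*", "X")
    alignment = _protein_aligner().align(safe_a, safe_b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    pairs: list[tuple[str, str]] = []
    ia = ib = 0
    for col in range(len(aligned_a)):
        ca = a[3 * ia : 3 * ia + 3] if aligned_a[col] != "-" else "---"
        cb = b[3 * ib : 3 * ib + 3] if aligned_b[col] != "-" else "---"
        if aligned_a[col] != "-":
            ia += 1
        if aligned_b[col] != "-":
            ib += 1
        pairs.append((ca, cb))
    return pairs


def nei_gojobori(
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    min_codons: int = MIN_CODONS,
) -> KsEstimate:
    """Estimate Ks and Ka for one coding-sequence pair (Nei-Gojobori 1986).

    Sequences are codon-aligned via their translations; codon columns with
    a gap, an ambiguity base, or a stop codon are dropped.  Site counts are
    averaged over the two sequences; differences are pathway-averaged per
    codon pair; rates are Jukes-Cantor corrected.  Pairs with fewer than
    ``min_codons`` usable codons are flagged short with rates suppressed.
    """
    est = KsEstimate(gene_a=gene_a, gene_b=gene_b)
    usable: list[tuple[str, str]] = []
    for ca, cb in codon_align(cds_a, cds_b):
        if "-" in ca or "-" in cb:
            continue
        if any(x not in _BASES for x in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        usable.append((ca, cb))

    est.n_codons_used = len(usable)
    if len(usable) < min_codons:
        est.flags.add("short")
        return est

    s_a = sum(syn_site_fraction(ca) for ca, _ in usable)
    s_b = sum(syn_site_fraction(cb) for _, cb in usable)
    est.S = (s_a + s_b) / 2.0
    est.N = 3.0 * len(usable) - est.S
    for ca, cb in usable:
        sd, nd = codon_path_differences(ca, cb)
        est.Sd += sd
        est.Nd += nd

    est.pS = est.Sd / est.S if est.S > 0 else 0.0
    est.pN = est.Nd / est.N if est.N > 0 else 0.0
    try:
        est.Ks = jukes_cantor(est.pS)
    except ValueError:
        est.flags.add("saturated_S")
    try:
        est.Ka = jukes_cantor(est.pN)
    except ValueError:
        est.flags.add("saturated_N")
    return est


def welch_t(group_1: Sequence[float], group_2: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t test on two samples.

    Both groups entirely constant and equal returns (0, 1) by contract.
    """
    x, y = np.asarray(group_1, float), np.asarray(group_2, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return (0.0, 1.0)
        # constant groups with different means: infinitely strong separation
        return (math.copysign(math.inf, float(np.mean(x) - np.mean(y))), 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return (float(t), float(p))


def ancestral_gene_count(
    region_genes_a: Iterable[str],
    region_genes_b: Iterable[str],
    ortholog_map: Mapping[str, str],
    split_merge_map: Mapping[str, str] | None = None,
) -> int:
    """Minimum ancestral gene number for a pair of orthologous regions.

    Split daughters are first collapsed onto their mother gene via
    ``split_merge_map``.  The count is then: ortholog pairs within the
    region, plus region genes of either species without an ortholog (each
    orphan assumed present in the ancestor and lost in the other lineage).
    """
    merge = split_merge_map or {}

    def collapse(genes: Iterable[str]) -> list[str]:
        seen: list[str] = []
        for g in genes:
            m = merge.get(g, g)
            if m not in seen:
                seen.append(m)
        return seen

    genes_a = collapse(region_genes_a)
    genes_b = set(collapse(region_genes_b))
    fwd = {merge.get(k, k): merge.get(v, v) for k, v in ortholog_map.items()}
    rev = {v: k for k, v in fwd.items()}

    pairs = sum(1 for g in genes_a if fwd.get(g) in genes_b)
    orphans_a = sum(1 for g in genes_a if fwd.get(g) not in genes_b)
    orphans_b = sum(1 for g in genes_b if rev.get(g) not in genes_a)
    return pairs + orphans_a + orphans_b


def loss_rate(ancestral: int, retained: int, decimals: int = 1) -> float:
    """Percent gene loss, 100*(ancestral - retained)/ancestral.

    Region-scope rates are conventionally reported to 1 decimal,
    genome-scope rates to 2 (pass ``decimals=2``).
    """
    if ancestral <= 0:
        raise ValueError("ancestral count must be positive")
    if not 0 <= retained <= ancestral:
        raise ValueError("retained must satisfy 0 <= retained <= ancestral")
    return round(100.0 * (ancestral - retained) / ancestral, decimals)


@dataclass
class LossSummary:
    scope: str  # "region" or "genome"
    species: str
    ancestral_count: int
    retained_count: int
    orphan_count: int
    loss_rate: float


@dataclass
class RegionContrast:
    mean_ks_affected: float
    mean_ks_background: float
    ratio: float
    t_stat: float
    p_value: float
    n_affected: int
    n_background: int


def region_contrast(
    ks_affected: Sequence[float], ks_background: Sequence[float]
) -> RegionContrast:
    """Contrast mean Ks of an affected region against background orthologs.

    The fold elevation is reported to 2 decimals alongside the Welch t test.
    """
    if len(ks_affected) == 0 or len(ks_background) == 0:
        raise ValueError("both Ks groups must be non-empty")
    mean_aff = float(np.mean(ks_affected))
    mean_bg = float(np.mean(ks_background))
    if mean_bg <= 0:
        raise ValueError("background mean Ks must be positive")
    if len(ks_affected) >= 2 and len(ks_background) >= 2:
        t, p = welch_t(ks_affected, ks_background)
    else:
        t, p = float("nan"), float("nan")
    return RegionContrast(
        mean_ks_affected=mean_aff,
        mean_ks_background=mean_bg,
        ratio=round(mean_aff / mean_bg, 2),
        t_stat=t,
        p_value=p,
        n_affected=len(ks_affected),
        n_background=len(ks_background),
    )
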