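"""Quartet-level gene-conversion inference.

Two within-species paralogs, their cross-species orthologs, and a best-hit
outgroup form a homologous gene quartet.  Under lineage-independent
divergence the expected topology pairs each paralog with its ortholog;
ectopic gene conversion homogenizes the paralogs and pulls them together
as sisters instead.  This module builds neighbor-joining trees from
Jukes-Cantor distances, classifies the quartet topology into a conversion
verdict, delineates converted tracts and hypermutated flanks along the
paralog alignment, contrasts segment identities with a chi-square test,
and detects stop-codon gene splits through alignment projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import dendropy
from scipy import stats

from .evostats import STOP_CODONS
from .homology import Alignment, DEFAULT_SCORING, ScoringScheme, global_align

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "ConversionCall",
    "TractSegment",
    "SplitEvent",
    "jc_distance",
    "nj_tree",
    "star_msa",
    "distance_matrix_from_msa",
    "classify_quartet_topology",
    "bootstrap_support",
    "delineate_tracts",
    "window_contrast_test",
    "detect_split",
]

CONVERSION_MIN_IDENTITY = 0.92  # homology floor for conversion competence
TRACT_MIN_IDENTITY = 0.95
FLANK_MAX_IDENTITY = 0.70
SATURATION_P = 0.75


def jc_distance(aligned_a: str, aligned_b: str) -> tuple[float, bool]:
    """Jukes-Cantor distance over gap-free columns; returns (d, saturated).

    When the mismatch proportion reaches the model ceiling (p >= 0.75) the
    distance is capped at the value just inside the domain and flagged.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    mismatches = 0
    gapfree = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            gapfree += 1
            if x != y:
                mismatches += 1
    if gapfree == 0:
        raise ValueError("distance undefined: no gap-free columns")
    p = mismatches / gapfree
    if p >= SATURATION_P:
        p_capped = SATURATION_P - 1.0 / (2 * gapfree) if gapfree > 2 else 0.74
        return (-0.75 * math.log(1 - 4 * p_capped / 3), True)
    return (-0.75 * math.log(1 - 4 * p / 3), False)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.d).all():
            raise ValueError("matrix entries must be finite")


@dataclass
class PhyloTree:
    """An unrooted (or outgroup-rooted) tree with branch lengths."""

    newick: str
    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        # clade queries interpret the written structure as-is; explicit
        # rooting goes through rooted_at()
        t.is_rooted = True
        return cls(newick, t)

    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def rooted_at(self, outgroup: str) -> "PhyloTree":
        t = dendropy.Tree.get(data=self.newick, schema="newick", preserve_underscores=True)
        node = t.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        t.reroot_at_edge(node.edge, update_bipartitions=True)
        return PhyloTree(t.as_string(schema="newick", unquoted_underscores=True).strip(), t)

    def is_clade(self, labels: Sequence[str], min_edge: float = 0.0) -> bool:
        """True when the labels form an exact clade.

        ``min_edge`` additionally requires the clade's subtending branch to
        exceed that length, so zero-signal resolutions (arbitrary joins of
        equidistant taxa) do not count as support.
        """
        mrca = self.tree.mrca(taxon_labels=list(labels))
        if mrca is None or len(mrca.leaf_nodes()) != len(labels):
            return False
        if min_edge > 0.0:
            return (mrca.edge.length or 0.0) > min_edge
        return True


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically smallest
    (label_i, label_j) pair.  Negative branch-length estimates are clamped
    to zero.  Returns an unrooted tree (trifurcating base in the newick).
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # each active node carries a newick fragment
    nodes: list[str] = list(matrix.labels)
    frags: list[str] = list(matrix.labels)
    d = matrix.d.astype(float).copy()

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.10f}"

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((nodes[i], nodes[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best is not None
                    and key < tuple(sorted((nodes[best[0]], nodes[best[1]])))
                ):
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new_frag = f"({frags[i]}:{fmt(li)},{frags[j]}:{fmt(lj)})"
        dn = np.zeros(m - 1)
        keep = [k for k in range(m) if k not in (i, j)]
        for idx, k in enumerate(keep):
            dn[idx] = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
        d_new = np.zeros((m - 1, m - 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                d_new[a, b] = d[ka, kb]
        d_new[-1, : m - 2] = dn[: m - 2]
        d_new[: m - 2, -1] = dn[: m - 2]
        nodes = [nodes[k] for k in keep] + [f"__int{len(nodes)}"]
        frags = [frags[k] for k in keep] + [new_frag]
        d = d_new

    # resolve the final three nodes around a central vertex
    la = max(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), 0.0)
    lb = max(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), 0.0)
    lc = max(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), 0.0)
    newick = (
        f"({frags[0]}:{la:.10f},{frags[1]}:{lb:.10f},{frags[2]}:{lc:.10f});"
    )
    return PhyloTree.from_newick(newick)


def star_msa(sequences: Mapping[str, str], reference: str,
             scoring: ScoringScheme = DEFAULT_SCORING) -> dict[str, str]:
    """Star multiple alignment: every sequence pairwise-aligned to a reference.

    Gap patterns are merged through reference coordinates, the standard
    star decomposition; adequate at quartet scale where all members are
    homologous over their full length.
    """
    if reference not in sequences:
        raise ValueError(f"reference {reference!r} not among sequences")
    ref_seq = sequences[reference]
    pairwise: dict[str, Alignment] = {}
    for label, seq in sequences.items():
        if label == reference:
            continue
        pairwise[label] = global_align(ref_seq, seq, scoring)

    # insertion length relative to the reference, before each ref position
    n_ref = len(ref_seq)
    ins_before = [0] * (n_ref + 1)
    for aln in pairwise.values():
        pos = 0
        run = 0
        for x in aln.aligned_a:
            if x == "-":
                run += 1
            else:
                ins_before[pos] = max(ins_before[pos], run)
                run = 0
                pos += 1
        ins_before[n_ref] = max(ins_before[n_ref], run)

    def expand(aligned_ref: str, aligned_other: str) -> str:
        out = []
        pos = 0
        run_cols: list[str] = []
        for x, y in zip(aligned_ref, aligned_other):
            if x == "-":
                run_cols.append(y)
            else:
                out.append("-" * (ins_before[pos] - len(run_cols)) + "".join(run_cols))
                run_cols = []
                out.append(y)
                pos += 1
        out.append("-" * (ins_before[n_ref] - len(run_cols)) + "".join(run_cols))
        return "".join(out)

    msa: dict[str, str] = {}
    ref_aligned = []
    for pos in range(n_ref):
        ref_aligned.append("-" * ins_before[pos] + ref_seq[pos])
    ref_aligned.append("-" * ins_before[n_ref])
    msa[reference] = "".join(ref_aligned)
    for label, aln in pairwise.items():
        msa[label] = expand(aln.aligned_a, aln.aligned_b)
    width = len(msa[reference])
    assert all(len(s) == width for s in msa.values())
    return msa


def distance_matrix_from_msa(msa: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances over the columns of an alignment."""
    labels = sorted(msa)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist, _ = jc_distance(msa[labels[i]], msa[labels[j]])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


@dataclass
class ConversionCall:
    quartet_id: str
    verdict: str  # converted_in_A | converted_in_B | converted_in_both | none | ambiguous
    paralog_identity_A: float | None = None
    paralog_identity_B: float | None = None
    support: float | None = None
    reason: str = ""
    tract_segments: list["TractSegment"] = field(default_factory=list)


def classify_quartet_topology(
    tree: PhyloTree,
    a_labels: tuple[str, str],
    b_labels: tuple[str, str],
    outgroup_label: str | None,
    paralog_identity_a: float | None = None,
    paralog_identity_b: float | None = None,
    conversion_min_identity: float = CONVERSION_MIN_IDENTITY,
) -> tuple[str, str]:
    """Conversion verdict from a quartet(+outgroup) tree topology.

    ``a_labels`` are the two species-A members of the quartet, ``b_labels``
    the two species-B members, with ``a_labels[i]`` orthologous to
    ``b_labels[i]``.  A within-species pair emerging as sisters in the
    outgroup-rooted tree indicates conversion in that species; both
    ortholog pairs as sisters indicates independent descent (``none``);
    anything else is ambiguous.  A converted verdict additionally requires
    the converted lineage's paralog identity to reach the conversion-
    competence floor, else it is downgraded to ambiguous.  Returns
    (verdict, reason).
    """
    a1, a2 = a_labels
    b1, b2 = b_labels
    expected = {a1, a2, b1, b2} | ({outgroup_label} if outgroup_label else set())
    if tree.leaf_labels() != expected:
        raise ValueError(
            f"tree leaves {sorted(tree.leaf_labels())} do not match quartet "
            f"{sorted(expected)}"
        )

    def identity_ok(lineage: str) -> bool:
        ident = paralog_identity_a if lineage == "A" else paralog_identity_b
        return ident is None or ident >= conversion_min_identity

    def finish(verdict: str, reason: str = "") -> tuple[str, str]:
        need = {"converted_in_A": ["A"], "converted_in_B": ["B"],
                "converted_in_both": ["A", "B"]}.get(verdict, [])
        bad = [ln for ln in need if not identity_ok(ln)]
        if bad:
            return (
                "ambiguous",
                f"paralog identity in {','.join(bad)} below conversion "
                f"floor {conversion_min_identity:.2f}",
            )
        return (verdict, reason)

    if outgroup_label is not None:
        rooted = tree.rooted_at(outgroup_label)
        eps = 1e-9  # a sister pair must sit behind a real internal branch
        a_sisters = rooted.is_clade([a1, a2], min_edge=eps)
        b_sisters = rooted.is_clade([b1, b2], min_edge=eps)
        pair1 = rooted.is_clade([a1, b1], min_edge=eps)
        pair2 = rooted.is_clade([a2, b2], min_edge=eps)
        if a_sisters and b_sisters:
            return finish("converted_in_both")
        if a_sisters:
            return finish("converted_in_A")
        if b_sisters:
            return finish("converted_in_B")
        if pair1 and pair2:
            return ("none", "orthologous pairing")
        return ("ambiguous", "topology matches no recognized pattern")

    # unrooted 4-taxon tree: only the central split is informative
    para_split = tree.is_clade([a1, a2]) or tree.is_clade([b1, b2])
    ortho_split = tree.is_clade([a1, b1]) or tree.is_clade([a2, b2])
    if ortho_split:
        return ("none", "orthologous pairing (unrooted)")
    if para_split:
        return finish(
            "converted_unpolarized",
            "paralogs cluster but no outgroup to polarize the lineage",
        )
    return ("ambiguous", "unrooted topology uninformative")


def bootstrap_support(
    msa: Mapping[str, str],
    point_verdict: str,
    a_labels: tuple[str, str],
    b_labels: tuple[str, str],
    outgroup_label: str | None,
    n_reps: int = 100,
    seed: int = 0,
) -> float | None:
    """Fraction of site-bootstrap replicates reproducing the point verdict.

    Columns are resampled with replacement; undefined (None) when the
    alignment is shorter than 10 columns or distances degenerate.
    """
    labels = sorted(msa)
    width = len(msa[labels[0]])
    if width < 10:
        return None
    rng = np.random.default_rng(seed)
    rows = np.array([list(msa[l]) for l in labels])
    agree = 0
    valid = 0
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        sub = {l: "".join(rows[i, cols]) for i, l in enumerate(labels)}
        try:
            dm = distance_matrix_from_msa(sub)
            tree = nj_tree(dm)
            verdict, _ = classify_quartet_topology(
                tree, a_labels, b_labels, outgroup_label
            )
        except ValueError:
            continue
        valid += 1
        if verdict == point_verdict:
            agree += 1
    if valid == 0:
        return None
    return agree / valid


@dataclass
class TractSegment:
    start_col: int
    end_col: int  # half-open alignment columns
    seg_class: str  # converted | mutated_flank | deleted | unclassified
    paralog_identity: float | None = None
    ortholog_identity: float | None = None
    span_a: tuple[int, int] = (0, 0)  # ungapped positions in paralog 1
    span_b: tuple[int, int] = (0, 0)  # ungapped positions in paralog 2
    chi2: float | None = None
    p_value: float | None = None
    test_method: str = ""


def _column_spans(alignment: Alignment, start_col: int, end_col: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Map an alignment-column interval to ungapped spans in both rows."""
    pos_a = pos_b = 0
    sa = ea = sb = eb = None
    for col in range(alignment.columns):
        if col == start_col:
            sa, sb = pos_a, pos_b
        if alignment.aligned_a[col] != "-":
            pos_a += 1
        if alignment.aligned_b[col] != "-":
            pos_b += 1
        if col == end_col - 1:
            ea, eb = pos_a, pos_b
    if sa is None:
        sa, sb = pos_a, pos_b
    if ea is None:
        ea, eb = pos_a, pos_b
    return (sa, ea), (sb, eb)


def _segment_identity(alignment: Alignment, start_col: int, end_col: int) -> float | None:
    matches = gapfree = 0
    for col in range(start_col, end_col):
        x, y = alignment.aligned_a[col], alignment.aligned_b[col]
        if x != "-" and y != "-":
            gapfree += 1
            if x == y:
                matches += 1
    return matches / gapfree if gapfree else None


def _ortholog_identity_for_span(
    ortholog_alignment: Alignment, span: tuple[int, int]
) -> float | None:
    """Identity of an ortholog alignment restricted to a paralog span.

    ``span`` is an ungapped interval in the paralog row (row a of the
    ortholog alignment).
    """
    s, e = span
    if e <= s:
        return None
    pos = 0
    matches = gapfree = 0
    for x, y in zip(ortholog_alignment.aligned_a, ortholog_alignment.aligned_b):
        if x != "-":
            if s <= pos < e and y != "-":
                gapfree += 1
                if x == y:
                    matches += 1
            pos += 1
    return matches / gapfree if gapfree else None


def delineate_tracts(
    paralog_alignment: Alignment,
    ortholog_alignments: tuple[Alignment | None, Alignment | None] = (None, None),
    window: int = 50,
    step: int = 10,
    tract_min_identity: float = TRACT_MIN_IDENTITY,
    flank_max_identity: float = FLANK_MAX_IDENTITY,
    min_del_run: int = 5,
) -> list[TractSegment]:
    """Partition a paralog alignment into converted / flank / deleted segments.

    Sliding-window identity (gap columns count as mismatches) marks
    candidate converted runs, whose boundaries are then refined to the
    exact matching columns.  Long one-sided gap runs become ``deleted``
    segments.  Remaining intervals with paralog identity below the flank
    ceiling — and, when ortholog alignments are supplied, ortholog
    identity below the converted-region background — are classified
    ``mutated_flank``; everything else is ``unclassified``.  The returned
    segments tile the alignment without overlap.
    """
    cols = paralog_alignment.columns
    aligned_a, aligned_b = paralog_alignment.aligned_a, paralog_alignment.aligned_b
    match = [
        aligned_a[c] != "-" and aligned_b[c] != "-" and aligned_a[c] == aligned_b[c]
        for c in range(cols)
    ]
    one_gap = [
        (aligned_a[c] == "-") != (aligned_b[c] == "-") for c in range(cols)
    ]

    # deleted runs first (carved out of everything else)
    deleted: list[tuple[int, int]] = []
    c = 0
    while c < cols:
        if one_gap[c]:
            j = c
            while j < cols and one_gap[j]:
                j += 1
            if j - c >= min_del_run:
                deleted.append((c, j))
            c = j
        else:
            c += 1

    if cols < window:
        ident = _segment_identity(paralog_alignment, 0, cols)
        cls = "converted" if ident is not None and ident >= tract_min_identity else "unclassified"
        (sa, ea), (sb, eb) = _column_spans(paralog_alignment, 0, cols)
        return [
            TractSegment(0, cols, cls, ident, None, (sa, ea), (sb, eb))
        ]

    # candidate converted runs from qualifying windows
    high = [False] * cols
    for s in range(0, cols - window + 1, step):
        w_match = sum(match[s : s + window])
        if w_match / window >= tract_min_identity:
            for c in range(s, s + window):
                high[c] = True
    # tail window so the final columns are covered
    s = cols - window
    if s % step != 0:
        if sum(match[s:cols]) / window >= tract_min_identity:
            for c in range(s, cols):
                high[c] = True

    converted: list[tuple[int, int]] = []
    c = 0
    while c < cols:
        if high[c]:
            j = c
            while j < cols and high[j]:
                j += 1
            # refine boundaries to the exact identity run
            a, b = c, j
            while a < b and not match[a]:
                a += 1
            while b > a and not match[b - 1]:
                b -= 1
            while a > 0 and match[a - 1]:
                a -= 1
            while b < cols and match[b]:
                b += 1
            if b > a:
                converted.append((a, b))
            c = j
        else:
            c += 1

    # knock deleted intervals out of converted runs
    def subtract(runs: list[tuple[int, int]], cuts: list[tuple[int, int]]):
        out = []
        for s0, e0 in runs:
            pieces = [(s0, e0)]
            for cs, ce in cuts:
                nxt = []
                for ps, pe in pieces:
                    if ce <= ps or cs >= pe:
                        nxt.append((ps, pe))
                    else:
                        if ps < cs:
                            nxt.append((ps, cs))
                        if ce < pe:
                            nxt.append((ce, pe))
                pieces = nxt
            out.extend(pieces)
        return [r for r in out if r[1] > r[0]]

    converted = subtract(converted, deleted)
    # merge converted runs separated only by deleted runs? keep separate; tiling below
    labeled: list[tuple[int, int, str]] = [(s, e, "converted") for s, e in converted]
    labeled += [(s, e, "deleted") for s, e in deleted]
    labeled.sort()

    # background ortholog identity over converted columns, for flank calls
    ortho_background: list[float] = []
    for s0, e0, cls in labeled:
        if cls != "converted":
            continue
        (sa, ea), (sb, eb) = _column_spans(paralog_alignment, s0, e0)
        for aln, span in zip(ortholog_alignments, ((sa, ea), (sb, eb))):
            if aln is not None:
                v = _ortholog_identity_for_span(aln, span)
                if v is not None:
                    ortho_background.append(v)
    background = float(np.mean(ortho_background)) if ortho_background else None

    # fill gaps -> flank or unclassified
    segments: list[TractSegment] = []
    cursor = 0
    bounds = labeled + [(cols, cols, "end")]
    for s0, e0, cls in bounds:
        if cursor < s0:
            seg = _classify_gap_segment(
                paralog_alignment, ortholog_alignments, cursor, s0,
                flank_max_identity, background,
            )
            segments.append(seg)
        if cls != "end":
            ident = _segment_identity(paralog_alignment, s0, e0)
            (sa, ea), (sb, eb) = _column_spans(paralog_alignment, s0, e0)
            segments.append(
                TractSegment(s0, e0, cls, ident, None, (sa, ea), (sb, eb))
            )
        cursor = max(cursor, e0)
    segments.sort(key=lambda t: t.start_col)
    return segments


def _classify_gap_segment(
    paralog_alignment: Alignment,
    ortholog_alignments: tuple[Alignment | None, Alignment | None],
    start_col: int,
    end_col: int,
    flank_max_identity: float,
    ortho_background: float | None,
) -> TractSegment:
    ident = _segment_identity(paralog_alignment, start_col, end_col)
    (sa, ea), (sb, eb) = _column_spans(paralog_alignment, start_col, end_col)
    ortho_vals = []
    for aln, span in zip(ortholog_alignments, ((sa, ea), (sb, eb))):
        if aln is not None:
            v = _ortholog_identity_for_span(aln, span)
            if v is not None:
                ortho_vals.append(v)
    ortho_ident = float(np.mean(ortho_vals)) if ortho_vals else None
    cls = "unclassified"
    if ident is not None and ident < flank_max_identity:
        if ortho_ident is None or ortho_background is None or ortho_ident < ortho_background:
            cls = "mutated_flank"
    return TractSegment(start_col, end_col, cls, ident, ortho_ident, (sa, ea), (sb, eb))


@dataclass
class ContrastResult:
    chi2: float | None
    p_value: float
    method: str  # "chi2" | "fisher"


def window_contrast_test(
    matches_1: int, mismatches_1: int, matches_2: int, mismatches_2: int
) -> ContrastResult:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Contrasts match/mismatch proportions of two alignment segments.
    Fisher's exact test substitutes whenever an expected cell falls below
    5, with the method recorded in the result.
    """
    table = np.array([[matches_1, mismatches_1], [matches_2, mismatches_2]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("each segment must contain at least one column")
    if table.sum(axis=0).min() == 0:
        # a degenerate margin (e.g. no mismatches anywhere): proportions equal
        return ContrastResult(0.0, 1.0, "chi2")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        return ContrastResult(None, float(p), "fisher")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ContrastResult(float(chi2), float(p), "chi2")


@dataclass
class SplitEvent:
    mother_gene: str
    daughters: list[tuple[int, int]]  # spans in target coordinates
    stop_offsets: list[int]  # codon positions in the mother frame
    frameshift_indels: list[tuple[int, int]]  # (mother bp offset, length)
    mode: str = ""


def _validate_orf(cds: str) -> int:
    """Check start / internal / terminal stop structure; return codon count."""
    if len(cds) % 3 != 0 or len(cds) < 9:
        raise ValueError("mother CDS length must be a multiple of 3 and >= 9")
    if cds[:3] != "ATG":
        raise ValueError("mother CDS must start with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError("mother CDS must end with a stop codon")
    for i in range(3, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            raise ValueError(f"mother CDS has internal stop at codon {i // 3}")
    return len(cds) // 3


def projected_stops(
    aligned_mother: str, aligned_target: str, n_mother_codons: int
) -> tuple[list[int], list[tuple[int, int]], list[tuple[int, int]], list[int]]:
    """Walk an alignment reading the target in the mother's (shifting) frame.

    Target bases are consumed in triplets starting in the mother's frame;
    indels whose length is not a multiple of 3 shift the frame, exactly as
    translation would experience them.  Returns (stop offsets in mother
    codon units, frameshift indels as (mother bp offset, length), stop
    spans in target coordinates, frame offset mod 3 at each stop — zero
    for a stop created by point mutation, nonzero downstream of a net
    frameshift).
    """
    stops: list[int] = []
    stop_spans: list[tuple[int, int]] = []
    stop_frames: list[int] = []
    indels: list[tuple[int, int]] = []
    mother_pos = 0
    target_pos = 0
    net = 0  # cumulative insertions minus deletions in the target
    buffer: list[tuple[str, int]] = []  # (base, target position)
    gap_run = 0
    gap_start_mother = 0
    for x, y in zip(aligned_mother, aligned_target):
        if (x == "-") != (y == "-"):
            if gap_run == 0:
                gap_start_mother = mother_pos
            gap_run += 1
            net += 1 if x == "-" else -1
        else:
            if gap_run and gap_run % 3 != 0:
                indels.append((gap_start_mother, gap_run))
            gap_run = 0
        if y != "-":
            buffer.append((y, target_pos))
            target_pos += 1
        if x != "-":
            mother_pos += 1
        if len(buffer) == 3:
            codon = "".join(b for b, _ in buffer)
            codon_index = max(mother_pos - 1, 0) // 3
            if codon in STOP_CODONS and codon_index < n_mother_codons - 1:
                stops.append(codon_index)
                stop_spans.append((buffer[0][1], buffer[2][1] + 1))
                stop_frames.append(net % 3)
            buffer = []
    if gap_run and gap_run % 3 != 0:
        indels.append((gap_start_mother, gap_run))
    return stops, indels, stop_spans, stop_frames


def detect_split(
    mother_cds: str,
    target_region_sequence: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_daughter_codons: int = 30,
    mother_id: str = "mother",
) -> SplitEvent | None:
    """Detect premature stop codons splitting a gene, via alignment projection.

    The candidate target region is globally aligned to the mother CDS and
    translated in the mother's frame as projected through the alignment.
    Internal stops strictly before the mother's terminal codon are
    reported; alignment gaps of length not divisible by 3 are reported as
    frameshift indels.  Daughters are the maximal inter-stop segments of at
    least ``min_daughter_codons`` codons.  Returns None when no internal
    stop is found.
    """
    mother = mother_cds.upper()
    target = target_region_sequence.upper()
    n_codons = _validate_orf(mother)
    aln = global_align(mother, target, scoring)
    stops, indels, stop_spans, stop_frames = projected_stops(
        aln.aligned_a, aln.aligned_b, n_codons
    )
    if not stops:
        return None
    boundaries = [0]
    for s, e in stop_spans:
        boundaries.append(e)
    boundaries.append(len(target))
    daughters = []
    for i in range(len(boundaries) - 1):
        s, e = boundaries[i], boundaries[i + 1]
        if (e - s) // 3 >= min_daughter_codons:
            daughters.append((s, e))
    # a stop reached in a shifted frame implicates a frameshifting indel;
    # stops found in frame 0 are point-mutation stops even if the
    # alignment carries compensating gap pairs elsewhere
    mode = "frameshift" if any(f != 0 for f in stop_frames) else "point_mutation"
    return SplitEvent(mother_id, daughters, stops, indels, mode)
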