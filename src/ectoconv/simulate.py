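"""Synthetic two-genome generator with a proximally duplicated region.

The generator instantiates the evolutionary scenario under study: an
ancestral chromosome carries a block of genes that is duplicated proximally
(optionally inverted) before the split of two descendant lineages A and B.
Each lineage then accumulates Jukes-Cantor point substitutions, undergoes
ectopic gene-conversion events that copy a donor-arm tract over the
acceptor arm, receives hypermutated flanking patches with sampled
deletions, splits genes through introduced stop codons (point-mutation or
frameshifting-deletion mode), and loses genes — all recorded in an exact
truth table for recovery testing.  An outgroup gene set diverged before
the duplication is emitted alongside.

All randomness flows from a single integer seed; identical parameters give
byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .evostats import STOP_CODONS
from .genome_io import (
    GeneModel,
    Genome,
    reverse_complement,
    write_fasta,
    write_gff,
)
from .conversion import projected_stops

__all__ = [
    "SimParams",
    "ConversionSpec",
    "SplitSpec",
    "TruthRecord",
    "SimulatedDataset",
    "build_ancestor",
    "duplicate_block",
    "evolve_lineages",
    "simulate_dataset",
    "emit_dataset",
]

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)
_STOP_LIST = sorted(STOP_CODONS)


@dataclass(frozen=True)
class ConversionSpec:
    """One ectopic conversion: donor arm tract copied over the acceptor arm.

    ``tract`` is either a fraction of the CDS interior (float in (0, 1]) or
    an explicit (start, end) bp interval in acceptor CDS coordinates; it is
    snapped to codon boundaries and kept clear of the start and stop codons.
    """

    lineage: str  # "A" | "B"
    pair_index: int
    tract: float | tuple[int, int] = 1.0
    donor_arm: int = 1
    n_flank_deletions: int = 1


@dataclass(frozen=True)
class SplitSpec:
    """One stop-codon gene split of a duplicated-arm gene."""

    lineage: str
    pair_index: int
    arm: int = 1
    n_daughters: int = 3
    mode: str = "point"  # "point" | "frameshift"


@dataclass
class SimParams:
    seed: int = 0
    n_genes_region: int = 12
    n_genes_background: int = 24
    gene_len_codons: tuple[int, int] = (150, 300)
    intergenic_len: tuple[int, int] = (200, 400)
    dup_block_span: tuple[int, int] = (0, 4)
    dup_orientation: str = "inverted"  # "same" | "inverted"
    branch_sub_rate: float = 0.033
    dup_branch_sub_rate: float = 0.02
    region_rate_multiplier: float = 3.5
    outgroup_sub_rate: float = 0.05
    flank_mut_rate: float = 0.5
    flank_len: int = 140
    deletion_len_range: tuple[int, int] = (3, 700)
    conversion_events: tuple[ConversionSpec, ...] = ()
    split_events: tuple[SplitSpec, ...] = ()
    loss_prob_affected: float = 0.25
    loss_prob_background: float = 0.02
    delete_dna_on_loss_prob: float = 0.5
    min_daughter_codons: int = 30

    def validate(self) -> None:
        for name in ("branch_sub_rate", "dup_branch_sub_rate", "outgroup_sub_rate",
                     "flank_mut_rate", "loss_prob_affected", "loss_prob_background",
                     "delete_dna_on_loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes_region < 0 or self.n_genes_background < 0:
            raise ValueError("gene counts must be non-negative")
        lo, hi = self.dup_block_span
        if self.n_genes_region and not (0 <= lo < hi <= self.n_genes_region):
            raise ValueError("dup_block_span must lie within the region")
        if self.gene_len_codons[0] < 10 or self.gene_len_codons[0] > self.gene_len_codons[1]:
            raise ValueError("gene_len_codons range infeasible")
        if self.deletion_len_range[0] < 1:
            raise ValueError("deletion lengths must be >= 1 bp")
        if self.dup_orientation not in ("same", "inverted"):
            raise ValueError("dup_orientation must be 'same' or 'inverted'")
        for ev in self.conversion_events:
            if ev.lineage not in ("A", "B"):
                raise ValueError(f"conversion lineage must be A or B, got {ev.lineage!r}")
        for ev in self.split_events:
            if ev.mode not in ("point", "frameshift"):
                raise ValueError(f"split mode must be point or frameshift, got {ev.mode!r}")


@dataclass
class TruthRecord:
    event_id: str
    event_type: str  # conversion | deletion | point_patch | split | gene_loss
    lineage: str
    chrom: str
    start: int
    end: int
    donor_id: str = ""
    acceptor_id: str = ""
    mode: str = ""
    detail: dict = field(default_factory=dict)


@dataclass
class _SimGene:
    anc_id: str  # ancestral gene id; arm-2 copies carry a 'b' suffix
    start: int
    end: int
    strand: str
    region: bool  # inside the affected neighborhood
    arm: int = 0  # 0 background/intervening, 1 original arm, 2 duplicate arm


@dataclass
class _Lineage:
    name: str
    chrom: str
    seq: str
    genes: dict[str, _SimGene]  # anc_id -> gene
    truth: list[TruthRecord] = field(default_factory=list)

    def gene_seq(self, g: _SimGene) -> str:
        s = self.seq[g.start : g.end]
        return reverse_complement(s) if g.strand == "-" else s

    def set_gene_seq(self, g: _SimGene, new: str) -> None:
        if len(new) != g.end - g.start:
            raise ValueError("in-place gene replacement must preserve length")
        block = reverse_complement(new) if g.strand == "-" else new
        self.seq = self.seq[: g.start] + block + self.seq[g.end :]

    def gene_to_genome(self, g: _SimGene, s: int, e: int) -> tuple[int, int]:
        """Map a gene-relative (transcription-orientation) interval to genome."""
        if g.strand == "+":
            return (g.start + s, g.start + e)
        return (g.end - e, g.end - s)

    def genome_to_gene(self, g: _SimGene, s: int, e: int) -> tuple[int, int]:
        if g.strand == "+":
            return (s - g.start, e - g.start)
        return (g.end - e, g.end - s)

    def apply_deletion(self, start: int, end: int) -> None:
        """Remove [start, end) from the chromosome, shifting all bookkeeping."""
        length = end - start
        self.seq = self.seq[:start] + self.seq[end:]
        for g in self.genes.values():
            if g.end <= start:
                continue
            if g.start >= end:
                g.start -= length
                g.end -= length
            elif g.start <= start and g.end >= end:
                g.end -= length
            else:
                raise ValueError("deletion straddles a gene boundary")
        for rec in self.truth:
            if rec.chrom != self.chrom:
                continue
            if rec.start >= end:
                rec.start -= length
                rec.end -= length
            elif rec.end > start:
                rec.start = min(rec.start, start)
                rec.end = max(rec.end - length, rec.start)


def ancestral_base_id(anc_id: str) -> str:
    """Pre-duplication ancestral gene id: strip daughter and arm-2 suffixes."""
    base = anc_id.split(".")[0]
    return base[:-1] if base.endswith("b") else base


@dataclass
class SimulatedDataset:
    genome_a: Genome
    genome_b: Genome
    outgroup_cds: dict[str, str]
    truth: list[TruthRecord]
    affected_region: dict[str, tuple[int, int]]  # lineage -> genome interval
    ancestral_region_genes: list[str]  # anc ids in the affected neighborhood
    ancestral_genes: list[str]  # all post-duplication ancestral gene ids
    gene_to_ancestor: dict[str, str]  # emitted gene id -> post-dup anc id
    params: SimParams

    def split_merge_map(self, lineage: str | None = None) -> dict[str, str]:
        """Map emitted daughter gene ids back to their mother gene id."""
        merge: dict[str, str] = {}
        for rec in self.truth:
            if rec.event_type != "split":
                continue
            if lineage is not None and rec.lineage != lineage:
                continue
            for did in rec.detail.get("daughters", []):
                merge[f"{rec.lineage}_{did}"] = f"{rec.lineage}_{rec.acceptor_id}"
        return merge


# ---------------------------------------------------------------------------
# sequence-level helpers


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOP_LIST[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate_intergenic(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    p = 0.75 * (1.0 - math.exp(-4.0 * rate / 3.0))
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p
    if hit.any():
        arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


def _mutate_cds(
    rng: np.random.Generator,
    cds: str,
    rate: float,
    window: tuple[int, int] | None = None,
) -> str:
    """Jukes-Cantor substitutions on a coding sequence, frame-preserving.

    Substitution counts per site are Poisson(rate); a change that would
    turn an internal codon into a stop is discarded (rejection), and the
    start and terminal-stop codons are shielded, so the ORF structure
    survives every pass.  ``window`` restricts mutation to a gene-relative
    interval (used for hypermutated flank patches); stop rejection always
    sees the full current codon context.
    """
    if rate <= 0:
        return cds
    seq = list(cds)
    n = len(seq)
    lo = 3 if window is None else max(3, window[0])
    hi = n - 3 if window is None else min(n - 3, window[1])
    if hi <= lo:
        return cds
    counts = rng.poisson(rate, size=hi - lo)
    for off in np.nonzero(counts)[0]:
        pos = lo + int(off)
        for _ in range(int(counts[off])):
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            new = choices[int(rng.integers(0, 3))]
            c0 = 3 * (pos // 3)
            codon = seq[c0 : c0 + 3]
            codon[pos - c0] = new
            if "".join(codon) in STOP_CODONS:
                continue  # rejected: would create an internal stop
            seq[pos] = new
    return "".join(seq)


def _sample_deletion_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Log-uniform deletion length in [lo, hi] bp."""
    u = rng.random()
    return int(round(math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))))


# ---------------------------------------------------------------------------
# ancestor construction


@dataclass
class Ancestor:
    seq: str
    genes: dict[str, _SimGene]
    order: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    dup_orientation: str = "same"


def build_ancestor(params: SimParams, rng: np.random.Generator | None = None) -> Ancestor:
    """Ancestral single-chromosome genome: background + region genes.

    Every gene is a clean single-exon ORF (ATG start, sense body, terminal
    stop).  Region genes sit contiguously between two background flanks so
    collinearity-break detection has context to operate on.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_left = params.n_genes_background // 2
    n_right = params.n_genes_background - n_left
    layout = (
        [("bgL", i, False) for i in range(n_left)]
        + [("reg", i, True) for i in range(params.n_genes_region)]
        + [("bgR", i, False) for i in range(n_right)]
    )
    seq_parts: list[str] = []
    genes: dict[str, _SimGene] = {}
    order: list[str] = []
    pos = 0
    for tag, i, in_region in layout:
        gap = int(rng.integers(params.intergenic_len[0], params.intergenic_len[1] + 1))
        seq_parts.append(_random_dna(rng, gap))
        pos += gap
        n_codons = int(rng.integers(params.gene_len_codons[0], params.gene_len_codons[1] + 1))
        orf = _random_orf(rng, n_codons)
        anc_id = f"g{tag}{i:03d}"
        genes[anc_id] = _SimGene(anc_id, pos, pos + len(orf), "+", in_region)
        order.append(anc_id)
        seq_parts.append(orf)
        pos += len(orf)
    tail = int(rng.integers(params.intergenic_len[0], params.intergenic_len[1] + 1))
    seq_parts.append(_random_dna(rng, tail))
    return Ancestor("".join(seq_parts), genes, order)


def duplicate_block(
    ancestor: Ancestor, params: SimParams, rng: np.random.Generator | None = None
) -> Ancestor:
    """Insert a proximal copy of the region's duplication block.

    The block (gene span ``dup_block_span`` within the region, including
    its internal intergenic spacers) is copied immediately downstream of
    the region; in inverted orientation the copy is reverse-complemented,
    putting arm-2 genes on the minus strand in reversed order.  Paralog-
    pair bookkeeping is recorded on the returned ancestor.
    """
    if ancestor.pairs:
        raise ValueError("block already duplicated")
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    region_ids = [i for i in ancestor.order if ancestor.genes[i].region]
    if not region_ids:
        return ancestor
    lo, hi = params.dup_block_span
    block_ids = region_ids[lo:hi]
    if not block_ids:
        raise ValueError("dup_block_span selects no genes")
    block_start = ancestor.genes[block_ids[0]].start
    block_end = ancestor.genes[block_ids[-1]].end
    block_seq = ancestor.seq[block_start:block_end]
    region_end = ancestor.genes[region_ids[-1]].end
    downstream_starts = [
        g.start for g in ancestor.genes.values() if g.start >= region_end
    ]
    ceiling = min(downstream_starts) if downstream_starts else len(ancestor.seq)
    spacer = int(rng.integers(params.intergenic_len[0], params.intergenic_len[1] + 1))
    # insertion must land in the intergenic gap, never inside a gene
    insert_at = min(region_end + spacer, ceiling, len(ancestor.seq))
    inverted = params.dup_orientation == "inverted"
    insert_seq = reverse_complement(block_seq) if inverted else block_seq

    new_seq = ancestor.seq[:insert_at] + insert_seq + ancestor.seq[insert_at:]
    genes = {k: replace(v) for k, v in ancestor.genes.items()}
    for g in genes.values():
        if g.start >= insert_at:
            g.start += len(insert_seq)
            g.end += len(insert_seq)
    new_order = list(ancestor.order)
    pairs: list[tuple[str, str]] = []
    for anc_id in block_ids:
        g = ancestor.genes[anc_id]
        genes[anc_id].arm = 1
        off_s, off_e = g.start - block_start, g.end - block_start
        if inverted:
            s = insert_at + (len(block_seq) - off_e)
            e = insert_at + (len(block_seq) - off_s)
            strand = "-" if g.strand == "+" else "+"
        else:
            s, e = insert_at + off_s, insert_at + off_e
            strand = g.strand
        copy_id = anc_id + "b"
        genes[copy_id] = _SimGene(copy_id, s, e, strand, True, arm=2)
        pairs.append((anc_id, copy_id))
    # keep order sorted by coordinate
    new_order = sorted(genes, key=lambda k: genes[k].start)
    return Ancestor(new_seq, genes, new_order, pairs, params.dup_orientation)


# ---------------------------------------------------------------------------
# lineage evolution


def _affected_interval(lin: _Lineage) -> tuple[int, int]:
    region = [g for g in lin.genes.values() if g.region]
    if not region:
        return (0, 0)
    return (min(g.start for g in region), max(g.end for g in region))


def _apply_substitutions(
    lin: _Lineage, rng: np.random.Generator, rate: float, multiplier: float
) -> None:
    """Per-gene JC substitutions; region genes at ``rate * multiplier``."""
    for anc_id in sorted(lin.genes):
        g = lin.genes[anc_id]
        r = rate * multiplier if g.region else rate
        lin.set_gene_seq(g, _mutate_cds(rng, lin.gene_seq(g), r))
    # intergenic at the background rate (single pass over the gaps)
    spans = sorted((g.start, g.end) for g in lin.genes.values())
    out = []
    prev = 0
    for s, e in spans:
        if s < prev:
            raise ValueError("gene intervals overlap; genome bookkeeping corrupt")
        out.append(_mutate_intergenic(rng, lin.seq[prev:s], rate))
        out.append(lin.seq[s:e])
        prev = e
    out.append(_mutate_intergenic(rng, lin.seq[prev:], rate))
    lin.seq = "".join(out)


def _codon_snap(s: int, e: int, n: int) -> tuple[int, int]:
    s = max(3, s - s % 3)
    e = min(n - 3, e - e % 3)
    return s, e


def _apply_conversion(
    lin: _Lineage,
    ev: ConversionSpec,
    pairs: list[tuple[str, str]],
    params: SimParams,
    rng: np.random.Generator,
    counter: list[int],
) -> None:
    donor_id, acceptor_id = pairs[ev.pair_index]
    if ev.donor_arm == 2:
        donor_id, acceptor_id = acceptor_id, donor_id
    for gid in (donor_id, acceptor_id):
        if gid not in lin.genes:
            raise ValueError(
                f"conversion requested on lost or split gene {gid!r} in lineage {lin.name}"
            )
    donor, acceptor = lin.genes[donor_id], lin.genes[acceptor_id]
    d_seq, a_seq = lin.gene_seq(donor), lin.gene_seq(acceptor)
    if len(d_seq) != len(a_seq):
        raise ValueError("paralog arms have diverged in length; convert earlier")
    n = len(a_seq)
    if isinstance(ev.tract, float):
        span = int(round((n - 6) * ev.tract))
        s = (n - span) // 2
        s, e = _codon_snap(s, s + span, n)
    else:
        s, e = _codon_snap(ev.tract[0], ev.tract[1], n)
    if e <= s:
        raise ValueError("conversion tract is empty after codon snapping")
    new_a = a_seq[:s] + d_seq[s:e] + a_seq[e:]
    lin.set_gene_seq(acceptor, new_a)
    gs, ge = lin.gene_to_genome(acceptor, s, e)
    counter[0] += 1
    lin.truth.append(
        TruthRecord(
            event_id=f"ev{counter[0]:04d}",
            event_type="conversion",
            lineage=lin.name,
            chrom=lin.chrom,
            start=gs,
            end=ge,
            donor_id=donor_id,
            acceptor_id=acceptor_id,
            detail={"tract_cds": [s, e], "pair_index": ev.pair_index},
        )
    )
    _mutate_flanks(lin, ev, acceptor_id, donor_id, (s, e), params, rng, counter)


def _mutate_flanks(
    lin: _Lineage,
    ev: ConversionSpec,
    acceptor_id: str,
    donor_id: str,
    tract: tuple[int, int],
    params: SimParams,
    rng: np.random.Generator,
    counter: list[int],
) -> None:
    """Hypermutate the tract's flanking patches in both arms, with deletions.

    Flanks receive independent elevated substitutions in each arm, driving
    both paralog and ortholog identity down; in-gene deletions are snapped
    to codon multiples so only deliberate split events break frames, and a
    deletion never removes the conversion tract itself.
    """
    s, e = tract
    for gid in (acceptor_id, donor_id):
        g = lin.genes[gid]
        seq = lin.gene_seq(g)
        n = len(seq)
        left = (max(3, s - params.flank_len), s)
        right = (e, min(n - 3, e + params.flank_len))
        touched = []
        for fs, fe in (left, right):
            if fe <= fs:
                continue
            seq = _mutate_cds(rng, seq, params.flank_mut_rate, window=(fs, fe))
            touched.append((fs, fe))
        if not touched:
            continue
        lin.set_gene_seq(g, seq)
        for fs, fe in touched:
            fgs, fge = lin.gene_to_genome(g, fs, fe)
            counter[0] += 1
            lin.truth.append(
                TruthRecord(
                    event_id=f"ev{counter[0]:04d}",
                    event_type="point_patch",
                    lineage=lin.name,
                    chrom=lin.chrom,
                    start=min(fgs, fge),
                    end=max(fgs, fge),
                    acceptor_id=gid,
                    detail={"flank_cds": [fs, fe], "rate": params.flank_mut_rate},
                )
            )
    # sampled deletions in the acceptor's flanks (codon-multiple, in-gene)
    g = lin.genes[acceptor_id]
    for _ in range(ev.n_flank_deletions):
        raw = _sample_deletion_length(rng, *params.deletion_len_range)
        length = max(3, raw - raw % 3)
        seq_len = g.end - g.start
        side = "left" if rng.random() < 0.5 else "right"
        if side == "left":
            avail_s, avail_e = max(3, s - params.flank_len), s
        else:
            avail_s, avail_e = e, min(seq_len - 3, e + params.flank_len)
        avail = avail_e - avail_s
        if avail < 6:
            continue
        length = min(length, avail - avail % 3 - 3)
        if length < 3:
            continue
        ds = avail_s + 3 * int(rng.integers(0, (avail - length) // 3 + 1))
        ds -= ds % 3
        gs, ge = lin.gene_to_genome(g, ds, ds + length)
        gs, ge = min(gs, ge), max(gs, ge)
        counter[0] += 1
        lin.truth.append(
            TruthRecord(
                event_id=f"ev{counter[0]:04d}",
                event_type="deletion",
                lineage=lin.name,
                chrom=lin.chrom,
                start=gs,
                end=ge,
                acceptor_id=acceptor_id,
                detail={"length": length, "in_gene": True},
            )
        )
        lin.apply_deletion(gs, ge)


def _pick_stop_codons(
    rng: np.random.Generator, n_codons: int, n_stops: int, min_seg: int
) -> list[int]:
    """Roughly evenly spaced internal codon indices for stop introduction."""
    usable = n_codons - 2  # exclude start and terminal stop
    if usable < (n_stops + 1) * min_seg:
        raise ValueError("gene too short for the requested number of daughters")
    offsets = []
    for k in range(1, n_stops + 1):
        base = round(k * usable / (n_stops + 1))
        jitter = int(rng.integers(-min_seg // 3, min_seg // 3 + 1))
        offsets.append(max(min_seg, min(usable - min_seg, base + jitter)))
    return sorted(set(offsets))


def _apply_split(
    lin: _Lineage,
    ev: SplitSpec,
    pairs: list[tuple[str, str]],
    params: SimParams,
    rng: np.random.Generator,
    counter: list[int],
) -> None:
    gid = pairs[ev.pair_index][ev.arm - 1]
    if gid not in lin.genes:
        raise ValueError(f"split requested on missing gene {gid!r}")
    g = lin.genes[gid]
    seq = lin.gene_seq(g)
    n_codons = len(seq) // 3
    pre_split_seq = seq

    if ev.mode == "point":
        stops = _pick_stop_codons(
            rng, n_codons, ev.n_daughters - 1, params.min_daughter_codons
        )
        for c in stops:
            stop = _STOP_LIST[int(rng.integers(0, 3))]
            seq = seq[: 3 * c] + stop + seq[3 * c + 3 :]
        lin.set_gene_seq(g, seq)
        boundaries = [0] + [3 * c + 3 for c in stops] + [len(seq)]
        indels: list[tuple[int, int]] = []
        stop_offsets = stops
    else:  # frameshift: small deletion shifts the frame into a premature stop
        del_len = 4
        found = None
        for attempt in range(50):
            c0 = int(
                rng.integers(params.min_daughter_codons, n_codons // 2)
            )
            dpos = 3 * c0
            target = seq[:dpos] + seq[dpos + del_len :]
            aligned_m = seq
            aligned_t = target[:dpos] + "-" * del_len + target[dpos:]
            stops_w, indels_w, spans_w, _frames_w = projected_stops(
                aligned_m, aligned_t, n_codons
            )
            if stops_w and stops_w[0] >= c0 and stops_w[0] < n_codons - params.min_daughter_codons:
                found = (dpos, target, stops_w, indels_w, spans_w)
                break
        if found is None:
            raise ValueError("could not place a frameshift split; gene too short")
        dpos, target, stop_offsets, indels, spans = found
        gs, ge = lin.gene_to_genome(g, dpos, dpos + del_len)
        gs, ge = min(gs, ge), max(gs, ge)
        lin.apply_deletion(gs, ge)
        g = lin.genes[gid]
        seq = lin.gene_seq(g)
        first_stop_end = spans[0][1]
        boundaries = [0, first_stop_end, len(seq)]
        stop_offsets = stop_offsets[:1]

    # re-annotate: daughters = maximal inter-stop segments >= min length
    daughters = []
    for i in range(len(boundaries) - 1):
        ds, de = boundaries[i], boundaries[i + 1]
        if (de - ds) // 3 >= params.min_daughter_codons:
            daughters.append((ds, de))
    del lin.genes[gid]
    daughter_ids = []
    for i, (ds, de) in enumerate(daughters, 1):
        did = f"{gid}.d{i}"
        gds, gde = lin.gene_to_genome(g, ds, de)
        gds, gde = min(gds, gde), max(gds, gde)
        lin.genes[did] = _SimGene(did, gds, gde, g.strand, g.region, g.arm)
        daughter_ids.append(did)
    counter[0] += 1
    lin.truth.append(
        TruthRecord(
            event_id=f"ev{counter[0]:04d}",
            event_type="split",
            lineage=lin.name,
            chrom=lin.chrom,
            start=g.start,
            end=g.end,
            acceptor_id=gid,
            mode=ev.mode,
            detail={
                "stop_offsets": list(stop_offsets),
                "daughters": daughter_ids,
                "frameshift_indels": [list(x) for x in indels],
                "n_mother_codons": n_codons,
            },
        )
    )


def _apply_losses(
    lin: _Lineage,
    params: SimParams,
    rng: np.random.Generator,
    protected: set[str],
    counter: list[int],
) -> None:
    for anc_id in sorted(lin.genes):
        if anc_id in protected:
            continue
        g = lin.genes[anc_id]
        p = params.loss_prob_affected if g.region else params.loss_prob_background
        if rng.random() >= p:
            continue
        delete_dna = rng.random() < params.delete_dna_on_loss_prob
        counter[0] += 1
        lin.truth.append(
            TruthRecord(
                event_id=f"ev{counter[0]:04d}",
                event_type="gene_loss",
                lineage=lin.name,
                chrom=lin.chrom,
                start=g.start,
                end=g.end if not delete_dna else g.start,
                acceptor_id=anc_id,
                mode="dna_deleted" if delete_dna else "annotation_only",
            )
        )
        start, end = g.start, g.end
        del lin.genes[anc_id]
        if delete_dna:
            lin.apply_deletion(start, end)


def evolve_lineages(
    ancestor: Ancestor, params: SimParams, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Evolve two lineages from the duplicated ancestor and assemble a dataset.

    Order of events per lineage: Jukes-Cantor substitutions (region genes at
    the elevated rate), ectopic conversions with flank hypermutation and
    deletions, stop-codon splits, then gene losses.  The outgroup diverges
    from the pre-duplication ancestral genes.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    counter = [0]

    # shared ancestral branch after duplication, before speciation
    shared = _Lineage("anc", "chr_anc", ancestor.seq,
                      {k: replace(v) for k, v in ancestor.genes.items()})
    _apply_substitutions(shared, rng, params.dup_branch_sub_rate,
                         params.region_rate_multiplier)

    lineages: dict[str, _Lineage] = {}
    for name in ("A", "B"):
        lin = _Lineage(
            name,
            f"chr{name}",
            shared.seq,
            {k: replace(v) for k, v in shared.genes.items()},
        )
        _apply_substitutions(lin, rng, params.branch_sub_rate,
                             params.region_rate_multiplier)
        lineages[name] = lin

    event_genes: dict[str, set[str]] = {"A": set(), "B": set()}
    for ev in params.conversion_events:
        _apply_conversion(lineages[ev.lineage], ev, ancestor.pairs, params, rng, counter)
        d, a = ancestor.pairs[ev.pair_index]
        event_genes[ev.lineage].update({d, a})
        other = "B" if ev.lineage == "A" else "A"
        event_genes[other].update({d, a})  # keep orthologs for quartet formation
    for ev in params.split_events:
        _apply_split(lineages[ev.lineage], ev, ancestor.pairs, params, rng, counter)
        event_genes[ev.lineage].add(pairsgid(ancestor.pairs, ev))
    for name in ("A", "B"):
        _apply_losses(lineages[name], params, rng, event_genes[name], counter)

    # outgroup: one lightly diverged CDS per pre-duplication ancestral gene
    outgroup: dict[str, str] = {}
    anc0 = build_ancestor(params)  # regenerate the pre-duplication state
    pre_dup = _Lineage("O", "chrO", anc0.seq,
                       {k: replace(v) for k, v in anc0.genes.items()})
    for anc_id in anc0.order:
        cds = pre_dup.gene_seq(pre_dup.genes[anc_id])
        outgroup[f"out_{anc_id}"] = _mutate_cds(rng, cds, params.outgroup_sub_rate)

    genomes: dict[str, Genome] = {}
    gene_to_anc: dict[str, str] = {}
    for name, lin in lineages.items():
        models = []
        for anc_id in sorted(lin.genes, key=lambda k: lin.genes[k].start):
            g = lin.genes[anc_id]
            gene_id = f"{name}_{anc_id}"
            gene_to_anc[gene_id] = anc_id.split(".")[0]
            models.append(
                GeneModel(gene_id, lin.chrom, g.start, g.end, g.strand,
                          ((g.start, g.end),))
            )
        genomes[name] = Genome({lin.chrom: lin.seq}, {lin.chrom: models})

    region_anc_ids = sorted(
        {k for k, v in ancestor.genes.items() if v.region}
    )
    dataset = SimulatedDataset(
        genome_a=genomes["A"],
        genome_b=genomes["B"],
        outgroup_cds=outgroup,
        ancestral_genes=sorted(ancestor.genes),
        truth=lineages["A"].truth + lineages["B"].truth,
        affected_region={
            "A": _affected_interval(lineages["A"]),
            "B": _affected_interval(lineages["B"]),
        },
        ancestral_region_genes=region_anc_ids,
        gene_to_ancestor=gene_to_anc,
        params=params,
    )
    return dataset


def pairsgid(pairs: list[tuple[str, str]], ev: SplitSpec) -> str:
    return pairs[ev.pair_index][ev.arm - 1]


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """End-to-end generation: ancestor, duplication, lineage evolution."""
    rng = np.random.default_rng(params.seed)
    anc = build_ancestor(params, np.random.default_rng(params.seed))
    if params.n_genes_region and params.dup_block_span[1] > params.dup_block_span[0]:
        anc = duplicate_block(anc, params, np.random.default_rng(params.seed + 1))
    return evolve_lineages(anc, params, np.random.default_rng(params.seed + 2))


def emit_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write genomeA/B FASTA+GFF3, outgroup FASTA, and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_a_fasta": outdir / "genomeA.fa",
        "genome_a_gff": outdir / "genomeA.gff3",
        "genome_b_fasta": outdir / "genomeB.fa",
        "genome_b_gff": outdir / "genomeB.gff3",
        "outgroup_fasta": outdir / "outgroup.fa",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(dataset.genome_a.sequences, paths["genome_a_fasta"])
    write_gff(dataset.genome_a.all_genes(), paths["genome_a_gff"])
    write_fasta(dataset.genome_b.sequences, paths["genome_b_fasta"])
    write_gff(dataset.genome_b.all_genes(), paths["genome_b_gff"])
    write_fasta(dataset.outgroup_cds, paths["outgroup_fasta"])
    with open(paths["truth"], "w") as fh:
        cols = ["event_id", "event_type", "lineage", "chrom", "start", "end",
                "donor_id", "acceptor_id", "mode", "detail"]
        fh.write("\t".join(cols) + "\n")
        for rec in dataset.truth:
            fh.write(
                "\t".join(
                    [rec.event_id, rec.event_type, rec.lineage, rec.chrom,
                     str(rec.start), str(rec.end), rec.donor_id,
                     rec.acceptor_id, rec.mode, json.dumps(rec.detail, sort_keys=True)]
                )
                + "\n"
            )
    return paths
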