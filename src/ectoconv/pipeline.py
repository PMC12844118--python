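"""End-to-end analysis pipeline: homology -> collinearity -> quartets ->
conversion calls -> splits -> Ks -> region contrast -> loss summaries.

The pipeline consumes two annotated genomes plus an outgroup CDS set and
produces machine-readable tables for every stage.  It is the programmatic
surface behind the command-line tool; each stage is also callable on its
own through the underlying modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import collinearity as coll
from . import conversion as conv
from . import evostats
from .genome_io import Genome, extract_cds, reverse_complement
from .homology import HomologyHit, ScoringScheme, find_homologs, global_align, percent_identity

__all__ = ["ScanConfig", "ScanResult", "scan", "write_outputs", "render_report"]


@dataclass
class ScanConfig:
    """All thresholds of the analysis chain, config-file exposed."""

    kmer_size: int = 11
    min_shared_kmers: int = 2
    split_min_identity: float = 0.7
    # stiff gap penalties for the split alignment: spurious 1-2 bp gap
    # pairs at 25-30% divergence would otherwise jitter the projected frame
    split_gap_open: float = -10.0
    split_gap_extend: float = -4.0
    min_identity: float = 0.5
    min_cov: float = 0.5
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    gap_penalty: float = 1.0
    min_block_anchors: int = 3
    min_gap_genes: int = 5
    max_paralog_separation: int = 50
    paralog_min_identity: float = 0.80
    conversion_min_identity: float = 0.92
    tract_min_identity: float = 0.95
    flank_max_identity: float = 0.70
    window: int = 50
    step: int = 10
    min_del_run: int = 5
    bootstrap_reps: int = 100
    min_daughter_codons: int = 30
    seed: int = 0

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)

    @property
    def split_scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch,
                             self.split_gap_open, self.split_gap_extend)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class QuartetCall:
    quartet: coll.HomologQuartet
    verdict: str
    reason: str
    paralog_identity_A: float | None
    paralog_identity_B: float | None
    support: float | None
    newick: str
    tracts: list[conv.TractSegment] = field(default_factory=list)


@dataclass
class ScanResult:
    cross_hits: list[HomologyHit]
    paralog_hits_a: list[HomologyHit]
    paralog_hits_b: list[HomologyHit]
    blocks: list[coll.CollinearBlock]
    dotplot: list[dict]
    breaks: list[coll.BreakRegion]
    ortholog_map: dict[str, str]
    orphans_a: list[str]
    orphans_b: list[str]
    quartets: list[coll.HomologQuartet]
    calls: list[QuartetCall]
    splits: list[conv.SplitEvent]
    ks: list[evostats.KsEstimate]
    contrast: evostats.RegionContrast | None
    loss: list[evostats.LossSummary]
    affected_span: dict[str, tuple[int, int]]  # species -> gene-index span


def _paralog_identity(cds: Mapping[str, str], g1: str, g2: str,
                      scoring: ScoringScheme) -> tuple[float, "conv.Alignment"]:
    aln = global_align(cds[g1], cds[g2], scoring)
    return percent_identity(aln), aln


def _detect_splits_direction(
    mothers: Mapping[str, str],
    target_genome: Genome,
    target_order: list,
    target_cds: Mapping[str, str],
    cfg: ScanConfig,
) -> list[conv.SplitEvent]:
    """Mothers in one genome vs tandem multi-gene counterparts in the other.

    A candidate mother is an intact ORF whose counterpart region in the
    other genome is annotated as two or more consecutive genes, each of
    which fits inside the mother by a semi-global (infix) edit-distance
    screen.  The tandem run's genomic span is then aligned to the mother
    for stop-codon projection.
    """
    import edlib

    out = []
    for mother_id in sorted(mothers):
        mother_cds = mothers[mother_id]
        try:
            conv._validate_orf(mother_cds)
        except ValueError:
            continue
        contained: list[int] = []
        for i, g in enumerate(target_order):
            tcds = target_cds[g.gene_id]
            if len(tcds) > len(mother_cds) or len(tcds) < 3 * cfg.min_daughter_codons:
                continue
            k = int(len(tcds) * (1.0 - cfg.split_min_identity))
            r = edlib.align(tcds, mother_cds, mode="HW", task="distance", k=k)
            if r["editDistance"] != -1:
                contained.append(i)
        # maximal runs of consecutive gene indices, length >= 2
        runs: list[list[int]] = []
        for i in contained:
            if runs and i == runs[-1][-1] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        runs = [r for r in runs if len(r) >= 2]
        if not runs:
            continue
        idx = max(runs, key=len)
        target_genes = [target_order[i] for i in idx]
        chrom = target_genes[0].chrom
        if any(g.chrom != chrom for g in target_genes):
            continue
        # the tandem run should jointly account for most of the mother
        covered = sum(g.end - g.start for g in target_genes)
        if covered < 0.5 * len(mother_cds):
            continue
        span_s = min(g.start for g in target_genes)
        span_e = max(g.end for g in target_genes)
        region = target_genome.sequences[chrom][span_s:span_e]
        if target_genes[0].strand == "-":
            region = reverse_complement(region)
        try:
            ev = conv.detect_split(
                mother_cds, region, cfg.split_scoring,
                min_daughter_codons=cfg.min_daughter_codons, mother_id=mother_id,
            )
        except ValueError:
            continue
        if ev is not None:
            out.append(ev)
    return out


def scan(
    genome_a: Genome,
    genome_b: Genome,
    outgroup_cds: Mapping[str, str],
    cfg: ScanConfig | None = None,
    affected_span_hint: dict[str, tuple[int, int]] | None = None,
) -> ScanResult:
    """Run the full conversion-detection chain on a genome pair + outgroup.

    ``affected_span_hint`` optionally fixes the affected region (genomic bp
    intervals per species) used for the Ks contrast and region loss
    statistics; by default the region is inferred as the gene-index span
    covered by the detected quartets.
    """
    cfg = cfg or ScanConfig()
    genes_a = genome_a.all_genes()
    genes_b = genome_b.all_genes()
    cds_a = {g.gene_id: extract_cds(g, genome_a) for g in genes_a}
    cds_b = {g.gene_id: extract_cds(g, genome_b) for g in genes_b}
    order_a = [g.gene_id for g in genes_a]
    order_b = [g.gene_id for g in genes_b]

    kw = dict(
        scoring=cfg.scoring,
        min_identity=cfg.min_identity,
        min_cov=cfg.min_cov,
        kmer_size=cfg.kmer_size,
        min_shared_kmers=cfg.min_shared_kmers,
    )
    cross_hits = find_homologs(cds_a, cds_b, **kw)
    paralog_hits_a = find_homologs(cds_a, cds_a, **kw)
    paralog_hits_b = find_homologs(cds_b, cds_b, **kw)

    blocks = coll.chain_anchors(
        cross_hits, order_a, order_b, cfg.gap_penalty, cfg.min_block_anchors
    )
    dotplot = coll.classify_dotplot(cross_hits, blocks, order_a, order_b)
    breaks = coll.detect_insertion_breaks(blocks, order_a, order_b, cfg.min_gap_genes)
    ortholog_map, _ = coll.assign_orthologs(blocks, cross_hits)
    orphans_a = sorted(set(order_a) - set(ortholog_map))
    orphans_b = sorted(set(order_b) - set(ortholog_map.values()))

    quartets = coll.detect_quartets(
        paralog_hits_a, paralog_hits_b, ortholog_map, order_a, order_b,
        cfg.max_paralog_separation, cfg.paralog_min_identity,
    )

    calls: list[QuartetCall] = []
    for q in quartets:
        cds_p = cds_a if q.species_with_paralogs == "A" else cds_b
        cds_o = cds_b if q.species_with_paralogs == "A" else cds_a
        members = {
            q.paralog_1: cds_p[q.paralog_1],
            q.paralog_2: cds_p[q.paralog_2],
            q.ortholog_1: cds_o[q.ortholog_1],
            q.ortholog_2: cds_o[q.ortholog_2],
        }
        q.outgroup = coll.pick_outgroup(members, outgroup_cds, cfg.scoring,
                                        min_identity=cfg.min_identity,
                                        kmer_size=cfg.kmer_size,
                                        min_shared_kmers=cfg.min_shared_kmers)
        seqs = dict(members)
        if q.outgroup is not None:
            seqs[q.outgroup] = outgroup_cds[q.outgroup]
        msa = conv.star_msa(seqs, q.paralog_1, cfg.scoring)
        tree = conv.nj_tree(conv.distance_matrix_from_msa(msa))

        ident_p, paralog_aln = _paralog_identity(cds_p, q.paralog_1, q.paralog_2, cfg.scoring)
        ident_o, _ = _paralog_identity(cds_o, q.ortholog_1, q.ortholog_2, cfg.scoring)
        q.paralog_identity = ident_p
        if q.species_with_paralogs == "A":
            a_labels = (q.paralog_1, q.paralog_2)
            b_labels = (q.ortholog_1, q.ortholog_2)
            ident_a, ident_b = ident_p, ident_o
        else:
            a_labels = (q.ortholog_1, q.ortholog_2)
            b_labels = (q.paralog_1, q.paralog_2)
            ident_a, ident_b = ident_o, ident_p
        verdict, reason = conv.classify_quartet_topology(
            tree, a_labels, b_labels, q.outgroup,
            paralog_identity_a=ident_a, paralog_identity_b=ident_b,
            conversion_min_identity=cfg.conversion_min_identity,
        )
        support = conv.bootstrap_support(
            msa, verdict, a_labels, b_labels, q.outgroup,
            n_reps=cfg.bootstrap_reps, seed=cfg.seed,
        )
        tracts: list[conv.TractSegment] = []
        if verdict.startswith("converted"):
            ortho1 = global_align(cds_p[q.paralog_1], cds_o[q.ortholog_1], cfg.scoring)
            ortho2 = global_align(cds_p[q.paralog_2], cds_o[q.ortholog_2], cfg.scoring)
            tracts = conv.delineate_tracts(
                paralog_aln, (ortho1, ortho2), cfg.window, cfg.step,
                cfg.tract_min_identity, cfg.flank_max_identity, cfg.min_del_run,
            )
        calls.append(
            QuartetCall(q, verdict, reason, ident_a, ident_b, support,
                        tree.newick, tracts)
        )

    splits = _detect_splits_direction(cds_a, genome_b, genes_b, cds_b, cfg)
    splits += _detect_splits_direction(cds_b, genome_a, genes_a, cds_a, cfg)

    # Ks for every ortholog pair
    ks_list: list[evostats.KsEstimate] = []
    for ga, gb in sorted(ortholog_map.items()):
        est = evostats.nei_gojobori(cds_a[ga], cds_b[gb], ga, gb)
        ks_list.append(est)

    # affected region: bp span covered by quartet members, per species
    affected_span: dict[str, tuple[int, int]] = {}
    if affected_span_hint:
        affected_span = dict(affected_span_hint)
    elif quartets:
        pos_a: list[int] = []
        pos_b: list[int] = []
        gene_by_id_a = {g.gene_id: g for g in genes_a}
        gene_by_id_b = {g.gene_id: g for g in genes_b}
        for q in quartets:
            mem_a = (
                [q.paralog_1, q.paralog_2]
                if q.species_with_paralogs == "A"
                else [q.ortholog_1, q.ortholog_2]
            )
            mem_b = (
                [q.paralog_1, q.paralog_2]
                if q.species_with_paralogs == "B"
                else [q.ortholog_1, q.ortholog_2]
            )
            for gid in mem_a:
                pos_a += [gene_by_id_a[gid].start, gene_by_id_a[gid].end]
            for gid in mem_b:
                pos_b += [gene_by_id_b[gid].start, gene_by_id_b[gid].end]
        affected_span = {"A": (min(pos_a), max(pos_a)), "B": (min(pos_b), max(pos_b))}

    contrast = None
    loss: list[evostats.LossSummary] = []
    if affected_span:
        span_a, span_b = affected_span.get("A"), affected_span.get("B")
        in_region_a = {
            g.gene_id for g in genes_a if span_a and g.start >= span_a[0] and g.end <= span_a[1]
        }
        in_region_b = {
            g.gene_id for g in genes_b if span_b and g.start >= span_b[0] and g.end <= span_b[1]
        }
        ks_aff = [e.Ks for e in ks_list if e.Ks is not None and (e.gene_a in in_region_a or e.gene_b in in_region_b)]
        ks_bg = [e.Ks for e in ks_list if e.Ks is not None and not (e.gene_a in in_region_a or e.gene_b in in_region_b)]
        if len(ks_aff) >= 2 and len(ks_bg) >= 2:
            contrast = evostats.region_contrast(ks_aff, ks_bg)

        merge: dict[str, str] = {}
        for ev in splits:
            # collapse a mother's tandem counterparts when counting ancestry
            merge[ev.mother_gene] = ev.mother_gene
        ancestral = evostats.ancestral_gene_count(
            sorted(in_region_a), sorted(in_region_b), ortholog_map, merge
        )
        for species, in_region in (("A", in_region_a), ("B", in_region_b)):
            retained = len({merge.get(g, g) for g in in_region})
            loss.append(
                evostats.LossSummary(
                    scope="region",
                    species=species,
                    ancestral_count=ancestral,
                    retained_count=retained,
                    orphan_count=ancestral - retained,
                    loss_rate=evostats.loss_rate(ancestral, retained) if ancestral else 0.0,
                )
            )
    for species, total, orphans in (
        ("A", len(genes_a), orphans_a),
        ("B", len(genes_b), orphans_b),
    ):
        rate = round(100.0 * len(orphans) / total, 2) if total else 0.0
        loss.append(
            evostats.LossSummary("genome", species, total, total - len(orphans),
                                 len(orphans), rate)
        )

    return ScanResult(
        cross_hits=cross_hits,
        paralog_hits_a=paralog_hits_a,
        paralog_hits_b=paralog_hits_b,
        blocks=blocks,
        dotplot=dotplot,
        breaks=breaks,
        ortholog_map=ortholog_map,
        orphans_a=orphans_a,
        orphans_b=orphans_b,
        quartets=quartets,
        calls=calls,
        splits=splits,
        ks=ks_list,
        contrast=contrast,
        loss=loss,
        affected_span=affected_span,
    )


def write_outputs(result: ScanResult, outdir: str | Path) -> dict[str, Path]:
    """Write every stage table as TSV/JSON/newick under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def tsv(name: str, rows: list[dict]) -> None:
        p = outdir / name
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths[name] = p

    tsv("hits.tsv", [vars(h) for h in result.cross_hits])
    tsv(
        "blocks.tsv",
        [
            {
                "block_id": b.block_id,
                "orientation": b.orientation,
                "n_anchors": len(b.anchors),
                "score": b.score,
                "anchors": ";".join(f"{x.hit.query_id}|{x.hit.subject_id}" for x in b.anchors),
            }
            for b in result.blocks
        ],
    )
    tsv("dotplot.tsv", result.dotplot)
    tsv("breaks.tsv", [vars(b) for b in result.breaks])
    tsv(
        "quartets.tsv",
        [
            {
                "species": q.species_with_paralogs,
                "paralog_1": q.paralog_1,
                "paralog_2": q.paralog_2,
                "ortholog_1": q.ortholog_1,
                "ortholog_2": q.ortholog_2,
                "outgroup": q.outgroup or "",
                "paralog_identity": round(q.paralog_identity, 4),
                "separation": q.separation,
            }
            for q in result.quartets
        ],
    )
    tsv(
        "calls.tsv",
        [
            {
                "quartet": f"{c.quartet.paralog_1}|{c.quartet.paralog_2}",
                "species": c.quartet.species_with_paralogs,
                "verdict": c.verdict,
                "support": "" if c.support is None else round(c.support, 3),
                "paralog_identity_A": "" if c.paralog_identity_A is None else round(c.paralog_identity_A, 4),
                "paralog_identity_B": "" if c.paralog_identity_B is None else round(c.paralog_identity_B, 4),
                "reason": c.reason,
            }
            for c in result.calls
        ],
    )
    tsv(
        "tracts.tsv",
        [
            {
                "quartet": f"{c.quartet.paralog_1}|{c.quartet.paralog_2}",
                "class": t.seg_class,
                "start_col": t.start_col,
                "end_col": t.end_col,
                "span_a": f"{t.span_a[0]}-{t.span_a[1]}",
                "span_b": f"{t.span_b[0]}-{t.span_b[1]}",
                "paralog_identity": "" if t.paralog_identity is None else round(t.paralog_identity, 4),
                "ortholog_identity": "" if t.ortholog_identity is None else round(t.ortholog_identity, 4),
            }
            for c in result.calls
            for t in c.tracts
        ],
    )
    tsv(
        "splits.tsv",
        [
            {
                "mother": s.mother_gene,
                "mode": s.mode,
                "stop_offsets": ";".join(map(str, s.stop_offsets)),
                "n_daughters": len(s.daughters),
                "frameshift_indels": ";".join(f"{o}+{l}" for o, l in s.frameshift_indels),
            }
            for s in result.splits
        ],
    )
    tsv(
        "ks.tsv",
        [
            {
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "S": round(e.S, 4),
                "N": round(e.N, 4),
                "Sd": round(e.Sd, 4),
                "Nd": round(e.Nd, 4),
                "pS": "" if e.pS is None else round(e.pS, 6),
                "pN": "" if e.pN is None else round(e.pN, 6),
                "Ks": "" if e.Ks is None else round(e.Ks, 3),
                "Ka": "" if e.Ka is None else round(e.Ka, 3),
                "n_codons": e.n_codons_used,
                "flags": ",".join(sorted(e.flags)),
            }
            for e in result.ks
        ],
    )
    tsv("loss.tsv", [vars(ls) for ls in result.loss])

    trees = outdir / "trees.nwk"
    with open(trees, "w") as fh:
        for c in result.calls:
            fh.write(c.newick.rstrip() + "\n")
    paths["trees.nwk"] = trees

    contrast_path = outdir / "contrast.json"
    with open(contrast_path, "w") as fh:
        json.dump(
            asdict(result.contrast) if result.contrast else {}, fh, indent=2
        )
    paths["contrast.json"] = contrast_path
    return paths


def render_report(outdir: str | Path) -> dict:
    """Headline summary assembled from existing stage outputs (no recompute)."""
    outdir = Path(outdir)
    required = ["calls.tsv", "ks.tsv", "loss.tsv", "contrast.json"]
    for name in required:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"missing stage output {name}")
    calls = pd.read_csv(outdir / "calls.tsv", sep="\t") if (outdir / "calls.tsv").stat().st_size else pd.DataFrame()
    loss = pd.read_csv(outdir / "loss.tsv", sep="\t")
    with open(outdir / "contrast.json") as fh:
        contrast = json.load(fh)
    verdicts = (
        calls["verdict"].value_counts().to_dict() if "verdict" in calls else {}
    )
    summary = {
        "n_quartets": int(len(calls)),
        "verdicts": {k: int(v) for k, v in verdicts.items()},
        "contrast": contrast,
        "loss": loss.to_dict(orient="records"),
    }
    return summary
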