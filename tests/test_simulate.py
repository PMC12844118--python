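import numpy as np
import pytest

from ectoconv.evostats import STOP_CODONS
from ectoconv.genome_io import extract_cds, read_fasta, read_gff
from ectoconv.homology import global_align, percent_identity
from ectoconv.simulate import (
    ConversionSpec,
    SimParams,
    SplitSpec,
    build_ancestor,
    duplicate_block,
    emit_dataset,
    simulate_dataset,
)


def _all_cds(dataset):
    out = {}
    for genome in (dataset.genome_a, dataset.genome_b):
        for g in genome.all_genes():
            out[g.gene_id] = extract_cds(g, genome)
    return out


def _is_clean_orf(cds):
    if len(cds) % 3 or cds[:3] != "ATG" or cds[-3:] not in STOP_CODONS:
        return False
    return all(cds[i : i + 3] not in STOP_CODONS for i in range(3, len(cds) - 3, 3))


class TestAncestor:
    def test_seed_determinism(self):
        p = SimParams(seed=42)
        a1 = build_ancestor(p)
        a2 = build_ancestor(p)
        assert a1.seq == a2.seq
        assert a1.order == a2.order

    def test_every_cds_is_clean_orf(self):
        anc = build_ancestor(SimParams(seed=1))
        for g in anc.genes.values():
            assert _is_clean_orf(anc.seq[g.start : g.end])

    def test_region_zero_degenerate(self):
        p = SimParams(seed=2, n_genes_region=0, n_genes_background=6)
        ds = simulate_dataset(p)
        assert ds.affected_region == {"A": (0, 0), "B": (0, 0)}
        assert len(ds.genome_a.all_genes()) <= 6

    def test_infeasible_gene_length_rejected(self):
        with pytest.raises(ValueError):
            SimParams(gene_len_codons=(5, 5)).validate()


class TestDuplicateBlock:
    def test_direct_orientation_identical_copy(self):
        p = SimParams(seed=3, dup_orientation="same", dup_block_span=(0, 1))
        anc = duplicate_block(build_ancestor(p), p)
        (orig, copy), = anc.pairs
        g1, g2 = anc.genes[orig], anc.genes[copy]
        assert g1.strand == g2.strand == "+"
        assert anc.seq[g1.start : g1.end] == anc.seq[g2.start : g2.end]

    def test_inverted_orientation_geometry(self):
        p = SimParams(seed=4, dup_orientation="inverted", dup_block_span=(0, 3))
        anc = duplicate_block(build_ancestor(p), p)
        copies = [anc.genes[b] for _, b in anc.pairs]
        assert all(g.strand == "-" for g in copies)
        # order reversed on the chromosome relative to the originals
        originals = [anc.genes[a] for a, _ in anc.pairs]
        orig_order = sorted(range(3), key=lambda i: originals[i].start)
        copy_order = sorted(range(3), key=lambda i: copies[i].start)
        assert copy_order == orig_order[::-1]

    def test_pairwise_identity_100_after_duplication(self):
        from ectoconv.genome_io import reverse_complement

        p = SimParams(seed=5, dup_block_span=(0, 4))
        anc = duplicate_block(build_ancestor(p), p)
        for a, b in anc.pairs:
            ga, gb = anc.genes[a], anc.genes[b]
            sa = anc.seq[ga.start : ga.end]
            sb = anc.seq[gb.start : gb.end]
            if gb.strand != ga.strand:
                sb = reverse_complement(sb)
            assert sa == sb

    def test_double_duplication_rejected(self):
        p = SimParams(seed=6)
        anc = duplicate_block(build_ancestor(p), p)
        with pytest.raises(ValueError, match="already duplicated"):
            duplicate_block(anc, p)


class TestEvolve:
    def test_zero_rate_limit_genomes_identical(self):
        p = SimParams(
            seed=7, branch_sub_rate=0.0, dup_branch_sub_rate=0.0,
            loss_prob_affected=0.0, loss_prob_background=0.0,
        )
        ds = simulate_dataset(p)
        cds = _all_cds(ds)
        a_ids = [g.gene_id for g in ds.genome_a.all_genes()]
        for aid in a_ids:
            bid = "B" + aid[1:]
            assert cds[aid] == cds[bid]

    def test_full_conversion_homogenizes_one_lineage_only(self):
        p = SimParams(
            seed=8, loss_prob_affected=0.0, loss_prob_background=0.0,
            conversion_events=(ConversionSpec("A", 0, 1.0, 1),),
        )
        ds = simulate_dataset(p)
        cds = _all_cds(ds)
        assert cds["A_greg000"] == cds["A_greg000b"]
        assert cds["B_greg000"] != cds["B_greg000b"]

    def test_partial_tract_identical_between_arms(self):
        p = SimParams(
            seed=9, loss_prob_affected=0.0, loss_prob_background=0.0,
            conversion_events=(ConversionSpec("A", 1, (120, 420), 1,
                                              n_flank_deletions=0),),
        )
        ds = simulate_dataset(p)
        rec, = [r for r in ds.truth if r.event_type == "conversion"]
        s, e = rec.detail["tract_cds"]
        cds = _all_cds(ds)
        donor, acceptor = cds["A_" + rec.donor_id], cds["A_" + rec.acceptor_id]
        assert acceptor[s:e] == donor[s:e]
        # outside the tract the arms differ (flanks are hypermutated)
        assert acceptor != donor

    def test_invalid_event_parameters_rejected(self):
        with pytest.raises(ValueError, match="lineage"):
            SimParams(conversion_events=(ConversionSpec("C", 0),)).validate()
        with pytest.raises(ValueError, match="mode"):
            SimParams(split_events=(SplitSpec("A", 0, mode="x"),)).validate()
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            SimParams(branch_sub_rate=1.5).validate()

    def test_conversion_on_missing_gene_rejected(self):
        # the split removes the mother annotation; a later run that asks
        # for conversion on the same (now absent) gene must fail loudly
        from ectoconv.simulate import build_ancestor, duplicate_block, evolve_lineages

        p = SimParams(
            seed=10,
            split_events=(SplitSpec("A", 0, arm=2),),
        )
        anc = duplicate_block(build_ancestor(p), p)
        ds = evolve_lineages(anc, p)  # split applied, arm-2 gene gone
        p_bad = SimParams(
            seed=10,
            split_events=(SplitSpec("A", 0, arm=2),
                          SplitSpec("A", 0, arm=2)),
        )
        with pytest.raises(ValueError, match="missing gene"):
            evolve_lineages(anc, p_bad)

    def test_split_point_mode_daughters_and_truth(self):
        p = SimParams(
            seed=11, loss_prob_affected=0.0, loss_prob_background=0.0,
            split_events=(SplitSpec("B", 2, arm=1, n_daughters=3, mode="point"),),
        )
        ds = simulate_dataset(p)
        rec, = [r for r in ds.truth if r.event_type == "split"]
        assert rec.mode == "point"
        daughters = rec.detail["daughters"]
        assert len(daughters) == 3
        assert len(rec.detail["stop_offsets"]) == 2
        ids_b = {g.gene_id for g in ds.genome_b.all_genes()}
        assert {f"B_{d}" for d in daughters} <= ids_b
        assert "B_greg002" not in ids_b  # mother annotation replaced
        # the introduced stops sit at the recorded codons of the mother frame
        mother_pre = None
        cds = _all_cds(ds)
        d1 = cds[f"B_{daughters[0]}"]
        assert d1[-3:] in STOP_CODONS

    def test_split_frameshift_mode_records_indel(self):
        p = SimParams(
            seed=12, loss_prob_affected=0.0, loss_prob_background=0.0,
            split_events=(SplitSpec("B", 2, arm=1, n_daughters=2,
                                    mode="frameshift"),),
        )
        ds = simulate_dataset(p)
        rec, = [r for r in ds.truth if r.event_type == "split"]
        assert rec.mode == "frameshift"
        (off, length), = rec.detail["frameshift_indels"]
        assert length % 3 != 0

    def test_loss_accounting_matches_truth(self, small_dataset):
        ds = small_dataset
        merge = ds.split_merge_map()
        for lineage, genome in (("A", ds.genome_a), ("B", ds.genome_b)):
            survivors = {
                merge.get(g.gene_id, g.gene_id) for g in genome.all_genes()
            }
            losses = [
                r for r in ds.truth
                if r.event_type == "gene_loss" and r.lineage == lineage
            ]
            assert len(ds.ancestral_genes) - len(survivors) == len(losses)

    def test_flank_divergence_exceeds_background(self):
        # orthologous identity inside hypermutated flanks is lower than in
        # unaffected background genes, averaged over replicates
        flank_vals, background_vals = [], []
        for seed in range(20):
            p = SimParams(
                seed=seed, n_genes_region=6, n_genes_background=4,
                dup_block_span=(0, 2), region_rate_multiplier=1.0,
                loss_prob_affected=0.0, loss_prob_background=0.0,
                conversion_events=(ConversionSpec("A", 0, (150, 450),
                                                  n_flank_deletions=0),),
            )
            ds = simulate_dataset(p)
            cds = _all_cds(ds)
            rec, = [r for r in ds.truth if r.event_type == "conversion"]
            patches = [r for r in ds.truth if r.event_type == "point_patch"
                       and r.acceptor_id == rec.acceptor_id]
            acc_a = cds["A_" + rec.acceptor_id]
            acc_b = cds["B_" + rec.acceptor_id]
            assert len(acc_a) == len(acc_b)
            for pr in patches:
                fs, fe = pr.detail["flank_cds"]
                pa, pb = acc_a[fs:fe], acc_b[fs:fe]
                flank_vals.append(np.mean([x == y for x, y in zip(pa, pb)]))
            bg_a = cds["A_gbgL000"]
            bg_b = cds["B_gbgL000"]
            background_vals.append(
                np.mean([x == y for x, y in zip(bg_a, bg_b)])
            )
        assert np.mean(flank_vals) < np.mean(background_vals)


class TestEmit:
    def test_byte_identical_reruns(self, small_params, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        emit_dataset(simulate_dataset(small_params), d1)
        emit_dataset(simulate_dataset(small_params), d2)
        for name in ("genomeA.fa", "genomeA.gff3", "genomeB.fa",
                     "genomeB.gff3", "outgroup.fa", "truth.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_round_trip_gene_counts(self, small_dataset, tmp_path):
        paths = emit_dataset(small_dataset, tmp_path)
        seqs = read_fasta(paths["genome_a_fasta"])
        genes = read_gff(paths["genome_a_gff"], seqs)
        assert len(genes) == len(small_dataset.genome_a.all_genes())

    def test_truth_row_count(self, small_dataset, tmp_path):
        paths = emit_dataset(small_dataset, tmp_path)
        rows = paths["truth"].read_text().strip().splitlines()
        assert len(rows) - 1 == len(small_dataset.truth)

    def test_affected_region_contains_conversions(self, small_dataset):
        for rec in small_dataset.truth:
            if rec.event_type != "conversion":
                continue
            lo, hi = small_dataset.affected_region[rec.lineage]
            assert lo <= rec.start < rec.end <= hi

    def test_emitted_genes_are_clean_orfs(self, small_dataset):
        ds = small_dataset
        for genome in (ds.genome_a, ds.genome_b):
            for g in genome.all_genes():
                if ".d" in g.gene_id:
                    continue  # split daughters are ORF fragments by design
                assert _is_clean_orf(extract_cds(g, genome)), g.gene_id
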