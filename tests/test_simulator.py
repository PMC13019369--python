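"""Simulator contracts: tree shape, Jukes-Cantor evolution, event truth."""

import math

import dendropy
import numpy as np
import pytest

from genemobility.relatedness import whole_genome_identity
from genemobility.seqio import assembly_stats, extract_proteome
from genemobility.simulator import (FocalFamily, HetInjection, SimConfig,
                                    inject_heterozygous_block, jc_p,
                                    mutate_assembly, sample_tree,
                                    simulate_pangenome, write_sim_output)


def test_tree_structure_and_labels():
    tree = dendropy.Tree.get(data=sample_tree(3, 1.0, seed=1),
                             schema="newick")
    labels = sorted(t.label for t in tree.taxon_namespace)
    assert labels == ["T001", "T002", "T003"]


def test_tree_deterministic_per_seed():
    assert sample_tree(6, 1.0, seed=9) == sample_tree(6, 1.0, seed=9)
    assert sample_tree(6, 1.0, seed=9) != sample_tree(6, 1.0, seed=10)


def test_tree_is_ultrametric_with_positive_branches():
    tree = dendropy.Tree.get(data=sample_tree(10, 2.0, seed=4),
                             schema="newick")
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    assert max(depths) - min(depths) < 1e-9
    assert all(e.length is None or e.length > 0
               for e in tree.preorder_edge_iter())


def test_mean_depth_matches_pure_birth_expectation():
    """Root-to-tip depth of the Yule tree averages H_n / birth_rate."""
    n, rate = 8, 1.5
    expected = sum(1.0 / k for k in range(1, n + 1)) / rate
    depths = []
    for seed in range(100):
        tree = dendropy.Tree.get(data=sample_tree(n, rate, seed=seed),
                                 schema="newick")
        depths.append(next(tree.leaf_node_iter()).distance_from_root())
    assert np.mean(depths) == pytest.approx(expected, rel=0.10)


def test_tree_requires_three_taxa():
    with pytest.raises(ValueError):
        sample_tree(2, 1.0, seed=0)


def test_simulation_bit_reproducible(tmp_path):
    cfg = dict(n_taxa=5, n_core_genes=20, seed=13,
               focal_families=[FocalFamily("fam", hgt_rate=0.6,
                                           loss_prob=0.1, trunc_prob=0.1)],
               het_injections=[HetInjection("T002", 10, 8.0)])
    out = []
    for d in ("a", "b"):
        sim = simulate_pangenome(SimConfig(**cfg))
        write_sim_output(sim, tmp_path / d)
        out.append({p.name: p.read_bytes()
                    for p in sorted((tmp_path / d).iterdir())})
    assert out[0] == out[1]


def test_gc_tracks_target():
    for target in (50.0, 65.0):
        sim = simulate_pangenome(SimConfig(n_taxa=3, n_core_genes=30,
                                           gc_target=target, seed=17))
        for asm in sim.assemblies:
            assert assembly_stats(asm).gc_percent == pytest.approx(target,
                                                                   abs=2.0)


def test_zero_rates_give_vertical_truth_and_jc_divergence():
    sim = simulate_pangenome(SimConfig(
        n_taxa=6, n_core_genes=40, subst_rate=0.03, seed=19,
        focal_families=[FocalFamily("fam")]))
    assert all(v == "vertical" for v in sim.tip_family_status.values())
    assert sim.truth_events == []
    # observed pairwise divergence matches the closed form within a binomial
    # envelope (small slack covers the coding-gene stop-redraw constraint)
    for _, row in sim.true_divergence.iterrows():
        a = sim.assembly(row.tip_a)
        b = sim.assembly(row.tip_b)
        p_obs = 1.0 - whole_genome_identity(a, b) / 100.0
        L = a.total_length
        sigma = math.sqrt(row.expected_p * (1 - row.expected_p) / L)
        assert abs(p_obs - row.expected_p) <= 3 * sigma + 2e-3


def test_mutate_assembly_realized_rate(plain_genome):
    p = 0.05
    partner = mutate_assembly(plain_genome, p, seed=23)
    obs = 1.0 - whole_genome_identity(plain_genome, partner) / 100.0
    L = plain_genome.total_length
    assert abs(obs - p) <= 4 * math.sqrt(p * (1 - p) / L)


def test_forced_loss_removes_family_everywhere():
    """loss_prob=1 guarantees loss on the stem; no tip retains the family,
    the emitted annotations lack it, and truth agrees."""
    sim = simulate_pangenome(SimConfig(
        n_taxa=4, n_core_genes=10, seed=29,
        focal_families=[FocalFamily("gone", loss_prob=1.0)]))
    assert all(sim.tip_family_status[(a.id, "gone")] == "loss"
               for a in sim.assemblies)
    for asm in sim.assemblies:
        assert all(ann.product != "gone" for ann in asm.annotations)


def test_truth_statuses_consistent_with_annotations():
    sim = simulate_pangenome(SimConfig(
        n_taxa=10, n_core_genes=10, seed=31,
        focal_families=[FocalFamily("fam", hgt_rate=0.4, loss_prob=0.15,
                                    trunc_prob=0.15)]))
    statuses = {sim.tip_family_status[(a.id, "fam")] for a in sim.assemblies}
    assert len(statuses) >= 2
    for asm in sim.assemblies:
        has_gene = any(ann.product == "fam" for ann in asm.annotations)
        status = sim.tip_family_status[(asm.id, "fam")]
        assert has_gene == (status != "loss")
        if status == "truncation":
            prot = next(p for p in sim.proteomes[asm.id]
                        if p.description == "fam")
            full = FocalFamily("fam").length // 3 - 1
            assert len(prot.sequence) < 0.7 * full


def test_hgt_pulls_gene_distances_below_vertical_expectation():
    """Replacement HGT can only make family copies coalesce more recently,
    so mean realized family divergence under HGT falls below the vertical
    runs' (same seeds, HGT switched off)."""
    def mean_family_divergence(hgt_rate, seed):
        sim = simulate_pangenome(SimConfig(
            n_taxa=8, n_core_genes=5, subst_rate=0.03, seed=seed,
            focal_families=[FocalFamily("fam", hgt_rate=hgt_rate)]))
        seqs = []
        for asm in sim.assemblies:
            ann = next(a for a in asm.annotations if a.product == "fam")
            seqs.append(asm.contig(ann.contig_id).sequence[ann.start:ann.end])
        divs = [sum(x != y for x, y in zip(s1, s2)) / len(s1)
                for i, s1 in enumerate(seqs) for s2 in seqs[i + 1:]]
        return np.mean(divs)

    seeds = range(40, 48)
    with_hgt = np.mean([mean_family_divergence(1.0, s) for s in seeds])
    without = np.mean([mean_family_divergence(0.0, s) for s in seeds])
    assert with_hgt < without


def test_injection_zero_divergence_identical_copy(plain_genome):
    asm, record = inject_heterozygous_block(plain_genome, 10, 0.0, seed=37)
    src = asm.contig(record["source_contig"]).sequence[
        record["source_start"]:record["source_end"]]
    assert asm.contig(record["copy_contig"]).sequence == src


def test_injection_truth_coordinates_map_to_annotations(plain_genome):
    asm, record = inject_heterozygous_block(plain_genome, 12, 10.0, seed=38)
    by_tag = {a.locus_tag: a for a in asm.annotations}
    src_tags = record["source_locus_tags"]
    cp_tags = record["copy_locus_tags"]
    assert len(src_tags) == len(cp_tags) == 12
    for s_tag, c_tag in zip(src_tags, cp_tags):
        s, c = by_tag[s_tag], by_tag[c_tag]
        assert s.end - s.start == c.end - c.start
        assert c.contig_id == record["copy_contig"]
        assert s.start - record["source_start"] == c.start
    asm.validate()


def test_injection_block_too_long_rejected(plain_genome):
    with pytest.raises(ValueError, match="genes"):
        inject_heterozygous_block(plain_genome, 10 ** 4, 10.0, seed=39)


def test_jc_p_closed_form_limits():
    assert jc_p(0.05, 0.0) == 0.0
    assert jc_p(0.05, 1e9) == pytest.approx(0.75)
    assert jc_p(0.02, 1.0) == pytest.approx(
        0.75 * (1 - math.exp(-4 * 0.02 / 3)))
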