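"""Gene-vs-genome distance decoupling and the Mantel permutation test."""

import itertools
import math

import numpy as np
import pytest

from genemobility.markers import PRESENT, TRUNCATED, MarkerCall
from genemobility.mobility import (MobilityPoint, gene_distance_matrix,
                                   mantel_test, mobility_points,
                                   mobility_report, ortholog_pairs)
from genemobility.relatedness import DistMatrix
from genemobility.seqio import SeqRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _call(tag, status=PRESENT):
    return MarkerCall("fam", status, 100.0, 100.0, tag,
                      all_evidence=[(tag, 100.0)] if status == PRESENT else [])


def test_identical_family_sequences_give_identity_100():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list(AA), size=200))
    strains = [(f"s{i}", [SeqRecord("fam_gene", seq)]) for i in range(3)]
    calls = {f"s{i}": _call("fam_gene") for i in range(3)}
    pairs = ortholog_pairs(strains, "fam", calls)
    assert len(pairs) == 3
    assert all(p.gene_identity == 100.0 for p in pairs)


def test_truncated_strain_excluded_and_min_strains_enforced():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list(AA), size=200))
    strains = [(f"s{i}", [SeqRecord("g", seq)]) for i in range(4)]
    calls = {"s0": _call("g"), "s1": _call("g"),
             "s2": _call("g", TRUNCATED), "s3": _call("g")}
    pairs = ortholog_pairs(strains, "fam", calls)
    assert {p.strain_a for p in pairs} | {p.strain_b for p in pairs} \
        == {"s0", "s1", "s3"}
    calls["s1"] = _call("g", TRUNCATED)
    with pytest.raises(ValueError, match="insufficient"):
        ortholog_pairs(strains, "fam", calls)


def test_multi_copy_strain_uses_best_pair_and_flags():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list(AA), size=200))
    far = list(seq)
    for i in rng.choice(200, size=60, replace=False):
        far[i] = AA[int(rng.integers(20))]
    strains = [
        ("s0", [SeqRecord("a1", seq), SeqRecord("a2", "".join(far))]),
        ("s1", [SeqRecord("b1", seq)]),
        ("s2", [SeqRecord("c1", seq)]),
    ]
    calls = {"s0": MarkerCall("fam", PRESENT, 100, 100, "a1",
                              all_evidence=[("a1", 100.0), ("a2", 70.0)]),
             "s1": _call("b1"), "s2": _call("c1")}
    pairs = ortholog_pairs(strains, "fam", calls)
    p01 = next(p for p in pairs if {p.strain_a, p.strain_b} == {"s0", "s1"})
    assert p01.gene_identity == 100.0
    assert p01.multi_copy


def test_point_transformation_matches_printed_example():
    """ANI 98.0 with 99.2%-identical genes maps to the point (2.0, 0.8)."""
    from genemobility.mobility import OrthologPair
    dm = DistMatrix(["a", "b", "c"],
                    100.0 - np.array([[100, 98.0, 94.2],
                                      [98.0, 100, 94.2],
                                      [94.2, 94.2, 100.0]]))
    pairs = [OrthologPair("a", "b", 99.2, False),
             OrthologPair("a", "c", 91.8, False)]
    points = mobility_points(pairs, dm)
    assert (points[0].genome_distance, points[0].gene_distance) \
        == pytest.approx((2.0, 0.8))
    assert (points[1].genome_distance, points[1].gene_distance) \
        == pytest.approx((5.8, 8.2))


def test_identical_everything_is_origin_and_pair_count():
    from genemobility.mobility import OrthologPair
    labels = [f"s{i}" for i in range(8)]
    dm = DistMatrix(labels, np.zeros((8, 8)))
    pairs = [OrthologPair(a, b, 100.0, False)
             for a, b in itertools.combinations(labels, 2)]
    points = mobility_points(pairs, dm)
    assert len(points) == 28
    assert all(p.genome_distance == 0 and p.gene_distance == 0 for p in points)


def test_missing_ani_entry_names_pair():
    from genemobility.mobility import OrthologPair
    dm = DistMatrix(["a", "b"], np.zeros((2, 2)))
    with pytest.raises(KeyError, match="a.*x|x.*a"):
        mobility_points([OrthologPair("a", "x", 99.0, False)], dm)


def _random_dm(rng, n, labels=None):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    return DistMatrix(labels or [f"s{i}" for i in range(n)], d)


def test_mantel_perfect_concordance():
    rng = np.random.default_rng(5)
    dm = _random_dm(rng, 8)
    res = mantel_test(dm, dm, n_perm=999, seed=1)
    assert res.r == pytest.approx(1.0)
    assert res.p_value <= 0.01


def test_mantel_seeded_reproducibility_and_seed_sensitivity():
    rng = np.random.default_rng(6)
    a, b = _random_dm(rng, 8), _random_dm(rng, 8)
    r1 = mantel_test(a, b, n_perm=199, seed=42)
    r2 = mantel_test(a, b, n_perm=199, seed=42)
    assert (r1.r, r1.p_value) == (r2.r, r2.p_value)


def test_mantel_constant_matrix_flagged():
    dm = DistMatrix(["a", "b", "c"], np.zeros((3, 3)))
    rng = np.random.default_rng(7)
    res = mantel_test(dm, _random_dm(rng, 3, ["a", "b", "c"]),
                      n_perm=99, seed=0)
    assert res.flagged and math.isnan(res.r)


def test_mantel_exhaustive_matches_brute_force_enumeration():
    """n=4: p from the implementation equals the fraction of all 24 label
    permutations with r >= r_obs, enumerated independently here."""
    rng = np.random.default_rng(8)
    a, b = _random_dm(rng, 4), _random_dm(rng, 4)
    res = mantel_test(a, b, exhaustive=True)
    iu = np.triu_indices(4, k=1)
    x = a.values[iu]
    r_obs = np.corrcoef(x, b.values[iu])[0, 1]
    count = 0
    for perm in itertools.permutations(range(4)):
        yp = b.values[np.ix_(perm, perm)][iu]
        count += np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12
    assert res.p_value == pytest.approx(count / 24)
    assert res.r == pytest.approx(r_obs)


def test_mantel_minimum_p_attained_under_identity():
    """For d_gene = d_genome the sampled p converges to 1/(1+n_perm)."""
    rng = np.random.default_rng(9)
    dm = _random_dm(rng, 10)
    res = mantel_test(dm, dm, n_perm=199, seed=3)
    assert res.p_value == pytest.approx(1 / 200)


def test_report_self_reference_gives_zero_delta(small_clade):
    from genemobility.markers import MarkerReference, screen_marker
    sim = small_clade
    p0 = next(p for p in sim.proteomes["T001"] if p.description == "vertical")
    ref = MarkerReference("vertical", SeqRecord("ref", p0.sequence))
    calls = {a.id: screen_marker(sim.proteomes[a.id], ref)
             for a in sim.assemblies}
    from genemobility.relatedness import distance_matrix
    dm = distance_matrix(sim.assemblies, "hamming")
    strains = [(a.id, sim.proteomes[a.id]) for a in sim.assemblies]
    reports = mobility_report("vertical", "vertical", strains,
                              {"vertical": calls}, dm, n_perm=99, seed=0)
    assert reports[0].delta_r == pytest.approx(0.0)
    assert reports[0].n_pairs == reports[0].n_strains * (
        reports[0].n_strains - 1) // 2


def test_mobility_index_invariant_to_strain_order(small_clade):
    from genemobility.markers import MarkerReference, screen_marker
    from genemobility.relatedness import distance_matrix
    sim = small_clade
    p0 = next(p for p in sim.proteomes["T001"] if p.description == "mobile")
    ref = MarkerReference("mobile", SeqRecord("ref", p0.sequence))
    calls = {a.id: screen_marker(sim.proteomes[a.id], ref)
             for a in sim.assemblies}
    dm = distance_matrix(sim.assemblies, "hamming")
    fwd = [(a.id, sim.proteomes[a.id]) for a in sim.assemblies]
    rev = fwd[::-1]
    r_fwd = mobility_report("mobile", None, fwd, {"mobile": calls}, dm,
                            n_perm=99, seed=0)[0]
    r_rev = mobility_report("mobile", None, rev, {"mobile": calls}, dm,
                            n_perm=99, seed=0)[0]
    assert r_fwd.mobility_index == pytest.approx(r_rev.mobility_index)
    assert r_fwd.pearson_r == pytest.approx(r_rev.pearson_r)


def test_gene_distance_matrix_structure():
    from genemobility.mobility import OrthologPair
    pairs = [OrthologPair(a, b, 95.0, False)
             for a, b in itertools.combinations(["x", "y", "z"], 2)]
    dm = gene_distance_matrix(pairs)
    assert dm.labels == ["x", "y", "z"]
    assert np.allclose(dm.condensed(), 5.0)


def test_mantel_agrees_with_independent_library():
    """Cross-check r and p against skbio's Mantel implementation."""
    import skbio
    rng = np.random.default_rng(12)
    a, b = _random_dm(rng, 9), _random_dm(rng, 9)
    ours = mantel_test(a, b, n_perm=999, seed=4)
    r_skbio, p_skbio, _ = skbio.stats.distance.mantel(
        skbio.DistanceMatrix(a.values, a.labels),
        skbio.DistanceMatrix(b.values, b.labels),
        method="pearson", permutations=999, alternative="greater")
    assert ours.r == pytest.approx(float(r_skbio), abs=1e-9)
    assert ours.p_value == pytest.approx(float(p_skbio), abs=0.06)
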