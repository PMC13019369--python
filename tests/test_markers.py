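"""Marker screening: presence/truncation calls, clusters, RuBisCO forms."""

import numpy as np
import pytest

from genemobility.experiments import marker_accuracy, marker_truth_set
from genemobility.markers import (ABSENT, PRESENT, TRUNCATED, ClusterDef,
                                  MarkerReference, call_cluster,
                                  classify_rubisco_form, screen_marker)
from genemobility.seqio import SeqRecord, extract_proteome
from genemobility.simulator import FocalFamily, SimConfig, simulate_pangenome

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def truth_genome():
    asm, references, truth = marker_truth_set(n_markers=30, seed=5)
    return asm, references, truth, extract_proteome(asm)


def test_planted_marker_called_present(truth_genome):
    asm, references, truth, proteome = truth_genome
    ref = next(r for r in references if truth[r.name] == PRESENT)
    call = screen_marker(proteome, ref)
    assert call.status == PRESENT
    assert call.best_identity == pytest.approx(100.0)
    assert call.best_coverage == pytest.approx(100.0, abs=0.5)
    assert call.evidence


def test_half_deleted_marker_called_truncated(truth_genome):
    asm, references, truth, proteome = truth_genome
    ref = next(r for r in references if truth[r.name] == TRUNCATED)
    call = screen_marker(proteome, ref)
    assert call.status == TRUNCATED
    assert call.best_coverage == pytest.approx(50.0, abs=3.0)


def test_deleted_marker_called_absent(truth_genome):
    asm, references, truth, proteome = truth_genome
    ref = next(r for r in references if truth[r.name] == ABSENT)
    assert screen_marker(proteome, ref).status == ABSENT


def test_internal_stop_triggers_truncated():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list(AA), size=200))
    ref = MarkerReference("m", SeqRecord("m_ref", seq))
    pseudo = SeqRecord("hit", seq[:100] + "*" + seq[101:], pseudo=True)
    call = screen_marker([pseudo], ref)
    assert call.status == TRUNCATED
    assert call.best_coverage > 90  # full-length, only frame-disrupted


def test_truncation_series_status_monotone():
    """Progressively shorter copies move present -> truncated -> absent."""
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list(AA), size=300))
    ref = MarkerReference("m", SeqRecord("m_ref", seq))
    order = {PRESENT: 2, TRUNCATED: 1, ABSENT: 0}
    statuses = []
    for frac in (1.0, 0.8, 0.5, 0.25, 0.1, 0.03):
        copy = SeqRecord("hit", seq[:max(3, int(300 * frac))])
        statuses.append(order[screen_marker([copy], ref).status])
    assert statuses == sorted(statuses, reverse=True)
    assert statuses[0] == 2 and statuses[-1] == 0


def test_calls_deterministic(truth_genome):
    asm, references, truth, proteome = truth_genome
    a = [screen_marker(proteome, r) for r in references]
    b = [screen_marker(proteome, r) for r in references]
    assert [(c.status, c.evidence, c.best_identity) for c in a] \
        == [(c.status, c.evidence, c.best_identity) for c in b]


def test_marker_accuracy_is_perfect_far_from_thresholds():
    res = marker_accuracy(n_markers=30, seed=9)
    assert res["accuracy"] == 1.0


def _sox_cluster(rng, drop=None):
    members = []
    proteome = []
    for name in ("soxY", "soxZ", "soxX", "soxA", "soxB", "soxC", "soxD"):
        seq = "".join(rng.choice(list(AA), size=150))
        members.append(MarkerReference(name, SeqRecord(f"{name}_ref", seq)))
        if name != drop:
            proteome.append(SeqRecord(f"{name}_gene", seq))
    return ClusterDef("sox", members), proteome


def test_full_sox_set_complete():
    cdef, proteome = _sox_cluster(np.random.default_rng(6))
    cc = call_cluster(proteome, cdef)
    assert cc.complete
    assert all(c.status == PRESENT for c in cc.member_calls)


def test_sox_missing_member_incomplete():
    cdef, proteome = _sox_cluster(np.random.default_rng(7), drop="soxC")
    cc = call_cluster(proteome, cdef)
    assert not cc.complete
    assert next(c for c in cc.member_calls if c.marker == "soxC").status == ABSENT


def test_duplicate_cluster_members_rejected():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list(AA), size=100))
    ref = MarkerReference("soxB", SeqRecord("r", seq))
    with pytest.raises(ValueError, match="duplicate"):
        ClusterDef("sox", [ref, ref])


def test_cluster_calls_match_simulator_truth():
    """Per-tip loss/truncation truth maps onto screen statuses exactly."""
    sim = simulate_pangenome(SimConfig(
        n_taxa=10, n_core_genes=20, seed=74,
        focal_families=[FocalFamily("prk", loss_prob=0.15, trunc_prob=0.15)]))
    donor = next(p for a in sim.assemblies
                 for p in sim.proteomes[a.id]
                 if p.description == "prk" and not p.pseudo
                 and sim.tip_family_status[(a.id, "prk")] in ("vertical", "hgt"))
    ref = MarkerReference("prk", SeqRecord("prk_ref", donor.sequence))
    expected = {"vertical": PRESENT, "hgt": PRESENT,
                "loss": ABSENT, "truncation": TRUNCATED}
    statuses = {s for s in
                (sim.tip_family_status[(a.id, "prk")] for a in sim.assemblies)}
    assert len(statuses) > 1  # the seed exercises more than one outcome
    for a in sim.assemblies:
        call = screen_marker(sim.proteomes[a.id], ref)
        assert call.status == expected[
            sim.tip_family_status[(a.id, "prk")]], a.id


def test_rubisco_form_self_and_shuffled():
    rng = np.random.default_rng(10)
    panel = [(form, SeqRecord(f"{form}_ref",
                              "".join(rng.choice(list(AA), size=470))))
             for form in ("I", "II", "III")]
    assert classify_rubisco_form(panel[0][1], panel) == "I"
    shuffled = list(panel[0][1].sequence)
    rng.shuffle(shuffled)
    assert classify_rubisco_form(SeqRecord("x", "".join(shuffled)),
                                 panel) == "unclassified"


def test_rubisco_form_recovers_diverged_descendant():
    rng = np.random.default_rng(11)
    panel = [(form, SeqRecord(f"{form}_ref",
                              "".join(rng.choice(list(AA), size=470))))
             for form in ("I", "II", "III")]
    desc = list(panel[0][1].sequence)
    for i in rng.choice(len(desc), size=int(0.15 * len(desc)), replace=False):
        desc[i] = AA[int(rng.integers(20))]
    assert classify_rubisco_form(SeqRecord("d", "".join(desc)), panel) == "I"


def test_empty_panel_rejected():
    with pytest.raises(ValueError, match="empty"):
        classify_rubisco_form(SeqRecord("x", "MKV"), [])
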