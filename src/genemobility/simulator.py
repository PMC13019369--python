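"""Pangenome evolution simulator with ground truth.

Emulates a clade of bacterial genomes descending from an ultrametric
pure-birth species tree: a mostly-vertical core of protein-coding genes
evolving under Jukes-Cantor substitution, one or more focal "facultative"
gene families subject to per-branch loss, truncation, and within-clade HGT
replacement, and optional heterozygous duplicated blocks appended as extra
contigs at a chosen divergence. Every event is logged in a truth table, so
downstream estimators (ANI, marker calls, mobility correlation, duplicated
block detection) can be scored against the generating process.

Model notes
-----------
* Substitution is Jukes-Cantor: over a branch of length ``t`` each site
  substitutes with probability ``p(t) = 3/4 (1 - exp(-4 lambda t / 3))`` and
  moves to a uniformly chosen different base. No indels are simulated, so
  every realized identity has an unambiguous column denominator.
* Substitutions creating an in-frame internal stop in an intact coding gene
  are re-drawn (a crude proxy for purifying selection); truncated gene
  remnants evolve unconstrained.
* HGT is homologous replacement: the recipient's copy is replaced by the
  donor lineage's realized sequence at the event time, the donor being drawn
  uniformly among lineages alive at that time that carry the family. HGT
  into a lineage that lost the family models reacquisition; optionally the
  old copy persists as a truncated remnant (``remnant_prob``).
* All randomness flows from a single seed through named child streams, so
  identical configs give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import (GeneAnnotation, GenomeAssembly, SeqRecord, extract_proteome,
                    write_fasta, write_gff3)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = _BASES
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
# stop codons TAA, TAG, TGA with A=0,C=1,G=2,T=3
_STOPS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}
_STOP_ARR = np.array(sorted(_STOPS), dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return bytes(_DECODE[arr]).decode()


def _encode(s: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


# ---------------------------------------------------------------------------
# configuration

@dataclass
class FocalFamily:
    """A facultative gene family with its per-branch event rates."""

    name: str
    hgt_rate: float = 0.0      # Poisson mean, events/branch
    loss_prob: float = 0.0     # Bernoulli, /branch
    trunc_prob: float = 0.0    # Bernoulli, /branch
    remnant_prob: float = 0.0  # truncated remnant retained on loss
    length: int = 1434         # bp, multiple of 3

    def __post_init__(self) -> None:
        if min(self.hgt_rate, self.loss_prob, self.trunc_prob,
               self.remnant_prob) < 0:
            raise ValueError("rates must be >= 0")
        if self.length % 3:
            raise ValueError("focal gene length must be a multiple of 3")


@dataclass
class HetInjection:
    tip: str
    block_len_genes: int
    divergence: float  # percent


@dataclass
class SimConfig:
    n_taxa: int = 12
    birth_rate: float = 1.0
    n_core_genes: int = 300
    gene_length_range: tuple[int, int] = (600, 1500)  # bp, multiples of 3
    gc_target: float = 65.0
    subst_rate: float = 0.02   # substitutions/site/unit time
    spacer_length: int = 20
    focal_families: list[FocalFamily] = field(default_factory=list)
    het_injections: list[HetInjection] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.birth_rate <= 0 or self.subst_rate < 0:
            raise ValueError("invalid rates")


# ---------------------------------------------------------------------------
# species tree

@dataclass
class _Node:
    name: str
    time: float
    parent: "_Node | None" = None
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


def _sample_tree_nodes(n_taxa: int, birth_rate: float, rng: np.random.Generator
                       ) -> tuple[_Node, list[_Node]]:
    """Yule process run until the n-th birth plus one more waiting time."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    origin = _Node("N000", 0.0)
    edges = [origin]  # parent nodes of currently growing edges
    t = 0.0
    n_internal = 0
    while len(edges) < n_taxa:
        k = len(edges)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        parent = edges.pop(idx)
        n_internal += 1
        inode = _Node(f"N{n_internal:03d}", t, parent=parent)
        parent.children.append(inode)
        edges.insert(idx, inode)
        edges.insert(idx + 1, inode)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    tips = []
    for i, parent in enumerate(edges):
        tip = _Node(f"T{i + 1:03d}", t_end, parent=parent)
        parent.children.append(tip)
        tips.append(tip)
    return origin, tips


def _to_newick(node: _Node) -> str:
    length = node.time - (node.parent.time if node.parent else 0.0)
    if node.is_tip:
        return f"{node.name}:{length:.10f}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}):{length:.10f}"


def sample_tree(n_taxa: int, birth_rate: float, seed: int) -> str:
    """Ultrametric pure-birth tree as a Newick string; tips T001..Tn.

    The waiting time after the n-th birth is included, so no terminal branch
    has zero length. Mean root-to-tip depth is ``H_n / birth_rate`` with
    ``H_n`` the n-th harmonic number (closed form used by the tests).
    """
    rng = np.random.default_rng(seed)
    origin, _tips = _sample_tree_nodes(n_taxa, birth_rate, rng)
    return _to_newick(origin.children[0]) + ";"


def _branches(origin: _Node) -> list[tuple[_Node, _Node]]:
    out = []
    stack = [origin]
    while stack:
        node = stack.pop()
        for child in node.children:
            out.append((node, child))
            stack.append(child)
    return sorted(out, key=lambda b: (b[0].time, b[1].name))


# ---------------------------------------------------------------------------
# sequence machinery

def _random_gene(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=length, p=probs).astype(np.uint8)
    seq[:3] = (0, 3, 2)  # ATG
    seq[-3:] = _STOP_ARR[int(rng.integers(3))]
    codons = seq[:length - 3].reshape(-1, 3)
    for i in range(1, len(codons)):
        while tuple(codons[i]) in _STOPS:
            codons[i] = rng.choice(4, size=3, p=probs)
    return seq


def _random_spacer(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def jc_p(subst_rate: float, t: float) -> float:
    """Expected proportion of differing sites after time ``t``."""
    return 0.75 * (1.0 - math.exp(-4.0 * subst_rate * t / 3.0))


def _jc_mutate(seq: np.ndarray, p: float, rng: np.random.Generator,
               coding: bool) -> np.ndarray:
    """One Jukes-Cantor step at site substitution probability ``p``."""
    out = seq.copy()
    if p <= 0 or seq.size == 0:
        return out
    mask = rng.random(seq.size) < p
    if not mask.any():
        return out
    shifts = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
    out[mask] = (out[mask] + shifts) % 4
    if coding:
        _fix_internal_stops(out, seq, mask, rng)
    return out


def _fix_internal_stops(out: np.ndarray, parent: np.ndarray, mask: np.ndarray,
                        rng: np.random.Generator) -> None:
    """Re-draw mutations that created an in-frame internal stop codon."""
    n_codons = out.size // 3
    if n_codons < 2:
        return
    for _ in range(8):
        codons = out[:3 * n_codons].reshape(-1, 3)
        bad = np.where(
            (codons[:-1, 0] == 3)
            & (((codons[:-1, 1] == 0) & ((codons[:-1, 2] == 0) | (codons[:-1, 2] == 2)))
               | ((codons[:-1, 1] == 2) & (codons[:-1, 2] == 0))))[0]
        if bad.size == 0:
            return
        for ci in bad:
            pos = slice(3 * ci, 3 * ci + 3)
            mutated = np.where(mask[pos])[0]
            if mutated.size == 0:  # stop not caused by this step; leave it
                continue
            for off in mutated:
                i = 3 * ci + off
                out[i] = (parent[i] + rng.integers(1, 4)) % 4
    # any stop still standing after the retries reverts to the parent codon
    codons = out[:3 * n_codons].reshape(-1, 3)
    for ci in range(n_codons - 1):
        if tuple(codons[ci]) in _STOPS and mask[3 * ci:3 * ci + 3].any():
            out[3 * ci:3 * ci + 3] = parent[3 * ci:3 * ci + 3]


# ---------------------------------------------------------------------------
# genome representation during simulation

@dataclass
class _Unit:
    kind: str            # gene | spacer
    family: str | None
    seq: np.ndarray
    strand: str = "+"
    truncated: bool = False


def _evolve_units(units: list[_Unit], p: float, rng: np.random.Generator
                  ) -> list[_Unit]:
    return [
        _Unit(u.kind, u.family,
              _jc_mutate(u.seq, p, rng, coding=(u.kind == "gene"
                                                and not u.truncated)),
              u.strand, u.truncated)
        for u in units
    ]


# ---------------------------------------------------------------------------
# truth model

@dataclass
class TruthEvent:
    branch: str   # child-node name of the branch the event occurred on
    family: str
    event: str    # vertical | hgt_from:<donor> | loss | truncation | het_duplication
    time: float
    detail: str = ""


@dataclass
class SimOutput:
    tree: str
    assemblies: list[GenomeAssembly]
    proteomes: dict[str, list[SeqRecord]]
    truth_events: list[TruthEvent]
    tip_family_status: dict[tuple[str, str], str]
    # (tip, family) -> vertical | hgt | loss | truncation
    true_divergence: pd.DataFrame
    config: SimConfig

    def assembly(self, tip: str) -> GenomeAssembly:
        for a in self.assemblies:
            if a.id == tip:
                return a
        raise KeyError(tip)


# ---------------------------------------------------------------------------
# focal-family chronology

@dataclass
class _FocalState:
    seq: np.ndarray | None
    status: str            # present | lost
    time: float
    via_hgt: bool = False
    truncated: bool = False
    remnant: np.ndarray | None = None


def _truncate_seq(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    frac = rng.uniform(0.2, 0.6)
    n = max(1, int(seq.size * frac) // 3) * 3
    return seq[:n].copy()


def _simulate_focal(family: FocalFamily, origin: _Node, tips: list[_Node],
                    root_seq: np.ndarray, subst_rate: float,
                    rng: np.random.Generator
                    ) -> tuple[dict[str, _FocalState], list[TruthEvent]]:
    """Chronological sweep over all branches for one focal family."""
    branches = _branches(origin)
    events: list[tuple[float, int, str, str, object]] = []
    counter = 0
    for parent, child in branches:
        t0, t1 = parent.time, child.time
        for _ in range(int(rng.poisson(family.hgt_rate))):
            events.append((rng.uniform(t0, t1), counter, "hgt", child.name, None))
            counter += 1
        if rng.random() < family.loss_prob:
            events.append((rng.uniform(t0, t1), counter, "loss", child.name, None))
            counter += 1
        if rng.random() < family.trunc_prob:
            events.append((rng.uniform(t0, t1), counter, "trunc", child.name, None))
            counter += 1
    for parent, child in branches:
        events.append((child.time, counter, "node", child.name, child))
        counter += 1
    events.sort(key=lambda e: (e[0], e[1]))

    node_by_name = {child.name: child for _, child in branches}
    node_by_name[origin.name] = origin
    active: dict[str, _FocalState] = {
        origin.children[0].name: _FocalState(root_seq.copy(), "present", 0.0)}
    finals: dict[str, _FocalState] = {}
    log: list[TruthEvent] = []

    def advance(state: _FocalState, to: float) -> None:
        dt = to - state.time
        if dt > 0:
            p = jc_p(subst_rate, dt)
            if state.seq is not None:
                state.seq = _jc_mutate(state.seq, p, rng,
                                       coding=not state.truncated)
            if state.remnant is not None:
                state.remnant = _jc_mutate(state.remnant, p, rng, coding=False)
            state.time = to

    for time, _, kind, branch, payload in events:
        if branch not in active:
            continue  # defensive; every branch is activated at its parent node
        state = active[branch]
        if kind == "node":
            advance(state, time)
            node = payload
            del active[branch]
            if node.is_tip:
                finals[branch] = state
            else:
                for child in node.children:
                    active[child.name] = _FocalState(
                        None if state.seq is None else state.seq.copy(),
                        state.status, time, state.via_hgt, state.truncated,
                        None if state.remnant is None else state.remnant.copy())
        elif kind == "loss":
            if state.status != "present":
                continue
            advance(state, time)
            if rng.random() < family.remnant_prob and state.seq is not None:
                state.remnant = _truncate_seq(state.seq, rng)
            state.seq = None
            state.status = "lost"
            state.truncated = False
            log.append(TruthEvent(branch, family.name, "loss", time))
        elif kind == "trunc":
            if state.status != "present" or state.truncated:
                continue
            advance(state, time)
            state.seq = _truncate_seq(state.seq, rng)
            state.truncated = True
            log.append(TruthEvent(branch, family.name, "truncation", time,
                                  detail=f"kept_bp={state.seq.size}"))
        elif kind == "hgt":
            donors = sorted(
                b for b, s in active.items()
                if b != branch and s.status == "present" and not s.truncated)
            if not donors:
                continue
            donor = donors[int(rng.integers(len(donors)))]
            donor_state = active[donor]
            advance(donor_state, time)
            advance(state, time)
            state.seq = donor_state.seq.copy()
            state.status = "present"
            state.truncated = False
            state.via_hgt = True
            log.append(TruthEvent(branch, family.name, f"hgt_from:{donor}",
                                  time))
    for tip in tips:
        if tip.name not in finals:  # no event ever touched this lineage
            raise RuntimeError(f"lineage {tip.name} never finalized")
    return finals, log


# ---------------------------------------------------------------------------
# main entry points

def simulate_pangenome(config: SimConfig) -> SimOutput:
    """Run the full simulation described by ``config``.

    Deterministic: identical configs (including seed) give bit-identical
    assemblies, annotations, and truth tables.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_root, rng_core, rng_focal, rng_het = (
        np.random.default_rng(s) for s in ss.spawn(5))

    origin, tips = _sample_tree_nodes(config.n_taxa, config.birth_rate, rng_tree)
    newick = _to_newick(origin.children[0]) + ";"
    gc = config.gc_target / 100.0

    lo, hi = config.gene_length_range
    root_units: list[_Unit] = []
    for g in range(config.n_core_genes):
        root_units.append(_Unit("spacer", None,
                                _random_spacer(config.spacer_length, gc, rng_root)))
        length = 3 * int(rng_root.integers(lo // 3, hi // 3 + 1))
        strand = "-" if g % 7 == 3 else "+"
        root_units.append(_Unit("gene", f"core{g:05d}",
                                _random_gene(length, gc, rng_root), strand))

    # vertical core: recursive descent in deterministic branch order
    tip_units: dict[str, list[_Unit]] = {}

    def descend(node: _Node, units: list[_Unit]) -> None:
        for child in sorted(node.children, key=lambda c: c.name):
            p = jc_p(config.subst_rate, child.time - node.time)
            child_units = _evolve_units(units, p, rng_core)
            if child.is_tip:
                tip_units[child.name] = child_units
            else:
                descend(child, child_units)

    descend(origin, root_units)

    # focal families: chronological sweep with HGT/loss/truncation
    truth_events: list[TruthEvent] = []
    tip_family_status: dict[tuple[str, str], str] = {}
    focal_finals: dict[str, dict[str, _FocalState]] = {}
    for family in config.focal_families:
        root_seq = _random_gene(family.length, gc, rng_root)
        finals, log = _simulate_focal(family, origin, tips, root_seq,
                                      config.subst_rate, rng_focal)
        truth_events.extend(log)
        focal_finals[family.name] = finals
        for tip in tips:
            st = finals[tip.name]
            if st.status == "lost":
                status = "loss"
            elif st.truncated:
                status = "truncation"
            else:
                status = "hgt" if st.via_hgt else "vertical"
            tip_family_status[(tip.name, family.name)] = status

    # assemble tip genomes
    assemblies = []
    for tip in tips:
        units = list(tip_units[tip.name])
        for family in config.focal_families:
            st = focal_finals[family.name][tip.name]
            if st.seq is not None:
                units.append(_Unit("spacer", None,
                                   _random_spacer(config.spacer_length, gc,
                                                  rng_het)))
                units.append(_Unit("gene", family.name, st.seq, "+",
                                   truncated=st.truncated))
            if st.remnant is not None:
                units.append(_Unit("spacer", None,
                                   _random_spacer(config.spacer_length, gc,
                                                  rng_het)))
                units.append(_Unit("gene", f"{family.name}_remnant",
                                   st.remnant, "+", truncated=True))
        assemblies.append(_units_to_assembly(tip.name, units))

    # heterozygous block injections
    for inj in config.het_injections:
        idx = next(i for i, a in enumerate(assemblies) if a.id == inj.tip)
        seed = int(rng_het.integers(2 ** 31))
        assemblies[idx], record = inject_heterozygous_block(
            assemblies[idx], inj.block_len_genes, inj.divergence, seed)
        truth_events.append(TruthEvent(
            inj.tip, "het_block", "het_duplication", math.nan,
            detail=json.dumps(record)))

    proteomes = {a.id: extract_proteome(a) for a in assemblies}
    return SimOutput(
        tree=newick,
        assemblies=assemblies,
        proteomes=proteomes,
        truth_events=truth_events,
        tip_family_status=tip_family_status,
        true_divergence=_divergence_table(tips, config.subst_rate),
        config=config,
    )


def _units_to_assembly(tip: str, units: list[_Unit]) -> GenomeAssembly:
    parts = []
    annotations = []
    offset = 0
    n_genes = 0
    for u in units:
        if u.kind == "gene":
            n_genes += 1
            tag = f"{tip}_{n_genes:05d}"
            seq = u.seq if u.strand == "+" else _revcomp(u.seq)
            annotations.append(GeneAnnotation(
                contig_id=f"{tip}_chr", start=offset, end=offset + u.seq.size,
                strand=u.strand, locus_tag=tag, product=u.family or ""))
            parts.append(seq)
        else:
            parts.append(u.seq)
        offset += u.seq.size
    contig = SeqRecord(id=f"{tip}_chr", sequence=_decode(np.concatenate(parts)))
    asm = GenomeAssembly(id=tip, contigs=[contig], annotations=annotations)
    asm.validate()
    return asm


def _revcomp(seq: np.ndarray) -> np.ndarray:
    return (3 - seq)[::-1]


def _divergence_table(tips: list[_Node], subst_rate: float) -> pd.DataFrame:
    def ancestors(node: _Node) -> list[_Node]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    rows = []
    for i, a in enumerate(tips):
        anc_a = ancestors(a)
        set_a = {id(x): x for x in anc_a}
        for b in tips[i + 1:]:
            node = b
            while id(node) not in set_a:
                node = node.parent
            d = (a.time - node.time) + (b.time - node.time)
            rows.append({"tip_a": a.name, "tip_b": b.name,
                         "tree_distance": d,
                         "expected_p": jc_p(subst_rate, d)})
    return pd.DataFrame(rows)


def mutate_assembly(assembly: GenomeAssembly, p: float, seed: int
                    ) -> GenomeAssembly:
    """Per-site substitution at exact probability ``p`` (calibration partner).

    Raw Bernoulli substitution without coding constraints: the realized
    divergence is exactly binomial around ``p``, which is what the ANI
    estimator-recovery checks need as ground truth.
    """
    rng = np.random.default_rng(seed)
    contigs = []
    for c in assembly.contigs:
        arr = _encode(c.sequence)
        contigs.append(SeqRecord(id=c.id,
                                 sequence=_decode(_jc_mutate(arr, p, rng,
                                                             coding=False))))
    return GenomeAssembly(id=f"{assembly.id}_mut", contigs=contigs,
                          annotations=list(assembly.annotations))


def inject_heterozygous_block(assembly: GenomeAssembly, block_len_genes: int,
                              divergence: float, seed: int,
                              start_gene: int | None = None
                              ) -> tuple[GenomeAssembly, dict]:
    """Append a diverged copy of a contiguous gene block as a new contig.

    The copy spans from the start of the block's first gene to the end of its
    last gene (intergenic sequence included) and is mutated per site at
    ``divergence``% (in-frame stops introduced inside genes are re-drawn).
    Annotations are duplicated with new locus tags; the returned truth record
    holds both copies' coordinates.
    """
    rng = np.random.default_rng(seed)
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for ann in assembly.annotations:
        by_contig.setdefault(ann.contig_id, []).append(ann)
    for anns in by_contig.values():
        anns.sort(key=lambda a: a.start)
    contig_id = max(by_contig, key=lambda c: len(by_contig[c]))
    anns = by_contig[contig_id]
    if len(anns) < block_len_genes:
        raise ValueError(
            f"contig {contig_id} has {len(anns)} genes < {block_len_genes}")
    if start_gene is None:
        start_gene = int(rng.integers(len(anns) - block_len_genes + 1))
    block = anns[start_gene:start_gene + block_len_genes]
    src = assembly.contig(contig_id)
    region_start, region_end = block[0].start, block[-1].end

    arr = _encode(src.sequence[region_start:region_end])
    p = divergence / 100.0
    mask = rng.random(arr.size) < p
    out = arr.copy()
    if mask.any():
        shifts = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
        out[mask] = (out[mask] + shifts) % 4
    # re-draw stop-creating substitutions gene by gene, strand aware
    for ann in block:
        s, e = ann.start - region_start, ann.end - region_start
        gene = out[s:e] if ann.strand == "+" else _revcomp(out[s:e])
        parent = arr[s:e] if ann.strand == "+" else _revcomp(arr[s:e])
        gmask = mask[s:e] if ann.strand == "+" else mask[s:e][::-1]
        _fix_internal_stops(gene, parent, gmask, rng)
        out[s:e] = gene if ann.strand == "+" else _revcomp(gene)

    het_contig_id = f"{assembly.id}_het"
    new_contig = SeqRecord(id=het_contig_id, sequence=_decode(out))
    new_anns = []
    for k, ann in enumerate(block):
        new_anns.append(GeneAnnotation(
            contig_id=het_contig_id,
            start=ann.start - region_start,
            end=ann.end - region_start,
            strand=ann.strand,
            locus_tag=f"{assembly.id}_HET{k + 1:05d}",
            product=ann.product,
        ))
    modified = GenomeAssembly(
        id=assembly.id,
        contigs=list(assembly.contigs) + [new_contig],
        annotations=list(assembly.annotations) + new_anns,
    )
    modified.validate()
    record = {
        "tip": assembly.id,
        "source_contig": contig_id,
        "source_start": int(region_start),
        "source_end": int(region_end),
        "source_locus_tags": [a.locus_tag for a in block],
        "copy_contig": het_contig_id,
        "copy_start": 0,
        "copy_end": int(region_end - region_start),
        "copy_locus_tags": [a.locus_tag for a in new_anns],
        "block_len_genes": block_len_genes,
        "divergence": divergence,
    }
    return modified, record


# ---------------------------------------------------------------------------
# output directory

def write_sim_output(sim: SimOutput, outdir) -> None:
    """Write per-tip FASTA/GFF3/protein FASTA plus tree and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(sim.tree + "\n")
    for asm in sim.assemblies:
        write_fasta(asm.contigs, outdir / f"{asm.id}.fna")
        write_gff3(asm, outdir / f"{asm.id}.gff3")
        write_fasta(sim.proteomes[asm.id], outdir / f"{asm.id}.faa")
    with open(outdir / "truth_events.tsv", "w") as fh:
        fh.write("branch\tfamily\tevent\ttime\tdetail\n")
        for e in sim.truth_events:
            fh.write(f"{e.branch}\t{e.family}\t{e.event}\t{e.time:.6f}\t"
                     f"{e.detail}\n")
    with open(outdir / "truth_status.tsv", "w") as fh:
        fh.write("tip\tfamily\tstatus\n")
        for (tip, fam), status in sorted(sim.tip_family_status.items()):
            fh.write(f"{tip}\t{fam}\t{status}\n")
    sim.true_divergence.to_csv(outdir / "truth_divergence.tsv", sep="\t",
                               index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(sim.config), fh, indent=2, default=list)
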