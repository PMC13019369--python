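"""Detection of within-assembly duplicated syntenic blocks at intermediate
nucleotide identity — the signature of sustained heterozygous diploidy
(merodiploidy): two homologous copies of a long gene run (tens of genes) at
~90% identity, too diverged for a recent tandem duplication or an assembly
artifact, too similar for an ancient paralogy.

The scan works at the gene level rather than by raw nucleotide
self-alignment: proteins are clustered into families (greedy single-linkage
on pairwise identity), and the detector chains family-level anchor pairs
whose order is conserved (or reversed) between two gene runs, allowing a few
unmatched genes per run. Gene-level synteny is robust to fragmented draft
assemblies where a long duplicated region is split across contigs. Reported
block identity is *nucleotide* identity averaged over the aligned gene
pairs, and the report says so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .pairalign import edit_identity
from .seqio import GeneAnnotation, GenomeAssembly, SeqRecord


@dataclass
class GeneFamilyMap:
    family_of: dict[str, str]  # locus_tag -> family id
    threshold: float

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tag, fam in self.family_of.items():
            out.setdefault(fam, []).append(tag)
        return out


@dataclass
class Region:
    contig_id: str
    start: int  # 0-based half-open, nucleotide coordinates
    end: int
    locus_tags: list[str]


@dataclass
class DuplicatedBlock:
    region_a: Region
    region_b: Region
    n_shared_families: int
    mean_nt_identity: float
    orientation: str  # collinear | inverted
    edge_conflict: bool


@dataclass
class BlockParams:
    min_genes: int = 40
    identity_floor: float = 80.0
    identity_ceiling: float = 98.0
    max_gap_genes: int = 3


def build_families(proteome: list[SeqRecord], threshold: float = 50.0,
                   min_coverage: float = 70.0) -> GeneFamilyMap:
    """Greedy single-linkage clustering of proteins into gene families.

    Two proteins join one family when their global identity is at least
    ``threshold`` with mutual coverage of at least ``min_coverage``. Inputs
    are sorted by locus_tag first, so the clustering (and the family ids,
    named after each family's first member) is independent of input order.

    The default threshold of 50% protein identity is deliberately permissive:
    duplicated-block copies near the 80% *nucleotide* identity floor translate
    to roughly 55% protein identity, and unrelated proteins sit far below 30%,
    so 50% separates homologous copies from noise with margin on both sides.
    """
    if not proteome:
        raise ValueError("empty proteome")
    prots = sorted(proteome, key=lambda p: p.id)
    n = len(prots)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ratio = min_coverage / 100.0 * 0.9  # slack below the exact coverage bound
    # shared-4-mer prefilter: proteins >=50% identical share many intact
    # 4-mers while unrelated pairs share <1 by chance
    kmers = []
    for p in prots:
        s = p.sequence
        kmers.append({s[k:k + 4] for k in range(len(s) - 3)})
    for i in range(n):
        li = len(prots[i].sequence)
        for j in range(i + 1, n):
            lj = len(prots[j].sequence)
            if min(li, lj) / max(li, lj) < ratio:
                continue
            if len(kmers[i] & kmers[j]) < max(3, (min(li, lj) * 3) // 50):
                continue
            res = edit_identity(prots[i].sequence, prots[j].sequence)
            if (res.identity_percent >= threshold
                    and min(res.coverage_a, res.coverage_b) >= min_coverage):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    family_of = {}
    fam_name: dict[int, str] = {}
    for i, p in enumerate(prots):
        root = find(i)
        if root not in fam_name:
            fam_name[root] = f"F{len(fam_name):05d}"
        family_of[p.id] = fam_name[root]
    return GeneFamilyMap(family_of=family_of, threshold=threshold)


def _gene_seq(assembly: GenomeAssembly, ann: GeneAnnotation,
              seqs: dict[str, str]) -> str:
    s = seqs[ann.contig_id][ann.start:ann.end]
    return str(Seq(s).reverse_complement()) if ann.strand == "-" else s


def _chain(anchors: list[tuple[int, int]], max_gap: int, inverted: bool
           ) -> list[list[tuple[int, int]]]:
    """Greedy chaining of (i, j) anchors into (anti)diagonal runs."""
    step = max_gap + 1
    order = sorted(anchors, key=(lambda a: (a[0], -a[1])) if inverted
                   else (lambda a: (a[0], a[1])))
    chains: list[list[tuple[int, int]]] = []
    for i, j in order:
        attached = False
        for chain in chains:
            pi, pj = chain[-1]
            dj = (pj - j) if inverted else (j - pj)
            if 0 < i - pi <= step and 0 < dj <= step:
                chain.append((i, j))
                attached = True
                break
        if not attached:
            chains.append([(i, j)])
    return chains


def detect_duplicated_blocks(assembly: GenomeAssembly, families: GeneFamilyMap,
                             params: BlockParams | None = None
                             ) -> list[DuplicatedBlock]:
    """Scan an annotated assembly for duplicated syntenic gene blocks.

    Two gene runs (same contig or different contigs) qualify as a block when
    at least ``min_genes`` family-level anchors chain in conserved (or
    reversed) order with at most ``max_gap_genes`` unmatched genes between
    consecutive anchors in each run, and the mean nucleotide identity over
    the anchored gene pairs lies in ``[identity_floor, identity_ceiling]``.
    The ceiling excludes recent tandem repeats and collapsed assembly
    duplicates; the floor excludes ancient paralogy. ``edge_conflict`` marks
    blocks whose both copies abut contig ends — the "competitors for the
    docking sites" configuration seen when neither copy can be circularized
    into the chromosome. An empty list is a valid result.
    """
    params = params or BlockParams()
    seqs = {c.id: c.sequence for c in assembly.contigs}
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for ann in assembly.annotations:
        by_contig.setdefault(ann.contig_id, []).append(ann)
    for anns in by_contig.values():
        anns.sort(key=lambda a: a.start)
    contig_ids = sorted(by_contig)
    fam_counts: dict[str, int] = {}
    for fam in families.family_of.values():
        fam_counts[fam] = fam_counts.get(fam, 0) + 1

    blocks: list[DuplicatedBlock] = []
    for ci in range(len(contig_ids)):
        for cj in range(ci, len(contig_ids)):
            a_anns, b_anns = by_contig[contig_ids[ci]], by_contig[contig_ids[cj]]
            same = ci == cj
            anchors = []
            b_pos: dict[str, list[int]] = {}
            for j, ann in enumerate(b_anns):
                fam = families.family_of.get(ann.locus_tag)
                if fam and fam_counts.get(fam, 0) >= 2:
                    b_pos.setdefault(fam, []).append(j)
            for i, ann in enumerate(a_anns):
                fam = families.family_of.get(ann.locus_tag)
                for j in b_pos.get(fam, ()):
                    if same and j <= i:
                        continue
                    anchors.append((i, j))
            if not anchors:
                continue
            for inverted in (False, True):
                for chain in _chain(anchors, params.max_gap_genes, inverted):
                    block = _chain_to_block(
                        chain, a_anns, b_anns, same, inverted,
                        assembly, families, seqs, params)
                    if block is not None:
                        blocks.append(block)
    return _drop_dominated(blocks)


def _chain_to_block(chain, a_anns, b_anns, same, inverted, assembly,
                    families, seqs, params: BlockParams
                    ) -> DuplicatedBlock | None:
    if len(chain) < params.min_genes:
        return None
    i_idx = [i for i, _ in chain]
    j_idx = [j for _, j in chain]
    if same and max(i_idx) >= min(j_idx):  # overlapping runs on one contig
        return None
    fams = {families.family_of[a_anns[i].locus_tag] for i in i_idx}
    if len(fams) < params.min_genes:
        return None
    idents = []
    for i, j in chain:
        ga = _gene_seq(assembly, a_anns[i], seqs)
        gb = _gene_seq(assembly, b_anns[j], seqs)
        idents.append(edit_identity(ga, gb, nucleotide=True).identity_percent)
    mean_ident = float(np.mean(idents))
    if not (params.identity_floor <= mean_ident <= params.identity_ceiling):
        return None
    region_a = _make_region(a_anns, i_idx)
    region_b = _make_region(b_anns, j_idx)
    edge_conflict = (
        _touches_end(i_idx, a_anns) and _touches_end(j_idx, b_anns))
    return DuplicatedBlock(
        region_a=region_a, region_b=region_b,
        n_shared_families=len(fams),
        mean_nt_identity=mean_ident,
        orientation="inverted" if inverted else "collinear",
        edge_conflict=edge_conflict,
    )


def _make_region(anns, idx) -> Region:
    lo, hi = min(idx), max(idx)
    run = anns[lo:hi + 1]
    return Region(
        contig_id=run[0].contig_id,
        start=run[0].start,
        end=run[-1].end,
        locus_tags=[a.locus_tag for a in run],
    )


def _touches_end(idx, anns) -> bool:
    return min(idx) == 0 or max(idx) == len(anns) - 1


def _drop_dominated(blocks: list[DuplicatedBlock]) -> list[DuplicatedBlock]:
    """Remove blocks whose anchor gene set is contained in a larger block."""
    keep = []
    sets = [set(b.region_a.locus_tags) | set(b.region_b.locus_tags)
            for b in blocks]
    for i, b in enumerate(blocks):
        dominated = any(
            j != i and sets[i] <= sets[j]
            and (len(sets[i]) < len(sets[j]) or j < i)
            for j in range(len(blocks)))
        if not dominated:
            keep.append(b)
    return keep


def blocks_to_tsv(blocks: list[DuplicatedBlock], path) -> None:
    """TSV block report; coordinates 1-based inclusive on output."""
    cols = ["contig_a", "start_a", "end_a", "contig_b", "start_b", "end_b",
            "n_shared_families", "mean_nt_identity", "orientation",
            "edge_conflict"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for b in blocks:
            fh.write("\t".join(map(str, [
                b.region_a.contig_id, b.region_a.start + 1, b.region_a.end,
                b.region_b.contig_id, b.region_b.start + 1, b.region_b.end,
                b.n_shared_families, f"{b.mean_nt_identity:.2f}",
                b.orientation, b.edge_conflict,
            ])) + "\n")
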