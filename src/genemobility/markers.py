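"""Marker-gene screening: present / truncated / absent calls, cluster
completeness, and RuBisCO form assignment.

A marker reference (a protein) is screened against a genome's proteome (or,
when annotations are missing, against stop-free segments of the six-frame
translation). The best hit is chosen by the identity x reference-coverage
product; status follows configurable thresholds:

* ``present``    — identity >= min_identity and coverage >= min_coverage_present
* ``truncated``  — identity >= min_identity and either
                   min_coverage_truncated <= coverage < min_coverage_present,
                   or the hit protein carries an internal-stop (pseudo) flag
* ``absent``     — otherwise

Coverage is always the percentage of the *reference* length spanned by the
alignment, so a gene remnant keeping only its 5' half screens at ~50%
coverage and is called truncated. The defaults (40% identity, 70/20%
coverage bounds) are conventional homology-screening values and are
configurable per marker.

Cluster completeness is a boolean over member calls: the CBB key-determinant
rule requires form I RuBisCO (cbbL) and phosphoribulokinase (prk) both
present; the sox thiosulfate-oxidation rule requires all of
soxY, soxZ, soxX, soxA, soxB, soxC, soxD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import yaml
from Bio.Seq import Seq

from .pairalign import global_protein_identity
from .seqio import GenomeAssembly, SeqRecord, read_fasta

PRESENT = "present"
TRUNCATED = "truncated"
ABSENT = "absent"

#: members whose joint presence defines completeness for the built-in rules
CBB_KEY_RULE = ("cbbL_formI", "prk")
SOX_RULE = ("soxY", "soxZ", "soxX", "soxA", "soxB", "soxC", "soxD")


@dataclass
class MarkerReference:
    name: str
    sequence: SeqRecord
    min_identity: float = 40.0
    min_coverage_present: float = 70.0
    min_coverage_truncated: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage_truncated < self.min_coverage_present <= 100):
            raise ValueError(
                "require 0 < min_coverage_truncated < min_coverage_present <= 100")


@dataclass
class MarkerCall:
    marker: str
    status: str
    best_identity: float
    best_coverage: float
    evidence: str  # locus_tag, or contig:start-end(strand) for six-frame hits
    all_evidence: list[tuple[str, float]] = field(default_factory=list)
    # (locus_tag, identity) for every hit passing the present thresholds;
    # >1 entry flags a multi-copy marker


@dataclass
class ClusterDef:
    name: str
    members: list[MarkerReference]
    required: tuple[str, ...] | None = None  # None -> all members required

    def __post_init__(self) -> None:
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate marker names in cluster {self.name}")
        if self.required is not None:
            unknown = set(self.required) - set(names)
            if unknown:
                raise ValueError(f"required markers {unknown} not in cluster")


@dataclass
class ClusterCall:
    cluster: str
    complete: bool
    member_calls: list[MarkerCall]


def _screen_candidates(ref: MarkerReference, proteins: list[SeqRecord],
                       top_k: int = 10) -> list[SeqRecord]:
    """Cheap edit-distance prefilter; keeps every plausibly homologous hit.

    The shorter sequence is placed within the longer (infix mode) so that
    truncated copies are never screened out by a length penalty.
    """
    if len(proteins) <= 50:
        return proteins
    scored = []
    rseq = ref.sequence.sequence
    for p in proteins:
        short, long_ = (p.sequence, rseq) if len(p.sequence) <= len(rseq) \
            else (rseq, p.sequence)
        d = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
        scored.append((1.0 - d / max(1, len(short)), p))
    scored.sort(key=lambda t: -t[0])
    keep = [p for s, p in scored[:top_k]]
    keep += [p for s, p in scored[top_k:] if s >= 0.5]
    return keep


def screen_marker(proteome: list[SeqRecord], ref: MarkerReference,
                  assembly: GenomeAssembly | None = None) -> MarkerCall:
    """Call one marker in one genome.

    Uses the supplied proteome; falls back to a six-frame translated search
    over ``assembly`` contigs when the proteome is empty. Ties on the
    identity x coverage product break toward higher coverage, then
    lexicographic locus_tag, so calls are deterministic.
    """
    candidates = proteome
    if not candidates:
        if assembly is None:
            raise ValueError("no proteome and no assembly for six-frame search")
        candidates = six_frame_segments(assembly)
    best = None
    passing: list[tuple[str, float]] = []
    for prot in sorted(_screen_candidates(ref, candidates), key=lambda p: p.id):
        res = global_protein_identity(ref.sequence, prot)
        identity, coverage = res.identity_percent, res.coverage_a
        if identity >= ref.min_identity and coverage >= ref.min_coverage_present \
                and not prot.pseudo:
            passing.append((prot.id, identity))
        key = (identity * coverage, coverage, _neg_lex(prot.id))
        if best is None or key > best[0]:
            best = (key, identity, coverage, prot)
    if best is None:
        return MarkerCall(ref.name, ABSENT, 0.0, 0.0, "")
    _, identity, coverage, prot = best
    if identity < ref.min_identity or coverage < ref.min_coverage_truncated:
        status = ABSENT
    elif coverage >= ref.min_coverage_present and not prot.pseudo:
        status = PRESENT
    else:
        status = TRUNCATED
    if status == ABSENT:
        return MarkerCall(ref.name, ABSENT, identity, coverage, "")
    return MarkerCall(ref.name, status, identity, coverage, prot.id,
                      all_evidence=passing)


class _neg_lex(str):
    """Orders lexicographically smaller strings as larger keys (tie-break)."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def six_frame_segments(assembly: GenomeAssembly, min_aa: int = 30
                       ) -> list[SeqRecord]:
    """Stop-free amino-acid segments from all six reading frames."""
    segments = []
    for contig in assembly.contigs:
        seq = contig.sequence
        for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
            for frame in range(3):
                sub = s[frame:frame + 3 * ((len(s) - frame) // 3)]
                if not sub:
                    continue
                aa = str(Seq(sub).translate(table=11))
                pos = 0
                for seg in aa.split("*"):
                    if len(seg) >= min_aa:
                        segments.append(SeqRecord(
                            id=f"{contig.id}:frame{strand}{frame}:aa{pos}",
                            sequence=seg))
                    pos += len(seg) + 1
    return segments


def call_cluster(proteome: list[SeqRecord], cluster_def: ClusterDef,
                 assembly: GenomeAssembly | None = None) -> ClusterCall:
    """Screen every cluster member and apply the completeness rule."""
    calls = [screen_marker(proteome, m, assembly) for m in cluster_def.members]
    required = cluster_def.required or tuple(m.name for m in cluster_def.members)
    by_name = {c.marker: c for c in calls}
    complete = all(by_name[r].status == PRESENT for r in required)
    return ClusterCall(cluster_def.name, complete, calls)


def classify_rubisco_form(protein: SeqRecord,
                          panel: list[tuple[str, SeqRecord]],
                          min_identity: float = 35.0) -> str:
    """Label a RuBisCO large-subunit protein by its nearest panel reference.

    ``panel`` holds (form_label, reference) entries covering forms I/II/III.
    Returns the nearest label by semi-global identity when that identity is
    at least ``min_identity``; ``"unclassified"`` otherwise.
    """
    if not panel:
        raise ValueError("empty reference panel")
    best_label, best_identity = "unclassified", -1.0
    for label, ref in panel:
        ident = global_protein_identity(protein, ref).identity_percent
        if ident > best_identity:
            best_label, best_identity = label, ident
    return best_label if best_identity >= min_identity else "unclassified"


def load_marker_panel(fasta_path, config_path=None
                      ) -> tuple[dict[str, MarkerReference], list[ClusterDef]]:
    """Load a marker panel (protein FASTA) plus optional cluster YAML/JSON.

    The config maps marker names to threshold overrides and defines clusters:
    ``clusters: [{name, members: [...], required: [...]}]``.
    """
    refs = {r.id: MarkerReference(name=r.id, sequence=r)
            for r in read_fasta(fasta_path)}
    clusters: list[ClusterDef] = []
    if config_path is not None:
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        for name, overrides in (cfg.get("markers") or {}).items():
            if name not in refs:
                raise ValueError(f"config marker {name!r} not in panel FASTA")
            for k, v in overrides.items():
                setattr(refs[name], k, v)
        for c in cfg.get("clusters") or []:
            members = [refs[m] for m in c["members"]]
            clusters.append(ClusterDef(
                name=c["name"], members=members,
                required=tuple(c["required"]) if "required" in c else None))
    return refs, clusters


def calls_to_tsv(genome_calls: dict[str, list[MarkerCall]], path) -> None:
    """Write calls as TSV: genome, marker, status, identity, coverage, evidence."""
    with open(path, "w") as fh:
        fh.write("genome\tmarker\tstatus\tidentity\tcoverage\tevidence\tmulti_copy\n")
        for genome in sorted(genome_calls):
            for c in genome_calls[genome]:
                fh.write("\t".join([
                    genome, c.marker, c.status, f"{c.best_identity:.2f}",
                    f"{c.best_coverage:.2f}", c.evidence,
                    "yes" if len(c.all_evidence) > 1 else "no",
                ]) + "\n")
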