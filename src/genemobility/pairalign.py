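"""Pairwise alignment kernels and the identity conventions used downstream.

Identity convention (stated here once, reported with every result):
``identity_percent = 100 * n_matches / n_aligned_columns`` where
``n_aligned_columns`` counts every column between the first and the last
aligned residue pair — matches, mismatches, and internal gap columns — and
excludes terminal overhangs. Coverage of a sequence is the percentage of its
residues lying inside that aligned span. Ambiguous nucleotides (``N``) never
count as matches.

Two engines back this module: a scored semi-global aligner (BLOSUM62-style
matrices, affine gaps; Biopython's ``PairwiseAligner``) for protein identity,
and a bit-parallel edit-distance DP (edlib) for nucleotide infix search and
fast unscored screening. The infix search is exact, not seeded-heuristic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import SeqRecord

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ProteinAlignParams:
    """Scoring for global protein identity: BLOSUM62, gap open 11, extend 1."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass
class NtAlignParams:
    """Nucleotide local search: match +2, mismatch -3, gap open 5, extend 2.

    ``min_score`` is the acceptance threshold on the rescored best alignment;
    the search itself is an exact infix edit-distance DP.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: int = 60


@dataclass
class IdentityResult:
    identity_percent: float
    n_matches: int
    n_aligned_columns: int
    coverage_a: float
    coverage_b: float


@dataclass
class LocalHit:
    query_id: str
    subject_id: str
    identity_percent: float
    query_coverage: float
    subject_start: int  # 0-based half-open on the forward subject strand
    subject_end: int
    strand: str
    score: int
    n_matches: int
    n_aligned_columns: int


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    # end gaps free (semi-global); must be set after the interior gap scores,
    # whose setters reset the end-gap scores as well
    aligner.end_gap_score = 0
    return aligner


def _sanitize_protein(seq: str, alphabet) -> str:
    allowed = set(str(alphabet))
    return "".join(c if c in allowed else "X" for c in seq.upper())


def global_protein_identity(a: SeqRecord, b: SeqRecord,
                            params: ProteinAlignParams | None = None
                            ) -> IdentityResult:
    """Semi-global protein identity between two sequences.

    End gaps are free, so terminal overhangs of the longer sequence are
    excluded from the identity denominator; internal gaps are included.
    Deterministic for fixed params (the aligner's first optimal path is used;
    identity is computed from its column structure).
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequence")
    params = params or ProteinAlignParams()
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend)
    sa = _sanitize_protein(a.sequence, aligner.substitution_matrix.alphabet)
    sb = _sanitize_protein(b.sequence, aligner.substitution_matrix.alphabet)
    aln = aligner.align(sa, sb)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return IdentityResult(0.0, 0, 0, 0.0, 0.0)
    n_matches = 0
    n_pair_cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        n_pair_cols += ae - as_
        n_matches += sum(x == y for x, y in zip(sa[as_:ae], sb[bs:be]))
    gap_cols = 0
    for i in range(1, len(blocks_a)):
        gap_cols += (blocks_a[i][0] - blocks_a[i - 1][1])
        gap_cols += (blocks_b[i][0] - blocks_b[i - 1][1])
    n_cols = n_pair_cols + gap_cols
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    return IdentityResult(
        identity_percent=100.0 * n_matches / n_cols,
        n_matches=n_matches,
        n_aligned_columns=n_cols,
        coverage_a=100.0 * span_a / len(sa),
        coverage_b=100.0 * span_b / len(sb),
    )


def _cigar_counts(cigar: str, qa: str, sa: str,
                  exclude_n: bool = False) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_opens, gap_bases) from an extended cigar.

    With ``exclude_n`` (nucleotide mode) matches are recounted from the
    sequences so that an ambiguous ``N`` never counts as a match; protein
    callers leave it off (N is asparagine there).
    ``qa``/``sa`` are the aligned query slice and subject slice.
    """
    matches = mismatches = gap_opens = gap_bases = 0
    qi = si = 0
    check_n = exclude_n and ("N" in qa or "N" in sa)
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in "=XM":
            if op == "=" and not check_n:
                matches += n
            elif op == "X" and not check_n:
                mismatches += n
            else:
                for k in range(n):
                    qc, sc = qa[qi + k], sa[si + k]
                    if qc == sc and qc != "N":
                        matches += 1
                    else:
                        mismatches += 1
            qi += n
            si += n
        elif op == "I":  # bases in query only
            gap_opens += 1
            gap_bases += n
            qi += n
        elif op == "D":  # bases in subject only
            gap_opens += 1
            gap_bases += n
            si += n
    return matches, mismatches, gap_opens, gap_bases


def local_nt_align(query: SeqRecord, subject: SeqRecord,
                   params: NtAlignParams | None = None) -> LocalHit | None:
    """Best placement of ``query`` anywhere within ``subject``, both strands.

    The whole query is aligned (infix mode: subject ends are free), the best
    strand is chosen by edit distance, and the alignment is rescored with the
    match/mismatch/gap scheme in ``params``. Returns ``None`` when the best
    score falls below ``params.min_score`` — absence of a hit is a valid
    result, not an error.
    """
    params = params or NtAlignParams()
    q_fwd = query.sequence.upper()
    s_seq = subject.sequence.upper()
    if not q_fwd or not s_seq:
        return None
    q_rev = str(Seq(q_fwd).reverse_complement())
    best = None
    for strand, q in (("+", q_fwd), ("-", q_rev)):
        res = edlib.align(q, s_seq, mode="HW", task="distance")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], strand, q)
    if best is None:
        return None
    _, strand, q = best
    res = edlib.align(q, s_seq, mode="HW", task="path")
    loc_start, loc_end = res["locations"][0]
    sub_start, sub_end = loc_start, loc_end + 1
    matches, mismatches, gap_opens, gap_bases = _cigar_counts(
        res["cigar"], q, s_seq[sub_start:sub_end], exclude_n=True)
    score = (params.match * matches + params.mismatch * mismatches
             - gap_opens * params.gap_open
             - max(0, gap_bases - gap_opens) * params.gap_extend)
    if score < params.min_score:
        return None
    n_cols = matches + mismatches + gap_bases
    return LocalHit(
        query_id=query.id,
        subject_id=subject.id,
        identity_percent=100.0 * matches / n_cols if n_cols else 0.0,
        query_coverage=100.0,  # infix mode consumes the entire query
        subject_start=sub_start,
        subject_end=sub_end,
        strand=strand,
        score=score,
        n_matches=matches,
        n_aligned_columns=n_cols,
    )


def edit_identity(a: str, b: str, nucleotide: bool = False) -> IdentityResult:
    """Global (NW) identity from an unscored edit-distance alignment.

    Fast unscored counterpart of :func:`global_protein_identity`, used where
    thousands of comparisons are needed (AAI best-hit search, gene-family
    clustering, per-gene nucleotide identity of syntenic blocks). Terminal
    gaps of an NW path are counted as coverage shortfall, not identity
    columns, matching the semi-global convention.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    res = edlib.align(a, b, mode="NW", task="path")
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]
    # strip terminal overhangs (leading/trailing pure-gap runs)
    lead = 1 if ops and ops[0][1] in "ID" else 0
    trail = 1 if len(ops) > lead and ops[-1][1] in "ID" else 0
    core = ops[lead:len(ops) - trail] if trail else ops[lead:]
    qa_off = sum(n for n, op in ops[:lead] if op == "I")
    sa_off = sum(n for n, op in ops[:lead] if op == "D")
    core_cigar = "".join(f"{n}{op}" for n, op in core)
    matches, mismatches, _go, gap_bases = _cigar_counts(
        core_cigar, a[qa_off:], b[sa_off:], exclude_n=nucleotide)
    n_cols = matches + mismatches + gap_bases
    span_a = sum(n for n, op in core if op in "=XMI")
    span_b = sum(n for n, op in core if op in "=XMD")
    return IdentityResult(
        identity_percent=100.0 * matches / n_cols if n_cols else 0.0,
        n_matches=matches,
        n_aligned_columns=n_cols,
        coverage_a=100.0 * span_a / len(a),
        coverage_b=100.0 * span_b / len(b),
    )


def edit_similarity(a: str, b: str) -> float:
    """Cheap normalized similarity in [0,1] for candidate screening only."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / max(len(a), len(b)))
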