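"""Lateral-mobility analysis: decoupling of a gene family's pairwise
distances from host-genome distances.

For every unordered strain pair the analysis forms a point
``(100 - ANI, 100 - gene identity)``: the genome distance against the
protein distance of the family's representatives. A vertically inherited
family tracks its host genomes (strong positive correlation); a laterally
mobile family — repeatedly lost and reacquired from within the clade — shows
near-identical copies in distant hosts and divergent copies in close hosts,
collapsing the correlation.

Significance is assessed with a Mantel permutation test: strain labels of
the gene-distance matrix are permuted, which respects the non-independence
of pairwise points (i.i.d. point permutation would not). The mobility of a
target family is judged against a vertical reference family analyzed the
same way; the primary statistic is Pearson's r on raw distances, with
Spearman's rho reported alongside for robustness.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .markers import PRESENT, MarkerCall
from .pairalign import global_protein_identity
from .relatedness import DistMatrix
from .seqio import SeqRecord


@dataclass
class OrthologPair:
    strain_a: str
    strain_b: str
    gene_identity: float
    multi_copy: bool  # True when either strain had >1 copy (best pair used)


@dataclass
class MobilityPoint:
    strain_a: str
    strain_b: str
    genome_distance: float  # 100 - ANI
    gene_distance: float    # 100 - identity


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    flagged: bool = False  # zero-variance matrix; r undefined


@dataclass
class MobilityReport:
    family: str
    n_strains: int
    n_pairs: int
    pearson_r: float
    spearman_rho: float
    mantel_p: float
    mobility_index: float  # 1 - pearson_r, in [0, 2]
    reference_family: str | None = None
    delta_r: float | None = None  # r_reference - r_target
    laterally_mobile: bool | None = None


def ortholog_pairs(strains: list[tuple[str, list[SeqRecord]]], family: str,
                   calls: dict[str, MarkerCall]) -> list[OrthologPair]:
    """Pairwise family-protein identities over strains carrying the family.

    Only strains whose call status is ``present`` participate (truncated and
    absent strains are excluded). When a strain carries multiple copies, the
    copy pair with the highest identity is used and the pair is flagged.
    """
    eligible = []
    for sid, proteome in strains:
        call = calls.get(sid)
        if call is None or call.status != PRESENT:
            continue
        tags = [t for t, _ in call.all_evidence] or [call.evidence]
        by_tag = {p.id: p for p in proteome}
        copies = [by_tag[t] for t in tags if t in by_tag]
        if copies:
            eligible.append((sid, copies))
    if len(eligible) < 3:
        raise ValueError(
            f"insufficient strains: {len(eligible)} carry {family} (need >=3)")
    pairs = []
    for (sa, ca), (sb, cb) in itertools.combinations(eligible, 2):
        best = max(
            global_protein_identity(x, y).identity_percent
            for x in ca for y in cb)
        pairs.append(OrthologPair(sa, sb, best,
                                  multi_copy=len(ca) > 1 or len(cb) > 1))
    return pairs


def mobility_points(pair_table: list[OrthologPair],
                    ani_matrix: DistMatrix) -> list[MobilityPoint]:
    """Join gene identities with genome distances into scatter points.

    ``ani_matrix`` already holds distances (100 - ANI); gene identity is
    transformed to 100 - identity here. A missing matrix entry raises,
    naming the pair.
    """
    points = []
    for p in pair_table:
        if p.strain_a not in ani_matrix.labels or p.strain_b not in ani_matrix.labels:
            raise KeyError(f"no genome distance for pair ({p.strain_a}, {p.strain_b})")
        points.append(MobilityPoint(
            strain_a=p.strain_a,
            strain_b=p.strain_b,
            genome_distance=ani_matrix.get(p.strain_a, p.strain_b),
            gene_distance=100.0 - p.gene_identity,
        ))
    return points


def gene_distance_matrix(pair_table: list[OrthologPair]) -> DistMatrix:
    """Symmetric 100-identity matrix over the strains present in the table."""
    labels = sorted({p.strain_a for p in pair_table}
                    | {p.strain_b for p in pair_table})
    n = len(labels)
    values = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for p in pair_table:
        i, j = idx[p.strain_a], idx[p.strain_b]
        values[i, j] = values[j, i] = 100.0 - p.gene_identity
    return DistMatrix(labels, values)


def mantel_test(d_genome: DistMatrix, d_gene: DistMatrix,
                n_perm: int = 9999, seed: int = 0,
                exhaustive: bool = False) -> MantelResult:
    """One-sided Mantel test of positive association between two matrices.

    Pearson's r is computed on the vectorized upper triangles; the null
    distribution permutes strain labels of ``d_gene`` (rows and columns
    jointly). ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``; reproducible
    for a fixed seed. A constant matrix leaves r undefined (flagged result).

    With ``exhaustive=True`` (n <= 8) all n! label permutations are
    enumerated instead of sampled and ``p = #{r_perm >= r_obs} / n!`` — the
    identity permutation makes this at least 1/n!.
    """
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if set(d_genome.labels) != set(d_gene.labels):
        raise ValueError("matrices must share labels")
    d_gene = d_gene.reorder(d_genome.labels)
    x = d_genome.condensed()
    gene_vals = d_gene.values
    y = d_gene.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        return MantelResult(math.nan, math.nan, n_perm, flagged=True)
    r_obs = float(stats.pearsonr(x, y).statistic)
    n = len(d_genome.labels)
    iu = np.triu_indices(n, k=1)
    xc = x - x.mean()
    xnorm = np.sqrt((xc ** 2).sum())

    def perm_r(perm) -> float:
        yp = gene_vals[np.ix_(perm, perm)][iu]
        yc = yp - yp.mean()
        return float((xc * yc).sum() / (xnorm * np.sqrt((yc ** 2).sum())))

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        perms = list(itertools.permutations(range(n)))
        n_ge = sum(perm_r(np.array(p)) >= r_obs - 1e-12 for p in perms)
        return MantelResult(r_obs, n_ge / len(perms), len(perms))
    rng = np.random.default_rng(seed)
    n_ge = sum(perm_r(rng.permutation(n)) >= r_obs - 1e-12
               for _ in range(n_perm))
    return MantelResult(r_obs, (1 + n_ge) / (1 + n_perm), n_perm)


def _family_report(family: str,
                   strains: list[tuple[str, list[SeqRecord]]],
                   calls: dict[str, MarkerCall],
                   ani_matrix: DistMatrix,
                   n_perm: int, seed: int) -> MobilityReport:
    pairs = ortholog_pairs(strains, family, calls)
    d_gene = gene_distance_matrix(pairs)
    d_genome = ani_matrix.reorder(d_gene.labels) if \
        set(d_gene.labels) <= set(ani_matrix.labels) else None
    if d_genome is None:
        missing = set(d_gene.labels) - set(ani_matrix.labels)
        raise KeyError(f"no genome distances for strains {sorted(missing)}")
    x, y = d_genome.condensed(), d_gene.condensed()
    if np.std(x) > 0 and np.std(y) > 0:
        pearson_r = float(stats.pearsonr(x, y).statistic)
        spearman_rho = float(stats.spearmanr(x, y).statistic)
    else:
        pearson_r = spearman_rho = math.nan
    mantel = mantel_test(d_genome, d_gene, n_perm=n_perm, seed=seed)
    n = len(d_gene.labels)
    return MobilityReport(
        family=family, n_strains=n, n_pairs=n * (n - 1) // 2,
        pearson_r=pearson_r, spearman_rho=spearman_rho,
        mantel_p=mantel.p_value,
        mobility_index=1.0 - pearson_r if not math.isnan(pearson_r) else math.nan,
    )


def mobility_report(target_family: str, reference_family: str | None,
                    strains: list[tuple[str, list[SeqRecord]]],
                    calls: dict[str, dict[str, MarkerCall]],
                    ani_matrix: DistMatrix,
                    n_perm: int = 999, seed: int = 0,
                    mobility_margin: float = 0.3,
                    alpha: float = 0.05,
                    common_strains: bool = False) -> list[MobilityReport]:
    """Mobility reports for a target family and an optional vertical reference.

    ``calls`` maps family -> strain -> MarkerCall. Each family is analyzed on
    its own eligible strain set unless ``common_strains`` restricts both to
    the intersection. The target is classified laterally mobile when its
    Mantel p exceeds ``alpha`` or its mobility index exceeds the reference's
    by ``mobility_margin``.
    """
    if common_strains and reference_family is not None:
        shared = {
            sid for sid, _ in strains
            if all(calls[f].get(sid) and calls[f][sid].status == PRESENT
                   for f in (target_family, reference_family))}
        strains = [(sid, p) for sid, p in strains if sid in shared]
    reports = []
    target = _family_report(target_family, strains, calls[target_family],
                            ani_matrix, n_perm, seed)
    target.reference_family = reference_family
    reports.append(target)
    if reference_family is not None:
        ref = _family_report(reference_family, strains, calls[reference_family],
                             ani_matrix, n_perm, seed)
        reports.append(ref)
        target.delta_r = ref.pearson_r - target.pearson_r
        target.laterally_mobile = bool(
            target.mantel_p > alpha
            or target.mobility_index > ref.mobility_index + mobility_margin)
    else:
        target.laterally_mobile = bool(target.mantel_p > alpha)
    return reports


def points_to_tsv(points: list[MobilityPoint], path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_a\tstrain_b\tgenome_distance\tgene_distance\n")
        for p in points:
            fh.write(f"{p.strain_a}\t{p.strain_b}\t"
                     f"{p.genome_distance:.4f}\t{p.gene_distance:.4f}\n")
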