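# Methods

`genemobility` quantifies whether a facultative gene family in a bacterial
clade is inherited vertically or shuttled around the clade by horizontal
gene transfer (HGT), and detects the genomic signatures that accompany that
lifestyle: gene loss and truncation, replacement from within-clade donors,
and long duplicated syntenic regions at intermediate identity (sustained
heterozygous diploidy, or merodiploidy). The motivating biology is
autotrophy in *Thermaceae*: the Calvin–Benson–Bassham (CBB) cycle there
hinges on two key determinants — form I RuBisCO (CbbL) and
phosphoribulokinase (PRK) — whose patchy, truncation-riddled distribution
and decoupled gene/genome distances point to repeated losses and
reacquisitions from the clade pangenome rather than simple vertical descent.

## Identity conventions

Every downstream statistic reduces to pairwise sequence identity, so the
convention is fixed once, in `pairalign`, and reported with every result:

    identity% = 100 · matches / aligned_columns

where `aligned_columns` counts all columns between the first and last
aligned residue pair — matches, mismatches, and internal gap columns — and
excludes terminal overhangs. Coverage of a sequence is the percentage of its
residues inside that aligned span. Ambiguous nucleotides (`N`) never count
as matches. Published identity figures rarely state their denominator;
fixing and reporting one is the only defensible way to make values
comparable across the pipeline.

Protein identity uses a scored semi-global alignment (BLOSUM62, gap open 11
/ extend 1 — conventional values; end gaps free). Nucleotide placement of a
fragment inside a genome uses an exact bit-parallel edit-distance DP in
infix mode over both strands (no heuristic seeding), rescored with
match +2 / mismatch −3 / gap open 5 / extend 2. A fast unscored global
edit-distance identity (`edit_identity`) backs the high-volume steps (AAI
best-hit search, gene-family clustering, per-gene block identity); on
substitution-only data it agrees with the scored aligner exactly, and the
tests assert that.

## Genome relatedness

**ANI** follows the classical fragment recipe: chop each genome into
non-overlapping 1,020-bp fragments, place each fragment in the other genome
(best infix alignment over both strands), keep fragments with ≥30% identity
and ≥70% coverage, average identity per direction, and report the unweighted
mean of the two directional means. Defaults are the classical filters;
everything is a parameter. The estimator recovers 100·(1−p) within ±0.3 on
substitution-only pairs at p ∈ {1,2,5,10}% (20 seeds per level, ~44-kb
genomes; binomial noise at that genome size is ≪0.1%).

**AAI** is the mean identity over reciprocal best-hit (RBH) protein pairs.
Best hits are found with the fast edit-distance similarity over all protein
pairs (symmetric, so one matrix serves both directions, with a length-ratio
prefilter); reciprocal pairs passing ≥20% identity and ≥70% mutual coverage
are rescored with the scored aligner. RBH is the standard operational
orthology proxy; an all-hit mean would be inflated by paralogs.

`whole_genome_identity` is an exact column-identity for structurally
matched assemblies (equal contig layout, as produced by substitution-only
simulation). It coincides with fragment ANI under that model and costs one
vectorized pass; the mobility-recovery experiments use it for their dense
12-strain distance matrices so that replicate counts, not the ANI kernel
(validated separately), dominate the budget.

## Marker screening

A marker reference (protein) is screened against a proteome — or, without
annotations, against stop-free segments of the six-frame translation. Best
hit = highest identity × reference-coverage product; ties break toward
higher coverage, then lexicographically smaller locus tag, so calls are
deterministic. Status thresholds (per marker, configurable):

* present: identity ≥ 40% and reference coverage ≥ 70%
* truncated: identity ≥ 40% and 20% ≤ coverage < 70%, **or** the hit
  carries an internal-stop (pseudo) flag from translation
* absent: otherwise

The published analyses this mirrors do not quantify their
truncated/absent boundary; these are declared defaults, and the validation
plants edits far from the thresholds (coverage 100/50/0%), where status
accuracy is 100%. Cluster completeness is a boolean over member calls: the
CBB key rule is `cbbL_formI AND prk` (accessory CBB genes are deliberately
ignored — PRK is the indispensable determinant); the sox thiosulfate
oxidation rule requires all of SoxY, Z, X, A, B, C, D. RuBisCO form
assignment is nearest-reference classification against a labeled panel of
form I/II/III sequences with a 35% identity floor.

## Mobility statistic

For each strain pair carrying a full-length family copy, form the point
(100−ANI, 100−identity): host-genome distance against family-protein
distance. The report gives Pearson's r on raw distances (primary — the
relationship is approximately linear at within-genus scales), Spearman's ρ
(robustness), a mobility index 1−r, and a one-sided Mantel permutation p.
Labels of the gene-distance matrix are permuted, not the points: pairwise
distances sharing a strain are not independent, so i.i.d. point permutation
would anticonservative. `p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)` with a
seeded generator; for n ≤ 8 an exhaustive mode enumerates all n!
permutations. Null calibration: type-I error 0.05 ± 0.03 at α = 0.05 over
200 independent-matrix simulations (n = 8, 999 permutations).

A target family is compared against a vertical reference family (citrate
synthase is the natural choice in the motivating system); each family is
analyzed on its own eligible strain set (present-status strains only) with
an option to intersect. Classification "laterally mobile": Mantel p > 0.05
or mobility index exceeding the reference's by 0.3 (configurable margin).
Multi-copy strains contribute their best-identity copy pair, flagged.
Under the study design of 12-taxon clades with the target at 0.5 HGT
events/branch, the target's r falls below the vertical reference's in
≥90% of 50 replicates; vertical-only controls keep both r ≥ 0.9.

## Duplicated syntenic blocks (merodiploidy)

Proteins are clustered into gene families by greedy single-linkage on
pairwise identity ≥50% with ≥70% mutual coverage (inputs sorted by locus
tag, so clustering is order-independent; a shared-4-mer prefilter makes the
all-vs-all cheap). The 50% protein threshold is deliberately permissive:
copies near the 80% *nucleotide* identity floor translate to ~55% protein
identity, while unrelated proteins sit below 30%, leaving margin on both
sides.

The detector chains family-level anchors between two gene runs (same or
different contigs) whose order is conserved or reversed, allowing ≤3
unmatched genes between consecutive anchors per run. Chains of ≥40 anchors
whose mean per-gene nucleotide identity lies in [80%, 98%] are reported;
the ceiling excludes fresh tandem duplications and collapsed assembly
repeats, the floor excludes ancient paralogy. Identity is nucleotide-level
(strand-aware per-gene global alignment) and the output says so, since
region-level "percent identity" claims are otherwise ambiguous.
`edge_conflict` marks blocks whose two copies both abut contig ends — the
configuration in which the copies compete for the same chromosomal docking
sites and the assembly cannot be circularized. Gene-level synteny rather
than raw nucleotide self-alignment keeps the scan robust on fragmented
draft assemblies. On a 40-genome panel (half injected with 40- or 80-gene
blocks at 5 or 10% divergence, half clean), sensitivity ≥0.9 with FDR ≤0.1
and boundary error ≤2 genes; 80-gene 10%-divergence blocks report
90 ± 1% identity.

## Simulator

The generator emulates the inferred evolutionary regime so every estimator
can be scored against known truth.

* **Species tree**: ultrametric pure-birth (Yule), default birth rate 1.
  The waiting time after the n-th birth is included, so terminal branches
  are never zero; mean root-to-tip depth is H_n/λ (tested by Monte Carlo).
* **Genomes**: a root genome of 300 core genes by default (uniform 600–1500
  bp, multiple of 3; ATG start, sampled stop; GC target 65%, matching the
  *Thermus* range) with 20-bp spacers; every 7th gene on the minus strand
  to exercise strand handling.
* **Substitution**: Jukes–Cantor. Over a branch of length t each site
  substitutes with probability p(t) = 3/4·(1 − e^(−4λt/3)) to a uniform
  different base; per-branch steps compose exactly to the JC chain. No
  indels — an indel process would entangle the identity-denominator
  convention with alignment behavior; v1 keeps divergence interpretable
  column-wise. Substitutions creating an in-frame internal stop in intact
  coding genes are re-drawn (crude purifying selection); truncated remnants
  evolve unconstrained.
* **Focal-family events**, drawn per branch: HGT (Poisson, events/branch),
  loss (Bernoulli), truncation (Bernoulli, keeps a 5′ fraction uniform in
  [0.2, 0.6]). Events across the whole tree are processed in global
  chronological order; an HGT at time τ advances the chosen donor lineage's
  state to τ and copies its realized sequence — homologous replacement, the
  observed pattern in the motivating system, not novel-gene insertion. HGT
  into a lineage that lost the family models reacquisition; with
  configurable probability (`remnant_prob`, default 0) the lost copy
  persists as a truncated remnant, mirroring retained gene-cluster
  remnants alongside newly acquired copies.
* **Heterozygous blocks**: a contiguous gene run is copied onto a new
  contig and mutated per site at the requested divergence (stop-creating
  hits re-drawn, strand-aware); truth records both copies' coordinates.
* **Determinism**: one seed feeds named child streams
  (tree/root/core/focal/het), so identical configs give bit-identical
  FASTA/GFF3/truth outputs, verified byte-for-byte in the tests.

What the simulator does **not** emulate — and what passing tests therefore
do not certify on real data: indels and rearrangements, rate heterogeneity
across sites and lineages, codon-level selection beyond stop avoidance,
compositional drift, inter-clade HGT donors, and assembly/annotation error.
The estimators' behavior under those violations must be judged separately;
the synthetic results certify the statistical machinery, not the messiness
of real assemblies.

## Numerical and design choices

* Distances are plain 100−identity percentages throughout; matrices are
  validated symmetric with a zero diagonal.
* The fragment-ANI final value is the unweighted mean of the two
  directional means, making the matrix symmetric by construction.
* The pipeline fans a single seed out to per-stage seeds by hashing the
  stage name (crc32), so adding a stage never shifts another stage's
  randomness.
* Degenerate inputs are flagged, not silently zeroed: zero passing ANI
  fragments or zero RBH pairs give a `no_signal` result distinct from 0;
  constant distance matrices flag the Mantel r as undefined; an all-N
  contig leaves GC undefined with a logged warning.
* Experiment problem sizes (≈44-kb genomes for ANI recovery, 20-gene cores
  for the 12-taxon mobility replicates, 120-gene genomes for the
  heterozygosity panel) were chosen so binomial/sampling noise is far below
  each acceptance tolerance while the full battery stays desk-scale.

## Known limitations

* No indel model: identities on real data include alignment-gap ambiguity
  the simulator never generates.
* Six-frame screening reports stop-free segments only; a marker split by a
  frameshift may screen as truncated rather than present.
* Family clustering is single-linkage and can chain through promiscuous
  domains on real proteomes; the synteny requirement (≥40 ordered anchors)
  is what keeps false blocks rare.
* The Mantel test conditions on the observed distance matrices; it does not
  model phylogenetic non-independence beyond label exchangeability.
* dDDH, tree inference, and donor identification are out of scope.
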