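# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, the assumptions baked into the synthetic
fixtures, and the known limits of what the tests demonstrate.

## Data model and numbering

A complex is a set of role-labelled protein chains (heavy/light or
beta/alpha on the binder side; MHC α/β, β2-microglobulin, peptide, or
generic antigen on the antigen side), sanitized to heavy atoms only:
hydrogens, waters, heteroatom residues and all but the
highest-occupancy alternate conformer are removed at load time.
Residues are keyed by author numbering `(chain, number, insertion
code)`; IMGT numbers (immunoglobulin chains) and a renumbered MHC scale
are carried as parallel annotations supplied by a sidecar file, never
computed — numbering algorithms are a solved problem upstream (ANARCI
and kin) and re-implementing one here would only add a second source of
disagreement.

CDR windows on the IMGT scale are CDR1 = 27–38, CDR2 = 56–65,
CDR3 = 105–117, identical on all four chain types; everything else on
an immunoglobulin chain is framework. MHC groove helices default to
renumbered 50–86 (α1-style) and 138–176 (α2-style) on the class-I α
chain; class II uses per-chain windows. These windows are configuration,
not constants of nature — the helix bounds in particular are a
convention the user can override, since published analyses rarely state
them.

Heavy/beta chains are VDJ-recombined and light/alpha chains
VJ-recombined; the pairing map makes the H↔B and L↔A comparisons
explicit so antibody and TCR loops of common genetic origin can be
compared like for like.

## Solvent-accessible surface area and burial

SASA uses the Shrake–Rupley construction: each atom's sphere of radius
r_vdw + r_probe is covered with a deterministic golden-spiral lattice
(default 960 points, probe 1.4 Å), and a point is accessible iff it
lies outside every other atom's expanded sphere. Van der Waals radii
are pinned (C 1.70, N 1.55, O 1.52, S 1.80 Å) and an unknown element is
an error rather than a silent default: SASA differences at the percent
level are exactly the kind of discrepancy an unpinned radius table
produces. The golden-spiral lattice involves no random numbers, so
results are bit-reproducible; at 960 points the isolated-sphere value
is exact to machine precision and small-cluster values agree with a
10^5-point random-direction oracle to well under 2 %. Neighbor search
uses a k-d tree with a radius bound of r_i + r_j + 2·r_probe, which is
exactly equivalent to the all-pairs test (verified in the suite).

Burial follows the apo-minus-complex convention: each partner's SASA is
recomputed with the other partner's coordinates deleted, on the same
lattice, so ΔSASA ≥ 0 holds exactly per residue and the interface BSA
decomposes exactly into the two sides' totals. A residue is "buried"
when ΔSASA > ε with ε = 0.01 Å², absorbing floating-point noise without
admitting any genuine contact (a single blocked lattice point at 960
points corresponds to ~0.1 Å²). The peptide fraction of pMHC burial is
peptide_bsa / (peptide_bsa + mhc_bsa); β2-microglobulin counts toward
the MHC side.

No induced fit: both apo states reuse the bound-state coordinates, so
all burial quantities are rigid-body descriptors of the crystallized
pose, not free-energy surrogates.

## Interaction typing and consolidation

Contacts are typed on heavy atoms only, with pinned defaults:
hydrophobic — apolar-carbon pairs ≤ 4.5 Å, where backbone C/CA and a
per-residue table of heteroatom-bonded side-chain carbons are excluded;
aromatic — ring-centroid distance ≤ 5.0 Å over the Phe/Tyr/Trp/His ring
atoms; hydrogen bond — donor heavy atom to acceptor ≤ 3.5 Å with the
antecedent–donor–acceptor angle ≥ 90°, the angular test standing in for
the missing hydrogen and discarding "weak" assignments; salt-bridge
candidate — carboxylate O of Asp/Glu to Lys NZ / Arg NE,NH1,NH2 /
His ND1,NE2 ≤ 4.0 Å, with His treated as protonatable by default
(configurable — there is no protonation model). All cutoffs live in a
criteria object so users calibrating against an external typing tool
(e.g. Arpeggio output, which can also be imported directly from TSV)
can match its definitions.

Consolidation to residue pairs: any number of hydrophobic atom contacts
on a pair collapse to one hydrophobic interaction, likewise aromatic,
and a pair may carry both (different electrostatic origins). Charged
polar contacts are ambiguous "salt bridge/hydrogen bond" until
resolved: candidate residue pairs are sorted by closest atom–atom
distance (ties broken by lexicographic pair id, logged) and accepted
greedily so that each charged side chain participates in at most one
salt bridge; displaced candidates are recorded as hydrogen bonds. A
pair's interaction count in totals is the number of distinct types it
carries — a hydrophobic-plus-aromatic pair counts twice, which is an
interpretation the summary code makes explicit rather than hides.

## Binding geometry

The groove frame is built from the MHC helix windows: the groove axis
is the principal component of both helices' Cα atoms (or, in
`anchor_ca` mode, the vector through the peptide anchor Cα atoms,
defaulting to position 2 and the C-terminus), oriented along the
peptide N→C direction; the helix plane is the least-squares plane
through the same Cα set. The docking/crossing angle is measured between
the in-plane projections of the groove axis and of the line from the
VJ-domain to the VDJ-domain conserved-disulfide midpoint (Cα of IMGT
Cys23/Cys104, the convention of the docking-angle literature; the
anchor set is configurable). Projection makes the angle well-defined
for binders approaching at any elevation; the VJ→VDJ orientation makes
label-swapping map θ to 180° − θ, so canonical TCR-like poses cluster
diagonally near 45° and reverse-polarity diagonal poses near 135°.

Polarity is positional, not angular: a binder is canonical iff its VDJ
domain centre is nearer the α1-helix centroid and its VJ domain nearer
the α2-helix centroid, reverse otherwise. The classical description —
beta-chain centre of mass over the α1 C-terminus — is what this rule
yields for diagonal canonical binders; using distances to the helix
*C-terminal halves* directly was considered and rejected, because with
antiparallel helices those half-centroids sit at diagonally opposite
corners of the groove and the test then conflates a change of docking
angle with a change of polarity. Nearest-whole-helix assignment is
angle-independent and reproduces the reverse-polarity description of
known outliers (VDJ above α2 while VJ occludes α1). Poses whose
inter-domain axis lies almost exactly along the groove axis (θ within a
few degrees of 0° or 180°) have both domains near the groove midline
and polarity is genuinely ill-defined there, by geometry rather than by
implementation.

Diagonality folds angles to min(θ, 180°−θ), pooling absolute docking
angles across polarities, and tests membership in a reference band
derived from a TCR cohort (empty cohorts are an error). The guanidino
tilt of an arginine is the angle between the best-fit plane normal of
NE/CZ/NH1/NH2 and the helix-plane normal, folded to [0°, 90°]: 0° means
the guanidino group lies in the helix plane, 90° means it protrudes —
the discriminator between in-plane and extended conformations of MHC
α1-helix arginines at TCRm interfaces.

All geometric quantities are functions of inter-atomic configuration
only and are rigid-body invariant to numerical precision (property
tested under random rotations and translations).

## Dataset curation

Records are filtered to X-ray structures at ≤ 2.5 Å with protein
antigens, then clustered greedily in the cd-hit style: sequences sorted
by descending length (ties by id), the longest unassigned sequence
seeds a cluster, each subsequent sequence joins the first seed it
matches. Round one clusters concatenated CDR sequences at 80 %
identity ("paratope clusters"); round two clusters each paratope
cluster's concatenated antigen sequences (descending length order;
presented peptide for TCRs) at 80 % identity with minimum alignment
coverage 20 %, so a truncated antigen construct collapses onto its
full-length parent rather than counting as a new binding context. One
representative per (paratope, antigen) cluster is kept: best
resolution, then lexicographic id — the representative rule is this
package's own, since greedy seeding alone does not define one.

Identity is computed from an exact global alignment scoring match +1
with mismatch and gaps contributing nothing; a −10⁻³ internal-gap
tie-break selects one deterministic alignment among the co-optimal
max-match alignments (the identity denominator — alignment columns
excluding terminal gaps — depends on which co-optimal alignment is
realized). Coverage is the shorter sequence's aligned span over its
length. This is a documented, exact substitute for cd-hit's word-filter
heuristics: at desk scale exactness beats speed, and at the 80 %
threshold the two definitions agree except on adversarial inputs.
Clustering is invariant to input ordering by construction, and at
threshold 1.0 with full coverage reduces to exact-duplicate grouping.

## Energy-decomposition statistics

The pipeline consumes per-residue binding free-energy tables
(kcal/mol, attractive negative) such as MMGBSA DECOMP output; running
simulations is out of scope. Multiple per-frame or per-replica tables
are averaged per residue before any thresholding, so hotspot calls are
made on ensemble means. Hotspot bands: ≤ −7 kcal/mol hotspot,
(−7, −4] semi-hotspot, inclusive on the stronger side, so −7.0 is a
hotspot and −4.0 a semi-hotspot.

Regional fractions split the attractive pMHC energy between peptide,
α1 helix and α2 helix: f_region = |S_region| / Σ|S|, with a repulsive
(positive) regional sum clipped to zero before normalisation and
flagged. The denominator covers only those three regions — the rest of
the MHC is excluded by choice, pinned here because the fraction is
meant to compare groove-facing contributions across complexes; users
who want a whole-pMHC denominator can pass a region map that labels
more residues. CDR fractions divide each loop's sum by the signed total
over all six CDRs and clip negative (repulsive-loop) fractions to zero;
the unclipped fractions sum to exactly 1, so clipping leaves the
reported bars summing to ≥ 1 by the amount clipped. When repulsive
loops are small perturbations — the regime the measure is designed
for — all reported fractions stay in [0, 1]; a strongly repulsive loop
can push another loop's raw fraction above 1, which is reported as-is
rather than renormalised, since hiding it would misrepresent the
energetic balance.

## Synthetic fixtures: what they emulate, and what they don't

The groove generator builds a class-I-style scene in a canonical frame
(groove plane z = 0, axis +x): two coarse helical chains of Cα/CB
pseudo-atoms at ±9 Å flanking an extended Cα-only peptide (3.8 Å
spacing), and a two-domain binder whose conserved-cysteine midpoints
sit exactly at the requested docking angle, polarity and elevation.
Occlusion is engineered analytically: a nitrogen pseudo-atom 5.0 Å
above a peptide Cα shadows that residue's solvent sphere (5.0 < 6.05 Å,
the N···C occlusion reach at probe 1.4 Å) while clearing the
neighbouring Cα 3.8 Å away (√(3.8² + 5.0²) = 6.28 > 6.05 Å), so the
buried-peptide count equals the requested set exactly — a sphere-
geometry margin, not a tuned tolerance. An optional arginine planted at
MHC position 65 carries a guanidino plane at a requested tilt.

Generators are pure functions of (spec, seed) using numpy's PCG64;
groove output is byte-stable through PDB serialisation. Decomposition
fixtures draw backgrounds from a Gaussian truncated above zero (default
mean −1, sd 0.5 kcal/mol — attractive interface noise far from the −7
band) and plant hotspot energies exactly. Sequence-set fixtures plant
cluster structure by giving each cluster a distinct letter at a shared
divergent position set (between-cluster identity hit exactly) and
mutating disjoint within-cluster blocks inside that set (pairwise
within-cluster identity hit to within the ±3-point band); infeasible
designs raise instead of silently degrading.

These fixtures exercise the geometric and statistical code paths, not
molecular realism: no packing, no side chains beyond pseudo-atoms, no
fold. Passing tests therefore demonstrate correctness of the
computations and conventions on known-answer inputs — they do not
certify agreement with any published cohort statistics, which would
require profiling the deposited representative structures themselves.
On real structures the absolute SASA values additionally depend on the
radius table and point count, so cross-study comparisons at the percent
level should hold those fixed.

## Problem sizes and defaults

Default SASA lattice is 960 points per atom (convergence to < 1 %
against 4× refinement on fixtures); cohort batch profiling defaults to
240 points, plenty for ΔSASA-based counts on fixtures and adjustable
per call. The acceptance script uses 100 random interfaces for burial
invariants, 50 random poses for geometry recovery, 20-sequence sets for
clustering, and a 6-complex cohort — sizes at which every quantity it
reports is recomputed from scratch in seconds.

## Known limitations

* Rigid-body descriptors only: no induced fit, no flexibility, no
  energy model of our own.
* Polarity is undefined for poses docked along the groove axis (see
  above); diagonality inherits whatever reference cohort it is given.
* Contact typing is geometric and hydrogen-free; protonation-dependent
  chemistry (His tautomers, low-pH carboxylates) is approximated by
  configuration flags.
* The identity definition is an exact-alignment substitute for cd-hit's
  internal heuristic; cluster compositions can differ from cd-hit's on
  borderline pairs near the threshold.
* The MHC renumbering target scheme is whatever the sidecar supplies;
  the package ships class-I-style helix windows but does not validate
  biological correctness of a user's mapping.
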