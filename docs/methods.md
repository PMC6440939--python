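# Methods

## Scope and model

`ldlr-varstruct` interprets missense variants of the low-density
lipoprotein receptor (LDLR) in structural terms. LDLR loss of function
causes familial hypercholesterolemia; most reported variants are of
uncertain significance. The package annotates each variant with the
structural role of its residue — disulfide-bond cysteine, Ca²⁺-coordinating
residue, hydrophobic-core member, conserved position, glycosylation-site
neighbour — and classifies per-condition folding-stability changes
(ΔΔG_fold) computed for models of the receptor at extracellular and
endosomal conditions. The two-condition view matters because class-A
(LA) repeats are Ca²⁺- and pH-dependent: a substitution can be tolerated
in the endosome yet strongly destabilizing at the cell surface, or vice
versa.

All residue coordinates are kept in precursor (UniProt) numbering; the
signal peptide is 21 residues, so mature position *n* is precursor
*n* + 21. Variant tables are auto-checked against the canonical sequence
in both frames and normalized on ingest; rows whose stated reference
residue matches neither frame are excluded and logged, because silent
coordinate errors would corrupt every downstream count.

## Clinical harmonization

A variant is **pathogenic** if any source meets a pathogenic criterion:
ClinVar "(likely) pathogenic" (case-insensitive substring, excluding
"conflicting…"), HGMD class exactly `DM`, or LOVD ACGS class 4/5. It is
**benign** if a benign criterion holds (ClinVar "(likely) benign", ACGS
1/2) *and* no pathogenic criterion does. Everything else, including
population-frequency records, is a VUS. Pathogenic evidence therefore
dominates; the rule is monotone, which the property suite asserts.
Uniqueness is at the protein-change level: one record per
(ref, position, alt), sources merged before harmonization.

## Stability classification

Sign convention: positive ΔΔG_fold = destabilizing (stated in every
output header). Thresholds, in kcal/mol, with defaults:

| parameter     | default | meaning |
|---------------|---------|---------|
| `significant` | 0.6     | |ΔΔG| ≤ 0.6 is neutral; > 0.6 destabilizing; < −0.6 stabilizing |
| `strong`      | 1.8     | ΔΔG > 1.8 is strongly destabilizing; condition difference ≥ 1.8 leaves the gray band |
| `severe`      | 3.0     | condition difference > 3.0 is the red category |

The condition difference is the absolute value
|ΔΔG_extracellular − ΔΔG_endosomal| (the signed value is also emitted);
the orange band [1.8, 3.0] is closed on both ends, red strictly above 3.0.
Boundary behaviour is pinned by tests at exactly 0.6, 1.8, and 3.0.

Real analyses ingest ΔΔG tables computed externally (e.g. FoldX exports)
via `stability.load_ddg_table`; conflicting duplicate rows are an error,
not a silent overwrite. For self-contained synthetic pipelines the module
offers `estimate_ddg`, a deliberately transparent five-term score
(idealized side-chain swap): steric-overlap change of a side-chain
pseudo-atom, lost hydrogen-bonding capacity, Kyte–Doolittle hydropathy
change weighted by burial (1 − RSA), a fixed 4.0 kcal/mol penalty for
removing a disulfide-bonded cysteine's thiol, and a fixed 2.5 kcal/mol
penalty for removing a side-chain Ca²⁺-coordinating oxygen. Weights ship
in `data/ddg_weights.tsv`. It is an interpretable toy for testing, not a
calibrated energy function, and the reporting layer never substitutes it
for ingested energies.

## Geometric annotation

* **Disulfides**: Cys Sγ–Sγ pairs within 2.5 Å, matched greedily
  nearest-first so each cysteine joins at most one bond.
* **Ca²⁺ coordination**: per calcium ion, all protein oxygens within
  3.2 Å (mean Ca–O ≈ 2.4 Å plus modeling tolerance); side-chain and
  backbone oxygens are tracked separately because a substitution only
  necessarily changes the shell when a side-chain oxygen is lost —
  backbone-only coordinators are flagged only for substitutions to/from
  Pro or Gly, the cases that perturb backbone geometry.
* **Burial**: Shrake–Rupley SASA (probe 1.4 Å, 960 points per atom,
  element radii) via biotite, normalized by the theoretical maximum
  residue areas (Tien et al. set) and clipped to [0, 1]; core = RSA ≤
  0.15.
* **Glycosylation proximity**: a residue is `near_glyco` when its
  sequence distance to the nearest supplied site is ≤ 5 (window
  configurable); the shipped site list in fixtures is synthetic.

## Conservation

Per reference (non-gap) MSA column, the raw score is 1 − H/H_max with H
the Shannon entropy over amino acids (gaps excluded) and H_max = ln 20;
scores are z-normalized across the protein. "Conserved" means the column
is invariant or its z-score reaches the top quartile (threshold recorded
in output and configurable). No sequence weighting is applied — the
intended inputs are redundancy-reduced alignments. The cysteine-anchored
pairwise aligner forces given residue pairs into shared columns and
aligns the blocks between anchors independently (BLOSUM62, gap open 10,
extend 0.5), mirroring how class-A repeats are aligned to templates
without mispairing the structurally equivalent cysteines.

## Quality metrics

The panel (Ramachandran fractions and outlier z, hydrogen-bond
participation, clash z, "dope-like" statistical-potential z) judges model
plausibility on a common scale:

* φ/ψ are computed from backbone atoms; residues are binned with separate
  region definitions for Gly, Pro, pre-Pro and general residues. The
  regions are coarse analytic boxes over the canonical basins shipped in
  `data/rama_regions.json` — this package's own simplified definitions,
  not a published density grid, so absolute fractions are not comparable
  to external validation servers.
* Hydrogen bond: donor-heavy to acceptor ≤ 3.5 Å and
  antecedent–donor–acceptor angle ≥ 120°; backbone and side-chain bonds
  count alike; covalently constrained neighbours excluded.
* Clash: heavy-atom pairs closer than (Σ vdW − 0.4 Å), excluding pairs
  within 3 covalent bonds (estimated from backbone position plus
  side-chain branch depth) and disulfide-bonded cysteine side chains. An
  ideal α-helix scores zero clashes by construction of this rule.
* Statistical potential: coarse contact log-odds over Cβ–Cβ distance bins
  and hydrophobic/polar/charged residue classes
  (`data/contact_potential.tsv`, hand-designed, negative = favorable),
  standardized against decoys that shuffle residue identities on fixed
  coordinates (seeded). More negative z = more native-like packing.
* The z-standardizations for Ramachandran outliers and clash rate use the
  synthetic reference constants in `data/quality_reference.json`.

All metrics depend only on internal distances and angles, hence are
rigid-body invariant (asserted numerically). They are validated by this
invariant suite plus fixture limits (ideal helix: 100% core, full
interior hydrogen bonding, zero clashes) and O(n²) brute-force oracles,
not against any external server's numbers.

## Synthetic data

The generator produces every input with machine-readable planted truth:

* **Mini-domain** (~40 residues): a class-A-like toy with three planted
  disulfides (Sγ–Sγ exactly 2.05 Å), one Ca²⁺ ion whose coordinating
  carboxylate oxygens sit at 2.4 Å, and a hydrophobic interior. The Cα
  trace is a compact self-avoiding lattice path (3.8 Å step); side chains
  are Cβ plus only the functionally required terminal atoms. Pairs whose
  Cα distance exceeds 7 Å are rejected as infeasible. This captures the
  *detection geometry* of a class-A repeat, not its fold, dynamics, or
  real packing density.
* **Ideal backbones** for the quality panel are built separately from
  φ/ψ with ideal bond geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å;
  ω = 180°): helices (−57°, −47°) and random-dihedral decoys.
* **MSA**: invariant planted columns on a uniform 6-letter background.
* **Variant/ΔΔG tables**: clinical classes planted through unambiguous
  source labels (defaults 0.30 pathogenic / 0.20 benign / 0.50 VUS);
  endosomal ΔΔG drawn per class — pathogenic N(2.5, 1.5), benign
  N(0, 0.3) truncated to |ΔΔG| ≤ 0.6 so no benign variant is
  destabilizing, VUS an even mixture — and condition deltas drawn clear
  of the category boundaries to hit target gray/orange/red fractions
  exactly (defaults 0.56 / 0.14 / 0.30). These defaults qualitatively
  mimic the intended study conditions; no claim is made that they match
  any empirical distribution.

Every generator is a pure function of (spec, seed). Because classes and
categories are planted, recovery tests are exact-count checks, which
verifies the bookkeeping (parsing, harmonization, thresholding,
counting) rather than any statistical estimator; what passing does *not*
show is performance on real structural models or real database label
noise.

## Numerical choices and degenerate inputs

* Alternate locations resolve to the highest-occupancy conformer (ties:
  first by label); only the first model of multi-model files is read.
* Constant vectors make Spearman undefined → error, never NaN
  propagation. Rank-sum uses the exact null for n ≤ 10 per group without
  ties, otherwise the normal approximation with continuity correction.
* A potential-z decoy set with zero variance (e.g. uniform residue
  identities) returns z = 0 by convention.
* Reports are byte-deterministic: fixed ordering, no timestamps.
* Problem sizes used by the shipped acceptance run: 400-variant tables,
  20 generator seeds for geometry recovery, 200 decoys for the potential
  z — sizes at which every stochastic check is stable across seeds.

## Known limitations

* The internal ΔΔG estimator is not calibrated; only its ordinal
  properties are meaningful.
* Quality-panel absolute values depend on shipped synthetic reference
  constants and simplified Ramachandran regions; use them comparatively.
* The lattice mini-domain has non-physical backbone dihedrals; it is not
  suitable for Ramachandran fixtures (the dihedral builder is).
* Conservation scoring is unweighted entropy; phylogenetic rate models
  are out of scope.
* cDNA-level parsing, transcript mapping, splice/CNV variants, and
  homology-model construction are out of scope.
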