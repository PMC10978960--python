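# Methods

This note documents the models, conventions and design choices behind
`sahhkit`, in the order of the pipeline stages.

## Sequence analysis

**Alignment.** Pairwise global alignment is Needleman–Wunsch with affine
gaps through Biopython's `PairwiseAligner` (BLOSUM62, gap open 11, gap
extend 1; a gap of length L costs 11 + (L−1)).  These are the standard
protein defaults; both matrix and penalties are arguments on every
operation.  Where several tracebacks are co-optimal, the aligner's first
reported traceback is used — a deterministic choice for a fixed Biopython
version, which is what downstream reproducibility needs.  The
match-column mapping (reference index → query index) is the sole channel
through which alignments feed every later stage, so insertions and
deletions in either sequence are tolerated everywhere.

**Fingerprint motif.** The motif window is anchored at the reference
motif His and spans five residues.  Only relative positions 1, 3 and 5
determine the class (`HxExK`, `HxTxE`, `HxTxQ`; `HxExX` for an H/E pair
with a different position 5; otherwise `other`); positions 2 and 4 never
affect it.  If any anchor column is gapped the class is `undetermined` —
a value, not an error.  `HxExK` predicts SIH preference,
`HxTxE`/`HxTxQ` predict SAH preference, everything else maps to
`unknown`.  A non-His residue at position 1 forces `unknown` regardless
of the rest, because that His is catalytic.

**Architecture features.** The 40-residue catalytic-domain segment is
called present when at least 50 % of its reference columns align to
query residues; the threshold is deliberately loose so local
misalignment at segment edges cannot flip the call.  `cterm_delta` is
the signed difference in residues past the last aligned column, measured
against the segment-containing long-C-terminus reference;
`thermophile_flag` fires at `cterm_delta ≤ −15`.  The flag is a reported
heuristic only and never feeds the preference prediction.

**Homologue scan.** DadD/MTAN presence is a Smith–Waterman local scan
(same scoring) over a proteome; the best hit must reach 30 % identity
over the aligned length and 70 % reference coverage.  These are
conventional homology floors, configurable in `RunConfig`.

**Pathway inference** is a pure function of (preference label, DadD
present, MTAN present): SAH- and SIH-preferring hydrolases both support
direct SAH cleavage (SIH-preferring family members retain SAH activity —
a dual function); DadD together with an SIH-preferring hydrolase adds
the deamination route; MTAN adds the two-step MTAN/LuxS route; DadD with
an SAH-only hydrolase and no MTAN flags that SIH must be metabolised by
another pathway.

## Packaged reference data

Real SAHH/SIHH sequences are not redistributed.  The reference set
consists of synthetic scaffolds, generated from a fixed internal seed,
that place the published landmark numbering correctly: the PfuSAHH-like
scaffold has the motif at 55–59 (His55/Glu57/Lys59), gate His298/Phe299,
catalytic Asp128, His-OUT partner Glu302 and C6 main-chain partner
Asp348; the SacSAHH-like scaffold is offset by −4 so Thr53 occupies
motif position 3; the MmaSAHH-like scaffold carries a 15-residue
N-terminal extension and one internal deletion so the motif Lys lands at
74 and the C6 partner Asp at 362; the mesophile-like scaffold adds the
40-residue segment (151–190), an `HxTxQ` motif and a 25-residue
C-terminal extension.  Landmark *relationships* (what aligns onto what)
are therefore faithful even though the filler residues are random.  The
18-enzyme study table (organism, phylum, motif class, segment/C-terminus
state, the published assay symbols and DadD/MTAN presence) ships as
plain text; `study_sequences()` turns it into synthetic sequences with
each enzyme's features planted, which is how the study-level analyses
are reproduced without downloads.

## Structure analysis

**Parsing.** PDB/mmCIF files are read with gemmi (first model).  Of
alternate locations the highest-occupancy conformer is kept, ties going
to altloc `A`.  Waters are kept separately and excluded from hydrogen-
bond partner sets by default.  Het groups are classified by residue code
(NAD-type cofactors; ADN/INO nucleosides; SAH/SIH thioethers; monoatomic
ions).  O5′ naming dialects (`O5*`, `O5´`) are normalised.

**Landmark mapping** runs the sequence aligner between each chain's
extracted one-letter sequence and the reference, so renumbered
depositions are handled; author numbering is used only for display.  A
residue-type mismatch at a landmark warns rather than fails.  Chains
below a 30 % identity floor are skipped; if no chain maps, that is an
error.

**Gate state.** `d_gate` is the *minimum* heavy-atom distance between
the gate-His imidazole ring atoms (CG, ND1, CD2, CE1, NE2) and the
catalytic-Asp carboxylate oxygens (OD1, OD2) — matching the
"imidazole ring … γ-carboxylate" reading of the exemplar distances — and
the ring–carboxylate centroid distance is reported alongside for
diagnostics, since the printed values' convention is not stated.
Thresholds: IN at ≤ 6.0 Å, OUT at ≥ 8.0 Å *plus* a ≤ 3.5 Å contact to
the His-OUT partner Glu; the band between is `undetermined`.  The
exemplar geometries (4.2 Å IN, 10.4 Å OUT) sit well clear of the band on
either side.  χ1/χ2 are the N–CA–CB–CG and CA–CB–CG–ND1 dihedrals; the
coarse rotamer label bins χ2 to ±60°/180°, which is enough to express
the crenarchaeal-versus-euryarchaeal His-IN rotamer distinction.

**Hydrogen bonds.** Donor/acceptor N/O/S heavy-atom pairs between a
ligand and the protein within 3.5 Å, no angle term — hydrogens are not
observed at these resolutions, and a distance-only criterion keeps the
enumeration exactly reproducible by a brute-force all-pairs scan (which
the tests do).  Results are deduplicated and sorted by distance with
name-based tie-breaks, so output order is deterministic.

**Tautomer inference.** For hypoxanthine ligands (INO/SIH), an O6
contact to a main-chain carbonyl oxygen implies O6 donates a hydrogen,
i.e. the imino-hydroxy form; with no such contact the call defaults to
amino-oxo, the most stable form in water.  Adenine ligands (ADN/SAH) are
called amino, with the exo-amino N6 main-chain contacts as evidence.
Unknown ligand codes give `undetermined`.

**Cations.** Na⁺/K⁺ ions within 6.0 Å (configurable) of the hinge
selection — or, as fallback, of the ligand atoms — are reported with
their coordinating atoms (≤ 3.5 Å).  An empty report *is* the result
"no monovalent cation", which is the expected outcome for archaeal
structures.

**Superposition and RMSD.** Kabsch superposition via SVD with the
reflection branch excluded (determinant always +1); fewer than three
points or collinear point sets are geometry errors.  The test suite and
the acceptance script cross-check the RMSD against an independent
quaternion (Horn) implementation to 1e-6 Å.  ASU chain RMSD pairs chains
by sequence alignment and is Cα-only.

**Interdomain rotation.** Models are superposed on their
cofactor-binding-domain Cα atoms (matched by sequence id); the residual
Kabsch rotation mapping one substrate-binding domain onto the other
gives the angle (axis–angle from the rotation-matrix trace).  With the
comparison model in a known state, an angle within 6° of zero keeps that
state, an angle within 6° of the ~18° open/closed anchor flips it, and
anything else is `undetermined`.  Domain intervals for the synthetic
references are the implementer's choice (documented in `refdata`) and
are configurable, since the true boundaries are only available
graphically.

**Peptide flip.** After superposing the local backbone window
(Cα of His−2 … Phe+2), the angle between the *oriented* normals of the
two His–Phe peptide planes (through Cα/C/O of His and N of Phe; normal =
(C−Cα) × (N−Cα)) is returned.  A true flip is ~180°; the call threshold
of 120° leaves small librations far below it.

## Assay scoring

Conversion = 100 × Σ(product + side-product amounts) / Σ(substrate +
product + side-product amounts), with amount = peak area / response
factor.  Default response factors are 1.0 (equal-molar-absorptivity
assumption, appropriate for an explicitly semi-quantitative score);
per-analyte factors are configurable.  The nucleobase side product
(adenine/hypoxanthine) counts toward converted substrate in both
directions.  Homocysteine-derived species are excluded from the
denominator by default — their UV response is not comparable to the
purine species — via the analyte-role mapping, which is overridable.

Categories: `+++` above 70 %, `++` for 30–70 % (closed on both ends,
since the printed outer thresholds are strict), `+` below 30 %, and `-`
below a 1 % noise floor rather than exactly zero, because
chromatographic baselines never are.  The preference call compares the
four records ordinally; a substrate strictly better in one direction and
not worse in the other wins, a silent (−/−) loser upgrades the call to
SAH-only/SIH-only, four − is inactive, anything else is
both/no-preference.  Concordance counts an SIH prediction as matched by
SIH-preferring assays and an SAH prediction by SAH-preferring or
SAH-only assays.

## Synthetic fixtures, and what passing tests show

Toy active sites use idealised residue geometry placed so the *measured*
quantities (gate distance, OUT-partner contact, Nδ1–O5′ distance, O6
main-chain contact, cation distance) equal their targets exactly; base
chains are built on the 0.001 Å grid of the PDB coordinate field so a
written file reproduces the targets to full precision.  Extra chains are
rigid-moved copies with optional isotropic Gaussian noise.  Generated
peak tables score back to their true conversion exactly at zero noise by
construction.  Motif-planted sequences perturb only non-anchor columns.

These fixtures exercise the *measurement and classification logic* under
controlled truth.  They do not emulate real crystallographic data —
no alternate conformations in the toys, no missing density, no realistic
packing — so passing tests demonstrate correctness of the geometry and
decision rules, not robustness to every deposition quirk (the altloc and
naming-dialect policies are tested separately on constructed cases).
Likewise the synthetic study sequences reproduce the published *feature
table* (motif class, segment, C-terminus, assay symbols), so study-level
results recomputed from them — six `HxExK` homologues, full
motif/assay concordance, SAH-only Crenarchaeota — validate the pipeline
logic against the published summary rather than re-deriving it from
primary data.

## Problem sizes and numerical choices

The acceptance script uses 100 seeded superposition instances, 20
replicates per gate distance, 50 planted-motif trials per noise level,
200 noisy peak tables and 21 rotation-recovery cases — sizes at which
every stochastic check is stable across seeds while the whole run stays
in the seconds range.  Distances are Å throughout, residue indices are
1-based with closed intervals, all comparisons use explicit tolerances
(1e-6 Å for coordinate round-trips and oracle agreement, 0.2° for
rotation recovery), and every random draw descends from a single
user-visible seed.

## Known limitations

* Preference prediction is binary by motif class; the residual SIH
  activity of some `HxTxQ` enzymes is real but not explained by the
  fingerprint, and the concordance report only annotates such rows.
* The hydrogen-bond criterion has no angle term and will over-count
  contacts in dense pockets at permissive cutoffs.
* The open/closed call depends on configurable domain intervals; with
  heavily re-numbered or fragmented chains the reference-based interval
  resolution can fail and must be supplied manually.
* `fetch` requires network access; all analyses of deposited structures
  are optional conveniences, not dependencies of the test suite.
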