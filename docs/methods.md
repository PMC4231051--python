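# Methods

## The model

`saltbridger` treats salt-bridge design as a frequency-inference problem:
geometric categories of salt bridges that occur often on protein surfaces
are the ones most likely to actually form when engineered. The pipeline has
two halves — a survey that estimates those frequencies, and a design engine
that applies them to a target structure.

### Bridge definition and geometry

A salt bridge is any (basic, acidic) residue pair — K–D, K–E, R–D, R–E —
whose closest qualifying side-chain atom pair (NZ for Lys, NH1/NH2 for Arg,
OD1/OD2 for Asp, OE1/OE2 for Glu) is strictly closer than 4 Å. Histidine is
excluded throughout: its protonation state at pH 7 is ambiguous. One record
is kept per residue pair (the minimum over atom pairs), within and across
chains. Each bridge carries:

- `r`, the Cα–Cα distance;
- θ₁ = ∠Cβ₁Cα₁Cα₂ and θ₂ = ∠Cβ₂Cα₂Cα₁, the angles each residue's Cα→Cβ
  vector makes with the inter-residue axis. These backbone-proximal
  pseudo-angles capture whether the side chains point toward each other
  without requiring side-chain coordinates — which is what makes them
  usable for *hypothetical* substitutions. Residues lacking a Cβ (glycine,
  incomplete models) get an ideal virtual Cβ reconstructed from backbone
  N/Cα/C;
- the 3-state secondary structures of both residues (DSSP 8-state collapsed
  as {H,G,I}→helix, {B,E}→sheet, everything else→coil);
- an exposure class from relative solvent accessibility: *exposed* if one
  residue's RSA exceeds 0.35 and the other's 0.25, *buried* if both are
  below 0.09, otherwise *intermediate*. The three classes partition all
  bridges.

### The pair index

Surface (exposed-class) bridges are tallied into categories
(pair type, SSᵢ, SSⱼ, distance bin), with 1-Å bins over 3–15 Å on `r`
(the observed range of surface bridges; the bin edges are configurable
because the original binning of the reference survey is not published).
Weights are `w = 100 · count / total`, so the full matrix sums to exactly
100 and each weight reads as a percentage preference. Categories never
observed — including every repulsive combination, which is never counted by
construction — have weight 0.

### Per-residue descriptors

- **WCN / rWCN**: WCNᵢ = Σ_{j≠i} 1/d(Cαᵢ, Cαⱼ)², summed over every Cα of
  the whole assembly (not just the residue's own chain — packing at subunit
  interfaces is real packing and matters for interface positions).
  rWCN = 1/WCN; high rWCN means low packing density.
- **B-factor**: the Cα atom's isotropic displacement parameter, a proxy for
  local flexibility.
- **z-scores**: B-factor and rWCN are z-normalized per chain with the
  population (ddof = 0) standard deviation. Per-chain grouping matches the
  one-profile-per-protein convention of crystallographic B-factor analyses;
  the grouping and sd convention are arguments, not constants, since the
  choice shifts borderline candidates.
- **RSA**: DSSP's per-residue ASA (or the internal fallback, below) divided
  by the residue's maximal ASA in an extended Gly–X–Gly tripeptide. The
  shipped table is the empirical set of Tien et al. (2013). The empirical
  rather than theoretical variant is used deliberately: the package's
  fallback ASA is a heavy-atom Shrake–Rupley computation (ProtOr
  united-atom radii), and on an actual extended Gly–Ala–Gly it yields
  ~118 Å² for Ala — within a few percent of the empirical maximum (121)
  but ~9 % below the theoretical one (129), which is a maximum over all
  side-chain conformations rather than the extended one. Values above 1
  are retained, not clamped.
- **Conservation**: consumed, never computed — a `chain resnum grade` TSV
  in the ConSurf 1–9 convention (1 = variable, 9 = conserved). Grades
  outside 1–9 and duplicate rows are validation errors.

Annotation precedence: a supplied DSSP file is used verbatim (8-state codes
and ACC values); only in its absence does the fallback compute ASA by
Shrake–Rupley and secondary structure by the Cα-based P-SEA heuristic. The
fallback exists so the pipeline runs without a DSSP installation, but DSSP
input is preferred for bit-compatibility with DSSP-era surveys.

### Pre-filter cascade

Candidate design positions must be, in order: polar or charged
(S/T/C/N/Q/K/R/D/E — polar residues are depleted in thermophiles, charged
ones allow charge optimization), exposed (RSA > 0.35), flexible (z_B > 0),
loosely packed (z_rWCN > 0), and variable (conservation grade < 4).
Residues with no conservation grade fail the last filter — the conservative
choice, since an ungraded position cannot be certified safe to mutate. The
surviving count after each filter is reported (`--explain`).

### Scoring and suggestion logic

Each candidate position is hypothetically replaced by K, R, D and E and
evaluated against every charged residue within 15 Å Cα–Cα (any chain) — the
radius covers the longest surveyed surface bridges (~14.2 Å). The
substitution keeps the native residue's Cα/Cβ geometry; no side-chain
modelling is attempted. A pairing must satisfy the orientation rule
observed in the survey: if r > 7 Å, at least one of θ₁/θ₂ below 110°
(at r ≤ 7 Å any orientation passes). The score of a pairing is the index
weight of its category; repulsive and neutral pairings score 0, and a
position's total attraction is the sum over its neighbors.

Suggestions per position:

- pairings at sequence separation < 5 within a chain are considered
  uninfluential for stability; a position whose qualifying pairings are all
  sequence-local is dropped. Inter-chain pairings always satisfy the rule.
- the predicted pair is the highest-scoring pairing with separation ≥ 5;
  exact score ties yield one suggestion per tied pairing (this is how a
  position can suggest both K and R).
- if the globally best pairing is sequence-local, the alternative-
  substitution rule applies: a substitution is accepted only if its best
  long-range pairing outscores that same substitution's best short-range
  pairing; among accepted substitutions the highest-scoring pairing wins.
- a suggestion requires a strictly positive score: a zero weight means the
  geometric category was never observed in the survey, which is evidence
  against formability, not for it.
- output order is deterministic (position, substitution, partner), and
  repeated runs are byte-identical.

## Synthetic fixtures

`synthetic_fixtures` builds PDB files (with matching classic-DSSP text) in
which each planted bridge occupies its own site on a 30-Å grid: Cα atoms
separated by the requested `r`, Cβ atoms placed to realize θ₁/θ₂ exactly,
and charge-group atoms placed midway at the requested contact distance.
Decoy residues sit on isolated sites and can never satisfy the 4-Å
criterion. Planted secondary structure and exposure are realized through
the DSSP companion file (representative 8-state codes; ASA set to 100 %,
20 % or 5 % of the reference maximum for exposed/intermediate/buried). The
generator is a pure function of its spec including the seed; measured
geometry agrees with the request to PDB coordinate precision (0.001 Å).

What the fixtures deliberately do **not** emulate: real backbone
connectivity between sites, side chains beyond the charge group,
physically consistent B-factor/packing correlations, or crystallographic
noise (altlocs, missing atoms appear only in hand-written test inputs).
Passing fixture tests therefore validates the *bookkeeping and geometry* of
the pipeline exactly, but says nothing about detection completeness on
noisy real models — that is what the optional real-structure tests under
`tests/data/rcsb/` are for.

`generate_survey_set` distributes an exact per-category bridge count over n
structures, drawing distances (kept 0.05 Å inside bin edges so rounding
cannot cross a bin), angles and contact distances from the seeded rng:
different seeds change coordinates but recover identical index weights.

## Numerical choices and degenerate inputs

- Distance threshold comparisons are strict (`< 4 Å`, `< 110°`); the
  neighborhood radius and angle gate are inclusive (`≤ 15 Å`, `≤ 7 Å`).
- Altlocs: highest occupancy wins, ties to file order (the standard
  crystallographic convention). Model 1 only for multi-model files. MSE is
  read as Met; other non-standard residues are excluded but keep their
  author numbering. Residues without Cα are excluded with a warning.
- z-scores of a constant vector raise a degenerate-distribution error when
  requested directly; inside the assembled descriptor table the affected
  group gets NaN z-scores with a warning, so one single-residue chain does
  not abort an assembly-wide analysis (NaN z-scores then simply fail the
  pre-filter).
- Index lookups outside the binned range return 0 with a warning rather
  than raising: a 15-Å neighbor can legitimately sit outside the binned
  survey range.
- Angle computation clips cosines to [−1, 1]; zero-length Cα→Cβ or
  Cα→Cα vectors raise a geometry error.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic input:
a 100-structure survey set carrying 120 planted surface bridges across 7
categories, 50-to-60-residue random structures for the WCN oracle, 50
random neighborhoods for the scoring oracle, and single-position design
scenes. These sizes make every recovery check exact (category proportions,
detection, scoring) while keeping the whole suite in the seconds range.

## Known limitations

- Scores are pairing-preference weights, not energies: no ΔΔG, ΔTm,
  continuum electrostatics, or repulsion penalty (repulsive weights are
  zero by construction, so an engineered charge can still be placed into a
  locally repulsive environment that the model simply does not see).
- No salt-bridge network or cooperative multi-mutation optimization; each
  position is scored independently.
- Native secondary structure and geometry are assumed unchanged by the
  substitution.
- The quality of the index is bounded by the survey set supplied by the
  user; the reconstruction here does not ship the original large survey,
  and rebuilt weights depend on the chosen bin edges.
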