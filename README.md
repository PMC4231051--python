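# saltbridger

Survey-driven design of thermostabilizing salt bridges on protein surfaces.

Salt bridges — attractive contacts between a basic side chain (Lys NZ, Arg
NH1/NH2) and an acidic one (Asp OD1/OD2, Glu OE1/OE2) closer than 4 Å — are
one of the most effective handles for raising a protein's thermal stability,
but picking *where* to introduce one and *which* charged substitution to use
is the hard part. `saltbridger` implements an empirical, survey-based answer
for protein engineers:

1. **Survey**: detect salt bridges across a set of X-ray structures, record
   each pair's Cα–Cα distance *r*, the pseudo-angles θ₁ = ∠Cβ₁Cα₁Cα₂ and
   θ₂ = ∠Cβ₂Cα₂Cα₁ describing the mutual orientation of the Cα→Cβ vectors,
   the 3-state secondary structures, and an exposure class from relative
   solvent accessibility (exposed: one residue RSA > 35 % and the other
   > 25 %; buried: both < 9 %).
2. **Pair index**: over the *exposed* (surface) bridges, build an empirical
   weight matrix *w*(pair type, SS pair, distance bin) proportional to
   observed frequency and normalized so that Σw = 100 — the pairing
   preference of each geometric category.
3. **Descriptors & pre-filter**: for a design target, compute per-residue
   RSA, Cα B-factor and weighted contact number WCNᵢ = Σ_{j≠i} 1/d(Cαᵢ,Cαⱼ)²
   (rWCN = 1/WCN), z-normalized per chain. Candidate positions are polar or
   charged residues (S/T/C/N/Q/K/R/D/E) with RSA > 0.35, z_B > 0, z_rWCN > 0
   and ConSurf conservation grade < 4: exposed, flexible, loosely packed,
   variable sites.
4. **Design**: each candidate position is hypothetically substituted by K,
   R, D and E and scored against every charged residue within 15 Å (across
   subunit interfaces too) with the weighted electrostatic attraction model

   E_i = Σ_j w(pair(i,j), SSᵢ, SSⱼ, bin(r_ij)) for qᵢ·qⱼ < 0, else 0,

   subject to the survey-derived orientation rule (for r > 7 Å at least one
   of θ₁/θ₂ must be < 110°) and a sequence-separation rule (≥ 5 residues,
   with inter-chain pairs always eligible, including an alternative-
   substitution fallback when the top-scoring pairing is sequence-local).
   The highest-scoring pairings become ranked mutation suggestions.

A synthetic-fixture generator (`saltbridger.synthetic_fixtures`) builds
small PDB + DSSP files with exactly known planted bridge geometry and
descriptor statistics, so the entire pipeline is testable without any
structure downloads.

## Worked example

Simulate a small survey set with planted bridges, survey it, build the pair
index, and design substitutions on a synthetic target:

```
$ saltbridge simulate --n-structures 6 --n-bridges 30 --seed 11 --out fixtures
30 bridges in 6 structures -> fixtures
$ saltbridge survey fixtures --dssp-dir fixtures --out survey_out
30 bridges from 6 structures -> survey_out
$ saltbridge index survey_out/bridges.tsv --out pair_index.tsv
index over 30 bridges, weight sum 100.000000 -> pair_index.tsv
$ head -7 pair_index.tsv
# n_bridges=30
# bin_edges=3,4,5,6,7,8,9,10,11,12,13,14,15
pair_type       ss_i    ss_j    bin_lo  bin_hi  weight
K-D     H       H       6       7       20.0
K-E     C       C       4       5       20.0
K-E     H       H       8       9       20.0
R-D     S       C       5       6       20.0
```

Each index row says: of the surveyed surface bridges, 20 % were (for
example) Lys–Asp pairs with both residues helical at Cα–Cα distance 6–7 Å.

Designing on a target structure (here a fixture with a flexible, exposed,
variable Asn at A:50 and a Glu at A:60, 8.5 Å away):

```
$ saltbridge design target.pdb --index pair_index.tsv --dssp target.dssp \
      --conservation conservation.tsv --out suggestions.tsv --explain
pre-filter cascade: polar_or_charged=2, rsa=2, z_b=2, z_rwcn=2, conservation=1
1 suggestions at 1 candidate positions -> suggestions.tsv
$ cat suggestions.tsv
# saltbridger config=1529df787a1c
position  substitution  partner  score  ca_dist  theta1  theta2  seq_sep  inter_subunit  alternative_rule
A:50:N    K             A:60:E   20     8.5      0       0       10       False          False
```

Reading: mutate Asn50 to Lys; the predicted partner is Glu60 (an N50K–E60
bridge), whose geometric category carried weight 20 (out of 100) among the
surveyed surface bridges — the most frequently observed, hence most
formable, pairing available at this position. `--all-pairs` dumps the full
substitution × neighbor score matrix; conservation tables are plain
`chain resnum grade` TSVs in the ConSurf 1–9 convention.

The same functions are available as a library (`parse_structure`,
`detect_salt_bridges`, `build_pair_index`, `compute_descriptors`,
`prefilter_positions`, `suggest_mutations`, ...); see `docs/methods.md` for
the model details and design decisions.

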