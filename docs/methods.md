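# Methods

## The rate model

Non-adiabatic electron tunnelling between protein redox centers decays
exponentially with donor–acceptor separation:

    k_et(R) = A0 · exp(−β · R)

with R the **minimal heavy-atom edge-to-edge distance** between the two
prosthetic groups in Å, β (Å⁻¹) the decay constant describing how strongly
the electronic coupling attenuates through the protein medium, and A0 (s⁻¹)
the contact-limit rate. Temperature-dependent over-barrier activation is
deliberately outside the model: no vibrational quantum or activation
parameters are available for this system, and the distance dependence alone
is what the analysis rests on.

β and A0 are fixed by solving the two-equation system through
(5 Å, 10¹⁰ s⁻¹) and (15 Å, 2.5×10⁵ s⁻¹) — the span observed for
inter-center ET in proteins at 5–15 Å:

    β  = ln(k1/k2)/(R2−R1) = ln(4×10⁴)/10 = 1.0597 Å⁻¹  (printed as 1.06)
    A0 = k1·e^(βR1)       ≈ 2.0×10¹² s⁻¹

A third reference, (30 Å, 0.03 s⁻¹), over-determines the system; it is used
as a *verification anchor*, not a constraint. The calibrated model predicts
k(30 Å) = 0.0313 s⁻¹, 4.2 % above the anchor, well inside the default
tolerance factor of 1.2. Both the 1.0597… and the rounded 1.06 values of β
reproduce the worked rate examples at one significant figure.

## Distances

"Distance between prosthetic groups" means the closest pair of heavy atoms
(hydrogens excluded) between the two groups — not metal–metal or
centroid–centroid separation. This is the only definition compatible with
how the reference distances were measured, and it is what
`min_group_distance` computes (ties broken toward the lowest atom indices).
Predicted models and crystal structures differ in hydrogen content, so
heavy-atom distances are the reproducible choice.

## Pathways and the limiting link

A monomer has one chain, FAD1→FMN1→HEME1. A homodimer has both intra-chain
copies plus the two cross routes FMN1→HEME2 and FMN2→HEME1 (FAD never
crosses monomers: flavin-to-flavin transfer stays within a chain). The
**chain rate equals the rate of the limiting (longest) step**, not a
series-resistor combination: under an exponential decay with β ≈ 1 Å⁻¹ the
slowest step is orders of magnitude slower than the rest, so it alone sets
the chain throughput. The *naive* alternative — evaluating the model at the
**sum** of the step distances, as if the electron tunnelled FAD→heme in one
jump — is reported for contrast; for the wild-type monomer (28 + 11 = 39 Å)
it yields ~2×10⁻⁶ s⁻¹, unrealistically far below measured turnover, which
is what rules the single-jump picture out.

Cross routes with rates below a configurable threshold (default 10⁻⁷ s⁻¹)
are flagged as rejected. The two monomers of a homodimer are labelled by
chain order of first appearance in the file; the labelling of identical
monomers is physically arbitrary, so reports always state the convention.

The comparison of chain k_et with experimental k_cat uses qualitative
bounds (default: consistent when the ratio is within [1/3, 3]); WT dimer
0.031 vs 0.03 s⁻¹ is "consistent", A83I monomer 0.0038 vs 0.19 s⁻¹ is
"et_slower", and so on. Aromatic relay screening reports minimal
side-chain-to-heme distances for candidate residues (default residue 262)
and flags contacts under 4 Å: an aromatic ring packed against the heme edge
(5 Å → 3 Å upon A83F dimerization) can accelerate ET beyond what the bare
distance model predicts.

## Monomer ⇄ dimer equilibrium

For A + A ⇄ AA with K_D = [A]²/[AA] and total monomer-equivalent
concentration C = [A] + 2[AA], the free monomer concentration is the
positive quadratic root, computed in the cancellation-free conjugate form
x = 2C/(1 + √(1 + 8C/K_D)); the dimer is x²/K_D, so mass conservation and
K_D consistency hold to ~10⁻¹⁵ relative. Trimers and higher oligomers are
neglected, and mutants are assumed to share the wild-type K_D = 1.1 nM.
At assay concentrations of 1–5×10⁻⁷ M this gives monomer fractions of
7.1–3.3 % — the protein is overwhelmingly dimeric, which is why the dimer's
limiting step is the one compared with turnover. (A literature claim of
"about 20–8 %" monomer under the same conditions is **not** reproducible
under standard mass action with either the chain-fraction or
molar-species-fraction convention; the package reports the computed values
and does not assert the published ones.)

## Synthetic fixtures

The generator emulates the *file structure and geometry* of predicted
multi-domain models: one or two chains whose Cα trace spans the three
domain ranges (serpentine synthetic walks, ~1 050 residues per chain, plus
configurable decoy side-chain atoms), with HEM/FMN/FAD hetero groups of
≥ 10 heavy atoms each. It does **not** emulate real fold topology, side-chain
chemistry, or predictor confidence fields — so passing tests certify the
measurement/model pipeline, not structure-prediction quality.

Exactness through the PDB format is the central design problem: coordinates
carry only 3 decimals, so naive placement would perturb distances by
~10⁻³ Å. All atoms therefore live on the 0.001 Å grid, and each constrained
pair of groups receives a dedicated *contact pair* of atoms whose integer
milli-Å displacement v satisfies | |v| − 1000·d | < 5×10⁻⁴, giving
|achieved − target| ≤ 5×10⁻⁷ Å after the file round trip. (Demanding
|v|² = (1000d)² exactly is not generally possible: whole-Å targets make
1000d divisible by 8, and r₃(4N) = r₃(N) forces such representations onto an
8-fold sparser sphere.) Interior atoms stay within 1.2 Å of each group
center, contact shells at 2.0 Å, contact directions at one group are kept
≥ 40° apart and ≥ 8° off the coordinate axes (integer sphere points thin
out near axes) — margin arithmetic then guarantees the designated pair is
strictly the closest one. After writing, the generator re-reads the file
and re-measures every target; a violation raises, so a fixture that exists
is a correct fixture. Fixtures are byte-identical for identical spec+seed.

Scenario distances not fixed by the study were chosen once as generator
defaults: monomer FMN–HEME = 11 Å for all three forms (reported for WT
only); dimer FAD–FMN = 15 Å (reported only as "much less" than the
FMN–heme gaps — 15 Å keeps the step non-limiting while staying in the
calibrated regime); WT-dimer FMN2–HEME2 mirrored at 30 Å; A83F-dimer
FMN1–HEME1 and FMN2–HEME1 at 44 Å (only the 42 Å intra and 34 Å cross
minima are reported). The A83F monomer's 40 Å limiting gap is placed on
FAD–FMN, following the summary statement that FAD–FMN gaps of 28–40 Å are
the limiting links in all three monomers; the pipeline labels limiting
pairs from measured geometry, never from scenario names.

## Numerical choices and limitations

- Kabsch superposition enforces a proper rotation (det = +1) by flipping the
  smallest singular direction; reflections are never physical here.
  Collinear point sets and <3 correspondences are errors, not warnings.
- Superposition correspondence is Cα-only, matched by chain and author
  residue number (robust to side-chain differences at mutation sites);
  author numbering is used verbatim everywhere, no renumbering.
- Only the first MODEL of a file is read and only blank/'A' altlocs kept:
  a structure is one conformer.
- Distances are reported at 2 decimals in text output but carried at full
  precision internally; rates are never rounded before comparisons.
- The model has no orientation, packing-density or pathway-integral terms;
  two cofactor pairs at equal edge-to-edge distance always get equal rates.
  The F262 contact screen flags where this assumption is expected to fail,
  but no rate correction is applied.
- Kinetic network effects (parallel flux, electron occupancy, NADPH binding
  kinetics) are out of scope; the chain rate is a single-path bound.

## Problem sizes used in tests

Fixtures carry ~1 150 atoms (monomer) / ~2 300 atoms (homodimer); the
oracle suites use 200 random 12-atom cloud pairs for closest-pair
equivalence and 1 000 random superposition trials against the quaternion
method. The entire suite, including six generated scenarios analyzed end to
end, runs in a few seconds on one CPU.
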