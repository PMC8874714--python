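# redoxpath

Electron-transfer pathway analysis for multidomain cytochrome P450 models,
built around CYP102A1 (P450 BM3) — the self-sufficient bacterial P450 that
fuses a heme domain (residues 2–459), an FMN domain (460–650) and an FAD
domain (659–1049) into one polypeptide. Catalysis requires electrons to hop
along the FAD→FMN→heme chain, and in the homodimer additionally across
monomers (FMN of one chain to the heme of the partner). Given predicted or
experimental structures in PDB format, `redoxpath`:

- extracts the HEM/FMN/FAD prosthetic groups and measures minimal
  heavy-atom **edge-to-edge distances** R between them;
- converts distances to electron-transfer rate constants with the
  non-adiabatic tunnelling decay law
  **k_et(R) = A₀·e^(−βR)**, calibrated exactly through two reference points
  (R = 5 Å, k = 10¹⁰ s⁻¹) and (R = 15 Å, k = 2.5×10⁵ s⁻¹), which gives
  β = 1.06 Å⁻¹ and A₀ ≈ 2×10¹² s⁻¹, cross-checked against an independent
  anchor (R = 30 Å, k = 0.03 s⁻¹);
- identifies the **limiting link** of each chain (the longest gap; its rate
  is the chain rate), contrasts it with the rejected single-jump estimate
  over the summed path, and rejects cross-monomer routes whose rates fall
  below 10⁻⁷ s⁻¹;
- compares chain k_et with experimental turnover k_cat per enzyme form
  (WT 0.03, A83I 0.19, A83F 6 s⁻¹) and reports the monomer⇄dimer mass-action
  equilibrium (K_D = 1.1 nM) at assay concentrations;
- screens aromatic relay residues (e.g. F262) for ring-to-heme contacts;
- ships a **synthetic-structure generator** that writes valid multi-domain
  PDB fixtures whose cofactor distances equal prescribed targets to
  better than 10⁻⁶ Å, so the whole pipeline is testable without downloads.

Kabsch superposition, domain RMSD and rigid cofactor transfer (placing a
crystallographic heme/FMN/FAD into an apo predicted domain) are included for
working with real structures.

## Worked example

```sh
$ redoxpath simulate --scenario wt-dimer --seed 3 --out-dir fx
$ redoxpath analyze fx/wt-dimer.pdb --topology homodimer --form wt --out-dir res
source: wt-dimer.pdb  topology: homodimer
model: beta = 1.0597 1/A, A0 = 2e+12 1/s
anchor check OK: k(30 Å) = 0.0312 s^-1 vs 0.03 s^-1 (ratio 1.042, allowed x/1.2)
routes (monomer indices follow chain order in the file):
  [intra-1 ] FAD1 -> FMN1  15.00 A   k_et =    2.5e+05 1/s
  [intra-1 ] FMN1 -> HEM1  30.00 A   k_et =     0.0312 1/s *limiting*
  [intra-2 ] FAD2 -> FMN2  15.00 A   k_et =    2.5e+05 1/s
  [intra-2 ] FMN2 -> HEM2  30.00 A   k_et =     0.0312 1/s *limiting*
  [cross-1 ] FMN1 -> HEM2  47.00 A   k_et =   4.69e-10 1/s *limiting*
  [cross-2 ] FMN2 -> HEM1  48.00 A   k_et =   1.63e-10 1/s *limiting*
principal pathway: intra-1 (chain k_et = 0.0312 1/s)
naive single-jump rate over the summed path: 3.91e-09 1/s (rejected)
rejected cross routes: cross-1, cross-2
k_et vs k_cat: 0.0312 vs 0.03 1/s (ratio 1.04) -> consistent
```

Reading: the wild-type homodimer's ET chain is limited by the 30 Å
FMN1→HEME1 gap, giving k_et ≈ 0.03 s⁻¹ — consistent with the measured
turnover of 0.03 s⁻¹ — while the 47/48 Å cross-monomer routes are orders of
magnitude too slow and are rejected. Treating the whole FAD→heme path as a
single tunnelling jump (the "naive" number) underestimates the rate by seven
orders of magnitude, which is why the hopping picture with the limiting link
is used. `redoxpath calibrate`, `distances` and `equilibrium` expose the
individual stages; results also land in `res/` as TSV tables and a YAML
summary.

The same pipeline runs on real predicted or experimental structures: pass
any PDB with HEM/FMN/FAD hetero groups (or use `transfer_cofactor` to place
cofactors from reference domains into an apo model first).

## Configuration

Every constant (calibration points, anchor, domain ranges, K_D, k_cat per
form, thresholds) lives in the built-in profile
`src/redoxpath/data/default_config.yaml` and can be overridden with
`--config my.yaml` (unknown keys are rejected). See `docs/methods.md` for
the model assumptions, parameter choices and known limitations.
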