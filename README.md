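# mutscape

Computational prioritisation of enzyme mutations that change catalytic
activity, built around the workflow used to engineer chalcone–flavonone
isomerase (CHI) variants: sequence analysis proposes candidate sites,
structural screening narrows them, and a docking-landscape comparison
predicts the direction of each mutation's effect on activity.

## Who this is for

Protein engineers and computational biologists who already have the heavy
external computations in hand — a multiple sequence alignment, a
branch-site positive-selection analysis (e.g. codeml BEB output), a
receptor structural model, and AutoDock-style docking-pose ensembles —
and need the analysis layer that turns those artifacts into a ranked list
of mutations with predicted effects.

## The method

1. **Subfamily-specific positions (SSPs).** Given an alignment split into
   two functional subfamilies (for CHI: legume-specific type-II enzymes,
   group 1, versus type-I enzymes, group 2), an SSP is a column conserved
   within each group but different between groups. Sites are reported in
   the numbering of a chosen reference sequence.
2. **Positively selected sites.** Per-site posterior probabilities
   P(ω > 1) from a branch-site model are thresholded (default posterior
   > 0.95); these unconserved-but-selected sites complement the SSPs. The
   union of both lists is the candidate-site set.
3. **Structural screen.** A candidate is retained when any heavy atom lies
   within 10 Å of the catalytic residues (or a bound reference ligand) and
   its side chain does not hydrogen-bond directly into the catalytic
   network (heavy-atom N/O–N/O ≤ 3.5 Å), since mutating a network member
   risks breaking the catalytic geometry.
4. **Mutation panel.** Each retained site gets one representative
   substitution per side-chain class — non-polar (Ala), aromatic (Phe),
   polar (Gln), basic (His), acidic (Glu) — with a within-class alternate
   when the wild type already belongs to the class (Glu→Asp, Gln→Asn,
   Arg→His), plus proline for loop sites.
5. **Docking landscape and the group-III rule.** For each receptor variant,
   every docked pose of the substrate is compared to the product's binding
   pose by receptor-frame RMSD over matched heavy atoms — **no
   superposition**, both poses live in the fixed receptor frame. Plotting
   binding energy against that RMSD resolves the ensemble into groups:
   near-product groups I–III in descending representative energy
   (E(I) > E(II) > E(III); group I is the initial encounter pose, group
   III the lowest-energy, transition-like pose) and a flipped-orientation
   group IV at RMSD > 6 Å. The group representative is its lowest-energy
   pose. The decision rule compares group-III representatives:

   ΔE(III) = E_mut(III) − E_wt(III);
   ΔE(III) < −ε ⇒ beneficial, ΔE(III) > +ε ⇒ detrimental, else neutral
   (default ε = 0.5 kcal/mol).

A synthetic-data module generates every input with planted ground truth —
subfamily MSAs with known SSP columns, selection tables with separated
posteriors, toy receptors, and 2,000-pose ensembles with planted RMSD
modes and group-III energy shifts — so the whole pipeline is testable end
to end without downloads.

## Worked example

Generate a synthetic wild-type ensemble plus six mutants with planted
group-III shifts, build two landscapes, and apply the decision rule:

```sh
mutscape simulate ensemble --out demo --seed 11 --n-poses 2000
mutscape landscape --poses demo/wild-type.dlg --reference demo/reference_pose.pdb -o demo/wt
mutscape landscape --poses demo/I197P.dlg   --reference demo/reference_pose.pdb -o demo/I197P
mutscape compare --wt demo/wt_groups.json --mut demo/I197P_groups.json
```

Output of the wild-type `landscape` call:

```
group I: n=587 rep rmsd=0.47 Å energy=-5.76 kcal/mol
group II: n=535 rep rmsd=1.86 Å energy=-6.78 kcal/mol
group III: n=509 rep rmsd=3.48 Å energy=-7.79 kcal/mol
group IV: n=369 rep rmsd=7.39 Å energy=-7.23 kcal/mol
```

The four groups land on the planted RMSD modes (0.5/1.8/3.5/7.5 Å) with
the expected energy ordering: the flipped group IV representative sits
beyond 6 Å, and the near-product groups descend in energy from I to III.
The comparisons then read:

```
$ mutscape compare --wt demo/wt_groups.json --mut demo/I197P_groups.json
delta_e_iii=-1.450 kcal/mol verdict=beneficial
$ mutscape compare --wt demo/wt_groups.json --mut demo/R110H_groups.json
delta_e_iii=+0.960 kcal/mol verdict=detrimental
```

The I197P ensemble was planted with a −1.5 kcal/mol group-III shift and
R110H with +1.0, so the recovered ΔE(III) values and verdicts match the
planted effects. With real docking logs the same two commands take
AutoDock DLG files (or multi-MODEL PDB + energy TSV via `--energies`)
and a product pose PDB. `mutscape run --config run.yaml --out results/`
chains all stages from a single YAML config and writes a ranked report.

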