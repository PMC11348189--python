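# capscan

Detection and quantification of **disorder-to-order active-site capping** in
protein structural ensembles.

Many enzymes gate access to their catalytic cavity with a mobile structural
element — typically a short α-helix — that is folded ("capped") in some
conformational states and disordered or displaced in others. Myo-inositol-1-
phosphate synthase (MIPS) is a prominent example: a ~16-residue helical
domain at the entry of the active site is folded in one substate, absent
(unfolded) in the majority substate, and back-folded ~8 Å away in a third.
`capscan` gives structural biologists a reproducible way to detect such
folding events across an ensemble of coordinate models of the same protein
and to quantify their consequences.

Given an ensemble of PDB/mmCIF models (deposited structures, cryo-EM
substate models, predicted ensembles) mapped onto one reference sequence,
the pipeline:

1. assigns per-residue secondary structure from Cα geometry alone
   (P-SEA-style distance/dihedral criteria), so backbone-only and
   full-atom models are treated uniformly;
2. builds an **order matrix** `M[position, member] ∈ {H, O, D}` (helix,
   ordered non-helix, disordered/missing);
3. calls **folding events**: maximal runs (length ≥ 5) of positions where
   the member fraction with H is ≥ θ_H and the fraction with D is ≥ θ_D
   (defaults 0.15 each);
4. assigns each member to **folded / unfolded / alternative** states —
   unfolded when the event segment's helicity is undefined or < 0.3, and
   otherwise folded vs. alternative by the segment's mean Cα displacement
   (after Kabsch superposition on the shared core) against a 4 Å threshold —
   and reports the ensemble state fractions;
5. tests whether the AlphaFold **pLDDT profile dips locally** at each event:
   the statistic Δ = mean pLDDT(segment) − mean pLDDT(flanks) is compared
   with a sliding-segment permutation null,
   p = (1 + #{Δ_null ≤ Δ_obs}) / (n_perm + 1);
6. quantifies site geometry: segment displacement, named atom distances
   (e.g. the C1–C6 distance of an acyclic intermediate), ion coordination
   shells, grid-based pocket volume with small/large probe radii
   (defaults 1.4 / 3.4 Å), and Shrake–Rupley SASA / buried interface areas.

A seeded synthetic-ensemble generator with planted ground truth
(`capscan.synthetic`) makes every stage testable end to end without any
downloads.

## Worked example

Generate an ensemble at the default study conditions — 100 members of a
552-residue chain, event segment 385–400, state fractions 0.23/0.69/0.08,
8 Å alternative-state displacement, first 39 residues unresolved — and run
the screen:

```python
import capscan as cs

spec = cs.EnsembleSpec(seed=7)          # 100 members, 23/69/8%, event 385-400
ens = cs.make_ensemble(spec)
maps = [cs.map_to_reference(m, "A", ens.reference_sequence) for m in ens.members]

matrix = cs.build_order_matrix(ens.members, maps)
event = cs.detect_folding_events(matrix)[0]
print("event:", event.segment, f"helical {event.helical_members:.2f}, disordered {event.disordered_members:.2f}")

states = cs.classify_states(ens.members, maps, event)
print("state fractions (folded, unfolded, alternative):", states.fractions)

i, j = states.labels.index("folded"), states.labels.index("alternative")
mean_d, max_d = cs.segment_displacement(ens.members[i], ens.members[j], maps[i], maps[j], event.segment)
print(f"helix displacement: mean {mean_d:.2f} A, max {max_d:.2f} A")

profile = cs.make_plddt(cs.PlddtSpec(dip_depth=5.0, seed=8), spec.chain_length)
dip = cs.plddt_dip_test(profile, event.segment, seed=9)
print(f"pLDDT dip: delta {dip.delta:.2f}, p = {dip.p_value:.4f}")
```

Output:

```
event: (385, 400) helical 0.31, disordered 0.69
state fractions (folded, unfolded, alternative): (0.23, 0.69, 0.08)
helix displacement: mean 8.00 A, max 8.00 A
pLDDT dip: delta -5.26, p = 0.0010
```

The caller recovers the planted event at exactly residues 385–400: 31% of
members model it as a helix (the 23% folded plus 8% alternative states), 69%
lack it entirely, the alternative helix placement sits 8.0 Å from the folded
one, and the synthetic pLDDT profile shows a significant localized dip.

The same analysis runs from the shell on files:

```sh
capscan simulate --config spec.json --seed 7 --out sim/     # PDBs + truth
capscan screen   --config run.json  --seed 7 --out report/  # events + states
capscan geometry --model site.pdb --selections sel.json --out geo.json
capscan report   --report report/report.json
```

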