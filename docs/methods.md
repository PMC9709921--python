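# Methods notes

## Model and assumptions

The package treats protein–ligand complex stability as the persistence of
a *binary interaction pattern* under a thermal ramp. Three assumptions
follow:

1. The equilibrated pose defines the reference pattern. The reference
   fingerprint is computed from the final equilibration frame; everything
   afterwards is scored relative to it. A pose that rearranges into a
   different but stable binding mode scores poorly by construction — the
   method measures conservation of the *native* mode, not affinity.
2. Coordinates are absolute and the ligand–protein pair is imaged
   together. Periodic-box wrapping is the MD backend's duty; all analysis
   is plain Cartesian geometry in Angstrom.
3. The statistic is qualitative. The MS coefficient ranks complexes and
   supports a binary tight/weak call against a cutoff; it is not a binding
   free energy, an off-rate, or a residence time.

## Fingerprint channels and geometric criteria

Eight channels per receptor residue, bits not counts. Defaults (every
value is a config key under `interactions:`):

| channel | criterion | default |
|---|---|---|
| HY | hydrophobic-atom pair distance | ≤ 4.0 Å |
| F2F | ring-centroid distance; normal angle | ≤ 4.5 Å; ≤ 30° |
| E2F | ring-centroid distance; normal angle | ≤ 5.5 Å; 60–90° |
| HB_PD / HB_PA | donor–acceptor distance; D–H···A angle | ≤ 3.5 Å; ≥ 130° |
| SB_PP / SB_PN | cationic–anionic group atom distance | ≤ 4.0 Å |
| MET | metal–acceptor distance | ≤ 2.8 Å |

These mirror widely used open-source interaction-fingerprint conventions
so scores are comparable across pipelines. Perception is geometric and
deterministic: bonds from interatomic distances, aromatic rings as planar
(≤ 0.1 Å out-of-plane) 5/6-rings, hydrophobic atoms as C/S bonded only to
C/H/S, charged groups from residue templates (Arg/Lys/His⁺, Asp/Glu,
C-terminal carboxylate) on the protein and from partial charges or
carboxylate/phosphate/sulfonate patterns on the ligand. Atoms of charged
groups are removed from the donor/acceptor pools so a salt bridge is not
double-counted as a hydrogen bond. When a side carries no hydrogens the
H-bond test degrades gracefully to the heavy-atom distance criterion,
with donors identified by free valence.

Two design choices were genuinely open:

- **Metal channel row.** The fingerprint is indexed by receptor residues,
  but the metal-coordination channel involves an ion. Metal-ion residues
  are therefore included in the residue order (receptor = protein + metal
  ions, in file order). Systems without metals are unaffected.
- **Null-vector cosine.** The cosine is undefined for a query with no set
  bits; it is defined here as 0, consistent with the semantics of total
  interaction loss. The score itself is computed from integer bit sums,
  with the −1 endpoint returned exactly when the query preserves the
  reference pattern, so "fully retained" and "fully lost" are exact
  floating-point endpoints rather than approximations.

## Protocol numerics

- Ramp default 300 → 450 K, +10 K, 10 ns windows (16 windows). No partial
  window beyond `t_end` is generated.
- Termination: the step average IFP_CS is "null" when ≥ −ε with
  ε = 1e-4 (config key). A float-safe equality to zero; termination is
  monotone in ε.
- Window chaining: each window starts from the previous window's final
  coordinates with velocities re-thermalized at the new temperature
  (standard NVT re-thermalization; the schedule's own convention).
- Seeds: one master seed per replicate; per-window sub-seeds derive
  deterministically via `numpy.random.SeedSequence([master, window])`,
  so a run replays bit-identically with the synthetic backend.
- Frame saving period defaults to 100 ps within a 10 ns window (100
  frames); the scoring stride defaults to every saved frame.
- RMSD series fit each frame onto the equilibrated reference over the
  protein backbone (N, CA, C, O) by least-squares rigid superposition
  (Kabsch); ligand RMSD is measured over ligand heavy atoms after that
  backbone fit. Degenerate (collinear/coincident) fit selections raise a
  geometry error. The fold monitor flags steps whose maximum backbone
  RMSD exceeds a threshold (default 5 Å); it never stops a run.

## MS coefficient and aggregation

MS = (⟨IFP_CS⟩_end + 1)/(T_end − T_start), with T_end the last explored
temperature; units K⁻¹, always ≥ 0, equal to 0 iff the final step still
averages −1. With the default ramp the largest reachable value is
1/ΔT = 0.1 K⁻¹ (total loss in the very first 10 K step), so the nominal
upper bound of 1 is not attainable; only non-negativity is enforced.
A one-window ramp that terminates at the starting temperature leaves the
slope undefined and raises.

Aggregation: five replicates per ligand; exactly one minimum and one
maximum occurrence are discarded (also with duplicated extremes) and the
remaining three averaged. Classification: tight iff aggregate MS is
strictly below the 0.004 K⁻¹ cutoff — the boundary value is assigned to
weak. The representative replicate is the one nearest the aggregate, ties
to the lowest index with a small relative tolerance so exact equidistance
is not decided by rounding. Protomer combination is a weighted mean with
weights summing to 1.

## Energy decomposition

Per-residue ligand interaction energies are plain pairwise nonbonded
terms: Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot
combination, and Coulomb k·qᵢqⱼ/r with k = 332.06 kcal·Å/mol/e², both
truncated at the simulation's 9.0 Å cutoff. No Ewald/PME and no
switching function in analysis: residue-wise sums are then exactly equal
to the undecomposed whole-protein ligand energy, which the tests assert
to 1e-8 kcal/mol. Parameters come from the structure's per-atom
charge/LJ table; missing parameters raise with the offending serials.
"Most contacted" residues (heat-map rows) are ranked by the number of
frames with any fingerprint bit set for that residue, ties broken by
residue order.

## What the synthetic generator does and does not emulate

The generator reproduces the *observable* the method consumes — per-frame
fingerprint dynamics — not physics. The toy complex is a ten-residue
pocket engineered so its reference pose sets seven bits across six
channels; thermal motion is isotropic Gaussian jitter resampled about the
pose with σ(T) = σ₀·T/300 K and σ₀ = 0.3 Å, chosen so the engineered
contacts (margins 0.3–1.0 Å below their cutoffs) persist to 450 K with
high per-frame retention; unbinding is a scripted 18 Å translation along
an exit vector at a chosen window, which exceeds every channel cutoff at
once. Consequently passing end-to-end tests demonstrates that the
protocol, scoring, slope and aggregation machinery recover a known
tight/weak distinction from fingerprint time series — they say nothing
about force fields, kinetics, solvent, conformational strain, or the
gradual multi-step unbinding of real trajectories. Replicate spread on
the toy system is far narrower than in real MD for the same reason.

Desk-scale problem sizes used throughout the tests and the acceptance
study — a 76-atom complex, 100 frames per window, 5 replicates, 20
seeded replicate sets — are the package's own default study conditions
for the synthetic backend; real applications substitute an external
engine behind `EngineContract` at whatever scale that engine provides.

## Known limitations

- Feature perception is heuristic (no bond orders, no pKa model): exotic
  ligand chemotypes may need explicit partial charges in the parameter
  table for correct cation/anion perception.
- Halogen bonds, cation–π and water-bridged interactions are not among
  the eight channels and are deliberately out of scope.
- The external-engine adapter is a contract, not an implementation:
  minimization, restrained equilibration and thermostats belong to the
  backend.
- Retained crystallographic waters carry `role='water'` and are kept
  through I/O, but they do not contribute fingerprint channels; only
  direct protein(or metal)–ligand contacts are encoded.
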