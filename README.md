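# ttmd — thermal titration molecular dynamics

`ttmd` estimates the *qualitative stability* of a protein–ligand complex
from how long its native binding mode survives a series of short MD
windows run at stepwise increasing temperatures. It is aimed at
computational medicinal chemists who want a cheap, unbiased-MD proxy for
binding-mode persistence (a stand-in ranking for residence time) without
free-energy or enhanced-sampling machinery.

## The method

**Interaction fingerprints.** For every trajectory frame, each receptor
residue is encoded into 8 bits, one per interaction type with the ligand:
hydrophobic contact (HY), aromatic face-to-face (F2F) and edge-to-face
(E2F) stacking, hydrogen bonds with the protein as donor (HB_PD) or
acceptor (HB_PA), salt bridges with the protein positive (SB_PP) or
negative (SB_PN), and metal coordination (MET). A complex with *r*
receptor residues yields a binary vector of length *r* × 8.

**IFP_CS scoring.** Each frame's fingerprint **q** is compared against the
reference fingerprint **ref** of the equilibrated pose (the last
equilibration frame) by negated cosine similarity:

    IFP_CS = − (q · ref) / (‖q‖ ‖ref‖)   ∈ [−1, 0]

−1 means the frame reproduces every interaction determinant of the
reference; 0 means all of them are lost.

**The titration protocol.** Fixed-length NVT windows ("TTMD steps",
default 10 ns) are run at temperatures 300, 310, …, 450 K. After each
window the mean IFP_CS is computed; if it is null — the native binding
mode was never sampled during the step — the run terminates, otherwise
the next window starts from the previous window's final frame. Protein
fold integrity is monitored (advisory only) through the backbone RMSD.

**The MS coefficient.** The titration profile plots the per-step mean
IFP_CS against step temperature. The MS coefficient is the slope of the
straight line joining the initial state and the final step:

    MS = (⟨IFP_CS⟩_end − (−1)) / (T_end − T_start)    [K⁻¹]

where `T_end` is the last *explored* temperature. MS = 0 means the binding
mode survived the whole ramp; early unbinding gives large MS. Five
independent replicates are run per ligand; their MS values are averaged
after discarding the highest and the lowest, and the complex is labelled
**tight** (aggregate MS < 0.004 K⁻¹) or **weak** (≥ 0.004 K⁻¹). When a
ligand's protonation state is ambiguous, per-protomer aggregates can be
combined with user weights (e.g. 50/50).

Real MD engines plug in behind a two-method `EngineContract`
(`equilibrate`, `run_window`). The package ships a deterministic synthetic
backend that emulates the fingerprint dynamics of a stable binder, a
scripted unbinder, and a partial unfold, so the entire pipeline runs on a
desk machine.

## Worked example

```python
from ttmd import TTMD
from ttmd.synthetic import make_toy_complex, SyntheticEngine, SyntheticScenario

system = make_toy_complex(seed=0)
model = TTMD(system, engine=SyntheticEngine(SyntheticScenario("unbinder", unbind_window=3)))
res = model.fit(seed=1)
print(res.summary())
```

```
Thermal Titration MD results
================================================================
residues:   10    ligand atoms:   12    reference bits: 7
ramp: 300 -> 450 K, +10 K / 10 ns (16 windows)
----------------------------------------------------------------
step    T (K)   <IFP_CS>  max bb RMSD   fold
   1    300.0    -0.9762         0.60     ok
   2    310.0    -0.9717         0.63     ok
   3    320.0     0.0000         0.61     ok
----------------------------------------------------------------
terminated early: True    last temperature: 320 K
MS coefficient: 0.050000 K^-1  (final <IFP_CS> = 0.0000 at 320 K)
single-run label at cutoff 0.004: weak
================================================================
```

The scripted unbinder expels the ligand in window 3: the step average
IFP_CS goes null, the run terminates at 320 K, and the MS coefficient is
(0 + 1)/(320 − 300) = 0.05 K⁻¹ — far above the 0.004 K⁻¹ cutoff, hence a
weak binder. The full five-replicate protocol and classification:

```python
rs, _ = model.fit_replicates(n_replicates=5, master_seed=1, ligand_id="toy-unbinder")
# ReplicateSet(ligand_id='toy-unbinder', ms_values=(0.05, 0.05, 0.05, 0.05, 0.05),
#              aggregate_ms=0.05, retained=(2, 3, 4), representative=0,
#              label='weak', cutoff=0.004)
```

`res.plot(out_dir)` writes the three standard figures: the titration
profile with its interpolating slope, the time-resolved per-residue
interaction-energy heat map (up to the 25 most contacted residues), and
ligand/backbone RMSD plus IFP_CS against time.

## Command line

```bash
ttmd fixtures --seed 2 --out fx          # toy PDB + parameter table + trajectory
ttmd run --config cfg.yaml --out lig1    # 5-replicate protocol, text artifacts
ttmd analyze lig1/rep_1                  # profile, MS, plots from saved artifacts
ttmd aggregate lig1 --out results.csv    # ligand-level results table
```

## Layout

- `ttmd.core` — structures, PDB/trajectory I/O, superposition, RMSD
- `ttmd.fingerprints` — feature perception and the r × 8 fingerprint
- `ttmd.scoring` — IFP_CS and window averaging
- `ttmd.protocol` — temperature ramp, engine contract, termination rule
- `ttmd.analysis` — titration profile, MS coefficient, energy decomposition, plots
- `ttmd.aggregation` — trimmed-mean replicates, protomer weighting, classification
- `ttmd.synthetic` — toy complex and scripted backend
- `ttmd.model` — `TTMD` / `TTMDResults` front end; `ttmd.cli` — the CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
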