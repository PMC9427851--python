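# pcsgrid

Pseudocontact-shift (PCS) analysis of interdomain geometry in
lanthanide-tagged two-domain proteins.

When a paramagnetic lanthanide (e.g. Dy³⁺) is chelated by a tag engineered
into one domain of a protein, every NMR-observable nucleus acquires a
pseudocontact shift

```
δ_pcs = (1 / 12π r⁵) · Σᵢⱼ Δχᵢⱼ (3 rᵢ rⱼ − r² δᵢⱼ)      [ppm]
```

where **r** is the ion→nucleus vector and Δχ is the anisotropic part of the
ion's magnetic susceptibility tensor (3×3 symmetric traceless, 5 free
components, m³). PCSs decay as r⁻³ and carry orientation information, so
methyl PCSs measured in *both* domains of a two-domain construct constrain
the relative domain orientation. `pcsgrid` implements the full workflow for
sparsely ¹³C-methyl-labeled (Ala/Val) proteins:

1. **Peak pairing** — extract PCSs from diamagnetic/paramagnetic 2D HETCOR
   peak lists using the 1:1 relation (the ¹H and ¹³C PCSs of one methyl are
   equal in ppm), solved as an exact minimum-cost matching with decoy
   rejection.
2. **Resonance assignment** — match methyl spin systems (Cγ/Hγ + TOCSY
   Hβ/Hα) to per-residue predicted shifts under mutagenesis force/forbid
   constraints, via the Hungarian algorithm with a brute-force-verified
   optimum.
3. **Tensor fit** — solve the linear system M·Δχ = P by least squares over
   the tagged domain's methyls (n ≥ 5), optionally pooling ligand-bound and
   unbound datasets; report principal values/axes and the fit Q-factor.
4. **Orientation grid search** — rotate the mobile domain rigidly about a
   linker pivot through a ZXZ Euler grid (defaults: α, γ ∈ [−90°, 90°],
   β ∈ [0°, 180°], 50 values per angle = 125,000 orientations), score every
   orientation with

   ```
   Q = Σ(PCS_obs − PCS_calc)² / Σ(PCS_obs)²
   ```

   and report the optimum, the top-20 ensemble, and contour-map slices.
5. **Synthetic data** — generate toy two-domain structures, planted tensors
   and rotations, noisy PCS tables, peak lists and shift predictions with
   ground-truth sidecars, so every stage is testable without experimental
   data.

## Worked example

Simulate a dataset whose mobile domain was rotated by ZXZ angles
(−40°, 30°, 55°) in the ligand-bound state, fit the tensor to the tagged
domain (both conditions pooled), and search orientations:

```bash
pcsgrid simulate --seed 7 --planted-rotation -40 30 55 --out data
pcsgrid fit-tensor --pcs data/pcs_unbound.tsv --pcs data/pcs_bound.tsv \
    --structure data/structure.pdb --out fit
pcsgrid grid-search --structure data/structure.pdb --pcs data/pcs_bound.tsv \
    --tensor fit/tensor.json --condition bound --n 25 --out grid
pcsgrid pair-peaks --dia data/peaks_dia.list --para data/peaks_para.list --out pairs
```

which prints

```
fit n=48 Q=6.796e-05 principal values (m^3): -4.35e-32, -3.36e-31, 3.8e-31
best orientation alpha=-37.5 beta=30.0 gamma=52.5 Q=0.004235 over 15625 orientations
24 pairs, 3 unmatched paramagnetic peaks
```

The 48-row pooled fit recovers the planted principal values
(−4.3, −34, 38.3)×10⁻³² m³ to within the 0.01 ppm measurement noise; the
grid minimum lands within one grid spacing (7.5° at 25 values per angle) of
the planted rotation; peak pairing recovers all 24 methyls and rejects the
3 decoy paramagnetic peaks. `grid/` also contains the full Q grid
(`grid.tsv`), the 20 best models as a multi-model PDB with a Q manifest,
and a contour slice over (α, β) at the optimal γ for plotting.

The same pipeline runs on experimental inputs: a PDB model with the
modelled ion (HETATM), tab-separated PCS tables, Sparky-style peak lists,
and predicted-shift tables (e.g. ShiftX2 output).

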