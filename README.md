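# dnaintercal

Thermodynamic and structural analysis of small-molecule–dsDNA
intercalation, built around the multi-technique workflow used to
characterise anthracycline (doxorubicin-type) binding: UV-Vis and
fluorescence titrations, time-resolved fluorescence, isothermal
titration calorimetry, umbrella-sampling free-energy profiles, and
conformational clustering.  It is intended for experimentalists fitting
titration or calorimetry tables, and for simulators post-processing
umbrella windows and conformer ensembles, who want one consistent,
tested toolchain with explicit units and cross-method consistency
checks.

## What it computes

**Absorbance titrations** — the association constant from the
Benesi–Hildebrand linearization

    A0/(A − A0) = eps_f/(eps_b − eps_f) + eps_f/(eps_b − eps_f) · 1/(K_A [DNA])

with `K_A = intercept/slope` and `ΔG = −RT ln K_A`.

**Fluorescence quenching** — Stern–Volmer (`F0/F = 1 + K_SV[Q]`,
`k_q = K_SV/τ0`), static-vs-dynamic mechanism classification against the
2.0×10¹⁰ M⁻¹s⁻¹ diffusion-collision ceiling, Lineweaver–Burk
(`F0/(F0−F) = 1 + K_D/[Q]`) and the double-log plot
(`log[(F0−F)/F] = log K_A + n log[Q]`) for the binding-site number.

**Lifetimes** — Poisson maximum-likelihood monoexponential fits of
TCSPC histograms with standard errors from the observed information.

**ITC** — simulation and nonlinear fitting of the single-set-of-
identical-sites (Wiseman) isotherm over `(n, logK, ΔH)`, with overflow-
cell dilution bookkeeping, blank subtraction, and the decomposition
`ΔG = −RT ln K = ΔH − TΔS`.

**Free-energy profiles** — self-consistent WHAM over harmonic umbrella
windows on a scalar intercalation coordinate, with connectivity
diagnostics, plateau referencing, and well-depth extraction.

**Structures** — Kabsch superposition, hybrid k-centers/k-medoids
clustering under an RMSD cutoff, cluster populations, closest-phosphate
distances, and chromophore rotation angles from multi-model PDB
ensembles.

A synthetic-data module generates every input class from known ground
truth (titrations, decays, isotherms, Metropolis-sampled umbrella
windows, labelled conformer ensembles), so each estimator has a
parameter-recovery test surface.  See `docs/methods.md` for models,
conventions, and limitations.

## Worked example

Generate a synthetic titration study at the conditions of the emulated
experiments (18 µM ligand vs ≤1.9 µM dsDNA for absorbance; 5–75 nM
titrant for quenching) and fit it:

```bash
$ dnaintercal simulate --out demo --seed 1 --stages uvvis,fluorescence
wrote fixtures and demo/pipeline.yaml

$ dnaintercal fit-uvvis demo/uvvis_DOX.csv
{
  "K_A_per_M": 1075655.609430442,
  "delta_G_kcal_mol": -8.219568202673722,
  "r_squared": 0.999848225562812
}

$ dnaintercal fit-fluor demo/quench_DOX.csv --tau0 1.057
{
  "K_SV_per_M": 11003911.097335666,
  "k_q_per_M_s": 1.0410511918009146e+16,
  "mechanism": "static",
  "K_A_LB_per_M": 10980495.56072422,
  "n_sites": 1.001354635347893,
  "log_K_A": 7.051211938935323
}
```

The absorbance fit recovers the generator's association constant
(1.10×10⁶ M⁻¹ truth; the residual deviation is the injected noise) and
converts it to a binding free energy of −8.2 kcal/mol.  The quenching
fit returns an apparent bimolecular rate of ~10¹⁶ M⁻¹s⁻¹ — five orders
of magnitude above the diffusion ceiling, hence the `static` call
(ground-state complexation, not collisions) — and a double-log slope of
~1.0, i.e. one binding site per duplex, with the three linearizations
agreeing on `K_A ≈ 1.1×10⁷ M⁻¹`.

`dnaintercal run-all --config demo/pipeline.yaml --out report.json`
executes every configured stage and writes a report whose consistency
section verifies each `ΔG = −RT ln K` identity and the cross-method
affinity ordering.  The same functionality is available as a library
(`dnaintercal.uvvis`, `.quenching`, `.itc`, `.wham`, `.clustering`,
`.synthetic`, `.pipeline`).

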