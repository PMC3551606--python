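# foldshift

Quantitative analysis of pH-driven disorder-to-order transitions in small
propeptide-like cysteine-protease inhibitors — proteins such as *Drosophila*
crammer, a 79-residue cathepsin inhibitor that is a molten globule at pH 4.0
and folds into an ordered, inhibition-competent structure at pH 6.0.
`foldshift` turns the raw spectroscopy and enzymology of an alanine-scanning
study of such a protein into numbers:

* **Thermal stability** — two-state fits of far-UV CD melts (signal at
  208 nm, 4–96 °C) with linear folded/unfolded baselines and a van't Hoff
  free energy:

  *y*(T) = [(Y<sub>n</sub> + M<sub>n</sub>T) + (Y<sub>d</sub> + M<sub>d</sub>T)·K(T)] / (1 + K(T)),
  K(T) = exp(−ΔG(T)/RT), ΔG(T) = ΔH(1 − T/T<sub>m</sub>)

  yielding ΔH, T<sub>m</sub>, ΔS = ΔH/T<sub>m</sub>, ΔG<sub>u</sub>(T), the
  fraction unfolded, and ΔΔG<sub>u</sub> between constructs.
* **Salt-bridge coupling** — double-mutant-cycle interaction energies
  ΔΔG<sub>int</sub> = ΔG<sub>wt</sub> − ΔG<sub>m1</sub> − ΔG<sub>m2</sub> + ΔG<sub>dm</sub>
  (positive = the two side chains couple favourably).
* **Folding readout by fluorescence** — tryptophan emission maxima
  (λ<sub>max</sub>, F<sub>max</sub>) and the pH 4→6 blue shift
  MEWD = λ<sub>max</sub>(pH 4) − λ<sub>max</sub>(pH 6), which reports
  tryptophan burial on folding.
* **Function** — cathepsin-inhibition metrics from fluorogenic (AMC-release)
  progress curves: initial rates, residual activity %, dose series with
  interpolated IC50, and E-64 active-site titration of enzyme concentration.
* **Sequence conservation** — scanning of the conserved propeptide aromatic
  motif `W-x(2)-[FYW]-x(3)-[FY]-x(3)-Y-x(12)-[FYW]` (PROSITE-like grammar,
  exact gaps) against FASTA files, alignments included.

Because studies of this kind rarely deposit raw spectra, the package ships a
first-class synthetic-data generator (`foldshift.synthetic_data`) that
emulates each acquisition mode — two-state melts on the 4–96 °C / 2 °C grid,
Gaussian emission peaks on 290–400 nm / 0.5 nm, linear progress curves —
so every stage of the pipeline is exercised end to end with known ground
truth. See `docs/methods.md` for models, defaults and caveats.

## Worked example

Simulate a lightly noisy melt for a C72S-like construct (ΔH = 40 kcal/mol,
T<sub>m</sub> = 58 °C) and refit it:

```bash
foldshift simulate melt --seed 1 --out melt_C72S.tsv \
    --param dH=40 --param Tm_c=58 --param noise_frac=0.02
foldshift fit-melt melt_C72S.tsv --variant C72S --ph 6.0 --tref-c 20
```

prints (abridged):

```
dH_kcal_per_mol      43.139
Tm_C                 58.038
dS_kcal_per_mol_K    0.13026
rmse_signal          0.08446
converged            True
cooperative          cooperative
dG_u_kcal_per_mol    4.9547
fraction_unfolded    0.00020236
```

At 2% amplitude noise the fit recovers the true midpoint to 0.04 °C; ΔH is
the softer parameter (here 8% high), which is why derived ΔG<sub>u</sub>
values carry most of their uncertainty through ΔH. The fraction unfolded at
20 °C (~2×10⁻⁴) says the construct is essentially fully folded there.

The same round trip in Python:

```python
from foldshift import synthetic_data, cd_thermo, fluor_shift

curve = synthetic_data.gen_melt(dH=40.0, Tm_c=58.0, noise_frac=0.02, seed=1)
fit = cd_thermo.fit_two_state(curve)
print(fit.tm_c)            # 58.04

s4 = synthetic_data.gen_emission(336.5, 1373.3, variant="C72S", ph=4.0)
s6 = synthetic_data.gen_emission(326.5, 1527.4, variant="C72S", ph=6.0)
print(fluor_shift.mewd(s4, s6).mewd)   # 10.0  (blue shift, nm)
```

A full panel is driven by `foldshift run --config run.yaml` over a variant
manifest; it writes a per-variant summary table (T<sub>m</sub>, λ<sub>max</sub>
and F<sub>max</sub> at both pH values, MEWD, residual activity), per-variant
fit JSON documents and double-mutant-cycle results.

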