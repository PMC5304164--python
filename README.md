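# augerdna

Quantitative evaluation of DNA-intercalating Auger-emitter
radioconjugates.

Auger-emitting radionuclides (e.g. ⁹⁹ᵐTc, ¹²⁵I) release a cascade of
very-low-energy electrons per decay with sub-cell ranges; anchored next
to the DNA double helix by an intercalator such as acridine orange,
they can produce double-strand breaks (DSBs) with high local
efficiency.  `augerdna` implements the full in-vitro/in-silico analysis
chain used to evaluate such conjugates:

1. **Cumulated-decay accounting** — converts initial activities and
   incubation schedules into accumulated decays per mL:
   N(T) = (A₀/λ)(1 − e^{−λT}), λ = ln2/T½.
2. **Plasmid strand-break analysis** — supercoiled (SC) → open-circular
   (OC) conversion marks a single-strand break, SC → linear (Lin) a
   DSB.  With Poisson break statistics,
   f_SC = e^{−(μ_SSB+μ_DSB)} and f_Lin = μ_DSB·e^{−μ_DSB};
   inverting gel densitometry fractions lane by lane and regressing
   μ_DSB on decays/mL gives D₀ = 1/slope (decays per mL per DSB) and
   the yield Y(DSB) = ρ_plasmid/D₀ per decay.  Running ± the radical
   scavenger DMSO splits Y into direct and indirect components.
3. **DNA-binding isotherms** — fluorescence titrations fitted with a
   saturable hyperbola (Kaminoh-style) and with the McGhee–von Hippel
   neighbor-exclusion isotherm
   r/C_f = K(1 − nr)[(1 − nr)/(1 − (n−1)r)]^{n−1},
   solved self-consistently with ligand mass balance; optional
   inner-filter correction I·10^{(A_ex+A_em)/2}.
4. **Nanodosimetric Monte Carlo** — event-by-event electron transport
   in liquid water from a point Auger source at distance d from a
   10-bp DNA cylinder (r = 1.15 nm, L = 3.4 nm); tallies the energy
   deposited in the DNA target per emitted electron and per decay.
5. **Correlation** — normalized measured yields vs normalized simulated
   deposits as functions of emitter–DNA distance, summarized by a
   pair-count Kendall-type rank concordance.
6. **Synthetic data** — exact forward models of every stage, for
   testing and power analysis without any experimental download.

## Worked example

```python
import numpy as np
from augerdna import (get_nuclide, cumulated_decays, PlasmidPrep,
                      dsb_dose_response, yield_from_D0,
                      CylinderTarget, deposition_vs_distance)
from augerdna.decay import uci_to_bq
from augerdna.synthdata import GelSimConfig, gen_gel_series

tc = get_nuclide("99mTc")                     # T1/2 = 6.02 h, 5 e-/decay
print(f"N = {cumulated_decays(tc, uci_to_bq(100.0), 24*3600.0):.3e}")
# N = 1.084e+11        decays accumulated by 100 uCi over 24 h

prep = PlasmidPrep(0.2 / 0.030)               # 200 ng plasmid in 30 uL
cfg = GelSimConfig(nuclide=tc, prep=prep, D0_true_per_ml=3.3e13,
                   densitometry_cv=0.05, seed=42)
res = dsb_dose_response(gen_gel_series(cfg), prep, 1.4)
print(f"D0 = {res.D0:.3e} decays/mL   Y(DSB) = {res.Y_dsb:.4f} per decay")
# D0 = 3.361e+13 decays/mL   Y(DSB) = 0.0332 per decay  (r2 = 0.9997)

for r in deposition_vs_distance(tc, CylinderTarget(),
                                [10.0, 12.0, 14.0], 20000, seed=1):
    print(f"d = {r.distance_A:4.1f} A  {r.e_dep_per_electron_eV:5.2f} "
          f"eV/electron  {r.e_dep_per_decay_eV:6.1f} eV/decay")
# d = 10.0 A  23.52 eV/electron   117.6 eV/decay
# d = 12.0 A  17.22 eV/electron    86.1 eV/decay
# d = 14.0 A  12.52 eV/electron    62.6 eV/decay
```

The simulated gel series (true D₀ = 3.3×10¹³ decays/mL, 5% band noise)
is recovered within 2%, and its yield Y(DSB) ≈ 0.033 per decay matches
what the same preparation gives from the printed D₀ directly
(`yield_from_D0(3.33e13, prep)` → 0.0335).  The deposition curve shows
the steep fall-off of deposited energy with emitter–DNA distance that
drives the distance dependence of direct DSB production.  Absolute eV
values depend on the simplified transport model (see
`docs/methods.md`); the distance trend and the per-electron/per-decay
normalizations are the meaningful outputs.

A command-line interface mirrors the library:

```sh
augerdna decays --nuclide 99mTc --a0-uci 100 --hours 24 --volume-ml 0.030
augerdna simulate gel --seed 3 --out gel.csv
augerdna dose-response gel.csv --prep-ug-per-ml 6.667
augerdna nanodose --nuclide 125I --distances 9:16:0.5 \
    --histories 200000 --seed 42 --out curve.csv
augerdna run --config assay.yaml --out report.json
```

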