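# alkflux

Carbon and electron partitioning between **methanogenesis** and **sulfate
reduction** during anaerobic n-alkane degradation.

When a hexadecane-degrading enrichment culture is incubated with sulfate,
the substrate's electrons can end up in methane (via syntrophic oxidation
plus methanogenesis) or in sulfide (via sulfate-reducing prokaryotes).
`alkflux` turns long-term batch-culture time series — headspace methane,
residual sulfate, δ¹³C of CH₄ and CO₂, endpoint residual alkane — into the
quantities that describe that competition:

* **Stoichiometry.** Complete oxidation of a saturated alkane CₙH₂ₙ₊₂
  is balanced exactly for both routes:

  CₙH₂ₙ₊₂ + (n−1)/2 H₂O → (3n+1)/4 CH₄ + (n−1)/4 CO₂

  CₙH₂ₙ₊₂ + (3n+1)/4 SO₄²⁻ + (3n+1)/2 H⁺ → (3n+1)/4 H₂S + n CO₂ + (n+1) H₂O

  Both transfer 6n+2 electron equivalents (8 e⁻ per CH₄ or SO₄²⁻), so
  *moles CH₄ produced + moles sulfate reduced* is a pathway-independent
  yield, Y = (3n+1)/4 — for hexadecane, **12.25**.
* **Mass balance.** Background-corrected net methane M and net sulfate
  reduced S give the carbon recovery 100·(M+S)/(Y·hex), the pathway
  contributions E_M = 100·M/(Y·hex) and E_S = 100·S/(Y·hex) (which sum to
  the recovery), the electron-flow split 100·M/(M+S) / 100·S/(M+S), and
  the partition ratio S/M.
* **Kinetics.** Cumulative methane curves are fitted with the logistic
  y(t) = a / (1 + e^(−k(t−t_c))); the maximum specific methane production
  rate μ_max is the fitted k (month⁻¹).
* **Isotopes.** The apparent fractionation factor
  α_app = (δ¹³CO₂ + 1000)/(δ¹³CH₄ + 1000) indexes the dominant
  methanogenic pathway (aceticlastic below ~1.025, hydrogenotrophic above
  ~1.065).
* **Sulfate response.** Per-day OLS of S/M against initial sulfate (mM),
  with a slope-stability summary across the production phase.
* **Synthetic experiments.** A seeded generator produces complete
  observation tables with known recovery, partition slope, kinetics and
  isotope structure, so every stage can be validated end to end without
  external data.

## Worked example

Endpoint summaries of a 421-day hexadecane culture across a 0.5–25 mM
sulfate gradient ship with the package:

```python
import alkflux as af

y = af.methanogenic_yields(af.parse_alkane_formula("C16H34"))
print("combined yield Y =", float(y.combined_yield))

ref = af.load_reference_endpoints()
row = ref[ref.initial_sulfate_mM == 25].iloc[0]
e_m, e_s = af.pathway_contributions(row.methane_mmol, row.sulfate_consumed_mmol,
                                    row.hexadecane_consumed_mmol, y)
print(f"25 mM: recovery {af.carbon_recovery(row.combined_ratio, y):.1f} %, "
      f"E_M {e_m:.1f} %, E_S {e_s:.1f} %, S/M {af.sm_ratio(row.methane_mmol, row.sulfate_consumed_mmol):.2f}")

sm = ref.sulfate_consumed_mmol / ref.methane_mmol
fit = af.fit_sm_regression(ref.initial_sulfate_mM.to_numpy(float), sm.to_numpy(float))
print(f"S/M vs sulfate: slope {fit.slope:.3f} per mM, R^2 {fit.r_squared:.3f}, p {fit.p_value:.1e}")

print(f"alpha_app low sulfate: {af.alpha_app(-17.0, -61.5):.3f} ->",
      af.classify_pathway(af.alpha_app(-17.0, -61.5)).value)
```

prints

```
combined yield Y = 12.25
25 mM: recovery 98.0 %, E_M 31.4 %, E_S 65.8 %, S/M 2.09
S/M vs sulfate: slope 0.086 per mM, R^2 0.985, p 8.3e-05
alpha_app low sulfate: 1.047 -> intermediate
```

Reading: at 25 mM sulfate, 98 % of the consumed hexadecane carbon is
accounted for, with roughly two-thirds of the flux through sulfate
reduction; across the whole gradient the S/M partition responds linearly
to initial sulfate (~0.09 per mM, R² 0.985); and the low-sulfate α_app of
1.047 sits between the canonical aceticlastic and hydrogenotrophic
windows — a mixed methanogenic pathway.

## Command line

```sh
alkflux stoich --formula C16H34            # balanced coefficient table
alkflux simulate --seed 42 --out obs.csv   # synthetic experiment
alkflux report --input obs.csv --out results/   # full report bundle
```

Subcommands `balance`, `kinetics`, `isotopes` and `regress` run single
stages; `report` writes `balance.tsv`, `kinetics.tsv`, `alpha.tsv`,
`sm_regression.tsv` and `run.log` into a versioned run directory.

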