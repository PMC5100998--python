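# tecfit

Pre-steady-state kinetic analysis for transcription elongation complexes
(TECs): the computational toolchain for studies that dissect how factors
such as NusG act on RNA polymerase — single-nucleotide addition and
translocation by rapid quench-flow and stopped-flow fluorescence,
backtracking read out through factor-stimulated RNA cleavage, equilibrium
titrations with translocation-state probes, and bimolecular binding
kinetics.  It is written for enzymologists and quantitative biologists who
want the full pipeline — mechanism → simulation → global fit → uncertainty
bounds — as a scriptable, tested Python library instead of an interactive
fitting GUI.

## What it computes

* **Mass-action schemes** declared as state graphs with named rate
  parameters, including the three-step single-round mechanism

  TEC16(inactive) ⇌ TEC16(active) → TEC17(pre) → TEC17(post)

  with rates k_rec/k_inact, pseudo-first-order nucleotide addition k_add,
  and irreversible translocation k_tr, plus an initial slow (inactive)
  fraction.
* **ODE simulation** (stiff-capable, conservation-checked) and projection
  onto gel product fractions or fluorescence signals.
* **Global fitting** of heterogeneous datasets (discrete quench-flow points
  + continuous stopped-flow traces) by joint least squares, with profiled
  per-trace scale/offset nuisances, and **profile bounds**: the interval
  where the re-optimized χ² stays within a 10% increase of its minimum,
  reported as (lower bound, best fit, upper bound) per parameter.
* **Stretched-exponential fits** s(t) = s₀ + A·(1 − exp(−(t/τ)^β)) and the
  **median reaction time** τ·(ln 2)^{1/β}, the half-amplitude crossing that
  generalizes the half-life to heterogeneous kinetics.
* **Depletion-corrected equilibrium binding**: the bound fraction is the
  physical root of b² − (R + L + K_D)·b + R·L = 0, fit jointly across
  titration curves with a profile-likelihood 95% CI on K_D.
* **Bimolecular binding kinetics** with explicit ligand depletion,
  recovering k_on, k_off and the derived K_D = k_off/k_on from a
  concentration series.
* **Seeded synthetic data** for every assay class, including presets that
  reproduce published per-condition median reaction times.

## Worked example

Generate a synthetic 2-AP dinucleotide-release trace for the wild-type TEC
(target median 12.4 s) and fit it:

```
$ tecfit synth --preset WT-2AP --seed 7 --out wt.csv
$ tecfit median --trace wt.csv
{
 "baseline": 0.08779057863398862,
 "amplitude": 1.0115152302422594,
 "tau_s": 17.65145666932532,
 "beta": 1.0014992352550744,
 "rss": 0.033842344049851245,
 "median_time_s": 12.241772231323633,
 "flags": [],
 "result_type": "StretchedExpFit"
}
```

The fit finds an essentially single-exponential relaxation (β ≈ 1.0) with
τ ≈ 17.7 s and a median reaction time of 12.24 s — within 1.3% of the
12.4 s target the trace was generated from, at 1% instrument noise.  An
empty `flags` list says the fit neither hit a β bound nor ran off the
sampled time span.

The same works as a library:

```python
from tecfit import fit_stretched_exponential, generate_stopped_flow_trace
from tecfit.synthetic_data import preset_generator_spec

trace = generate_stopped_flow_trace(preset_generator_spec("WT-2AP", seed=7))
fit = fit_stretched_exponential(trace)
print(fit.median_time)   # 12.241772231323633
```

Other subcommands: `simulate` (scheme → tidy trajectory CSV), `fit` /
`profile` (global fit of a manifest, with χ²-threshold bounds), `titrate`
(depletion-corrected K_D), `bind` (k_on/k_off series fit).

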