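# ratpbpk

Bottom-up rat PBPK prediction pipeline for early drug discovery:

- **IVIVE of hepatic clearance** — four incubation-binding assumptions
  (direct, dilution, unbound, Austin), external predicted clearance, and
  back-calculation of the unbound hepatocyte intrinsic clearance from an
  observed plasma clearance via the reverse well-stirred model (with the
  blood-flow exclusion rule).
- **Mechanistic tissue partitioning** — composition-based Kp prediction
  (acidic-phospholipid binding for moderate-to-strong bases calibrated from
  blood-cell partitioning; extracellular protein binding for acids,
  neutrals, and weak bases) and plasma-referenced Vss.
- **Whole-body IV model** — 11 perfusion-limited tissue compartments
  (adipose, bone, brain, gut, heart, kidney, liver, lung, muscle, skin,
  spleen) plus venous/arterial pools; linear system solved by
  eigendecomposition with a stiff-ODE fallback.
- **Oral absorption** — nine-compartment gut transit train with pH- and
  bile-salt-dependent solubility, shrinking-sphere dissolution for 50 um
  suspensions, ka = 2*Peff/R absorption, and hepatic first pass.
- **Reduced model** — single central compartment of mechanistic Vss for
  high-throughput batches, sharing the same parameter derivation.
- **NCA + metric panel** — linear-up/log-down AUC, terminal-slope
  extrapolation, and the prediction-success suite (%2/3/10-fold, AFE, AAFE,
  RMSLE, CCC on log and linear scales, Spearman rho, R2).
- **Synthetic data** — seeded compound libraries emulating the study's
  property marginals (MW ~ 413 Da, logD ~ 2.48, mostly basic/neutral,
  ~12% highly bound) and pseudo-observed PK from the package's own forward
  model, so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic dataset (compounds.csv + arms.csv)
ratpbpk synth --n-compounds 267 --seed 1 --outdir data/synth

# simulate one compound/arm and dump the tidy profile
ratpbpk simulate --compounds data/synth/compounds.csv --compound-id SYN0000 \
    --route PO --dose 5 --formulation suspension --out profile.csv

# batch evaluation: six clearance methods x model variants, metric panels
ratpbpk evaluate --compounds data/synth/compounds.csv --arms data/synth/arms.csv \
    --methods direct,dilution,unbound,austin,back_calculated \
    --model both --outdir results/eval

# full vs reduced model concordance
ratpbpk compare-models --compounds data/synth/compounds.csv \
    --arms data/synth/arms.csv --method back_calculated --routes PO \
    --outdir results/compare
```

`evaluate` writes `predictions.csv` (long per-arm table), `metric_panels.csv`
(overall plus binding/clearance/ECCS strata), `exclusions.csv` (with reasons:
blood-flow limit, missing observations, zero clearance), and a provenance
manifest. Physiology and gut configs are YAML-overridable
(`ratpbpk.physiology.save_physiology` documents the schema by example).

## Package layout

```
src/ratpbpk/
  compound_model.py    domain types, classification rules, Peff correlations
  ivive.py             fu_inc models, well-stirred model, back-calculation
  physiology.py        rat tissue volumes/flows/composition (YAML config)
  disposition.py       Kp, Vss, whole-body IV model, reduced IV model
  absorption_acat.py   gut transit/dissolution/absorption, reduced PO model
  pk_metrics.py        NCA and the fold-error metric panel
  synthetic_data.py    seeded library + pseudo-observation generators
  pipeline.py          batch evaluation, stratified panels, model comparison
  datasets.py          CSV schemas (compounds, study arms)
  cli.py               click entry points
```
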