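# yeastff

Kinetic modelling of *Saccharomyces cerevisiae* carbon-storage metabolism
under repeated feast/famine substrate cycles.

The package implements:

* **model core** — an ODE model of glycolysis, the glycerol branch, a
  complete trehalose cycle (cytosolic / vacuolar / extracellular pools),
  phenomenological glycogen synthesis/degradation, cofactor metabolism with
  exact adenylate and NAD(H) moiety conservation, and lumped sink reactions
  toward PPP/TCA/biomass (the pyruvate sink carries a reduction factor).
  Glucose uptake is facilitated diffusion with an optional
  extracellular-glucose threshold (`GLCec_min`) standing in for glucose
  sensing.
* **three-stage protocol** — chemostat steady state, 20 block-wise
  feast/famine cycles (20 s feed at 20x concentration, constant outflow
  until 260 s, closed until 400 s) with explicit broth-volume dynamics,
  then a ¹³C enrichment run (99% labelled feed).
* **¹³C labelling layer** — a labelled-fraction balance for every carbon
  species, with reversible fluxes split into forward/backward parts and
  pool-enrichment (not positional-isotopomer) accounting.
* **estimation** — a two-step pipeline: combinatorial enzyme-subset
  screening (every subset containing the trehalose cycle) with per-observable
  weighting grids, then L1-regularized re-estimation over a λ grid with a
  knee rule, all as bounded nonlinear least squares in log10 space.
* **ensembles** — ±10% parameter-perturbation ensembles and a log-uniform
  transporter-parameter feasibility scan under a pinned extracellular
  glucose trace (the passive-vs-sensing uptake trade-off).
* **synthetic data** — seeded observation bundles (concentrations, fluxes,
  enrichment) with denser early-cycle sampling, multiplicative log-normal
  noise and piecewise-linear flux resampling, plus a parameter-recovery
  experiment driver.

The shipped calibrated configuration (`yeastff/data/`) was constructed by
steady-state design (`scripts/build_parameter_sets.py`): target chemostat
concentrations and a closed flux distribution are fixed, the adapted
transporter/phosphorylation constants are pinned to their estimated values,
and every remaining Vmax is solved so the target state is an exact
equilibrium of the assembled system.

## CLI

```bash
yeastff simulate --out out/sim                # chemostat + 20 cycles
yeastff enrich   --out out/enr                # 13C enrichment run
yeastff synth    --seed 1 --out out/syn       # synthetic bundle
yeastff fit      --data out/syn/bundle.csv --subset HXT,GLK --out out/fit
yeastff screen   --data out/syn/bundle.csv \
                 --subsets "TPS1+TPS2+NTH1+AGT1+VACT+ATH1+HXT+GLK" --out out/scr
yeastff sweep    --data out/syn/bundle.csv --subset HXT,GLK \
                 --lambda-grid 0,0.03,1,100 --out out/sw
yeastff ensemble --n 50 --range 0.10 --out out/ens
yeastff hxt-scan --n 200 --decades 3 --out out/scan
yeastff report   --out out/rep                # fold-change table
```

Defaults use the shipped calibrated parameter set and protocol. Every run
writes a `manifest.json` with the configuration and package versions; CSV
outputs are byte-reproducible for a fixed seed. File formats are documented
in `FORMATS.md`.

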