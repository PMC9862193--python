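# File formats

All artifacts are plain text (JSON, YAML, CSV). Floating-point values in
CSV outputs are printed with `%.12g`, so identical runs are byte-identical.

## Parameter sets (`*.json`)

```json
{
 "role": "reference" | "estimated",
 "units": {"Vmax": "mM/s", "Km": "mM", "Ki": "mM", "Keq": "1"},
 "values": {"REACTION.constant": float, ...}
}
```

Keys are `REACTION.constant` (e.g. `HXT.Vmax`, `GLK.Ki_T6P`). The full key
registry lives in `yeastff.params.REQUIRED_KEYS`; unknown or missing keys
are rejected with the offending key named. Amplitude-class constants
(`Vmax`, `k`, `v_chemostat`, `GLCec_min`, `PI_ref`) may be zero, all other
constants must be strictly positive.

## Protocol (`protocol_default.yaml`)

| field | unit | default |
|---|---|---|
| `dilution_per_h` | h^-1 | 0.1 |
| `cs_chem_g_per_l` | g/L | calibrated (~37.5) |
| `cycle_s`, `feed_s`, `outflow_end_s` | s | 400 / 20 / 260 |
| `multiplier` | – | 20 |
| `n_cycles` | – | 20 |
| `biomass_gdw_per_l` | gDW/L | 16 |
| `vacuole_fraction` | – | 0.10 |
| `label_fraction` | – | 0.99 |

## Observation bundles (`bundle.csv`)

One tidy CSV with a comment header line carrying provenance:

```
# provenance=synthetic cycle_s=400
table,series,time_s,value,sd,unit
conc,G6P,0,0.899,0.045,mM
flux,HXT,0,0.021,0.002,mM/s
enrich,G6P,100,78.2,3,percent
```

`table` is `conc` (mM), `flux` (mM/s, cytosolic volume) or `enrich`
(percent). Rows are canonically sorted on read; shuffled files parse to
the same bundle. A missing `sd` column gets a 5% default with a warning.

## Glycogen flux tables (`glycogen_*.csv`)

Two columns, `time_s,flux_mM_per_s`, piecewise-linear over one cycle and
extended periodically. The chemostat phase instead uses the constant
`GLYS.v_chemostat` / `GLYD.v_chemostat` parameters.

## State files (`state_chemostat*.json`)

Flat mapping of species name to concentration (mM) plus `VOL` (L).

## Trajectory output (`trajectory.csv`)

`time_s,variable,value,unit,cycle_index`; species in mM, `VOL` in L and
fluxes as `v_<REACTION>` in mM/s.

## Enrichment output (`enrichment.csv`)

`species,time_s,enrichment_percent`.

## Screening / sweep / dispersion / scan tables

Column dictionaries:

* `screening.csv`: `rank,subset_id,n_enzymes,weight_index,cost,data_error,success,message`
* `sweep.csv`: `lam,data_error,param_error,param_deviation,cost,success`
* `dispersion.csv`: `time_s,kind,name,rsd` (relative SD across the ensemble)
* `scan.csv`: `sample,HXT.Vmax,HXT.Km,HXT.Ki,uptake_20s,uptake_400s,integrated`

## Manifests

Every CLI run writes `manifest.json` (command, full argument namespace,
package versions) beside its outputs.
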