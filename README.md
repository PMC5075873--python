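# statevar

Quantify the *variation of state* (Shannon entropy, in bits) and
*robustness* of biological network models under exhaustive perturbation,
before and after an external stimulus.

Two model classes are supported end to end:

- **Kinetic metabolic networks** — irreversible multiplicative
  Michaelis–Menten ODE models with two named parameter conditions
  (`control` / `stressed`). The pipeline integrates the model under all
  `2^k` doubling perturbations of the declared *state metabolites*,
  discretizes each daily sample into a Boolean accumulation tuple
  (accumulated ⇔ amount ≥ 2× its unperturbed baseline), and pools the
  resulting states into an entropy. Conditions can be blended with a linear
  interpolation parameter λ (`Vmax(λ) = Vmax(0) + λ·(Vmax(1) − Vmax(0))`),
  and single reactions can be over-expressed by a Vmax factor.
- **Boolean module networks** — synchronous signed-threshold dynamics
  with tie-hold memory over transcription-factor modules, with
  step-function external inputs and clamped ("enforced expression")
  modules, simulated exhaustively from all `2^n` initial states.

Four experiment stages wrap these primitives: a 33-point λ sweep with a
Wilcoxon rank-sum region comparison, a four-fold enzyme over-expression
screen with proportion and binomial summary tests, a step-input stimulation
experiment, and enforced-expression experiments (`case1`: four modules
clamped active with inputs on; `case2`: one module clamped active with
inputs off).

Because no measured parameter sets ship with the package, `synthetic_data`
provides seeded generators: a 33-reaction central-carbon fixture
(glycolysis, fermentation, TCA cycle, GABA shunt; 11 fitting-target
metabolites; 2OG/Glu/GABA/succinate as state metabolites) whose stressed
condition accumulates the GABA-shunt pools, a ladder-like 8-module Boolean
network with 19 promoting and 17 inhibitory interaction multiplicities, and
noisy observed time courses for calibration. All fixture kinetics are
authored reconstructions, not measurements.

## CLI

```bash
statevar synth --kind metabolic --out model.yaml      # packaged kinetic fixture
statevar synth --kind boolean --out network.yaml      # packaged module network
statevar synth --kind timecourse --seed 1 --out obs.csv

statevar validate --model model.yaml --network network.yaml
statevar fit --model model.yaml --observed obs.csv --condition control --out-dir out/fit
statevar sweep --model model.yaml --out-dir out/sweep
statevar screen --model model.yaml --out-dir out/screen
statevar pma --network network.yaml --out-dir out/pma
statevar enforce --network network.yaml --case case2 --out-dir out/enforce

statevar run --seed 1 --out-dir out/full              # every stage, synth inputs
```

Outputs are tidy CSV tables plus JSON metric records; each output directory
contains a `manifest.json` with the config echo, seed, package version and
input digests. Exit codes: 0 success, 2 validation failure, 3 numerical
failure.

Model and network files are versioned YAML/JSON documents
(`schema_version: 1`); see `statevar synth` output for worked examples. An
optional SBML Level 3 import (`metabolic_model.load_sbml`) maps kinetic-law
local parameters named `Vmax_control` / `Vmax_stressed` / `Km_<substrate>`
and requires `python-libsbml`.

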