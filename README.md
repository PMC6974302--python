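# chirosim

A spatial Monte-Carlo simulator of the joint origin of biological
homochirality and the RNA world, for researchers in origin-of-life
modelling and molecular evolution.

Life uses D-sugars in its nucleic acids, yet prebiotic chemistry delivers
racemic mixtures.  `chirosim` implements an agent-based model in which the
two can be reconciled *at the polymer level*: racemic nucleotide precursors
on an N x N toroidal grid polymerize into RNA by two routes —
surface-mediated (de novo) ligation and template-directed synthesis — both
of which prefer monomers matching the handedness of the growing
polymer/template (chiral selection, factors `F_CSS`/`F_CST`), terminate
after incorporating an opposite-handed monomer (cross-inhibition), and
extend established polymers faster than they start new ones (the primer
effect, ladders `R1..Rn`).  Precursors racemize freely (`P_CIC`), so
whichever handedness polymerizes faster drains the shared pool and
amplifies its own excess — an autocatalytic symmetry breaking measured by
the enantiomeric excess

```
ee = (D - L) / (D + L)
```

summed over precursors, nucleotides and every chain residue.
Sequence-defined ribozymes close the loop: a chain carrying the catalytic
domain `ACUGGC` (`CS_NSR`) in uniform handedness acts as a nucleotide
synthetase (rate `P_NFR`), one carrying `GUUCAG` (`CS_REP`) as a
template-ligase replicase (rate `P_TLR`), each serving only its own
handedness and thereby deepening the deviation.

Every event — racemization, nucleotide formation/decay, collision-driven
ligation and attraction, template ligation, end decay (`P_NDE`,
`P_NDE^(3/2)` when base-paired), bond breaking (`P_BB`, `P_BB^(3/2)` in a
duplex), duplex separation (`P_SP^((r+1)/2)` at r base pairs) and movement
(`P_MN/sqrt(m)`) — is an independent per-step Bernoulli trial.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

```
python examples/template_directed_symmetry_breaking.py
```

prints (deterministic for the example's seed):

```
scenario: fig2a_complete_reduced (expected regime: deviation)
steps: 200000, inoculation at step 50000
  step       0  ee=+0.000  D= 1000 L= 1000
  step   20000  ee=+0.019  D= 1019 L=  981
  step   40000  ee=-0.045  D=  955 L= 1045
  step   60000  ee=+0.416  D= 1628 L=  672
  step   80000  ee=+0.704  D= 1960 L=  340
  step  100000  ee=+0.761  D= 2025 L=  275
  step  120000  ee=+0.778  D= 2045 L=  255
  step  140000  ee=+0.790  D= 2058 L=  242
  step  160000  ee=+0.767  D= 2032 L=  268
  step  180000  ee=+0.761  D= 2025 L=  275
  step  200000  ee=+0.766  D= 2031 L=  269
final ee: +0.766 (positive: the inoculated D handedness prevails; |ee| < 1: degradation prevents full purity)
```

Before the inoculation of 50 homochiral D 6-mers at step 50000 the racemic
pool only fluctuates around ee = 0.  Replication on the D-templates then
consumes D-nucleotides; the formation/decay equilibrium and precursor
racemization drain the L side, and ee climbs to ~0.75 — but never to 1,
because degradation keeps recycling residues through the racemizing
precursor pool.  The other scripts in `examples/` demonstrate the
surface-only primer-effect route, ribozyme catalysis, the exact mirror
symmetry, and config-file/CLI round trips.

## Library and command line

The package is used from Python:

```python
from chirosim import Params, RunConfig, run, scenario

traj = run(scenario("fig3_ladder200_reduced").config.replace(seed=7))
print(traj.final_ee)
```

`chirosim.experiments.scenario` names the study conditions (the
template-directed `fig2a_*` family, de novo `fig2b`, the surface-only
`fig3_*` ladder family, ribozyme emergence `fig4a_nsr`/`fig4b_rep`); each
has a desk-scale `_reduced` variant (N=10, 2000 precursors, 2e5 steps)
with all probabilities unchanged.  Full-scale presets (N=20, 50000
precursors, millions of steps) are documented slow runs.  A thin CLI wraps
the same machinery:

```
chirosim run --config run.cfg --seed 1 --out outdir
chirosim scenario fig2a_complete --reduced --seeds 10 --out outdir
```

Outputs are plain TSV trajectories and per-molecule snapshots;
configurations are KEY=VALUE text files using the standard parameter
symbols (`P_AT=0.5`, `F_CST=0`, `R_SURFACE=1,10,200,200`, ...).

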