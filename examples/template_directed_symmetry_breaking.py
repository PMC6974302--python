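"""Template-directed symmetry breaking after inoculating D-templates.

A racemic precursor pool (reduced scale: 10x10 rooms, 2000 precursors)
receives 50 homochiral D 6-mers.  With complete chiral selection
(F_CST = 0) replication consumes D-nucleotides, the precursor equilibrium
and racemization funnel L-material into the D pool, and the enantiomeric
excess ee = (D-L)/(D+L) climbs well above zero - without ever reaching
purity, because degradation keeps recycling residues through the racemic
precursor pool.
"""

from chirosim import run, scenario

sc = scenario("fig2a_complete_reduced")
cfg = sc.config.replace(seed=1)
traj = run(cfg)

print(f"scenario: {sc.name} (expected regime: {sc.expected_regime})")
print(f"steps: {cfg.steps}, inoculation at step {cfg.inoculations[0].step}")
for rec in traj.records[:: len(traj.records) // 10]:
    print(f"  step {rec.step:>7d}  ee={rec.ee:+.3f}  "
          f"D={rec.D_total:>5d} L={rec.L_total:>5d}")
print(f"final ee: {traj.final_ee:+.3f} "
      "(positive: the inoculated D handedness prevails; "
      "|ee| < 1: degradation prevents full purity)")
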