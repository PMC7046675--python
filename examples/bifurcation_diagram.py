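"""Bifurcation structure of the autapse-free neuron in the applied current.

Class II: subcritical Hopf at I_H ~ 42.8 uA/cm^2 with a fold of limit cycles
slightly below it (~42.2), hence a narrow bistable window.  Class III: the
equilibrium never destabilises.
"""

import mlautapse as m

p2 = m.preset("typeII")
p3 = m.preset("typeIII")

hopf = m.find_hopf(0.0, 100.0, p2)
print(f"class II Hopf point:        I_H  = {hopf.I_H:.3f} uA/cm^2")

fold = m.find_fold_of_cycles(p2)
print(f"class II fold of cycles:    I_LC = {fold:.3f} uA/cm^2")
print(f"bistable window width:      {hopf.I_H - fold:.3f} uA/cm^2")

cyc = m.limit_cycle_from_simulation(100.0, p2, T=300.0, settle=100.0)
print(f"limit cycle at I=100:       period {cyc.period:.3f} ms, "
      f"V in [{cyc.V_min:.1f}, {cyc.V_max:.1f}] mV")

res3 = m.find_hopf(0.0, 200.0, p3)
branch = m.equilibrium_branch((0.0, 200.0), 41, p3)
print(f"class III Hopf on [0,200]:  {'none' if res3.I_H is None else res3.I_H}"
      f" (all {len(branch)} branch points stable: {all(q.stable for q in branch)})")

print(
    "\nBetween the fold and the Hopf point the stable cycle coexists with the"
    "\nstable rest state; brief inputs can switch the class II neuron between"
    "\nthem. Class III has no such window: sustained current never recruits"
    "\nrepetitive firing."
)
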