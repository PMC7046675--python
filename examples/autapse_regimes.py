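"""Firing regimes under delayed excitatory self-feedback (g_syn = 3, tau = 15 ms).

One brief trigger pulse elicits the first spike; afterwards only the delayed
autaptic current drives the neuron.  The synaptic decay rate beta selects the
regime, and the two excitability classes diverge as beta shrinks.
"""

import mlautapse as m

I_H = m.find_hopf(0.0, 100.0, m.preset("typeII")).I_H

print(f"{'class':8s} {'beta':>5s}  {'response':20s} {'steady ISI':>10s}  case")
for beta in (1.0, 0.1, 0.01):
    for name in ("typeII", "typeIII"):
        params = m.preset(name)
        syn = m.SynapseParams(g_syn=3.0, tau=15.0, beta=beta)
        traj = m.run_triggered(params, syn, T=1000.0)
        summ = m.summarize(traj, tau=syn.tau, I_H=I_H)
        isi = f"{summ.steady_isi:.2f} ms" if summ.steady_isi else "-"
        print(f"{name:8s} {beta:5.2f}  {summ.response_class:20s} {isi:>10s}  {summ.firing_case}")

print(
    "\nbeta = 1: both classes lock to the 15 ms delay (case-1). beta = 0.1:"
    "\nclass II switches to limit-cycle firing at ~7.7 ms (case-2) while"
    "\nclass III stays delay-locked at ~15.7 ms. beta = 0.01: class II fires"
    "\neven faster (~5.3 ms), but class III falls silent after two spikes —"
    "\nthe slowly decaying (stronger!) excitation cannot re-trigger it."
)
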