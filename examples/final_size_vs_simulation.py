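"""Final-size fixed point versus full ODE simulation.

Once dosing has stopped, the model is a plain 2n-group SIR, so the terminal
recovered fractions satisfy an exponential fixed-point relation.  This
script solves that relation for the two-group example and compares it with
the simulated trajectory's terminal state.
"""

import numpy as np

from vaxalloc import (simulate, solve_final_size, stack_parameters,
                      two_group_example)

ex = two_group_example(0.3, I_star=0.01, p_star=1.0,
                       chi_eff=0.5, rho_eff=0.5)
sol = solve_final_size(stack_parameters(ex.params))
traj = simulate(ex.params)
sim_R = np.concatenate([traj.R[-1], traj.RV[-1]])

labels = ["R_1(inf)", "R_2(inf)", "RV_1(inf)", "RV_2(inf)"]
print("compartment   fixed point     simulation      |difference|")
for lab, fp, sim in zip(labels, sol.R_inf, sim_R):
    print(f"{lab:10}   {fp:12.8f}   {sim:12.8f}   {abs(fp - sim):.2e}")
print(f"\nfixed-point residual {sol.residual:.1e} in {sol.iterations} "
      "iterations; both routes agree to solver accuracy, so terminal "
      "attack sizes can be read off without integrating the ODEs.")
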