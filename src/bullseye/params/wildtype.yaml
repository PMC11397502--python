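# Wild-type H. trionum model parameters (rates per day, lengths in μm)
r_g_distal: 0.91    # base relative growth rate of distal cells
r_g_ratio: 1.0      # proximal:distal expansion-rate ratio
r_d_distal: 1.1     # base division rate of distal cells
r_d_ratio: 1.0      # proximal:distal division-rate ratio
l_max: 20.0         # maximum cell length
L_max: 300.0        # threshold total petal length (ends the simulation)
L0_distal: 30.0     # division slow-down length scale, distal (= 0.1 * L_max)
L0_ratio: 0.6       # L0(distal) / L0(proximal)
dt: 0.01            # engine step, days
seed: 0
# initial state
n_cells: 21
cell_length: 0.1
n_proximal: 7
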