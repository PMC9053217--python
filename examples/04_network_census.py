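"""Build every architecture and print its trainable-parameter census.

The attention-gated multi-scale network (dagmnet) and the generic UNet/FCN
benchmarks are sized to comparable budgets; CH3 models take a third input
channel (the classical ischemic-probability map) and differ from CH2 by
exactly one extra slice of the first convolution kernel (27 * N_f weights).
"""

from ischeseg import netzoo

for name in ("dagmnet_ch3", "dagmnet_ch2", "unet_ch3", "unet_ch2",
             "fcn_ch3", "fcn_ch2"):
    net = netzoo.build_network(name)
    n = netzoo.count_parameters(net)
    print(f"{name:12s}  N_f={net.cfg.nf:2d}  {n:>12,d} parameters "
          f"({n / 1e6:.1f} M)")

d3 = netzoo.count_parameters(netzoo.build_network("dagmnet_ch3"))
d2 = netzoo.count_parameters(netzoo.build_network("dagmnet_ch2"))
print(f"\nCH3 - CH2 delta = {d3 - d2} = 27 * 32 (first-layer kernel slice)")
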