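"""Null quantiles of sqrt(n) * dip under the uniform distribution.

Generated by scripts/make_dip_table.py; do not edit by hand.
"""

DIP_TABLE_N = [10, 15, 20, 30, 50, 75, 100, 150, 200, 300, 500, 750, 1000, 1500, 2000, 3000]

DIP_TABLE_PROBS = [0.2, 0.5, 0.75, 0.9, 0.95, 0.975, 0.99, 0.995]

DIP_TABLE_QUANTILES = [
    [0.270164, 0.309866, 0.364871, 0.413518, 0.445629, 0.471642, 0.511343, 0.547615],
    [0.266798, 0.323860, 0.372904, 0.425048, 0.455977, 0.485756, 0.525179, 0.549267],
    [0.274574, 0.327046, 0.380738, 0.438716, 0.474202, 0.502361, 0.549920, 0.581720],
    [0.283375, 0.333839, 0.386832, 0.441780, 0.477519, 0.513764, 0.554010, 0.584759],
    [0.291239, 0.347458, 0.398662, 0.457619, 0.492383, 0.525285, 0.558853, 0.577989],
    [0.290315, 0.350729, 0.406654, 0.466668, 0.507550, 0.538737, 0.589109, 0.604195],
    [0.295016, 0.349783, 0.407561, 0.468198, 0.504680, 0.544154, 0.576240, 0.621353],
    [0.303186, 0.357785, 0.415336, 0.479720, 0.520240, 0.546108, 0.587637, 0.627511],
    [0.304867, 0.360164, 0.415369, 0.476838, 0.515840, 0.559714, 0.594972, 0.608767],
    [0.310452, 0.366536, 0.424968, 0.490334, 0.530784, 0.568722, 0.596003, 0.649028],
    [0.309400, 0.367244, 0.423144, 0.487750, 0.531153, 0.562950, 0.603622, 0.634909],
    [0.312016, 0.371196, 0.424547, 0.486949, 0.528975, 0.556830, 0.603814, 0.654123],
    [0.312872, 0.368233, 0.428575, 0.496507, 0.544055, 0.589920, 0.623084, 0.655409],
    [0.315198, 0.373930, 0.429151, 0.494280, 0.541716, 0.574156, 0.614412, 0.631612],
    [0.310791, 0.367898, 0.425957, 0.486144, 0.529478, 0.577833, 0.633342, 0.646946],
    [0.313643, 0.376382, 0.432861, 0.485915, 0.540939, 0.584294, 0.640986, 0.676980],
]
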