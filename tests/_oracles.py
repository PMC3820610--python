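"""Independent brute-force oracles shared by the test modules."""

import sympy

from lipidframe.chemistry import ISOTOPE_SHIFTS


def envelope_polynomial_oracle(comp, n_peaks):
    """Isotopologue abundances by symbolic polynomial expansion (sympy),
    independent of the numpy convolution implementation under test."""
    x = sympy.Symbol("x")
    poly = sympy.Integer(1)
    for element, count in comp.counts.items():
        heavy = ISOTOPE_SHIFTS.get(element, ())
        light = 1 - sum(sympy.Float(f, 15) for _, f in heavy)
        term = light + sum(sympy.Float(f, 15) * x**s for s, f in heavy)
        poly = sympy.expand(poly * term**count)
    poly = sympy.Poly(poly, x)
    return [float(poly.coeff_monomial(x**k)) for k in range(n_peaks)]
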