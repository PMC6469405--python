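"""Re-expressing a fitted polynomial in a translated marker coding.

The surface f(M) = 1 + 2 M1 + 0.5 M2 + 0.25 M1*M2 is rewritten in
shifted variables m = M - P for P = (0.5, 0.3).  The rewritten
polynomial has different low-order coefficients but the identical
top-degree coefficient and the identical value at every genotype.
"""

import numpy as np

import errblup as eb

monos = eb.enumerate_monomials(2, degree=2)
f = eb.PolynomialModel(monos, [1.0, 2.0, 0.5, 0.25])
P = np.array([0.5, 0.3])
ft = eb.translate_polynomial(f, P)

print("original   f :", "  ".join(
    f"{c:+.4f}*{m}" for m, c in zip(f.monomials, f.coefficients)))
print("translated f~:", "  ".join(
    f"{c:+.4f}*{m}" for m, c in zip(ft.monomials, ft.coefficients)))

point = np.array([[2.0, 2.0]])
print(f"\nf(2.0, 2.0)    = {eb.evaluate(f, point)[0]:.4f}")
print(f"f~(1.5, 1.7)   = {eb.evaluate(ft, point - P)[0]:.4f}")
print("""
The interaction coefficient 0.25 survives the translation untouched;
the intercept absorbs beta'P + h*P1*P2 = 1.1875.  Because f~ takes the
same value at the shifted coordinates, the sum of squared residuals of
any fit is the same in either coding - provided the model is complete.
An incomplete model (try dropping M2 and calling translate_polynomial)
has no slot for the generated term and raises CompletenessError.""")
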