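"""Independent exact oracles shared by the test modules."""

import math
from fractions import Fraction


def exact_two_sided_binomial(k: int, n: int, p: float) -> float:
    """Brute-force minimum-likelihood two-sided binomial p-value.

    Computed in exact rational arithmetic (a float p is a rational), so
    the enumeration has no rounding or underflow of its own; only the
    final conversion to float rounds.
    """
    fp = Fraction(p)
    na, da = fp.numerator, fp.denominator
    nb = da - na  # 1 - p == nb/da exactly
    # pmf(j) = comb(n, j) * na^j * nb^(n-j) / da^n: integer numerators
    pow_a = [1] * (n + 1)
    pow_b = [1] * (n + 1)
    for j in range(1, n + 1):
        pow_a[j] = pow_a[j - 1] * na
        pow_b[j] = pow_b[j - 1] * nb
    numerators = [math.comb(n, j) * pow_a[j] * pow_b[n - j] for j in range(n + 1)]
    obs = numerators[k]
    tol = Fraction(1) + Fraction(1, 10**7)
    total = sum(
        num for num in numerators if num * tol.denominator <= obs * tol.numerator
    )
    return float(Fraction(total, da**n))
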