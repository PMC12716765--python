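"""Independent brute-force evaluations of the screening formulas.

These deliberately avoid the package's code paths: ratios are built with
exact ``fractions.Fraction`` arithmetic before the final float/log step, and
deduplication is a literal max-by-(fda_dt, primaryid) per case group.
"""

import math
from fractions import Fraction


def ror_oracle(a, b, c, d):
    est = Fraction(a * d, b * c)
    se = math.sqrt(Fraction(1, a) + Fraction(1, b) + Fraction(1, c) + Fraction(1, d))
    lo = math.exp(math.log(est) - 1.96 * se)
    hi = math.exp(math.log(est) + 1.96 * se)
    return float(est), lo, hi


def prr_oracle(a, b, c, d):
    return float(Fraction(a * (c + d), c * (a + b)))


def chi2_oracle(a, b, c, d):
    n = a + b + c + d
    return float(Fraction((a * d - b * c) ** 2 * n,
                          (a + b) * (c + d) * (a + c) * (b + d)))


def ebgm_oracle(a, b, c, d):
    n = a + b + c + d
    est = Fraction(a * n, (a + c) * (a + b))
    se = math.sqrt(Fraction(1, a) + Fraction(1, b) + Fraction(1, c) + Fraction(1, d))
    return float(est), math.exp(math.log(est) - 1.96 * se)


def ic_oracle(a, b, c, d):
    n = a + b + c + d
    return math.log2(Fraction(a * n, (a + c) * (a + b)))


def dedup_oracle(keys):
    """Max-by-(fda_dt earliest-completion key, primaryid) within each caseid."""
    groups = {}
    for k in keys:
        groups.setdefault(k.caseid, []).append(k)
    out = []
    for caseid in sorted(groups):
        out.append(max(groups[caseid],
                       key=lambda k: (k.fda_dt.sort_key(), k.primaryid)))
    return out
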