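"""Independent brute-force reference implementations of the evaluation statistics.

Deliberately written with plain Python loops and ``math`` only, straight from
the defining formulas, so they share no code path with the package. Used to
pin expected values in unit tests and for the oracle-equivalence sweep.
"""

import math


def mean(xs):
    return sum(xs) / len(xs)


def pop_var(xs):
    m = mean(xs)
    return sum((x - m) ** 2 for x in xs) / len(xs)


def pop_cov(xs, ys):
    mx, my = mean(xs), mean(ys)
    return sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / len(xs)


def pearson(o, s):
    return pop_cov(o, s) / math.sqrt(pop_var(o) * pop_var(s))


def msor(o, s):
    return mean([si / oi for oi, si in zip(o, s)])


def cv_so_pct(o, s):
    ratios = [si / oi for oi, si in zip(o, s)]
    return 100.0 * math.sqrt(pop_var(ratios)) / mean(ratios)


def mean_bias_pct(o, s):
    return 100.0 * (mean(s) - mean(o)) / mean(o)


def slope_moment(o, s):
    return pop_cov(o, s) / pop_var(s)


def slope_origin(o, s):
    return sum(oi * si for oi, si in zip(o, s)) / sum(si * si for si in s)


def r2(o, s):
    return pearson(o, s) ** 2


def model_efficiency(o, s):
    mo = mean(o)
    return 1.0 - sum((si - oi) ** 2 for oi, si in zip(o, s)) / sum(
        (oi - mo) ** 2 for oi in o
    )


def mspe(o, s):
    return mean([(si - oi) ** 2 for oi, si in zip(o, s)])


def mspe_partition_pct(o, s):
    """(bias%, slope%, random%) of MSPE, each from its own defining formula."""
    total = mspe(o, s)
    bias = (mean(s) - mean(o)) ** 2
    b1 = slope_moment(o, s)
    slope = pop_var(s) * (1.0 - b1) ** 2
    random = (1.0 - pearson(o, s) ** 2) * pop_var(o)
    return 100.0 * bias / total, 100.0 * slope / total, 100.0 * random / total


def ccc(o, s):
    denom = pop_var(o) + pop_var(s) + (mean(s) - mean(o)) ** 2
    return 2.0 * pop_cov(o, s) / denom


def ca(o, s):
    denom = pop_var(o) + pop_var(s) + (mean(s) - mean(o)) ** 2
    return 2.0 * math.sqrt(pop_var(o)) * math.sqrt(pop_var(s)) / denom
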