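"""Shared fixtures and independent oracles for the polyedit test suite.

The oracles here deliberately avoid the implementation paths they check:
alignment penalties come from exhaustive path enumeration (tiny inputs) and a
memoized top-down recursion (small inputs), the guide scan from a literal
position-by-position loop, and rank statistics from hand-rolled formulas.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest
from hypothesis import settings

from polyedit import SimConfig, make_reference_set
from polyedit.homoeoassign import PhaseParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# small, distinctive penalty scheme used to probe the aligner's generality
ODD_PARAMS = PhaseParams(2, 5, 3, 2, 4, 1, 10**9)


@pytest.fixture(scope="session")
def default_refs():
    cfg = SimConfig(seed=7)
    return make_reference_set(cfg), cfg


def enumerated_min_penalty(read, ref, params, qual=None):
    """Exhaustive enumeration over every global alignment path (tiny inputs).

    No memoisation: every monotone path through the edit graph is walked, so
    this is exponential and only usable for len <= ~7.
    """
    mp = _mismatch_vector(read, params, qual)
    n, m = len(read), len(ref)
    best = [float("inf")]

    def walk(i, j, prev, cost):
        if cost >= best[0]:
            return
        if i == n and j == m:
            best[0] = cost
            return
        if i < n and j < m:
            sub = 0 if read[i] == ref[j] else mp[i]
            walk(i + 1, j + 1, "M", cost + sub)
        if i < n:
            extra = params.ref_gap_extend + (
                params.ref_gap_open if prev != "I" else 0
            )
            walk(i + 1, j, "I", cost + extra)
        if j < m:
            extra = params.read_gap_extend + (
                params.read_gap_open if prev != "D" else 0
            )
            walk(i, j + 1, "D", cost + extra)

    walk(0, 0, "-", 0)
    return best[0]


def recursive_min_penalty(read, ref, params, qual=None):
    """Memoized top-down recursion (independent formulation of the optimum)."""
    mp = _mismatch_vector(read, params, qual)
    n, m = len(read), len(ref)

    @functools.lru_cache(maxsize=None)
    def f(i, j, prev):
        if i == n and j == m:
            return 0
        options = []
        if i < n and j < m:
            sub = 0 if read[i] == ref[j] else mp[i]
            options.append(sub + f(i + 1, j + 1, "M"))
        if i < n:
            extra = params.ref_gap_extend + (
                params.ref_gap_open if prev != "I" else 0
            )
            options.append(extra + f(i + 1, j, "I"))
        if j < m:
            extra = params.read_gap_extend + (
                params.read_gap_open if prev != "D" else 0
            )
            options.append(extra + f(i, j + 1, "D"))
        return min(options)

    return f(0, 0, "-")


def _mismatch_vector(read, params, qual):
    if qual is None:
        return [params.mismatch_max] * len(read)
    q = np.minimum(np.asarray(qual), 40)
    span = params.mismatch_max - params.mismatch_min
    return list(params.mismatch_min + (span * q) // 40)


def scan_oracle(sequence, lo, hi):
    """Literal both-strand protospacer scan: (strand, cut_site, protospacer, pam)."""
    from polyedit.homoeoassign import revcomp

    out = set()
    n = len(sequence)
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for p in range(n - 2):
            if seq[p + 1] == "G" and seq[p + 2] == "G":
                for L in range(lo, hi + 1):
                    if p - L >= 0:
                        cut = p - 3 if strand == "+" else n - (p - 3)
                        out.add((strand, cut, seq[p - L : p], seq[p : p + 3]))
    return out


def spearman_oracle(x, y):
    """Spearman rho via average ranks + Pearson formula, written out by hand."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def welch_oracle(x, y):
    """Welch statistic, Satterthwaite df and two-sided p from first principles."""
    from scipy.stats import t as tdist

    x, y = list(map(float, x)), list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / se2**0.5
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
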