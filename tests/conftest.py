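"""Shared fixtures and independent brute-force oracles.

The oracles re-derive binding sites, efficiencies and product geometry
from first principles (naive scans, closed-form logistic evaluation) so
the indexed/seeded implementation can be checked against them exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ampliscore.thermo import NearestNeighborModel, reverse_complement


@pytest.fixture(scope="session")
def thermo():
    return NearestNeighborModel()


# ---------------------------------------------------------------------------
# independent piecewise logistic evaluation (closed form, written separately
# from the implementation)

def oracle_logistic(x, opt_min, opt_max, zero_min, zero_max, lim_min,
                    lim_max):
    if x == opt_min == opt_max:
        return 1.0  # single-point optimal range is attainable
    if x <= opt_min:
        if opt_min == lim_min:
            return 1.0
        k = 10.0 / (opt_min - lim_min)
        x0 = 0.5 * (opt_min + lim_min)
        y0 = math.exp(k * (zero_min - x0))
    elif x <= opt_max:
        return 1.0
    elif opt_max == lim_max:
        return 1.0
    else:
        k = 10.0 / (opt_max - lim_max)
        x0 = 0.5 * (opt_max + lim_max)
        y0 = math.exp(k * (zero_max - x0))
    e = -k * (x - x0)
    if e > 700.0:
        return -y0
    return (1.0 + y0) / (1.0 + math.exp(e)) - y0


def oracle_bound_efficiency(btm, mismatch_dist3):
    eff = oracle_logistic(btm, 60, 100, 45, 100, 45, 100)
    for m in mismatch_dist3:
        eff *= oracle_logistic(m, 25, 100, 0.95, 100, 0.95, 100)
    return min(max(eff, 0.0), 1.0)


# ---------------------------------------------------------------------------
# naive slide-and-score binding-site search

def oracle_find_sites(primer, reference, thermo, word=7, cutoff=1e-4):
    """Slide the primer over every position and strand; keep loci that
    share at least one exact word with the primer and pass the efficiency
    cutoff.  Returns (ref, strand, start) -> (btm, mismatches, eff)."""
    primer = primer.upper()
    length = len(primer)
    words = {primer[i:i + word] for i in range(length - word + 1)}
    out = {}
    for ref_id, seq in reference.items():
        seq = seq.upper()
        for start in range(len(seq) - length + 1):
            locus = seq[start:start + length]
            for strand, site in (("+", locus),
                                 ("-", reverse_complement(locus))):
                shared = any(site[i:i + word] in words
                             for i in range(length - word + 1))
                if not shared:
                    continue
                btm, mm = thermo.duplex_tm(primer, site)
                eff = oracle_bound_efficiency(btm, mm)
                if eff >= cutoff:
                    out[(ref_id, strand, start)] = (btm, mm, eff)
    return out


def oracle_products_face_to_face(sites1, sites2, dis_model, cutoff=1e-4):
    """All converging opposite-strand site pairs with their product
    efficiency.  Sites are (ref, strand, start, end, eff) tuples; the
    distance model is a 6-tuple.  Returns {(locus1, locus2): (bdis, eff)}
    keyed by ((ref, strand, start), (ref, strand, start))."""
    opt_min, opt_max, zero_min, zero_max, lim_min, lim_max = dis_model
    out = {}
    for r1, s1, p1, e1, eff1 in sites1:
        for r2, s2, p2, e2, eff2 in sites2:
            if r1 != r2 or s1 == s2:
                continue
            if s1 == "+":
                bdis = e2 - p1
            else:
                bdis = e1 - p2
            if not lim_min <= bdis <= lim_max:
                continue
            f = max(oracle_logistic(bdis, *dis_model), 0.0)
            eff = eff1 * eff2 * f
            if eff < cutoff:
                continue
            out[((r1, s1, p1), (r2, s2, p2))] = (bdis, eff)
    return out


def make_random_weights(rng: np.random.Generator, names):
    """A random integer weight table summing to 100."""
    cuts = sorted(rng.choice(np.arange(1, 100), size=len(names) - 1,
                             replace=False))
    bounds = [0, *map(int, cuts), 100]
    return {name: bounds[i + 1] - bounds[i]
            for i, name in enumerate(names)}
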