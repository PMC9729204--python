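"""Nearest-neighbor DNA thermodynamics.

Two-state nearest-neighbor model with the SantaLucia (1998) unified
parameter set: duplex melting temperature of oligos and of primer/site
hybrids with mismatches, self-structure (self-dimer and hairpin) melting
temperature, cross-dimer screening, and 3'-end stack free energy.

Conventions:

* ``Tm = dH*1000 / (dS_salt + R*ln(Ct/4)) - 273.15`` for bimolecular
  duplexes at equal strand concentrations (total strand concentration Ct);
  hairpins use the unimolecular form without the concentration term.
* Salt correction on entropy: ``dS + 0.368*(N-1)*ln([Na+]_eq)`` with the
  divalent cations converted to an equivalent monovalent concentration by
  ``[Na+]_eq = [mono] + 120*sqrt([divalent]-[dNTP])`` (concentrations in mM
  inside the square root).
* A mismatched stack contributes no stacking energy (dH = dS = 0), i.e. a
  fixed destabilization relative to any matched stack; an internal mismatch
  therefore voids both of its flanking stacks.  Exact agreement with any
  particular external engine is not a contract of this module -- the
  perfect-match and monotone-destabilization properties are, and an
  external engine can be substituted wherever a thermodynamics model object
  is accepted (any object with the same five methods).
* Sequences with no complementary stacking at all report ``NO_STRUCTURE_TM``
  (-100 C), i.e. "no stable structure".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

R_GAS = 1.987  # cal / (mol K)
NO_STRUCTURE_TM = -100.0

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# SantaLucia (1998) unified NN parameters, 5'->3' top-strand dinucleotide:
# (dH kcal/mol, dS cal/(mol K)).
_NN_HS = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# Duplex initiation per terminal base pair.
_INIT_HS = {"A": (2.3, 4.1), "T": (2.3, 4.1), "C": (0.1, -2.8),
            "G": (0.1, -2.8)}
# Fixed destabilization per mismatched position (kcal/mol), charged in
# addition to the voided flanking stacks.
MISMATCH_DH_PENALTY = 2.0

# Unified dG increments at 37 C (kcal/mol), used for 3'-end stability.
_NN_DG = {
    "AA": -1.00, "AT": -0.88, "TA": -0.58, "CA": -1.45, "GT": -1.44,
    "CT": -1.28, "GA": -1.30, "CG": -2.17, "GC": -2.24, "GG": -1.84,
}


def _mirror(table):
    full = dict(table)
    for dinuc, v in table.items():
        rc = _COMPLEMENT[dinuc[1]] + _COMPLEMENT[dinuc[0]]
        full.setdefault(rc, v)
    return full


_NN_HS = _mirror(_NN_HS)
_NN_DG = _mirror(_NN_DG)


class ThermoError(ValueError):
    """Invalid sequence or conditions."""


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions, all in molar units."""

    oligo_conc: float = 50e-9
    monovalent: float = 50e-3
    divalent: float = 1.5e-3
    dntp: float = 0.6e-3

    def __post_init__(self) -> None:
        for name in ("oligo_conc", "monovalent", "divalent", "dntp"):
            if getattr(self, name) < 0:
                raise ThermoError(f"negative concentration: {name}")

    @property
    def sodium_equivalent(self) -> float:
        """Effective monovalent cation concentration (molar)."""
        excess_mm = max(self.divalent - self.dntp, 0.0) * 1e3
        return self.monovalent + 120.0 * math.sqrt(excess_mm) * 1e-3


DEFAULT_CONDITIONS = ThermoConditions()


def check_dna(seq: str, min_len: int = 1) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise ThermoError(
            f"sequence of length {len(seq)} shorter than {min_len}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ThermoError(f"non-ACGT characters {sorted(bad)} in {seq!r}")
    return seq


def complement_base(base: str) -> str:
    return _COMPLEMENT[base]


def _duplex_sums(primer: str, site: str) -> tuple[float, float, int]:
    """(dH, dS, matched stack count) for an ungapped primer/site hybrid.

    ``site`` is written in primer orientation (the sequence a perfect-match
    primer would have); a position matches when the characters are equal.
    Both initiation terms are always charged (a mismatched terminus still
    leaves a helix end; waiving its unfavorable initiation would make the
    mismatch stabilizing), and every mismatched position pays a fixed
    enthalpy penalty on top of voiding its flanking stacks, so added
    mismatches lower the Tm monotonically even in very hot GC-rich
    duplexes.
    """
    dh = ds = 0.0
    matched = 0
    n = len(primer)
    for i in range(n - 1):
        if primer[i] == site[i] and primer[i + 1] == site[i + 1]:
            h, s = _NN_HS[primer[i] + primer[i + 1]]
            dh += h
            ds += s
            matched += 1
    if matched == 0:
        return 0.0, 0.0, 0
    dh += MISMATCH_DH_PENALTY * sum(
        1 for i in range(n) if primer[i] != site[i])
    for terminal in (primer[0], primer[-1]):
        h, s = _INIT_HS[terminal]
        dh += h
        ds += s
    return dh, ds, matched


def _tm_from_sums(dh: float, ds: float, n_bases: int,
                  cond: ThermoConditions, bimolecular: bool = True) -> float:
    if dh >= 0:
        return NO_STRUCTURE_TM
    ds_salt = ds + 0.368 * (n_bases - 1) * math.log(cond.sodium_equivalent)
    denom = ds_salt
    if bimolecular:
        denom = denom + R_GAS * math.log(cond.oligo_conc / 4.0)
    if denom >= 0:
        return NO_STRUCTURE_TM
    tm = dh * 1000.0 / denom - 273.15
    return max(tm, NO_STRUCTURE_TM)


def duplex_bound_tm(
    primer: str,
    site_seq: str,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
) -> tuple[float, tuple[int, ...]]:
    """Melting temperature of a (possibly mismatched) primer/site hybrid.

    ``site_seq`` is the binding locus written in primer orientation and of
    equal length (ungapped, full-length alignment).  Returns the duplex Tm in
    degrees C and the mismatch positions as 1-based distances from the
    primer 3' end (3'-terminal base = 1).  A perfect match reproduces
    :func:`oligo_tm` exactly.
    """
    primer = check_dna(primer)
    site_seq = check_dna(site_seq)
    if len(primer) != len(site_seq):
        raise ThermoError(
            f"primer ({len(primer)} nt) and site ({len(site_seq)} nt) "
            "must have equal length")
    n = len(primer)
    mismatches = tuple(n - i for i in range(n) if primer[i] != site_seq[i])
    dh, ds, matched = _duplex_sums(primer, site_seq)
    if matched == 0:
        return NO_STRUCTURE_TM, mismatches
    return _tm_from_sums(dh, ds, n, cond), mismatches


def oligo_tm(seq: str, cond: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Two-state NN melting temperature of an oligo against its perfect
    complement, in degrees C.  Requires length >= 8 and plain ACGT."""
    seq = check_dna(seq, min_len=8)
    tm, _ = duplex_bound_tm(seq, seq, cond)
    return tm


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def _best_antiparallel_duplex(
    a: str, site: str, cond: ThermoConditions,
    min_overlap: int = 4,
) -> tuple[float, int]:
    """Best ungapped alignment of ``a`` against ``site`` over all offsets.

    ``site`` must already be in ``a``'s orientation (i.e. the reverse
    complement of the partner strand).  Returns (Tm, offset); offset is the
    index of site[0] relative to a[0].
    """
    best = (NO_STRUCTURE_TM, 0)
    la, ls = len(a), len(site)
    for offset in range(-(ls - min_overlap), la - min_overlap + 1):
        a_lo = max(0, offset)
        a_hi = min(la, offset + ls)
        if a_hi - a_lo < min_overlap:
            continue
        sub_a = a[a_lo:a_hi]
        sub_s = site[a_lo - offset:a_hi - offset]
        dh, ds, matched = _duplex_sums(sub_a, sub_s)
        if matched == 0:
            continue
        tm = _tm_from_sums(dh, ds, len(sub_a), cond)
        if tm > best[0]:
            best = (tm, offset)
    return best


def self_dimer_tm(seq: str,
                  cond: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    seq = check_dna(seq)
    tm, _ = _best_antiparallel_duplex(seq, reverse_complement(seq), cond)
    return tm


# Entropic cost of closing a hairpin loop, as an entropy increment
# (cal/mol/K): a ~3.5 kcal/mol free-energy penalty at 37 C, loops of any
# length treated alike.  Without it a 4-bp stem would melt above 100 C.
_LOOP_DS = -3500.0 / 310.15


def hairpin_tm(seq: str,
               cond: ThermoConditions = DEFAULT_CONDITIONS,
               min_stem: int = 4, min_loop: int = 3) -> float:
    """Best perfect-stem hairpin Tm (unimolecular, no concentration term).

    Scans all antidiagonals for complementary runs with a loop of at least
    ``min_loop`` bases; mismatched stems only lower the Tm and are skipped.
    A fixed loop-closure entropy penalty is applied per hairpin.
    """
    seq = check_dna(seq)
    n = len(seq)
    best = NO_STRUCTURE_TM
    # i pairs with j on antidiagonal d = i + j; run downward in i.
    for d in range(2 * min_stem + min_loop - 1, 2 * n - 3):
        run: list[int] = []
        i_lo = max(0, d - n + 1)
        i_hi = (d - min_loop - 1) // 2  # innermost pair keeps loop >= min_loop
        for i in range(i_lo, i_hi + 2):  # one extra iteration flushes the run
            j = d - i
            paired = (i <= i_hi and j < n
                      and _COMPLEMENT[seq[i]] == seq[j])
            if paired:
                run.append(i)
            if not paired and len(run) >= min_stem:
                stem = seq[run[0]:run[-1] + 1]
                dh = ds = 0.0
                for t in range(len(stem) - 1):
                    h, s = _NN_HS[stem[t:t + 2]]
                    dh += h
                    ds += s
                tm = _tm_from_sums(dh, ds + _LOOP_DS, len(stem), cond,
                                   bimolecular=False)
                best = max(best, tm)
            if not paired:
                run = []
    return best


def self_structure_tm(seq: str,
                      cond: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Self feature value: max of self-dimer and hairpin Tm (degrees C)."""
    return max(self_dimer_tm(seq, cond), hairpin_tm(seq, cond))


def cross_dimer_tm(
    a: str, b: str,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
) -> tuple[float, bool]:
    """Best duplex Tm between two primers and a 3'-end-anchored flag.

    The flag is set when, in the best alignment, the 3'-terminal base of
    either primer lies inside the duplex window and is base-paired --
    the dimer geometry that a polymerase can extend.
    """
    a = check_dna(a)
    b = check_dna(b)
    site = reverse_complement(b)
    tm, offset = _best_antiparallel_duplex(a, site, cond)
    if tm <= NO_STRUCTURE_TM:
        return tm, False
    la, ls = len(a), len(site)
    a_lo, a_hi = max(0, offset), min(la, offset + ls)
    end_anchored = False
    # a's 3' end is a[la-1]; b's 3' end maps to site[0].
    if a_hi == la and a[la - 1] == site[la - 1 - offset]:
        end_anchored = True
    if a_lo <= offset < a_hi and a[offset] == site[0]:
        end_anchored = True
    return tm, end_anchored


def end_stability_dg(seq: str) -> float:
    """NN free energy (kcal/mol) of the 3'-terminal five bases: the sum of
    their four stack dG terms.  More negative = more stable 3' end."""
    seq = check_dna(seq, min_len=5)
    tail = seq[-5:]
    return sum(_NN_DG[tail[i:i + 2]] for i in range(4))


class NearestNeighborModel:
    """Default thermodynamics engine bound to fixed solution conditions.

    Any object exposing the same five methods can stand in for it wherever
    downstream modules accept a ``thermo`` argument.
    """

    def __init__(self, conditions: ThermoConditions = DEFAULT_CONDITIONS):
        self.conditions = conditions

    def oligo_tm(self, seq: str) -> float:
        return oligo_tm(seq, self.conditions)

    def duplex_tm(self, primer: str,
                  site_seq: str) -> tuple[float, tuple[int, ...]]:
        return duplex_bound_tm(primer, site_seq, self.conditions)

    def self_tm(self, seq: str) -> float:
        return self_structure_tm(seq, self.conditions)

    def cross_dimer(self, a: str, b: str) -> tuple[float, bool]:
        return cross_dimer_tm(a, b, self.conditions)

    def end_dg(self, seq: str) -> float:
        return end_stability_dg(seq)
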