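"""Binding-site discovery and in-silico PCR product enumeration.

A primer's plausible binding sites on a reference are found by exact-word
seeding (default word size 7) followed by ungapped full-length extension:
every reference locus sharing at least one exact 7-mer with the primer is
aligned, its bound melting temperature and mismatch positions computed, and
its *bound efficiency* predicted as

    E = f(btm) * prod_j f(m_j)

where ``btm`` is the bound Tm of the hybrid and ``m_j`` the 1-based distance
of mismatch ``j`` from the primer 3' end (a 3'-terminal mismatch still
amplifies a trace of product, so f(m)'s lower limit is 0.95, putting the
terminal-mismatch factor just above the default efficiency cutoff 1e-4).
With word size 7 a 20-mer site with up to 35% mismatches remains detectable
whenever one exact word survives.

Two sites in a legal orientation and distance form a potential product with
amplification efficiency ``E_prod = E1 * E2 * f(bdis)``; everything below
the cutoff is discarded.  The sum of the efficiencies of all non-target
products (oEff) is the pair's specificity value, scored downstream like any
other relation feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product
from typing import Iterable, Mapping, Sequence

from .score_model import ModelParams, piecewise_score, default_models
from .thermo import NearestNeighborModel, reverse_complement

#: Default minimum predicted efficiency for a site or product to be kept.
EFFICIENCY_CUTOFF = 1e-4
#: Default maximum PCR product size (bases) for the f(bdis) upper limit.
MAX_PCR_SIZE = 2000

ORIENTATIONS = ("face-to-face", "back-to-back", "unidirectional")


class SpecificityError(ValueError):
    """Invalid index or enumeration input."""


@dataclass(frozen=True)
class BindingSite:
    """One ungapped full-length primer-to-reference alignment.

    ``mismatch_dist3`` holds 1-based distances from the primer 3' end
    (terminal base = 1); ``efficiency`` is the bound efficiency
    f(btm)*prod f(m_j), clamped to [0, 1].
    """

    ref_id: str
    strand: str
    start: int
    end: int
    bound_tm: float
    mismatch_dist3: tuple[int, ...]
    efficiency: float

    @property
    def locus(self) -> tuple[str, str, int]:
        return (self.ref_id, self.strand, self.start)


@dataclass(frozen=True)
class Product:
    """An ordered site pair in a legal geometry, with its efficiency."""

    site1: BindingSite
    site2: BindingSite
    orientation: str
    bdis: int
    efficiency: float
    is_target: bool = False


class SeedIndex:
    """Exact k-mer -> positions index over the forward strand.

    Reverse-strand hits are found by querying the reverse complement of the
    word, so a single forward pass over the reference suffices.
    """

    def __init__(self, reference: Mapping[str, str], word: int = 7):
        if word < 4:
            raise SpecificityError(f"word size must be >= 4, got {word}")
        if not reference:
            raise SpecificityError("empty reference")
        self.word = word
        self.reference = {name: seq.upper()
                          for name, seq in reference.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.reference.items():
            for i in range(len(seq) - word + 1):
                index.setdefault(seq[i:i + word], []).append((name, i))
        self._index = index

    def positions(self, kmer: str) -> list[tuple[str, int]]:
        """Forward-strand occurrences of ``kmer`` as (ref_id, pos)."""
        return self._index.get(kmer.upper(), [])


def bound_efficiency(
    bound_tm: float,
    mismatch_dist3: Iterable[int],
    models: Mapping[str, ModelParams] | None = None,
) -> float:
    """Bound efficiency ``E = f(btm) * prod f(m_j)``, clamped at 0.

    The factor product can go negative below f(btm)'s zero point; a
    negative value means "no amplification" and is reported as 0.
    """
    if models is None:
        models = default_models()
    eff = piecewise_score(bound_tm, models["btm"])
    for m in mismatch_dist3:
        eff *= piecewise_score(m, models["mismatch_pos"])
    return min(max(eff, 0.0), 1.0)


def find_binding_sites(
    primer: str,
    index: SeedIndex,
    thermo: NearestNeighborModel,
    models: Mapping[str, ModelParams] | None = None,
    efficiency_cutoff: float = EFFICIENCY_CUTOFF,
) -> list[BindingSite]:
    """All binding sites of a primer that share an exact seed word.

    Every seed hit is extended ungapped to the full primer length on both
    strands; sites running off the reference end are skipped; sites are kept
    when their bound efficiency reaches ``efficiency_cutoff`` (pass 0 to
    keep every detected alignment) and deduplicated by locus.  Output is
    sorted by (ref_id, start, strand).
    """
    primer = primer.upper()
    w = index.word
    length = len(primer)
    if length < w:
        raise SpecificityError(
            f"primer ({length} nt) shorter than word size {w}")
    if models is None:
        models = default_models()
    rc_primer = reverse_complement(primer)
    candidates: set[tuple[str, str, int]] = set()
    for offset in range(length - w + 1):
        word = primer[offset:offset + w]
        for ref_id, pos in index.positions(word):
            candidates.add((ref_id, "+", pos - offset))
        # a minus-strand site carries the primer word as its reverse
        # complement on the forward reference strand
        for ref_id, pos in index.positions(reverse_complement(word)):
            candidates.add((ref_id, "-", pos + w + offset - length))
    sites = []
    for ref_id, strand, start in sorted(candidates):
        ref_seq = index.reference[ref_id]
        end = start + length
        if start < 0 or end > len(ref_seq):
            continue
        locus = ref_seq[start:end]
        site_seq = locus if strand == "+" else reverse_complement(locus)
        btm, mismatches = thermo.duplex_tm(primer, site_seq)
        eff = bound_efficiency(btm, mismatches, models)
        if eff >= efficiency_cutoff:
            sites.append(BindingSite(
                ref_id=ref_id, strand=strand, start=start, end=end,
                bound_tm=btm, mismatch_dist3=mismatches, efficiency=eff))
    sites.sort(key=lambda s: (s.ref_id, s.start, s.strand))
    return sites


def product_geometry(site1: BindingSite, site2: BindingSite,
                     orientation: str) -> int | None:
    """Signed primer-to-primer distance if the geometry is legal, else None.

    face-to-face: converging primers on opposite strands; bdis is the
    product size, the inclusive span between the two 5' ends.
    back-to-back: diverging primers; bdis is the gap between the 5' ends
    (the product forms across a circular template).
    unidirectional: both primers on the same strand (outer then nested);
    bdis = nested 5' start - outer 3' end, negative when they overlap.
    """
    if site1.ref_id != site2.ref_id:
        return None
    if orientation == "face-to-face":
        if site1.strand == "+" and site2.strand == "-":
            plus, minus = site1, site2
        elif site1.strand == "-" and site2.strand == "+":
            plus, minus = site2, site1
        else:
            return None
        return minus.end - plus.start
    if orientation == "back-to-back":
        if site1.strand == "-" and site2.strand == "+":
            left, right = site1, site2
        elif site1.strand == "+" and site2.strand == "-":
            left, right = site2, site1
        else:
            return None
        return right.start - left.end
    if orientation == "unidirectional":
        if site1.strand != site2.strand:
            return None
        if site1.strand == "+":
            return site2.start - (site1.end - 1)
        return (site1.start + 1) - site2.end
    raise SpecificityError(f"unknown orientation {orientation!r}")


def bdis_model(dis_params: ModelParams,
               orientation: str = "face-to-face",
               max_pcr_size: int = MAX_PCR_SIZE) -> ModelParams:
    """The f(bdis) product-distance model derived from the task's distance
    range: for face-to-face products the lower limit is 30 bases (shorter
    amplicons are not formed) and the upper limit is the maximum PCR size;
    other orientations keep the task's own limits."""
    if orientation == "face-to-face":
        return ModelParams(
            dis_params.opt_min, dis_params.opt_max,
            max(dis_params.zero_min, 30), dis_params.zero_max,
            30, max(max_pcr_size, dis_params.zero_max))
    return dis_params


def _canonical_key(p: Product) -> tuple:
    a = (p.site1.ref_id, p.site1.strand, p.site1.start, p.site1.end)
    b = (p.site2.ref_id, p.site2.strand, p.site2.start, p.site2.end)
    return (p.orientation,) + tuple(sorted((a, b)))


def enumerate_products(
    sites1: Sequence[BindingSite],
    sites2: Sequence[BindingSite],
    orientation: str,
    dis_params: ModelParams,
    efficiency_cutoff: float = EFFICIENCY_CUTOFF,
    origin1: tuple[str, str, int] | None = None,
    origin2: tuple[str, str, int] | None = None,
    distance_model: ModelParams | None = None,
) -> list[Product]:
    """All legal products between two site lists.

    A pair of sites forms a product when the geometry fits ``orientation``
    and ``MinL <= bdis <= MaxL`` of the distance model; its efficiency is
    ``E1 * E2 * f(bdis)`` and products below the cutoff are dropped.  The
    product whose sites match ``origin1``/``origin2`` (the design locus) is
    flagged as the target.  Duplicate geometries (e.g. when both lists
    contain the same site) are collapsed.
    """
    if orientation not in ORIENTATIONS:
        raise SpecificityError(f"unknown orientation {orientation!r}")
    dmodel = distance_model or bdis_model(dis_params, orientation)
    out: dict[tuple, Product] = {}
    for s1, s2 in iter_product(sites1, sites2):
        bdis = product_geometry(s1, s2, orientation)
        if bdis is None or not dmodel.lim_min <= bdis <= dmodel.lim_max:
            continue
        eff = s1.efficiency * s2.efficiency \
            * max(piecewise_score(bdis, dmodel), 0.0)
        if eff < efficiency_cutoff:
            continue
        is_target = (origin1 is not None and origin2 is not None
                     and s1.locus == origin1 and s2.locus == origin2)
        prod = Product(site1=s1, site2=s2, orientation=orientation,
                       bdis=bdis, efficiency=eff, is_target=is_target)
        key = _canonical_key(prod)
        prev = out.get(key)
        if prev is None or (prod.is_target and not prev.is_target):
            out[key] = prod
    products = list(out.values())
    products.sort(key=lambda p: (p.site1.ref_id, p.site1.start,
                                 p.site2.start, p.site1.strand,
                                 p.site2.strand))
    return products


def off_target_sum(products: Iterable[Product]) -> float:
    """oEff: the summed efficiency of every non-target product."""
    return sum(p.efficiency for p in products if not p.is_target)
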