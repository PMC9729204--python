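"""Candidate primer generation and single-primer evaluation.

Candidates are produced by walking along a template region on a position and
length grid.  Common variants are first folded into the reference as IUPAC
degenerate bases (:func:`mask_reference`), so each candidate carries both its
plain sequence (reference alleles) and a degenerate sequence from which the
covered SNPs are recovered.  Seven features are evaluated per candidate --
melting temperature (Tm), GC fraction, self-structure Tm (Self), 3'-terminal
adenine run (EndA), 3'-end stack free energy (EnddG), covered SNPs and
homopolymer runs (polys) -- and combined into a 0-100 score by the piecewise
logistic models and the weight table.

Coordinates are 0-based half-open throughout; minus-strand candidates read
as the reverse complement of the reference slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .score_model import (FeatureWeights, ModelParams, SiteAnnotation,
                          default_models, piecewise_score,
                          site_penalty_score, weighted_total)
from .thermo import NearestNeighborModel

#: IUPAC code -> set of bases (e.g. "R" -> {"A", "G"}).
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items() if code != "X"
}
#: set of bases -> IUPAC code.
BASES_TO_IUPAC: dict[frozenset[str], str] = {
    bases: code for code, bases in IUPAC_TO_BASES.items()
}


class CandidateError(ValueError):
    """Invalid region, reference or variant input."""


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R <-> Y etc.)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class TemplateRegion:
    """A template interval: 0-based half-open [start, end) on ``ref_id``."""

    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise CandidateError(
                f"invalid region {self.ref_id}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise CandidateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerCandidate:
    """A candidate oligo anchored on the reference.

    ``seq`` is the synthesized sequence 5'->3' (reference alleles only);
    ``degenerate_seq`` is the same read off the masked reference and may
    carry IUPAC codes at common-variant positions.  ``start``/``end`` span
    the occupied reference interval regardless of strand.
    """

    id: str
    seq: str
    degenerate_seq: str
    ref_id: str
    start: int
    end: int
    strand: str
    region: TemplateRegion | None = field(default=None, compare=False)

    @property
    def three_prime_pos(self) -> int:
        """Reference coordinate of the 3'-terminal base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def locus(self) -> tuple[str, str, int]:
        return (self.ref_id, self.strand, self.start)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureSet:
    """The seven evaluated single-primer features."""

    tm: float
    gc: float
    self_tm: float
    end_a: int
    end_dg: float
    snps: tuple[SiteAnnotation, ...]
    polys: tuple[SiteAnnotation, ...]


def _merge_codes(existing: str, new_bases: frozenset[str]) -> str:
    merged = IUPAC_TO_BASES[existing] | new_bases
    return BASES_TO_IUPAC[merged]


def mask_reference(
    reference: Mapping[str, str],
    variants: Iterable[tuple[str, int, str, Sequence[str]]],
) -> tuple[dict[str, str], pd.DataFrame]:
    """Fold common variants into the reference as degenerate bases.

    ``variants`` yields ``(chrom, pos0, ref_allele, alt_alleles)`` with
    0-based positions.  Substitutions become the IUPAC code covering the
    reference plus all alternate alleles (multi-allelic sites merge into one
    code).  Indels cannot be expressed as a single-base code; they are
    recorded in a side-channel interval table with the number of affected
    bases ``max(len(ref), len(alt)) - 1``: the bases after the anchor base
    for a deletion, the two junction bases for an insertion.

    Returns the masked sequences and the indel table
    (columns chrom/start/end/length).
    """
    masked = {name: list(seq.upper()) for name, seq in reference.items()}
    indels: list[tuple[str, int, int, int]] = []
    for chrom, pos0, ref_allele, alts in variants:
        if chrom not in masked:
            raise CandidateError(
                f"variant contig {chrom!r} not in reference "
                f"({sorted(masked)})")
        seq = masked[chrom]
        if not 0 <= pos0 < len(seq):
            raise CandidateError(
                f"variant position {pos0} outside {chrom} "
                f"(length {len(seq)})")
        ref_allele = ref_allele.upper()
        snp_alts = [a.upper() for a in alts
                    if len(a) == 1 and len(ref_allele) == 1]
        indel_alts = [a.upper() for a in alts
                      if len(a) != 1 or len(ref_allele) != 1]
        if snp_alts:
            bases = frozenset(snp_alts) | frozenset(ref_allele)
            seq[pos0] = _merge_codes(seq[pos0], bases)
        for alt in indel_alts:
            length = max(len(ref_allele), len(alt)) - 1
            if length < 1:
                continue
            if len(ref_allele) > 1:  # deletion: bases after the anchor
                start, end = pos0 + 1, pos0 + 1 + length
            else:  # insertion: the junction
                start, end = pos0, pos0 + 2
            indels.append((chrom, start, min(end, len(seq)), length))
    table = pd.DataFrame(indels, columns=["chrom", "start", "end", "length"])
    return {name: "".join(seq) for name, seq in masked.items()}, table


def walk_candidates(
    region: TemplateRegion,
    reference: Mapping[str, str],
    masked: Mapping[str, str] | None = None,
    min_len: int = 18,
    max_len: int = 30,
    pos_step: int = 1,
    len_step: int = 2,
    strands: Sequence[str] = ("+", "-"),
    id_prefix: str = "",
) -> list[PrimerCandidate]:
    """Enumerate candidates on the (position, length) grid inside a region.

    One candidate per grid point and strand, ordered by start position, then
    length, then strand; a region shorter than ``min_len`` yields an empty
    list.  Lengths run ``min_len, min_len+len_step, ...`` up to ``max_len``.
    """
    if min_len > max_len:
        raise CandidateError(f"min_len {min_len} > max_len {max_len}")
    if pos_step < 1 or len_step < 1:
        raise CandidateError("steps must be >= 1")
    ref_seq = reference[region.ref_id]
    if region.end > len(ref_seq):
        raise CandidateError(
            f"region {region.ref_id}:{region.start}-{region.end} exceeds "
            f"reference length {len(ref_seq)}")
    masked_seq = masked[region.ref_id] if masked else ref_seq
    out: list[PrimerCandidate] = []
    lengths = list(range(min_len, max_len + 1, len_step))
    for start in range(region.start, region.end - min_len + 1, pos_step):
        for length in lengths:
            end = start + length
            if end > region.end:
                continue
            plain = ref_seq[start:end].upper()
            degen = masked_seq[start:end].upper()
            for strand in strands:
                seq = plain if strand == "+" else reverse_complement(plain)
                dseq = degen if strand == "+" else reverse_complement(degen)
                out.append(PrimerCandidate(
                    id=f"{id_prefix}{region.ref_id}:{start}-{end}:{strand}",
                    seq=seq, degenerate_seq=dseq, ref_id=region.ref_id,
                    start=start, end=end, strand=strand, region=region))
    return out


def _end_a_run(seq: str) -> int:
    n = 0
    for base in reversed(seq):
        if base != "A":
            break
        n += 1
    return n


def _poly_sites(seq: str, min_run: int) -> tuple[SiteAnnotation, ...]:
    sites = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            # dist3 of the run's 3'-most base
            sites.append(SiteAnnotation(dist3=n - j, length=j - i))
        i = j
    return tuple(sites)


def _snp_sites(cand: PrimerCandidate,
               indel_table: pd.DataFrame | None) -> tuple[SiteAnnotation, ...]:
    sites = []
    n = len(cand.degenerate_seq)
    rows = None
    if indel_table is not None and len(indel_table):
        rows = indel_table[indel_table["chrom"] == cand.ref_id]
    for i, code in enumerate(cand.degenerate_seq):
        if code in "ACGT":
            continue
        dist3 = n - 1 - i
        # reference coordinate of this base
        g = cand.start + i if cand.strand == "+" else cand.end - 1 - i
        length = 1
        if rows is not None:
            hit = rows[(rows["start"] <= g) & (g < rows["end"])]
            if len(hit):
                length = int(hit["length"].max())
        sites.append(SiteAnnotation(dist3=dist3, length=length))
    return tuple(sites)


def extract_features(
    cand: PrimerCandidate,
    thermo: NearestNeighborModel,
    indel_table: pd.DataFrame | None = None,
    poly_min_run: int = 4,
) -> FeatureSet:
    """Evaluate the seven single-primer features of a candidate."""
    seq = cand.seq
    return FeatureSet(
        tm=thermo.oligo_tm(seq),
        gc=(seq.count("G") + seq.count("C")) / len(seq),
        self_tm=thermo.self_tm(seq),
        end_a=_end_a_run(seq),
        end_dg=thermo.end_dg(seq),
        snps=_snp_sites(cand, indel_table),
        polys=_poly_sites(seq, poly_min_run),
    )


def score_primer(
    features: FeatureSet,
    models: Mapping[str, ModelParams] | None = None,
    weights: FeatureWeights | None = None,
    opt_tm: float | None = None,
) -> tuple[float, dict[str, float]]:
    """Score a feature set; returns (total on the 0-100 scale, breakdown).

    ``models`` must contain an instantiated "Tm" entry or ``opt_tm`` must be
    given to build one.  The total is 100 exactly iff every feature lies in
    its optimal range.
    """
    from .score_model import DEFAULT_PRIMER_WEIGHTS, ScoreModelError
    if models is None or "Tm" not in models:
        if opt_tm is None:
            raise ScoreModelError(
                "either models['Tm'] or opt_tm must be provided")
        models = default_models(opt_tm, overrides=models)
    if weights is None:
        weights = DEFAULT_PRIMER_WEIGHTS
    scores = {
        "Tm": piecewise_score(features.tm, models["Tm"]),
        "GC": piecewise_score(features.gc, models["GC"]),
        "Self": piecewise_score(features.self_tm, models["Self"]),
        "EndA": piecewise_score(features.end_a, models["EndA"]),
        "EnddG": piecewise_score(features.end_dg, models["EnddG"]),
        "SNP": site_penalty_score(features.snps, "snp", models),
        "poly": site_penalty_score(features.polys, "poly", models),
    }
    return weighted_total(scores, weights), scores
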