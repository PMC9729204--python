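"""Synthetic fixture generation.

Everything the engine consumes can be generated here reproducibly from a
seed: a random reference with controlled GC content, duplicated segments at
controlled divergence (predictable off-target products), planted primer
binding sites with chosen mismatch counts that preserve one exact seed
word, embedded SNP positions (emitted as a VCF), homopolymer runs and
target spots.  Alongside the sequences a machine-readable truth table
records where every planted site and duplicated segment went, so oracle
tests can assert against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .candidate import TemplateRegion

_BASES = np.array(list("ACGT"))


class FixtureError(ValueError):
    """Inconsistent fixture specification."""


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for one planted primer binding site."""

    ref_id: str
    strand: str
    start: int
    n_mismatches: int


@dataclass(frozen=True)
class FixtureSpec:
    """What to synthesize.

    ``planted_copies`` lists the mismatch count of each planted copy of the
    planted primer site (0 = exact); mismatches are placed so that the
    ``preserved_word``-long window at the primer 3' end stays exact.
    """

    length: int = 10_000
    gc: float = 0.5
    n_duplications: int = 0
    segment_length: int = 500
    divergence: float = 0.0
    planted_primer_length: int = 20
    planted_copies: tuple[int, ...] = ()
    preserved_word: int = 7
    snp_count: int = 0
    homopolymer_runs: int = 0
    homopolymer_length: int = 8
    n_targets: int = 0
    ref_id: str = "synth1"

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 1:
            raise FixtureError("divergence must be in [0, 1]")
        if self.n_duplications:
            if self.segment_length > self.length:
                raise FixtureError(
                    "duplicated segment longer than the genome")
            if (self.n_duplications + 1) * self.segment_length > self.length:
                raise FixtureError("duplications do not fit in the genome")


@dataclass
class Fixture:
    """Generated sequences plus machine-readable truth."""

    reference: dict[str, str]
    variants: list[tuple[str, int, str, tuple[str, ...]]]
    regions: list[TemplateRegion]
    targets: list[tuple[str, int]]
    planted_primer: str | None
    planted_sites: list[PlantedSite]
    duplicated_segments: list[tuple[int, int, int]]  # (start, end, n_subs)
    spec: FixtureSpec = field(repr=False, default=None)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p_gc, p_at = gc / 2.0, (1.0 - gc) / 2.0
    return rng.choice(_BASES, size=n, p=[p_at, p_gc, p_gc, p_at])


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def _plant_mismatched_copy(
    rng: np.random.Generator, primer: str, n_mismatch: int, word: int,
) -> str:
    """A copy of the primer site with ``n_mismatch`` substitutions, keeping
    the 3'-terminal ``word`` bases exact so one seed word survives."""
    mutable = list(range(len(primer) - word))
    if n_mismatch > len(mutable):
        raise FixtureError(
            f"{n_mismatch} mismatches do not fit outside the preserved "
            f"{word}-mer of a {len(primer)}-mer")
    picks = rng.choice(mutable, size=n_mismatch, replace=False)
    site = list(primer)
    for i in sorted(int(p) for p in picks):
        site[i] = _substitute(rng, site[i])
    return "".join(site)


def generate_fixture(spec: FixtureSpec, seed: int,
                     outdir: str | Path | None = None) -> Fixture:
    """Synthesize a fixture; byte-identical for identical (spec, seed).

    Layout: duplicated segments first (the source segment is copied at
    even offsets with ``round(divergence * segment_length)`` substitutions
    each), then planted primer-site copies in the downstream half, then
    SNPs/homopolymers/targets scattered over unoccupied sequence.
    """
    rng = np.random.default_rng(seed)
    genome = _random_seq(rng, spec.length, spec.gc)
    occupied = np.zeros(spec.length, dtype=bool)

    duplicated: list[tuple[int, int, int]] = []
    if spec.n_duplications:
        seg_len = spec.segment_length
        n_subs = round(spec.divergence * seg_len)
        src = genome[:seg_len].copy()
        occupied[:seg_len] = True
        duplicated.append((0, seg_len, 0))
        gap = (spec.length - seg_len) // spec.n_duplications
        for k in range(spec.n_duplications):
            start = seg_len + k * gap
            copy = src.copy()
            if n_subs:
                idx = rng.choice(seg_len, size=n_subs, replace=False)
                for i in idx:
                    copy[i] = _substitute(rng, copy[i])
            genome[start:start + seg_len] = copy
            occupied[start:start + seg_len] = True
            duplicated.append((start, start + seg_len, n_subs))

    planted_primer = None
    planted_sites: list[PlantedSite] = []
    if spec.planted_copies:
        plen = spec.planted_primer_length
        primer_arr = _random_seq(rng, plen, 0.55)  # a designable 20-mer
        planted_primer = "".join(primer_arr)
        lo = spec.length // 2
        span = (spec.length - lo) // len(spec.planted_copies)
        if span < plen + 10:
            raise FixtureError("planted copies do not fit")
        for k, n_mm in enumerate(spec.planted_copies):
            start = lo + k * span
            site = _plant_mismatched_copy(rng, planted_primer, n_mm,
                                          spec.preserved_word)
            genome[start:start + plen] = list(site)
            occupied[start:start + plen] = True
            planted_sites.append(PlantedSite(
                ref_id=spec.ref_id, strand="+", start=start,
                n_mismatches=n_mm))

    free = np.flatnonzero(~occupied)
    variants: list[tuple[str, int, str, tuple[str, ...]]] = []
    if spec.snp_count:
        pos = rng.choice(free, size=min(spec.snp_count, len(free)),
                         replace=False)
        for p in sorted(int(v) for v in pos):
            ref_allele = str(genome[p])
            variants.append((spec.ref_id, p, ref_allele,
                             (_substitute(rng, ref_allele),)))

    for _ in range(spec.homopolymer_runs):
        run_len = spec.homopolymer_length
        p = int(rng.integers(0, spec.length - run_len))
        genome[p:p + run_len] = str(_BASES[rng.integers(4)])

    targets = []
    if spec.n_targets:
        pos = rng.choice(free, size=spec.n_targets, replace=False)
        targets = [(spec.ref_id, int(p)) for p in sorted(pos)]

    reference = {spec.ref_id: "".join(genome)}
    regions = [TemplateRegion(spec.ref_id, 0, spec.length)]
    fixture = Fixture(reference=reference, variants=variants,
                      regions=regions, targets=targets,
                      planted_primer=planted_primer,
                      planted_sites=planted_sites,
                      duplicated_segments=duplicated, spec=spec)
    if outdir is not None:
        write_fixture(fixture, outdir)
    return fixture


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write FASTA + VCF + BED files and a TSV truth table."""
    from .io import write_bed, write_fasta, write_vcf  # avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.reference, outdir / "reference.fa")
    write_vcf(fixture.variants, fixture.reference, outdir / "variants.vcf")
    write_bed(fixture.regions, outdir / "regions.bed")
    with open(outdir / "targets.bed", "w") as fh:
        for ref_id, pos in fixture.targets:
            fh.write(f"{ref_id}\t{pos}\t{pos + 1}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("kind\tref_id\tstrand\tstart\tend\tdetail\n")
        if fixture.planted_primer:
            fh.write(f"planted_primer\t.\t+\t.\t.\t"
                     f"{fixture.planted_primer}\n")
        for s in fixture.planted_sites:
            fh.write(f"planted_site\t{s.ref_id}\t{s.strand}\t{s.start}\t"
                     f"{s.start + len(fixture.planted_primer)}\t"
                     f"mismatches={s.n_mismatches}\n")
        for start, end, n_subs in fixture.duplicated_segments:
            fh.write(f"duplicated_segment\t{fixture.spec.ref_id}\t+\t"
                     f"{start}\t{end}\tsubstitutions={n_subs}\n")


def clean_template(length: int = 400, seed: int = 0, gc: float = 0.5,
                   ref_id: str = "tpl1") -> dict[str, str]:
    """A plain random template with no planted structure."""
    rng = np.random.default_rng(seed)
    return {ref_id: "".join(_random_seq(rng, length, gc))}


def hostile_template(length: int, seed: int, ref_id: str = "tpl1"
                     ) -> dict[str, str]:
    """Deliberately awkward templates: extreme GC, homopolymers, tandem
    repeats -- every feature lands outside its optimal range somewhere."""
    rng = np.random.default_rng(seed)
    style = seed % 4
    if style == 0:
        seq = _random_seq(rng, length, 0.9)
    elif style == 1:
        seq = _random_seq(rng, length, 0.08)
    elif style == 2:  # dinucleotide tandem repeat with noise
        unit = "AT" if rng.integers(2) else "GC"
        seq = np.array(list((unit * (length // 2 + 1))[:length]))
        idx = rng.choice(length, size=length // 10, replace=False)
        for i in idx:
            seq[i] = str(_BASES[rng.integers(4)])
    else:  # homopolymer-riddled
        seq = _random_seq(rng, length, 0.5)
        for _ in range(max(3, length // 40)):
            p = int(rng.integers(0, length - 8))
            seq[p:p + 8] = str(_BASES[rng.integers(4)])
    return {ref_id: "".join(seq)}
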