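"""Readers and writers for the standard input/output formats.

Four input types are supported: template sequences (FASTA), template
regions (BED), target spots (BED or VCF), and pre-designed primer lists
(TSV with columns ``id`` and ``seq``).  All coordinates are normalized to
0-based half-open internally (BED is native, VCF positions are converted
from 1-based).  Results are written as TSV with a documented column order.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .candidate import IUPAC_TO_BASES, TemplateRegion
from .design import PairResult, TargetSpot


class InputError(ValueError):
    """Malformed or inconsistent input file."""


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[TemplateRegion]:
    """BED (0-based half-open); strand read from column 6 when present."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path} line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(
                    f"{path} line {lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" \
                else "+"
            try:
                regions.append(TemplateRegion(fields[0], start, end, strand))
            except ValueError as exc:
                raise InputError(f"{path} line {lineno}: {exc}") from exc
    if not regions:
        raise InputError(f"no regions in {path}")
    return regions


def read_vcf_variants(
    path: str | Path,
) -> list[tuple[str, int, str, tuple[str, ...]]]:
    """(chrom, pos0, ref, alts) tuples; only CHROM/POS/REF/ALT are used."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            out.append((rec.chrom, rec.pos - 1, rec.ref, alts))
    return out


def read_targets(path: str | Path) -> list[TargetSpot]:
    """Target spots from BED (start coordinate) or VCF (POS - 1, REF/ALT
    become the assay alleles)."""
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz") or _looks_like_vcf(path):
        spots = []
        for chrom, pos0, ref, alts in read_vcf_variants(path):
            alleles = tuple(a for a in (ref,) + alts if len(a) == 1)
            spots.append(TargetSpot(ref_id=chrom, pos=pos0,
                                    name=f"{chrom}:{pos0}",
                                    alleles=alleles))
        return spots
    return [TargetSpot(ref_id=r.ref_id, pos=r.start,
                       name=f"{r.ref_id}:{r.start}")
            for r in read_bed(path)]


def _looks_like_vcf(path: Path) -> bool:
    try:
        with open(path) as fh:
            return fh.readline().startswith("##fileformat=VCF")
    except OSError:
        return False


_VALID_PRIMER_CHARS = set(IUPAC_TO_BASES)


def read_primer_tsv(path: str | Path) -> dict[str, str]:
    """Primer list: TSV with an id column and a sequence column (header
    optional).  IUPAC ambiguity codes are allowed; anything else names the
    offending line in the error."""
    primers: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(
                    f"{path} line {lineno}: expected id<TAB>sequence")
            name, seq = fields[0].strip(), fields[1].strip().upper()
            if lineno == 1 and set(seq) - _VALID_PRIMER_CHARS:
                continue  # header row
            bad = set(seq) - _VALID_PRIMER_CHARS
            if bad:
                raise InputError(
                    f"{path} line {lineno}: invalid sequence characters "
                    f"{sorted(bad)} in {name!r}")
            if name in primers:
                raise InputError(
                    f"{path} line {lineno}: duplicate primer id {name!r}")
            primers[name] = seq
    if not primers:
        raise InputError(f"no primers in {path}")
    return primers


def write_vcf(
    variants: Iterable[tuple[str, int, str, Sequence[str]]],
    contigs: Mapping[str, str],
    path: str | Path,
) -> None:
    """Minimal VCFv4 writer: (chrom, pos0, ref, alts) records."""
    header = pysam.VariantHeader()
    for name, seq in contigs.items():
        header.contigs.add(name, length=len(seq))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos0, ref, alts in variants:
            rec = vcf.new_record(contig=chrom, start=pos0,
                                 alleles=(ref, *alts))
            vcf.write(rec)


def write_bed(regions: Iterable[TemplateRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.ref_id}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")


#: Column order of the ranked-pair results table.
PAIR_COLUMNS = [
    "target", "rank", "primer1_id", "primer1_seq", "primer2_id",
    "primer2_seq", "primer1_start", "primer1_end", "primer1_strand",
    "primer2_start", "primer2_end", "primer2_strand", "score1", "score2",
    "relation_score", "final_score", "tmdiff", "lendiff", "pos", "dis",
    "oeff", "n_products",
]


def pairs_to_dataframe(
    results: Mapping[str, Sequence[PairResult]],
) -> pd.DataFrame:
    rows = []
    for target, pairs in results.items():
        for pr in pairs:
            rel = pr.relation
            rows.append({
                "target": target, "rank": pr.rank,
                "primer1_id": pr.primer1.id, "primer1_seq": pr.primer1.seq,
                "primer2_id": pr.primer2.id, "primer2_seq": pr.primer2.seq,
                "primer1_start": pr.primer1.start,
                "primer1_end": pr.primer1.end,
                "primer1_strand": pr.primer1.strand,
                "primer2_start": pr.primer2.start,
                "primer2_end": pr.primer2.end,
                "primer2_strand": pr.primer2.strand,
                "score1": round(pr.score1, 4),
                "score2": round(pr.score2, 4),
                "relation_score": round(pr.relation_score, 4),
                "final_score": round(pr.final_score, 4),
                "tmdiff": round(rel.tmdiff, 3),
                "lendiff": rel.lendiff,
                "pos": "" if rel.pos is None else rel.pos,
                "dis": rel.dis, "oeff": round(rel.oeff, 6),
                "n_products": len(pr.products),
            })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pairs_tsv(results, path: str | Path,
                    header_lines: Sequence[str] = ()) -> None:
    df = pairs_to_dataframe(results)
    buf = _io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def write_dimer_tsv(report, path: str | Path) -> None:
    rows = [{"primer_a": h.primer_a, "primer_b": h.primer_b,
             "duplex_tm": round(h.duplex_tm, 2),
             "end_anchored": h.end_anchored} for h in report.hits]
    pd.DataFrame(rows, columns=["primer_a", "primer_b", "duplex_tm",
                                "end_anchored"]).to_csv(
        path, sep="\t", index=False)
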