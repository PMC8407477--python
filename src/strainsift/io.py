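"""Readers and writers for the standard formats at the package boundary.

FASTA/FASTQ go through Biopython, SAM through pysam (NM tags carry mismatch
counts), VCF through pysam's VariantFile (minimal v4.2 records), and CDS
extraction from GFF3 through gffutils.  Internally everything is 0-based
half-open; 1-based coordinates appear only inside SAM/VCF/GFF records.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp
from .alignment import AlignmentRecord
from .snps import SNPCall
from .synthetic import SimulatedRead, StrainGenome

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_fastq",
    "read_sam",
    "write_sam",
    "write_vcf",
    "read_vcf",
    "read_cds_from_gff",
]


def write_fasta(genomes: Iterable[StrainGenome], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike, is_focal: bool = True) -> list[StrainGenome]:
    return [
        StrainGenome(id=rec.id, sequence=str(rec.seq).upper(), is_focal=is_focal)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fastq(
    reads: Iterable[SimulatedRead | tuple],
    path: str | os.PathLike,
    quality_char: str = "I",
) -> None:
    """Write reads with a fixed per-base quality symbol (default 'I', Q40)."""
    with open(path, "w") as fh:
        for r in reads:
            rid, seq = (r.read_id, r.sequence) if hasattr(r, "sequence") else r
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """(read_id, sequence, quality) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_sam(
    alignments: Iterable[AlignmentRecord],
    genome_lengths: Mapping[str, int],
    path: str | os.PathLike,
    read_sequences: Mapping[str, str] | None = None,
) -> None:
    """Write ungapped alignments with NM tags (and sequences when known)."""
    names = list(genome_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(genome_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.reference_id = tid[a.genome_id]
            seg.reference_start = a.start
            seg.cigarstring = f"{a.aligned_length}M"
            seg.mapping_quality = 255
            seg.flag = 16 if a.strand == "-" else 0
            if read_sequences and a.read_id in read_sequences:
                seq = read_sequences[a.read_id]
                seg.query_sequence = revcomp(seq) if a.strand == "-" else seq
            seg.set_tag("NM", int(a.n_mismatches))
            out.write(seg)


def _mismatches_from_md(md: str) -> int:
    """Substitution count encoded in an MD tag (deletion runs excluded)."""
    n = 0
    i = 0
    while i < len(md):
        c = md[i]
        if c == "^":  # deletion run: skip the deleted reference bases
            i += 1
            while i < len(md) and md[i].isalpha():
                i += 1
        elif c.isalpha():
            n += 1
            i += 1
        else:
            i += 1
    return n


def read_sam(
    path: str | os.PathLike,
    genome_registry: Mapping[str, StrainGenome] | None = None,
) -> list[AlignmentRecord]:
    """One AlignmentRecord per mapped SAM record (secondary and supplementary
    records kept as extra candidate placements; unmapped records skipped).

    Mismatch counts come from NM tags, or from MD tags when NM is absent; a
    mapped record carrying neither raises a parse error naming the read.
    """
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            if seg.has_tag("NM"):
                nmm = int(seg.get_tag("NM"))
            elif seg.has_tag("MD"):
                nmm = _mismatches_from_md(str(seg.get_tag("MD")))
            else:
                raise ValueError(
                    f"SAM record {seg.query_name!r} at "
                    f"{seg.reference_name}:{seg.reference_start + 1} has neither "
                    "an NM nor an MD tag; mismatch count unavailable"
                )
            genome_id = seg.reference_name
            if genome_registry is not None and genome_id not in genome_registry:
                raise ValueError(f"SAM references unknown genome {genome_id!r}")
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    genome_id=genome_id,
                    start=int(seg.reference_start),
                    aligned_length=int(seg.reference_length),
                    n_mismatches=nmm,
                    strand="-" if seg.is_reverse else "+",
                )
            )
    return records


def write_vcf(
    calls: Sequence[SNPCall],
    genome_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Minimal VCF v4.2 with DP/AD/AF INFO fields."""
    header = pysam.VariantHeader()
    for name, length in genome_lengths.items():
        header.contigs.add(name, length=int(length))
    header.info.add("DP", 1, "Integer", "Filtered read depth at the site")
    header.info.add("AD", 1, "Integer", "Alternate allele read count")
    header.info.add("AF", 1, "Float", "Alternate allele frequency")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.genome_id, c.position)):
            rec = out.new_record(
                contig=c.genome_id,
                start=c.position,
                stop=c.position + 1,
                alleles=(c.ref_base, c.alt_base),
            )
            rec.info["DP"] = c.depth
            rec.info["AD"] = c.alt_count
            rec.info["AF"] = c.alt_frequency
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> list[SNPCall]:
    calls = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            depth = int(rec.info.get("DP", 0))
            alt_count = int(rec.info.get("AD", 0))
            freq = float(rec.info.get("AF", alt_count / depth if depth else 0.0))
            calls.append(
                SNPCall(
                    genome_id=rec.chrom,
                    position=rec.start,
                    ref_base=rec.ref,
                    alt_base=rec.alts[0],
                    depth=depth,
                    alt_count=alt_count,
                    alt_frequency=freq,
                )
            )
    return calls


def read_cds_from_gff(
    fasta_path: str | os.PathLike, gff_path: str | os.PathLike
) -> dict[str, str]:
    """Extract CDS nucleotide sequences (strand-resolved) from GFF3 + FASTA.

    Returns gene/CDS id -> sequence.  The feature ID attribute names the CDS.
    """
    import gffutils

    genomes = {g.id: g.sequence for g in read_fasta(fasta_path)}
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    cds = {}
    for feat in db.features_of_type("CDS"):
        seq = genomes[feat.seqid][feat.start - 1 : feat.end]
        if feat.strand == "-":
            seq = revcomp(seq)
        cds_id = feat.id or feat.attributes.get("ID", [f"cds_{feat.start}"])[0]
        cds[cds_id] = seq
    return cds
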