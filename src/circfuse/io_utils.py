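"""FASTA/FASTQ/SAM input-output and the external-aligner hook.

FASTQ records are 4-line, Phred+33.  SAM is read through pysam (text SAM
only — no BAM/CRAM in this package) and converted to
:class:`~circfuse.align_core.ReadAlignment`; SAM output carries ``@SQ``
lines for the reconstructed fusion references so that supporting-read
distributions can be inspected in a genome browser.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from circfuse.align_core import AlnStatus, ReadAlignment, parse_cigar, revcomp

logger = logging.getLogger(__name__)


class FastqRead(NamedTuple):
    read_id: str
    seq: str
    qual: str


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as {id: sequence}; the id is the first whitespace token."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            out[title.split()[0]] = seq.upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Read a FASTQ file; read ids keep only the first whitespace token."""
    out: list[FastqRead] = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            out.append(FastqRead(title.split()[0], seq.upper(), qual))
    return out


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for rec in reads:
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{rec.qual}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(path: str | Path) -> Iterator[ReadAlignment]:
    """Stream a text SAM file as ReadAlignment records.

    ``seq``/``qual`` are restored to original read orientation (pysam keeps
    them as aligned); the CIGAR stays in SAM (oriented) convention.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            status = AlnStatus.NONE
            if rec.is_unmapped:
                status |= AlnStatus.UNMAPPED
            if rec.is_paired and rec.mate_is_unmapped:
                status |= AlnStatus.MATE_UNMAPPED
            if rec.is_reverse:
                status |= AlnStatus.REVERSE
            mate = 1 if rec.is_read1 else 2 if rec.is_read2 else None
            seq = rec.query_sequence or ""
            qual = (pysam.qualities_to_qualitystring(rec.query_qualities)
                    if rec.query_qualities is not None else "")
            if rec.is_reverse and seq:
                seq = revcomp(seq)
                qual = qual[::-1]
            yield ReadAlignment(
                read_id=rec.query_name,
                mate=mate,
                ref_id=None if rec.is_unmapped else rec.reference_name,
                ref_start=0 if rec.is_unmapped else rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                status=status,
                cigar=parse_cigar(rec.cigarstring or "*"),
                score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                seq=seq,
                qual=qual,
            )


def write_sam(path: str | Path, references: dict[str, int],
              alignments: Iterable[ReadAlignment]) -> None:
    """Write alignments as text SAM with @SQ lines for the given references."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
        "PG": [{"ID": "circfuse", "PN": "circfuse"}],
    }
    ref_index = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = aln.read_id
            flag = 0
            if aln.is_unmapped:
                flag |= 0x4
            if aln.strand == "-":
                flag |= 0x10
            if aln.mate == 1:
                flag |= 0x1 | 0x40
            elif aln.mate == 2:
                flag |= 0x1 | 0x80
            seg.flag = flag
            if not aln.is_unmapped and aln.ref_id in ref_index:
                seg.reference_id = ref_index[aln.ref_id]
                seg.reference_start = aln.ref_start
                seg.mapping_quality = 60
                seg.cigarstring = str(aln.cigar)
            oriented = aln.oriented_seq
            seg.query_sequence = oriented if oriented else None
            if aln.qual:
                qual = aln.qual if aln.strand == "+" else aln.qual[::-1]
                seg.query_qualities = pysam.qualitystring_to_array(qual)
            seg.set_tag("AS", aln.score)
            sam.write(seg)


# ---------------------------------------------------------------------------
# External aligner hook
# ---------------------------------------------------------------------------

def run_external_aligner(cmd_template: str, ref_fasta: str | Path,
                         fastq1: str | Path, fastq2: str | Path | None,
                         expected_refs: set[str],
                         workdir: str | Path) -> list[ReadAlignment]:
    """Run an external aligner command template and parse its SAM output.

    The template may use ``{ref}``, ``{fastq1}`` and ``{fastq2}``
    placeholders; the command must print SAM on stdout.  The SAM ``@SQ``
    names are validated against ``expected_refs``.
    """
    cmd = cmd_template.format(ref=ref_fasta, fastq1=fastq1, fastq2=fastq2 or "")
    sam_path = Path(workdir) / "external_aligner.sam"
    with open(sam_path, "w") as out:
        proc = subprocess.run(shlex.split(cmd), stdout=out,
                              stderr=subprocess.PIPE, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"external aligner failed (exit {proc.returncode}): {proc.stderr[-500:]}")
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        sq_names = set(sam.references)
    unknown = sq_names - expected_refs
    if unknown:
        raise ValueError(
            f"external aligner SAM names references outside the expected set: "
            f"{sorted(unknown)[:5]}")
    return list(read_sam(sam_path))
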