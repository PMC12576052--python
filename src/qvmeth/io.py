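"""Readers and writers for the standard formats the pipeline touches.

Loci tables use the extended bedMethyl dialect (tab-separated, ≥11 columns:
chrom, start, end, name, score, strand, thickStart, thickEnd, color,
coverage, methylation percent).  Alignments come from coordinate-sorted,
indexed BAM files via pysam; reference context from an indexed FASTA via
pyfaidx.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pyfaidx
import pysam

from .errors import (
    ContextUnencodableError,
    ParseError,
    WindowOutOfBoundsError,
)
from .features import WindowPileup
from .records import MethylationRecord, Region

logger = logging.getLogger(__name__)

#: samtools view -F mask dropping unmapped, secondary, supplementary,
#: duplicate, QC-fail and all pairing-related records (4079 = 0xFAF).
DEFAULT_FLAG_EXCLUDE = 4079

PREDICTION_HEADER = "#chrom\tstart\tend\tstrand\tdepth\tlevel_percent"


def read_loci_table(
    path: str | Path,
    min_depth: int = 10,
    min_score: int = 800,
) -> list[MethylationRecord]:
    """Parse a bedMethyl-dialect loci table, dropping low-confidence loci.

    Rows with coverage below ``min_depth`` or score below ``min_score`` are
    removed; the retained records carry ``level`` = percent / 100.
    """
    records: list[MethylationRecord] = []
    n_dropped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(
                    f"expected >= 11 tab-separated columns, got {len(fields)}",
                    line_number=line_no,
                )
            try:
                start = int(fields[1])
                score = int(fields[4])
                depth = int(fields[9])
                percent = float(fields[10])
            except ValueError as exc:
                raise ParseError(str(exc), line_number=line_no) from None
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"strand must be '+' or '-', got {strand!r}",
                    line_number=line_no,
                )
            if not (0.0 <= percent <= 100.0):
                raise ParseError(
                    f"methylation percent {percent} outside [0, 100]",
                    line_number=line_no,
                )
            if depth < min_depth or score < min_score:
                n_dropped += 1
                continue
            records.append(
                MethylationRecord(
                    chrom=fields[0],
                    start=start,
                    strand=strand,
                    level=percent / 100.0,
                    depth=depth,
                    score=score,
                )
            )
    logger.info(
        "read %d loci from %s (%d dropped by depth>=%d / score>=%d filter)",
        len(records), path, n_dropped, min_depth, min_score,
    )
    return records


def read_reference_window(
    fasta: str | Path | pyfaidx.Fasta,
    chrom: str,
    center: int,
    flank: int = 10,
) -> str:
    """Uppercased reference bases over [center−flank, center+flank].

    Raises WindowOutOfBoundsError at contig edges and
    ContextUnencodableError for non-ACGT bases; callers skip such loci.
    """
    fa = fasta if isinstance(fasta, pyfaidx.Fasta) else pyfaidx.Fasta(str(fasta))
    if chrom not in fa:
        raise KeyError(f"contig {chrom!r} not found in reference")
    start = center - flank
    end = center + flank + 1
    contig_len = len(fa[chrom])
    if start < 0 or end > contig_len:
        raise WindowOutOfBoundsError(
            f"window [{start}, {end}) outside contig {chrom} "
            f"of length {contig_len}"
        )
    seq = fa[chrom][start:end].seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ContextUnencodableError(
            f"window at {chrom}:{center} contains non-ACGT base(s) "
            f"{sorted(bad)}"
        )
    return seq


def collect_window_reads(
    bam: str | Path | pysam.AlignmentFile,
    chrom: str,
    center: int,
    flank: int = 10,
    flag_exclude: int = DEFAULT_FLAG_EXCLUDE,
    deletion_qv: int = 0,
    context: str | None = None,
    strand: str = "+",
) -> WindowPileup:
    """Build the rectangular window pileup for one candidate locus.

    Only reads whose alignment covers every reference position in the window
    with match/mismatch/deletion operations contribute; reads clipped or
    ending inside the window, reads with any flag bit in ``flag_exclude``,
    and reads showing 'N' at any window position are excluded whole.
    Insertions between window positions are ignored.  Deleted positions are
    recorded as base 'D' with QV ``deletion_qv``.
    """
    own = not isinstance(bam, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(bam)) if own else bam
    try:
        if chrom not in af.references:
            raise KeyError(f"contig {chrom!r} not found in BAM header")
        start = center - flank
        end = center + flank + 1
        width = 2 * flank + 1
        base_rows: list[list[str]] = []
        qv_rows: list[list[int]] = []
        for read in af.fetch(chrom, max(start, 0), end):
            if read.flag & flag_exclude:
                continue
            if read.reference_start > start or read.reference_end < end:
                continue
            ref_to_query = {
                rpos: qpos
                for qpos, rpos in read.get_aligned_pairs()
                if rpos is not None
            }
            seq = read.query_sequence
            quals = read.query_qualities
            bases: list[str] = []
            qvs: list[int] = []
            covered = True
            for rpos in range(start, end):
                if rpos not in ref_to_query:
                    covered = False  # e.g. reference-skip op in the window
                    break
                qpos = ref_to_query[rpos]
                if qpos is None:
                    bases.append("D")
                    qvs.append(deletion_qv)
                else:
                    base = seq[qpos].upper()
                    if base == "N":
                        covered = False
                        break
                    bases.append(base)
                    qvs.append(quals[qpos])
            if not covered:
                continue
            base_rows.append(bases)
            qv_rows.append(qvs)
    finally:
        if own:
            af.close()
    n = len(base_rows)
    Q = np.array(qv_rows, dtype=float).reshape(n, width)
    R = np.array(base_rows, dtype="U1").reshape(n, width)
    return WindowPileup(
        chrom=chrom, center=center, strand=strand, flank=flank,
        Q=Q, R=R, T=context,
    )


def write_predictions(
    records: list[MethylationRecord], path: str | Path
) -> None:
    """Write per-locus predictions as TSV, sorted by (chrom, start, strand)."""
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.strand))
    with open(path, "w") as fh:
        fh.write(PREDICTION_HEADER + "\n")
        for rec in ordered:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.strand}\t"
                f"{rec.depth}\t{100.0 * rec.level:.2f}\n"
            )


def read_predictions(path: str | Path) -> list[MethylationRecord]:
    """Parse a prediction TSV written by :func:`write_predictions`."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"expected 6 columns, got {len(fields)}", line_number=line_no
                )
            records.append(
                MethylationRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    strand=fields[3],
                    level=float(fields[5]) / 100.0,
                    depth=int(fields[4]),
                )
            )
    return records


def read_bed_regions(path: str | Path) -> list[Region]:
    """Parse BED3/BED4 region files."""
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 columns, got {len(fields)}",
                    line_number=line_no,
                )
            name = fields[3] if len(fields) > 3 else None
            try:
                regions.append(
                    Region(fields[0], int(fields[1]), int(fields[2]), name)
                )
            except ValueError as exc:
                raise ParseError(str(exc), line_number=line_no) from None
    return regions


def write_region_summaries(summaries, path: str | Path) -> None:
    """Write region summaries as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tmethod\tn_total\tn_used\t"
            "mean_level\tvariance\n"
        )
        for s in summaries:
            r = s.region
            mean = "NA" if np.isnan(s.mean_level) else f"{s.mean_level:.6f}"
            var = "NA" if np.isnan(s.variance) else f"{s.variance:.6f}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t"
                f"{s.method}\t{s.n_total}\t{s.n_used}\t{mean}\t{var}\n"
            )


def sam_to_sorted_bam(sam_path: str | Path, bam_path: str | Path) -> Path:
    """Convert a SAM file to a coordinate-sorted, indexed BAM."""
    bam_path = Path(bam_path)
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path
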