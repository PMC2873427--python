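"""SNP calling from EST-to-genome alignment mismatches.

Every aligned position where the EST base differs from the reference (both
unambiguous A/C/G/T) yields a candidate call.  Positions near the alignment
ends (``end_mask``) and near exon/intron junctions (``gap_mask``) are masked,
since spliced-alignment artifacts concentrate there; masks of 0 disable the
hygiene entirely.  Calls are aggregated across ESTs by (chrom, pos, alt), and
the mSNP filter keeps only positions supported by more than one EST, which
suppresses sequencing-error false positives: at an error rate of 0.0044 per
base a single 227-bp EST is expected to carry one spurious mismatch, but two
independent ESTs rarely err identically at the same position.

All bases are reported on the genome's forward strand.  The alignment model
is block-concatenation: the strand-oriented EST (reverse-complemented for
minus-strand alignments) aligns contiguously over the exon blocks starting at
``q_start``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from allelesplice.alignment_io import SplicedAlignment

__all__ = [
    "SnpCall",
    "call_mismatches",
    "aggregate_and_filter",
    "aggregate_calls",
    "est_length_for_one_false_positive",
    "write_vcf",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset(b"ACGT")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _orient(seq: str, strand: str) -> str:
    """EST sequence in genome-forward orientation."""
    return _revcomp(seq) if strand == "-" else seq


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Reference slice from a pyfaidx.Fasta, dict of strings, or similar."""
    if hasattr(genome, "fetch"):  # pysam-style
        return genome.fetch(chrom, start, end)
    seq = genome[chrom]
    piece = seq[start:end]
    return str(piece.seq) if hasattr(piece, "seq") else str(piece)


@dataclass(frozen=True)
class SnpCall:
    """A genomic position where one or more ESTs mismatch the reference."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    supporting_ests: frozenset[str]
    is_msnp: bool = False

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise ValueError(f"{self.chrom}:{self.pos}: ambiguous base in call")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_base)


def call_mismatches(
    aln: SplicedAlignment,
    est_seq: str,
    genome,
    end_mask: int = 3,
    gap_mask: int = 5,
) -> list[SnpCall]:
    """Singleton-support mismatch calls for one best alignment.

    ``est_seq`` is the EST read as deposited (reverse-complemented internally
    for minus-strand alignments).  Raises if the EST is shorter than the
    aligned blocks imply.
    """
    oriented = _orient(str(est_seq), aln.strand).upper()
    total = aln.aligned_length
    if aln.q_start + total > len(oriented):
        raise ValueError(
            f"{aln.est_id}: EST length {len(oriented)} inconsistent with "
            f"aligned blocks ({total} bp from offset {aln.q_start})"
        )
    ref = "".join(
        _fetch(genome, aln.chrom, s, e) for s, e in aln.blocks
    ).upper()
    qry = oriented[aln.q_start : aln.q_start + total]

    ra = np.frombuffer(ref.encode(), dtype=np.uint8)
    qa = np.frombuffer(qry.encode(), dtype=np.uint8)
    valid = np.isin(ra, list(_VALID)) & np.isin(qa, list(_VALID))
    mism = (ra != qa) & valid

    mask = np.zeros(total, dtype=bool)
    if end_mask > 0:
        mask[:end_mask] = True
        mask[total - end_mask :] = True
    if gap_mask > 0:
        offset = 0
        n = len(aln.blocks)
        for bi, (s, e) in enumerate(aln.blocks):
            blen = e - s
            if bi > 0:
                mask[offset : offset + gap_mask] = True
            if bi < n - 1:
                mask[max(offset, offset + blen - gap_mask) : offset + blen] = True
            offset += blen
    mism &= ~mask

    # map concatenated-alignment offsets back to genomic positions
    calls = []
    offset = 0
    idxs = np.flatnonzero(mism)
    ptr = 0
    for s, e in aln.blocks:
        blen = e - s
        while ptr < len(idxs) and idxs[ptr] < offset + blen:
            i = int(idxs[ptr])
            calls.append(
                SnpCall(
                    chrom=aln.chrom,
                    pos=s + (i - offset),
                    ref_base=chr(ra[i]),
                    alt_base=chr(qa[i]),
                    supporting_ests=frozenset([aln.est_id]),
                )
            )
            ptr += 1
        offset += blen
    return calls


def aggregate_calls(calls: Iterable[SnpCall]) -> list[SnpCall]:
    """Merge calls with identical (chrom, pos, alt); union supporting ESTs."""
    merged: dict[tuple, set[str]] = {}
    refs: dict[tuple, str] = {}
    for c in calls:
        merged.setdefault(c.key, set()).update(c.supporting_ests)
        refs[c.key] = c.ref_base
    out = []
    for key in sorted(merged):
        chrom, pos, alt = key
        ests = frozenset(merged[key])
        out.append(
            SnpCall(
                chrom=chrom,
                pos=pos,
                ref_base=refs[key],
                alt_base=alt,
                supporting_ests=ests,
                is_msnp=len(ests) >= 2,
            )
        )
    return out


def aggregate_and_filter(calls: Iterable[SnpCall], min_ests: int = 2) -> list[SnpCall]:
    """Aggregate across ESTs and keep calls supported by >= ``min_ests`` ESTs.

    With the default ``min_ests=2`` the result is exactly the mSNP set.  The
    ``is_msnp`` flag always means ">=2 supporting ESTs", independent of the
    threshold used for filtering.
    """
    return [c for c in aggregate_calls(calls) if len(c.supporting_ests) >= min_ests]


def est_length_for_one_false_positive(error_rate: float) -> int:
    """EST length at which one sequencing-error mismatch is expected.

    At 0.0044 errors per base this is 227 bp: a typical single EST carries
    about one spurious SNP, which is why multi-EST support is required.
    """
    if error_rate <= 0:
        raise ValueError("error rate must be positive")
    return round(1.0 / error_rate)


def write_vcf(calls: Sequence[SnpCall], path: str, reference: str = "") -> None:
    """Write calls as VCF 4.2 (one record per chrom/pos, multi-allelic ALT)."""
    by_pos: dict[tuple[str, int], list[SnpCall]] = {}
    for c in calls:
        by_pos.setdefault((c.chrom, c.pos), []).append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if reference:
            fh.write(f"##reference={reference}\n")
        fh.write('##INFO=<ID=EST_IDS,Number=.,Type=String,Description="Supporting EST ids per ALT allele (+-separated within allele)">\n')
        fh.write('##INFO=<ID=N_EST,Number=A,Type=Integer,Description="Number of supporting ESTs per ALT allele">\n')
        fh.write('##INFO=<ID=MSNP,Number=0,Type=Flag,Description="Any ALT supported by more than one EST">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (chrom, pos) in sorted(by_pos):
            recs = sorted(by_pos[(chrom, pos)], key=lambda c: c.alt_base)
            alts = ",".join(c.alt_base for c in recs)
            est_ids = ",".join("+".join(sorted(c.supporting_ests)) for c in recs)
            n_est = ",".join(str(len(c.supporting_ests)) for c in recs)
            info = f"EST_IDS={est_ids};N_EST={n_est}"
            if any(c.is_msnp for c in recs):
                info += ";MSNP"
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{recs[0].ref_base}\t{alts}\t.\t.\t{info}\n"
            )
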