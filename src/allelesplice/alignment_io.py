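"""Reading, filtering and clustering of spliced EST-to-genome alignments.

Coordinates are 0-based half-open internally.  BED12 is native; GFF3 records
(1-based inclusive) are converted on input.  Alignment quality metrics travel
with each record:

* BED12 — optional extra columns 13 and 14 hold coverage and identity as
  fractions in [0, 1] (absent columns mark the metrics as unknown);
* GFF3 — ``coverage=`` and ``identity=`` attributes on the parent ``match``
  feature, as percentages (the convention of spliced aligners that emit GFF3).

An EST may align to several loci; :func:`best_alignment_per_est` keeps the
single best placement.  :func:`cluster_alignments` groups alignments into
transcript clusters by single-linkage exonic (block-level) overlap on the
same chromosome and strand, and collapses members with identical intron
chains into isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "SplicedAlignment",
    "TranscriptCluster",
    "read_alignments",
    "filter_alignments",
    "drop_uniexonic",
    "best_alignment_per_est",
    "cluster_alignments",
]


@dataclass(frozen=True)
class SplicedAlignment:
    """One EST placed on the genome as ordered exon blocks.

    ``blocks`` are 0-based half-open genomic intervals, sorted and
    non-overlapping.  ``coverage`` is the fraction of the EST aligned and
    ``identity`` the fraction of aligned bases matching the reference; either
    may be ``None`` when the input format did not carry it.  ``q_start`` is
    the offset of the first aligned base within the strand-oriented EST
    (0 for full-coverage alignments and for BED12 input, which carries no
    query coordinates).
    """

    est_id: str
    chrom: str
    strand: str  # '+', '-', or 'unknown'
    blocks: tuple[tuple[int, int], ...]
    coverage: Optional[float] = None
    identity: Optional[float] = None
    source_tag: str = ""
    q_start: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.est_id}: alignment has no blocks")
        prev_end = None
        for start, end in self.blocks:
            if start >= end:
                raise ValueError(f"{self.est_id}: empty block ({start}, {end})")
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"{self.est_id}: blocks overlap or touch (introns must have "
                    f"positive length)"
                )
            prev_end = end
        for name in ("coverage", "identity"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.est_id}: {name}={v} outside [0, 1]")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"{self.est_id}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive blocks, as (left, right) genomic bounds."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )


@dataclass
class TranscriptCluster:
    """Overlapping same-locus alignments, with intron-chain isoforms.

    ``isoforms`` lists ``(intron_chain, est_ids)`` pairs; members with an
    identical intron chain are collapsed into one isoform.  Chains within a
    cluster are pairwise distinct.
    """

    cluster_id: str
    chrom: str
    strand: str
    members: list[SplicedAlignment] = field(default_factory=list)
    isoforms: list[tuple[tuple[tuple[int, int], ...], tuple[str, ...]]] = field(
        default_factory=list
    )

    @property
    def start(self) -> int:
        return min(a.start for a in self.members)

    @property
    def end(self) -> int:
        return max(a.end for a in self.members)


# ---------------------------------------------------------------------------
# input


def _parse_bed12_line(line: str, lineno: int, source_tag: str) -> SplicedAlignment:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: BED12 record has {len(fields)} fields (<12)")
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        name = fields[3]
        strand = fields[5] if fields[5] in ("+", "-") else "unknown"
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except (ValueError, IndexError) as exc:
        raise ValueError(f"line {lineno}: malformed BED12 record: {exc}") from None
    if len(sizes) != block_count or len(starts) != block_count:
        raise ValueError(
            f"line {lineno}: blockCount={block_count} does not match "
            f"blockSizes/blockStarts"
        )
    blocks = tuple(
        (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
    )
    coverage = identity = None
    if len(fields) >= 14:
        try:
            coverage = float(fields[12])
            identity = float(fields[13])
        except ValueError as exc:
            raise ValueError(
                f"line {lineno}: bad coverage/identity columns: {exc}"
            ) from None
    try:
        return SplicedAlignment(
            est_id=name,
            chrom=chrom,
            strand=strand,
            blocks=blocks,
            coverage=coverage,
            identity=identity,
            source_tag=source_tag,
        )
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None


def _read_bed12(path: str, source_tag: str) -> list[SplicedAlignment]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed12_line(line, lineno, source_tag))
    return out


def _gff3_attrs(col: str) -> dict[str, str]:
    attrs = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _read_gff3_alignments(path: str, source_tag: str) -> list[SplicedAlignment]:
    """Parse match/match_part (or *_match/exon) two-level alignment GFF3."""
    parents: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: GFF3 record has {len(cols)} columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_col = cols
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ValueError(f"line {lineno}: bad interval {start_s}..{end_s}")
            attrs = _gff3_attrs(attr_col)
            if ftype.endswith("match") or ftype in ("mRNA", "EST"):
                pid = attrs.get("ID")
                if pid is None:
                    raise ValueError(f"line {lineno}: parent feature without ID")
                rec = parents.setdefault(
                    pid,
                    {
                        "est_id": attrs.get("Name", pid),
                        "chrom": chrom,
                        "strand": strand if strand in ("+", "-") else "unknown",
                        "blocks": [],
                        "coverage": None,
                        "identity": None,
                    },
                )
                if pid not in order:
                    order.append(pid)
                for key in ("coverage", "identity"):
                    if key in attrs:
                        rec[key] = float(attrs[key]) / 100.0  # percent -> fraction
            elif ftype in ("match_part", "exon"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"line {lineno}: {ftype} without Parent")
                rec = parents.setdefault(
                    parent,
                    {
                        "est_id": parent,
                        "chrom": chrom,
                        "strand": strand if strand in ("+", "-") else "unknown",
                        "blocks": [],
                        "coverage": None,
                        "identity": None,
                    },
                )
                if parent not in order:
                    order.append(parent)
                rec["blocks"].append((start, end))
            # other feature types are ignored
    out = []
    for pid in order:
        rec = parents[pid]
        blocks = tuple(sorted(rec["blocks"]))
        if not blocks:
            raise ValueError(f"alignment {pid}: no match_part/exon children")
        out.append(
            SplicedAlignment(
                est_id=rec["est_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                blocks=blocks,
                coverage=rec["coverage"],
                identity=rec["identity"],
                source_tag=source_tag,
            )
        )
    return out


def read_alignments(path: str, format: str, source_tag: str = "") -> list[SplicedAlignment]:
    """Read spliced alignments from ``path`` in ``format`` (bed12 or gff3)."""
    if format == "bed12":
        return _read_bed12(path, source_tag)
    if format == "gff3":
        return _read_gff3_alignments(path, source_tag)
    raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# filters


def filter_alignments(
    alns: Iterable[SplicedAlignment],
    min_coverage: float = 0.80,
    min_identity: float = 0.95,
    missing_policy: str = "reject",
) -> list[SplicedAlignment]:
    """Keep alignments with coverage > min_coverage AND identity > min_identity.

    Both comparisons are strict, so an alignment at exactly the threshold is
    rejected.  ``missing_policy`` decides the fate of alignments whose input
    format carried no coverage/identity: ``"reject"`` (default) or ``"pass"``.
    """
    if not (0.0 <= min_coverage <= 1.0 and 0.0 <= min_identity <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    if missing_policy not in ("reject", "pass"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    out = []
    for a in alns:
        if a.coverage is None or a.identity is None:
            if missing_policy == "pass":
                out.append(a)
            continue
        if a.coverage > min_coverage and a.identity > min_identity:
            out.append(a)
    return out


def recompute_metrics(
    aln: SplicedAlignment, genome, est_seqs: dict
) -> SplicedAlignment:
    """Fill in coverage/identity from sequences, for inputs that lack them.

    Assumes the block-concatenation alignment model used throughout the
    package: the strand-oriented EST aligns contiguously over the blocks
    starting at ``q_start``.
    """
    from allelesplice.snp_call import _fetch, _orient

    est = _orient(str(est_seqs[aln.est_id]), aln.strand)
    matches = 0
    offset = aln.q_start
    for s, e in aln.blocks:
        ref = _fetch(genome, aln.chrom, s, e).upper()
        seg = est[offset : offset + (e - s)].upper()
        if len(seg) != e - s:
            raise ValueError(f"{aln.est_id}: EST shorter than aligned blocks")
        matches += sum(1 for r, q in zip(ref, seg) if r == q)
        offset += e - s
    alen = aln.aligned_length
    return replace(
        aln, coverage=alen / len(est), identity=matches / alen if alen else 0.0
    )


def drop_uniexonic(alns: Iterable[SplicedAlignment]) -> list[SplicedAlignment]:
    """Remove single-block alignments (genomic DNA / pre-mRNA contamination)."""
    return [a for a in alns if len(a.blocks) >= 2]


def best_alignment_per_est(alns: Sequence[SplicedAlignment]) -> list[SplicedAlignment]:
    """Keep, for each EST, the single placement maximizing identity x coverage.

    Alignments without metrics score 0.  Ties break deterministically by
    (chrom, start, input order).  Output preserves input order.
    """
    best: dict[str, tuple] = {}
    for idx, a in enumerate(alns):
        score = (a.identity or 0.0) * (a.coverage or 0.0)
        key = (-score, a.chrom, a.start, idx)
        cur = best.get(a.est_id)
        if cur is None or key < cur[0]:
            best[a.est_id] = (key, idx, a)
    chosen = sorted(best.values(), key=lambda t: t[1])
    return [a for _, _, a in chosen]


# ---------------------------------------------------------------------------
# clustering


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_alignments(alns: Sequence[SplicedAlignment]) -> list[TranscriptCluster]:
    """Single-linkage clusters by >=1 bp exonic (block-level) overlap.

    Alignments on different chromosomes or strands never cluster together;
    strand-unknown alignments form their own stratum.  Overlap is evaluated
    between exon blocks, not whole spans, so two genes sharing only an intron
    are not chained.  Within each cluster, members with identical intron
    chains collapse into one isoform.
    """
    strata: dict[tuple[str, str], list[int]] = {}
    for i, a in enumerate(alns):
        strata.setdefault((a.chrom, a.strand), []).append(i)

    clusters: list[TranscriptCluster] = []
    for (chrom, strand) in sorted(strata):
        idxs = strata[(chrom, strand)]
        uf = _UnionFind(len(idxs))
        # sweep over all blocks; a block starting before the running max end
        # overlaps the block that set that end, linking their alignments
        blocks = sorted(
            (s, e, local)
            for local, gi in enumerate(idxs)
            for (s, e) in alns[gi].blocks
        )
        cur_end = -1
        cur_owner = -1
        for s, e, local in blocks:
            if s < cur_end:
                uf.union(local, cur_owner)
                if e > cur_end:
                    cur_end, cur_owner = e, uf.find(local)
                else:
                    cur_owner = uf.find(cur_owner)
            else:
                cur_end, cur_owner = e, local
        groups: dict[int, list[int]] = {}
        for local, gi in enumerate(idxs):
            groups.setdefault(uf.find(local), []).append(gi)
        for root in sorted(groups, key=lambda r: min(alns[g].start for g in groups[r])):
            members = [alns[g] for g in groups[root]]
            members.sort(key=lambda a: (a.start, a.end, a.est_id))
            chains: dict[tuple, list[str]] = {}
            for m in members:
                chains.setdefault(m.introns, []).append(m.est_id)
            isoforms = [
                (chain, tuple(sorted(ests)))
                for chain, ests in sorted(chains.items())
            ]
            cid = f"{chrom}:{members[0].start}-{max(m.end for m in members)}({strand})"
            clusters.append(
                TranscriptCluster(
                    cluster_id=cid,
                    chrom=chrom,
                    strand=strand,
                    members=members,
                    isoforms=isoforms,
                )
            )
    return clusters
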