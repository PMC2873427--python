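"""Coding impact of structural events: CDS/UTR location and reading frame.

Each event's variable region is placed against gene models by maximal base
overlap.  An event overlapping several transcripts is assigned to the one
with the largest total overlap (ties by gene id); within the winning model
the region category (CDS, 5'UTR, 3'UTR) with the most overlapping bases wins,
ties resolved CDS > UTR5 > UTR3; an event overlapping no model is intergenic.
For CDS events the distance from the variable region's 3'-most base to the
stop codon is reported in transcript (spliced) coordinates, and events within
the final portion of the CDS (default 10% of CDS length) are flagged as
near-end: out-of-frame changes there truncate little of the protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import gffutils
import pandas as pd

from allelesplice.tsv_detect import TsvEvent

__all__ = [
    "GeneModel",
    "ImpactAnnotation",
    "read_gene_models",
    "annotate_event",
    "location_frame_summary",
]

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """One transcript's CDS and UTR intervals (0-based half-open, sorted)."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[Interval, ...]
    utr5_intervals: tuple[Interval, ...] = ()
    utr3_intervals: tuple[Interval, ...] = ()

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


def _internalize(feature) -> Interval:
    return (feature.start - 1, feature.end)


def _subtract(intervals: Sequence[Interval], holes: Sequence[Interval]) -> list[Interval]:
    out = []
    for s, e in intervals:
        cur = s
        for hs, he in sorted(holes):
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
        if cur < e:
            out.append((cur, e))
    return out


def read_gene_models(path: str) -> list[GeneModel]:
    """Load transcripts from GFF3; derive UTRs from exon - CDS when absent.

    Each mRNA (or transcript) with CDS children yields one GeneModel named by
    its ID.  Exonic sequence upstream of the CDS in transcription direction is
    5'UTR, downstream is 3'UTR.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    tx_types = ("mRNA", "transcript")
    seen_tx = set()
    for ttype in tx_types:
        for tx in db.features_of_type(ttype, order_by=("seqid", "start")):
            seen_tx.add(tx.id)
            cds = sorted(_internalize(f) for f in db.children(tx, featuretype="CDS"))
            if not cds:
                continue
            utr5 = sorted(
                _internalize(f) for f in db.children(tx, featuretype="five_prime_UTR")
            )
            utr3 = sorted(
                _internalize(f) for f in db.children(tx, featuretype="three_prime_UTR")
            )
            if not utr5 and not utr3:
                exons = sorted(
                    _internalize(f) for f in db.children(tx, featuretype="exon")
                )
                if exons:
                    noncoding = _subtract(exons, cds)
                    cds_lo = cds[0][0]
                    cds_hi = cds[-1][1]
                    left = [iv for iv in noncoding if iv[1] <= cds_lo]
                    right = [iv for iv in noncoding if iv[0] >= cds_hi]
                    if tx.strand == "-":
                        utr5, utr3 = right, left
                    else:
                        utr5, utr3 = left, right
            models.append(
                GeneModel(
                    gene_id=tx.id,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    cds_intervals=tuple(cds),
                    utr5_intervals=tuple(utr5),
                    utr3_intervals=tuple(utr3),
                )
            )
    # a CDS whose parent transcript is absent is a structural defect
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype=tx_types))
        if not parents:
            raise ValueError(f"CDS feature {cds.id!r} has no parent transcript")
    return models


@dataclass
class ImpactAnnotation:
    """Where one event falls relative to gene models, and its frame status."""

    event_id: str
    region: str  # 'CDS' | 'UTR5' | 'UTR3' | 'intergenic'
    in_frame: bool
    gene_id: Optional[str] = None
    distance_to_cds_end: Optional[int] = None
    near_cds_end: Optional[bool] = None


def _overlap_bp(region: Interval, intervals: Sequence[Interval]) -> int:
    lo, hi = region
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in intervals)


def _filled(intervals: Sequence[Interval]) -> tuple[Interval, ...]:
    """Genomic span of a category: a variable region falling in an intron
    between two CDS exons is counted as CDS, matching how retained introns
    and boundary shifts interrupt the coding sequence."""
    if not intervals:
        return ()
    return ((intervals[0][0], intervals[-1][1]),)


def _distance_to_stop(region: Interval, model: GeneModel) -> int:
    """Spliced-coordinate distance from the region's 3'-most CDS base to stop."""
    if model.strand == "-":
        # 3'-most base in transcription direction is the genomic-left end
        anchor = max(region[0], model.cds_intervals[0][0])
        return sum(
            max(0, min(e, anchor) - s) for s, e in model.cds_intervals
        )
    anchor = min(region[1], model.cds_intervals[-1][1])
    return sum(max(0, e - max(s, anchor)) for s, e in model.cds_intervals)


def annotate_event(
    event: TsvEvent,
    models: Sequence[GeneModel],
    near_end_fraction: float = 0.10,
) -> ImpactAnnotation:
    """Assign one region category to the event by maximal overlap."""
    region = event.variable_region
    best = None
    for m in sorted(models, key=lambda m: m.gene_id):
        if m.chrom != event.chrom:
            continue
        if event.strand in ("+", "-") and m.strand != event.strand:
            continue
        per_cat = {
            "CDS": _overlap_bp(region, _filled(m.cds_intervals)),
            "UTR5": _overlap_bp(region, _filled(m.utr5_intervals)),
            "UTR3": _overlap_bp(region, _filled(m.utr3_intervals)),
        }
        total = sum(per_cat.values())
        if total > 0 and (best is None or total > best[0]):
            best = (total, m, per_cat)
    if best is None:
        return ImpactAnnotation(
            event_id=event.event_id, region="intergenic", in_frame=event.in_frame
        )
    _, model, per_cat = best
    category = max(("CDS", "UTR5", "UTR3"), key=lambda c: (per_cat[c], c == "CDS", c == "UTR5"))
    ann = ImpactAnnotation(
        event_id=event.event_id,
        region=category,
        in_frame=event.in_frame,
        gene_id=model.gene_id,
    )
    if category == "CDS":
        dist = _distance_to_stop(region, model)
        ann.distance_to_cds_end = dist
        ann.near_cds_end = dist <= near_end_fraction * model.cds_length
    return ann


def location_frame_summary(annotations: Sequence[ImpactAnnotation]) -> pd.DataFrame:
    """Cross-tabulation of region x frame with per-region and overall fractions."""
    if not annotations:
        return pd.DataFrame(
            columns=["region", "in_frame", "out_of_frame", "n",
                     "fraction_in_frame", "fraction_of_events"]
        )
    order = ["CDS", "UTR5", "UTR3", "intergenic"]
    counts = {r: [0, 0] for r in order}
    for a in annotations:
        counts[a.region][0 if a.in_frame else 1] += 1
    total = len(annotations)
    rows = []
    for r in order:
        inf, outf = counts[r]
        n = inf + outf
        if n == 0:
            continue
        rows.append(
            {
                "region": r,
                "in_frame": inf,
                "out_of_frame": outf,
                "n": n,
                "fraction_in_frame": inf / n,
                "fraction_of_events": n / total,
            }
        )
    return pd.DataFrame(rows)
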