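"""Detection and classification of transcript structure variation (TSV) events.

Within a transcript cluster, isoforms are distinct intron chains.  For each
pair of isoforms the chains are compared over the genomic span covered by
both, and every localized structural difference becomes one event, classified
into six mutually exclusive categories:

* ``IntronR`` — intron retention: one isoform splices an intron that the other
  covers contiguously as exon;
* ``ExonS``  — exon skipping: an internal exon present in one isoform is
  absent from the other, whose single intron fuses the flanking introns;
* ``AltA``   — alternative acceptor: two introns share their donor site and
  differ at the acceptor;
* ``AltD``   — alternative donor: shared acceptor, different donor;
* ``AltS``   — alternative donor and acceptor: two overlapping introns differ
  at both ends;
* ``Others`` — everything else (alternative transcript initiation, multi-
  junction rearrangements, and any difference touching an isoform's terminal
  aligned base, where truncated ESTs cannot be distinguished from real
  variation).

Donor/acceptor are biological labels: on the minus strand the donor is the
genomic-right end of the intron, so AltA/AltD swap relative to genomic
left/right.  Strand-unknown clusters use the plus-strand convention.

The variable region is the genomic interval over which the two isoforms'
exonic structures differ; ``length_difference`` is the absolute difference of
exonic base counts over that region, and an event is in-frame when that
difference is divisible by 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from allelesplice.alignment_io import TranscriptCluster

__all__ = [
    "EVENT_TYPES",
    "TsvEvent",
    "detect_events",
    "intersect_event_sets",
    "event_type_frequencies",
    "classify_intron_pair",
]

EVENT_TYPES = ("IntronR", "AltA", "AltD", "AltS", "ExonS", "Others")

Interval = tuple[int, int]
Chain = tuple[Interval, ...]


@dataclass
class TsvEvent:
    """One classified structural difference between two isoforms."""

    event_id: str
    cluster_id: str
    chrom: str
    strand: str
    type: str
    variable_region: Interval
    isoform_a_ests: frozenset[str]
    isoform_b_ests: frozenset[str]
    length_difference: int
    in_frame: bool
    junctions: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.isoform_a_ests & self.isoform_b_ests:
            raise ValueError(f"{self.event_id}: EST appears on both sides")
        if self.in_frame != (self.length_difference % 3 == 0):
            raise ValueError(f"{self.event_id}: in_frame inconsistent with length")

    @property
    def identity_key(self) -> tuple:
        """Merge/intersection identity: coordinates are the shared vocabulary."""
        return (self.type, self.chrom, self.strand, self.variable_region, self.junctions)


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _intronic_bases(introns: Iterable[Interval], region: Interval) -> int:
    lo, hi = region
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in introns)


def classify_intron_pair(i: Interval, j: Interval, strand: str) -> str:
    """Category for two distinct introns occupying corresponding positions."""
    if i == j:
        raise ValueError("identical introns are not a difference")
    left_shared = i[0] == j[0]
    right_shared = i[1] == j[1]
    if left_shared:  # genomic-left end = donor on '+', acceptor on '-'
        return "AltA" if strand != "-" else "AltD"
    if right_shared:
        return "AltD" if strand != "-" else "AltA"
    if _overlap(i, j):
        return "AltS"
    return "Others"


def _components(ua: Sequence[Interval], ub: Sequence[Interval]):
    """Group differing introns (tagged by side) into overlap-connected runs."""
    tagged = sorted([(iv, "a") for iv in ua] + [(iv, "b") for iv in ub])
    comps: list[tuple[list[Interval], list[Interval]]] = []
    cur_end = None
    for (s, e), side in tagged:
        if cur_end is None or s >= cur_end:
            comps.append(([], []))
            cur_end = e
        else:
            cur_end = max(cur_end, e)
        comps[-1][0 if side == "a" else 1].append((s, e))
    return comps


def _classify_component(
    ca: list[Interval],
    cb: list[Interval],
    strand: str,
) -> tuple[str, Interval, int]:
    """(type, variable_region, side_with_more_exon) for one difference run.

    The third element is +1 when the "a" side has more exonic sequence over
    the variable region, -1 for the "b" side, 0 for a tie.
    """
    lo = min(iv[0] for iv in ca + cb)
    hi = max(iv[1] for iv in ca + cb)
    if len(ca) == 1 and not cb:
        etype, region = "IntronR", ca[0]
    elif len(cb) == 1 and not ca:
        etype, region = "IntronR", cb[0]
    elif len(ca) == 1 and len(cb) == 1:
        i, j = ca[0], cb[0]
        etype = classify_intron_pair(i, j, strand)
        if i[0] == j[0]:
            region = (min(i[1], j[1]), max(i[1], j[1]))
        elif i[1] == j[1]:
            region = (min(i[0], j[0]), max(i[0], j[0]))
        else:
            region = (lo, hi)
    elif _is_skip(ca, cb) or _is_skip(cb, ca):
        two = ca if len(ca) == 2 else cb
        etype, region = "ExonS", (two[0][1], two[1][0])
    else:
        etype, region = "Others", (lo, hi)
    ia = _intronic_bases(ca, region)
    ib = _intronic_bases(cb, region)
    side = 0 if ia == ib else (+1 if ia < ib else -1)
    return etype, region, side


def _is_skip(two: list[Interval], one: list[Interval]) -> bool:
    return (
        len(two) == 2
        and len(one) == 1
        and two[0][0] == one[0][0]
        and two[1][1] == one[0][1]
        and two[0][1] < two[1][0]
    )


def _pair_events(
    chain_a: Chain,
    span_a: Interval,
    chain_b: Chain,
    span_b: Interval,
    strand: str,
):
    """Localized differences between two chains over their shared span.

    Yields (type, region, junctions, side, length_difference) tuples; ``side``
    is +1 when chain_a is the exon-richer (inclusion) form, -1 when chain_b.
    """
    o_lo = max(span_a[0], span_b[0])
    o_hi = min(span_a[1], span_b[1])
    if o_lo >= o_hi:
        return
    set_a, set_b = set(chain_a), set(chain_b)
    ua = sorted(iv for iv in set_a - set_b if _overlap(iv, (o_lo, o_hi)))
    ub = sorted(iv for iv in set_b - set_a if _overlap(iv, (o_lo, o_hi)))
    for ca, cb in _components(ua, ub):
        comp_lo = min(iv[0] for iv in ca + cb)
        comp_hi = max(iv[1] for iv in ca + cb)
        etype, region, side = _classify_component(ca, cb, strand)
        # a difference reaching either isoform's terminal aligned base is not
        # interpretable: truncation and variation are indistinguishable there
        if comp_lo <= o_lo or comp_hi >= o_hi:
            etype = "Others"
            region = (comp_lo, comp_hi)
        # exonic difference is defined only where both isoforms are aligned
        clipped = (max(region[0], o_lo), min(region[1], o_hi))
        ldiff = abs(
            _intronic_bases(chain_a, clipped) - _intronic_bases(chain_b, clipped)
        )
        junctions = tuple(sorted(ca + cb))
        yield etype, region, junctions, side, ldiff


def detect_events(cluster: TranscriptCluster) -> list[TsvEvent]:
    """All classified pairwise isoform differences in one cluster.

    Identical differences found in several isoform pairs (same type, variable
    region and flanking junctions) are merged, with EST support unioned per
    side.  The "a" side is the exon-richer (inclusion) isoform.
    """
    spans = []
    for chain, ests in cluster.isoforms:
        members = [m for m in cluster.members if m.est_id in set(ests)]
        spans.append((min(m.start for m in members), max(m.end for m in members)))

    merged: dict[tuple, dict] = {}
    iso = cluster.isoforms
    for i in range(len(iso)):
        for j in range(i + 1, len(iso)):
            chain_i, ests_i = iso[i]
            chain_j, ests_j = iso[j]
            for etype, region, junctions, side, ldiff in _pair_events(
                chain_i, spans[i], chain_j, spans[j], cluster.strand
            ):
                if side > 0:
                    a_ests, b_ests = ests_i, ests_j
                elif side < 0:
                    a_ests, b_ests = ests_j, ests_i
                else:  # tie on exonic content: deterministic by EST ids
                    a_ests, b_ests = sorted((ests_i, ests_j))
                key = (etype, cluster.chrom, cluster.strand, region, junctions)
                rec = merged.setdefault(
                    key,
                    {"a": set(), "b": set(), "ldiff": ldiff},
                )
                rec["a"].update(a_ests)
                rec["b"].update(b_ests)
                # terminal Others events can be observed over different
                # overlaps; keep the most complete measurement
                rec["ldiff"] = max(rec["ldiff"], ldiff)

    events = []
    for n, (key, rec) in enumerate(
        sorted(merged.items(), key=lambda kv: (kv[0][3], kv[0][0]))
    ):
        etype, chrom, strand, region, junctions = key
        a = frozenset(rec["a"] - rec["b"])
        b = frozenset(rec["b"] - rec["a"])
        events.append(
            TsvEvent(
                event_id=f"{cluster.cluster_id}|TSV{n + 1}",
                cluster_id=cluster.cluster_id,
                chrom=chrom,
                strand=strand,
                type=etype,
                variable_region=region,
                isoform_a_ests=a,
                isoform_b_ests=b,
                length_difference=rec["ldiff"],
                in_frame=rec["ldiff"] % 3 == 0,
                junctions=junctions,
            )
        )
    return events


def intersect_event_sets(
    set_a: Sequence[TsvEvent], set_b: Sequence[TsvEvent], slack: int = 0
) -> list[TsvEvent]:
    """Events of ``set_a`` confirmed by ``set_b`` (within ``slack`` bp).

    Matching requires equal type, chromosome and strand, with both ends of
    the variable region within ``slack`` bp.  Used to remove alignment-tool
    false positives by keeping only events found by both tools.
    """
    by_locus: dict[tuple, list[TsvEvent]] = {}
    for ev in set_b:
        by_locus.setdefault((ev.type, ev.chrom, ev.strand), []).append(ev)
    out = []
    for ev in set_a:
        for cand in by_locus.get((ev.type, ev.chrom, ev.strand), []):
            if (
                abs(cand.variable_region[0] - ev.variable_region[0]) <= slack
                and abs(cand.variable_region[1] - ev.variable_region[1]) <= slack
            ):
                out.append(ev)
                break
    return out


def event_type_frequencies(events: Sequence[TsvEvent]) -> pd.DataFrame:
    """Count and fraction per event type (all six categories listed)."""
    if not events:
        return pd.DataFrame(columns=["type", "count", "fraction"])
    counts = {t: 0 for t in EVENT_TYPES}
    for ev in events:
        counts[ev.type] += 1
    total = len(events)
    return pd.DataFrame(
        {
            "type": list(EVENT_TYPES),
            "count": [counts[t] for t in EVENT_TYPES],
            "fraction": [counts[t] / total for t in EVENT_TYPES],
        }
    )
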