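"""Allelic variation vs. alternative splicing, decided by linked SNP patterns.

Alternative-splicing isoforms are spliced from the same pre-mRNA, so ESTs of
both isoforms carry the same allele SNPs; isoforms produced by two gene
alleles carry the two alleles' distinct, tightly linked SNP patterns.  For
each structural event the two isoform EST groups are therefore compared at
shared mSNP positions: every EST gets a pattern vector of its bases at the
mSNP sites its aligned blocks cover (the reference base where it matches the
reference), and each cross-group EST pair is compared over the positions both
cover.  If any informative pair matches at every shared position the event is
alternative splicing; if informative pairs exist and none matches, the event
is allelic; with no informative pair the event is undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from allelesplice.alignment_io import SplicedAlignment
from allelesplice.snp_call import SnpCall
from allelesplice.tsv_detect import EVENT_TYPES, TsvEvent

__all__ = [
    "EstSnpPattern",
    "SourceCall",
    "build_groups",
    "classify_source",
    "allelic_fraction_by_type",
]


@dataclass(frozen=True)
class EstSnpPattern:
    """One EST's bases at the mSNP positions its aligned blocks cover."""

    est_id: str
    positions: tuple[int, ...]
    bases: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.bases):
            raise ValueError(f"{self.est_id}: positions/bases length mismatch")
        if any(b > a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError(f"{self.est_id}: positions not strictly increasing")


@dataclass
class SourceCall:
    """Per-event verdict with the pairwise evidence that produced it."""

    event_id: str
    verdict: str  # 'allelic' | 'alternative_splicing' | 'undetermined'
    n_informative_pairs: int
    evidence: list[tuple[str, str, tuple[int, ...], bool]]


def _pattern_for(
    aln: SplicedAlignment,
    site_base: dict[int, dict[str, str]],
    sites: Sequence[tuple[int, str]],
) -> Optional[EstSnpPattern]:
    """Pattern at the sites covered by ``aln``; None when none are covered."""
    positions, bases = [], []
    for pos, ref in sites:
        if any(s <= pos < e for s, e in aln.blocks):
            positions.append(pos)
            bases.append(site_base[pos].get(aln.est_id, ref))
    if not positions:
        return None
    return EstSnpPattern(aln.est_id, tuple(positions), tuple(bases))


def build_groups(
    event: TsvEvent,
    alns: Sequence[SplicedAlignment],
    msnps: Sequence[SnpCall],
) -> tuple[list[EstSnpPattern], list[EstSnpPattern]]:
    """SNP-pattern groups for the event's two isoform EST sets.

    Only mSNP sites on the event's chromosome are considered.  ESTs whose
    aligned blocks cover no mSNP site are removed from their group: such
    sequences (including reads computationally matched to the reference) can
    contribute no evidence either way.
    """
    by_id = {a.est_id: a for a in alns if a.chrom == event.chrom}
    site_base: dict[int, dict[str, str]] = {}
    site_ref: dict[int, str] = {}
    for c in msnps:
        if c.chrom != event.chrom:
            continue
        site_ref[c.pos] = c.ref_base
        per_est = site_base.setdefault(c.pos, {})
        for est in c.supporting_ests:
            per_est[est] = c.alt_base
    sites = sorted(site_ref.items())

    groups: list[list[EstSnpPattern]] = []
    for est_ids in (event.isoform_a_ests, event.isoform_b_ests):
        patterns = []
        for est_id in sorted(est_ids):
            aln = by_id.get(est_id)
            if aln is None:
                raise KeyError(
                    f"event {event.event_id}: EST {est_id!r} has no alignment "
                    f"on {event.chrom}"
                )
            pat = _pattern_for(aln, site_base, sites)
            if pat is not None:
                patterns.append(pat)
        groups.append(patterns)
    return groups[0], groups[1]


def classify_source(
    group1: Sequence[EstSnpPattern],
    group2: Sequence[EstSnpPattern],
    event_id: str = "",
) -> SourceCall:
    """Compare every cross-group EST pair at their shared mSNP positions.

    A pair is informative when the two ESTs cover at least one common mSNP
    site, and matches when their bases agree at every shared site.  Any
    informative match means the two isoforms share an allele (alternative
    splicing); informative pairs that all mismatch mean distinct alleles.
    """
    evidence = []
    n_informative = 0
    any_match = False
    for p in group1:
        pos_p = dict(zip(p.positions, p.bases))
        for q in group2:
            shared = tuple(pos for pos in q.positions if pos in pos_p)
            if not shared:
                continue
            n_informative += 1
            qmap = dict(zip(q.positions, q.bases))
            match = all(pos_p[pos] == qmap[pos] for pos in shared)
            any_match |= match
            evidence.append((p.est_id, q.est_id, shared, match))
    if n_informative == 0:
        verdict = "undetermined"
    elif any_match:
        verdict = "alternative_splicing"
    else:
        verdict = "allelic"
    return SourceCall(
        event_id=event_id,
        verdict=verdict,
        n_informative_pairs=n_informative,
        evidence=evidence,
    )


def allelic_fraction_by_type(
    calls: Sequence[SourceCall], events: Sequence[TsvEvent]
) -> pd.DataFrame:
    """Fraction of events called allelic, per TSV type and overall.

    Undetermined events are excluded from the denominator; a type with no
    determined events gets a missing fraction.  The overall row is labeled
    ``"all"``.
    """
    by_event = {ev.event_id: ev for ev in events}
    rows = {t: {"allelic": 0, "alternative_splicing": 0, "undetermined": 0}
            for t in EVENT_TYPES}
    for call in calls:
        ev = by_event.get(call.event_id)
        if ev is None:
            raise KeyError(f"source call {call.event_id!r} joins to no event")
        rows[ev.type][call.verdict] += 1
    records = []
    for t in list(EVENT_TYPES) + ["all"]:
        if t == "all":
            counts = {
                k: sum(rows[tt][k] for tt in EVENT_TYPES)
                for k in ("allelic", "alternative_splicing", "undetermined")
            }
        else:
            counts = rows[t]
        denom = counts["allelic"] + counts["alternative_splicing"]
        records.append(
            {
                "type": t,
                "allelic": counts["allelic"],
                "alternative_splicing": counts["alternative_splicing"],
                "undetermined": counts["undetermined"],
                "fraction_allelic": counts["allelic"] / denom if denom else float("nan"),
            }
        )
    return pd.DataFrame(records)
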