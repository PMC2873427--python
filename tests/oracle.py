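"""Brute-force references and random-instance generators used by the tests.

The event oracle enumerates intron relations directly: differing introns are
grouped with an explicit overlap graph (networkx connected components) and
each group is classified by literally checking the category definitions;
length differences are recomputed by per-base set arithmetic.  It shares no
code with the detector beyond the type-label convention.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from allelesplice.alignment_io import SplicedAlignment, TranscriptCluster

Interval = tuple[int, int]


def exonic_positions(span: Interval, chain) -> set[int]:
    pos = set(range(span[0], span[1]))
    for d, a in chain:
        pos -= set(range(d, a))
    return pos


def oracle_pair_events(chain_a, span_a, chain_b, span_b, strand):
    """All (type, region, junctions, length_difference) for one isoform pair."""
    o_lo = max(span_a[0], span_b[0])
    o_hi = min(span_a[1], span_b[1])
    if o_lo >= o_hi:
        return []
    ua = [iv for iv in set(chain_a) - set(chain_b) if iv[0] < o_hi and iv[1] > o_lo]
    ub = [iv for iv in set(chain_b) - set(chain_a) if iv[0] < o_hi and iv[1] > o_lo]
    g = nx.Graph()
    for iv in ua:
        g.add_node(("a", iv))
    for iv in ub:
        g.add_node(("b", iv))
    for side1, iv1 in g.nodes:
        for side2, iv2 in g.nodes:
            if (side1, iv1) < (side2, iv2):
                if iv1[0] < iv2[1] and iv2[0] < iv1[1]:
                    g.add_edge((side1, iv1), (side2, iv2))
    exa = exonic_positions((o_lo, o_hi), chain_a)
    exb = exonic_positions((o_lo, o_hi), chain_b)

    out = []
    for comp in nx.connected_components(g):
        ca = sorted(iv for side, iv in comp if side == "a")
        cb = sorted(iv for side, iv in comp if side == "b")
        lo = min(iv[0] for iv in ca + cb)
        hi = max(iv[1] for iv in ca + cb)
        etype, region = _classify(ca, cb, (lo, hi), exa, exb, strand)
        if lo <= o_lo or hi >= o_hi:
            etype, region = "Others", (lo, hi)
        rpos = set(range(region[0], region[1]))
        ldiff = abs(len(exa & rpos) - len(exb & rpos))
        out.append((etype, region, tuple(sorted(ca + cb)), ldiff))
    return out


def _classify(ca, cb, bounds, exa, exb, strand):
    one, other_ex = (ca, exb) if len(ca) == 1 and not cb else (cb, exa)
    if len(one) == 1 and (not ca or not cb):
        d, a = one[0]
        if all(p in other_ex for p in range(d, a)):
            return "IntronR", (d, a)
        return "Others", bounds
    if len(ca) == 1 and len(cb) == 1:
        (d1, a1), (d2, a2) = ca[0], cb[0]
        donor_is_left = strand != "-"
        if d1 == d2:
            label = "AltA" if donor_is_left else "AltD"
            return label, (min(a1, a2), max(a1, a2))
        if a1 == a2:
            label = "AltD" if donor_is_left else "AltA"
            return label, (min(d1, d2), max(d1, d2))
        if max(d1, d2) < min(a1, a2):
            return "AltS", bounds
        return "Others", bounds
    for two, single in ((ca, cb), (cb, ca)):
        if len(two) == 2 and len(single) == 1:
            (d1, a1), (d2, a2) = two
            if single[0] == (d1, a2) and a1 < d2:
                return "ExonS", (a1, d2)
    return "Others", bounds


def oracle_cluster_events(isoforms, strand):
    """Deduplicated event set for a whole cluster.

    ``isoforms`` is a list of (chain, span) pairs; events identical in
    (type, region, junctions) found in several pairs count once.
    """
    seen = {}
    for i in range(len(isoforms)):
        for j in range(i + 1, len(isoforms)):
            ch_i, sp_i = isoforms[i]
            ch_j, sp_j = isoforms[j]
            for etype, region, junctions, ldiff in oracle_pair_events(
                ch_i, sp_i, ch_j, sp_j, strand
            ):
                key = (etype, region, junctions)
                seen[key] = max(seen.get(key, 0), ldiff)
    return {k + (v,) for k, v in seen.items()}


# ---------------------------------------------------------------------------
# random instances


def random_chain(rng: np.random.Generator, max_introns: int, lo=2, hi=398):
    n = int(rng.integers(1, max_introns + 1))
    cuts = sorted(rng.choice(np.arange(lo, hi), size=2 * n, replace=False))
    return [(int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n)]


def random_cluster(rng: np.random.Generator, max_isoforms=4, max_introns=6):
    """A random TranscriptCluster plus its (chain, span) list for the oracle."""
    strand = rng.choice(["+", "-"])
    n_iso = int(rng.integers(2, max_isoforms + 1))
    isoforms = []
    members = []
    seen_chains = set()
    for k in range(n_iso):
        chain = random_chain(rng, max_introns)
        span_lo = int(rng.integers(0, 40))
        span_hi = int(rng.integers(360, 401))
        # the span must start/end in exonic sequence: nudge out of introns
        for d, a in chain:
            if d < span_lo <= a:
                span_lo = a
            if d <= span_hi < a:
                span_hi = d
        chain = tuple((d, a) for d, a in chain if d > span_lo and a < span_hi)
        if not chain or chain in seen_chains:
            continue
        seen_chains.add(chain)
        blocks = []
        cur = span_lo
        for d, a in chain:
            blocks.append((cur, d))
            cur = a
        blocks.append((cur, span_hi))
        est_id = f"iso{k}"
        members.append(
            SplicedAlignment(
                est_id=est_id,
                chrom="chrT",
                strand=str(strand),
                blocks=tuple(blocks),
                coverage=1.0,
                identity=1.0,
            )
        )
        isoforms.append((chain, (span_lo, span_hi)))
    if len(isoforms) < 2:
        return None
    cluster = TranscriptCluster(
        cluster_id="test",
        chrom="chrT",
        strand=str(strand),
        members=members,
        isoforms=[(chain, (m.est_id,)) for (chain, _), m in zip(isoforms, members)],
    )
    return cluster, isoforms, str(strand)
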