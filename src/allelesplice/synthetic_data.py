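"""Synthetic loci, alleles, isoforms and error-bearing ESTs with truth tables.

Each simulated gene is a multi-exon locus on its own chromosome.  The
reference allele defines isoform 1; one structural variant (intron retention,
alternative donor/acceptor/both, or exon skipping) defines isoform 2.  With
probability ``fraction_allelic_events`` the variant is allelic: isoform 2 is
expressed from a second allele carrying linked SNPs (background density
``snp_density`` on exonic sequence common to both isoforms, plus one
guaranteed tag SNP in the exonic flank just upstream of the variant,
modeling the tight linkage between a causal mutation and nearby polymorphism).
Otherwise the variant is alternative splicing: the locus is still polymorphic
(two alleles with the same SNPs), but both alleles express both isoforms and
ESTs alternate between alleles within each isoform group, so cross-isoform
EST pairs from the same allele exist.

ESTs are windows of the mature transcript that always span the variant with
``flank`` exonic bases on each side, carrying uniform per-base substitution
errors at ``est_error_rate`` (no indels: the false-positive arithmetic of
mismatch SNP calling assumes a substitution rate).  Intronic SNPs are never
planted: they would be invisible in ESTs.  The generator emits genome FASTA,
EST FASTA, exact truth alignments (extended BED12), gene models (GFF3) and
truth tables, and is bit-reproducible for a fixed seed.

What this does not emulate: indel sequencing errors, alignment errors
(truth alignments are exact), expression imbalance between alleles,
population structure, or more than two isoforms per locus.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from allelesplice.alignment_io import SplicedAlignment
from allelesplice.snp_call import _revcomp
from allelesplice.tsv_detect import TsvEvent, _intronic_bases

__all__ = ["SimConfig", "SimResult", "simulate", "end_to_end_truth_eval"]

PLANTABLE_TYPES = ("IntronR", "AltA", "AltD", "AltS", "ExonS")

# Field frequencies of the five plantable categories in the A. gambiae EST
# survey (41/10/14/11/6 %), renormalized without the unplantable remainder.
_DEFAULT_MIX = {
    "IntronR": 41 / 82,
    "AltA": 10 / 82,
    "AltD": 14 / 82,
    "AltS": 11 / 82,
    "ExonS": 6 / 82,
}

Interval = tuple[int, int]


@dataclass
class SimConfig:
    """Study conditions for one simulation; same seed => identical output."""

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (90, 300)
    intron_len: tuple[int, int] = (60, 200)
    snp_density: float = 0.01  # one SNP per 100 bp on average
    est_error_rate: float = 0.0044  # substitutions per base
    ests_per_isoform: tuple[int, int] = (3, 6)
    est_len: tuple[int, int] = (350, 700)
    fraction_allelic_events: float = 0.28
    event_type_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    seed: int = 0
    flank: int = 30  # exonic anchor guaranteed on each side of the event
    utr5_len: int = 120
    utr3_len: int = 150

    def __post_init__(self) -> None:
        total = sum(self.event_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event_type_mix sums to {total}, not 1")
        for name in ("exons_per_gene", "exon_len", "intron_len",
                     "ests_per_isoform", "est_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad range {name}={lo, hi}")
        if not 0.0 <= self.fraction_allelic_events <= 1.0:
            raise ValueError("fraction_allelic_events outside [0, 1]")


@dataclass
class SimResult:
    genome: dict[str, str]
    est_seqs: dict[str, str]
    alignments: list[SplicedAlignment]
    truth_events: pd.DataFrame
    truth_snps: pd.DataFrame
    truth_ests: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# structure helpers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _blocks_from_chain(span: Interval, chain: Sequence[Interval]) -> list[Interval]:
    blocks = []
    cur = span[0]
    for d, a in chain:
        blocks.append((cur, d))
        cur = a
    blocks.append((cur, span[1]))
    return blocks


def _tpos(blocks: Sequence[Interval], g: int) -> int:
    """Exonic genomic position -> offset along the + direction."""
    t = 0
    for s, e in blocks:
        if s <= g < e:
            return t + (g - s)
        t += e - s
        if g < s:
            break
    raise ValueError(f"position {g} not exonic")


def _window_blocks(blocks: Sequence[Interval], t0: int, t1: int) -> list[Interval]:
    """Genomic pieces of the transcript-offset window [t0, t1)."""
    pieces = []
    t = 0
    for s, e in blocks:
        blen = e - s
        lo, hi = max(t0, t), min(t1, t + blen)
        if lo < hi:
            pieces.append((s + lo - t, s + hi - t))
        t += blen
    return pieces


def _tx_to_genomic(blocks: Sequence[Interval], strand: str, t0: int, t1: int):
    """Transcription-order transcript interval -> sorted genomic intervals."""
    T = sum(e - s for s, e in blocks)
    if strand == "-":
        t0, t1 = T - t1, T - t0
    return _window_blocks(blocks, t0, t1)


class _Infeasible(Exception):
    pass


def _apply_variant(
    etype: str,
    chain: list[Interval],
    strand: str,
    rng: np.random.Generator,
    min_exon_keep: int = 40,
    min_intron: int = 30,
    max_shift: int = 30,
):
    """Second intron chain carrying one variant of ``etype``.

    Returns (chain2, variable_region, outer_bounds).  Raises _Infeasible when
    the randomly chosen intron cannot host the variant.
    """
    n = len(chain)
    k = int(rng.integers(0, n))
    d, a = chain[k]
    prev_exon_start = chain[k - 1][1] if k > 0 else None
    next_exon_end = chain[k + 1][0] if k < n - 1 else None

    def shift(end: str) -> int:
        m = int(rng.integers(4, max_shift + 1))
        sign = -1 if rng.random() < 0.5 else 1
        delta = sign * m
        if end == "right":
            new = a + delta
            lo_ok = new - d >= min_intron
            hi_bound = next_exon_end if next_exon_end is not None else None
            hi_ok = hi_bound is None or hi_bound - new >= min_exon_keep
            if not (lo_ok and hi_ok):
                raise _Infeasible
            return new
        new = d + delta
        lo_bound = prev_exon_start if prev_exon_start is not None else None
        lo_ok = lo_bound is None or new - lo_bound >= min_exon_keep
        hi_ok = a - new >= min_intron
        if not (lo_ok and hi_ok):
            raise _Infeasible
        return new

    if etype == "IntronR":
        chain2 = chain[:k] + chain[k + 1 :]
        if not chain2:
            raise _Infeasible  # both isoforms must stay multi-exonic
        return chain2, (d, a), (d, a)

    if etype in ("AltA", "AltD"):
        # biological acceptor is the genomic-right intron end on '+',
        # genomic-left on '-'
        move_right = (etype == "AltA") == (strand != "-")
        if move_right:
            a2 = shift("right")
            chain2 = chain[:k] + [(d, a2)] + chain[k + 1 :]
            region = (min(a, a2), max(a, a2))
        else:
            d2 = shift("left")
            chain2 = chain[:k] + [(d2, a)] + chain[k + 1 :]
            region = (min(d, d2), max(d, d2))
        outer = (min(chain2[k][0], d), max(chain2[k][1], a))
        return chain2, region, outer

    if etype == "AltS":
        d2, a2 = shift("left"), shift("right")
        if d2 == d or a2 == a or a2 - d2 < min_intron:
            raise _Infeasible
        chain2 = chain[:k] + [(d2, a2)] + chain[k + 1 :]
        outer = (min(d, d2), max(a, a2))
        return chain2, outer, outer

    if etype == "ExonS":
        if k >= n - 1:
            raise _Infeasible  # needs a following intron
        d2, a2 = chain[k + 1]
        chain2 = chain[:k] + [(d, a2)] + chain[k + 2 :]
        return chain2, (a, d2), (d, a2)

    raise ValueError(f"unknown event type {etype!r}")


# ---------------------------------------------------------------------------
# generator


def simulate(config: SimConfig, out_dir: Optional[str] = None) -> SimResult:
    """Generate loci, alleles, isoforms, ESTs and truth tables.

    When ``out_dir`` is given, writes genome.fa, ests.fa, alignments.bed12
    (columns 13/14 = coverage/identity fractions), genes.gff3 and three truth
    TSVs there; paths are recorded in the result.
    """
    rng = np.random.default_rng(config.seed)
    types = sorted(config.event_type_mix)
    probs = np.array([config.event_type_mix[t] for t in types])
    probs = probs / probs.sum()

    genome: dict[str, str] = {}
    est_seqs: dict[str, str] = {}
    alignments: list[SplicedAlignment] = []
    ev_rows, snp_rows, est_rows = [], [], []
    gff_lines = ["##gff-version 3"]

    pad = 150
    for gi in range(config.n_genes):
        chrom = f"chr{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        intron_lens = rng.integers(
            config.intron_len[0], config.intron_len[1] + 1, n_ex - 1
        )
        blocks1 = []
        cur = pad
        for i, el in enumerate(exon_lens):
            blocks1.append((cur, cur + int(el)))
            cur += int(el)
            if i < n_ex - 1:
                cur += int(intron_lens[i])
        span = (blocks1[0][0], blocks1[-1][1])
        chrom_len = cur + pad
        ref_seq = _random_seq(rng, chrom_len)
        chain1 = [(blocks1[i][1], blocks1[i + 1][0]) for i in range(n_ex - 1)]

        etype = types[int(rng.choice(len(types), p=probs))]
        for attempt in range(50):
            try:
                chain2, region, outer = _apply_variant(etype, chain1, strand, rng)
                break
            except _Infeasible:
                continue
        else:
            raise RuntimeError(
                f"{chrom}: could not place a {etype} variant after 50 attempts; "
                f"loosen the geometry ranges"
            )
        blocks2 = _blocks_from_chain(span, chain2)
        allelic = bool(rng.random() < config.fraction_allelic_events)

        # SNPs on exonic sequence common to both isoforms, outside the event
        common = _subtract_intervals(
            _intersect_intervals(blocks1, blocks2), [outer]
        )
        snp_alt: dict[int, str] = {}
        for s, e in common:
            n_hits = rng.binomial(e - s, config.snp_density)
            if n_hits:
                for pos in sorted(rng.choice(e - s, size=n_hits, replace=False)):
                    snp_alt[s + int(pos)] = _mutate(ref_seq[s + int(pos)], rng)
        # guaranteed tag SNP in the upstream exonic flank, clear of the
        # default junction/end masks of the SNP caller
        tag_pos = int(rng.integers(outer[0] - 25, outer[0] - 9))
        tag_is_new = tag_pos not in snp_alt
        snp_alt[tag_pos] = snp_alt.get(tag_pos) or _mutate(ref_seq[tag_pos], rng)
        allele2 = _substitute(ref_seq, snp_alt)
        common_len = sum(e - s for s, e in common)

        ldiff = abs(_intronic_bases(chain1, region) - _intronic_bases(chain2, region))
        ev_rows.append(
            {
                "gene_id": chrom,
                "chrom": chrom,
                "strand": strand,
                "type": etype,
                "region_start": region[0],
                "region_end": region[1],
                "outer_start": outer[0],
                "outer_end": outer[1],
                "source": "allelic" if allelic else "alternative_splicing",
                "length_difference": ldiff,
                "common_exonic_bp": common_len,
                "n_snps": len(snp_alt),
            }
        )
        for pos in sorted(snp_alt):
            snp_rows.append(
                {
                    "gene_id": chrom,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref_seq[pos],
                    "alt": snp_alt[pos],
                    "is_tag": pos == tag_pos and tag_is_new,
                }
            )

        genome[chrom] = ref_seq
        alleles = {1: ref_seq, 2: allele2}
        for iso_idx, blocks in ((1, blocks1), (2, blocks2)):
            T = sum(e - s for s, e in blocks)
            t_lo = _tpos(blocks, outer[0] - config.flank)
            t_hi = _tpos(blocks, outer[1] + config.flank - 1) + 1
            # every EST must straddle a splice junction of its isoform, or
            # its alignment would be single-block and discarded as possible
            # genomic contamination
            junctions = []
            acc = 0
            for s, e in blocks[:-1]:
                acc += e - s
                junctions.append(acc)
            if not any(t_lo < c < t_hi for c in junctions):
                c = min(junctions, key=lambda c: min(abs(c - t_lo), abs(c - t_hi)))
                t_lo = min(t_lo, c - 5)
                t_hi = max(t_hi, c + 5)
            n_ests = int(
                rng.integers(config.ests_per_isoform[0], config.ests_per_isoform[1] + 1)
            )
            for j in range(n_ests):
                if allelic:
                    allele = iso_idx
                else:
                    allele = (j % 2) + 1  # balanced: both alleles in each group
                L = int(rng.integers(config.est_len[0], config.est_len[1] + 1))
                L = min(max(L, t_hi - t_lo), T)
                lo0 = max(0, t_hi - L)
                hi0 = min(t_lo, T - L)
                t0 = int(rng.integers(lo0, hi0 + 1))
                pieces = _window_blocks(blocks, t0, t0 + L)
                fwd = "".join(alleles[allele][s:e] for s, e in pieces)
                n_err = rng.binomial(L, config.est_error_rate)
                if n_err:
                    err_pos = rng.choice(L, size=n_err, replace=False)
                    chars = list(fwd)
                    for p in err_pos:
                        chars[int(p)] = _mutate(chars[int(p)], rng)
                    fwd = "".join(chars)
                ref_concat = "".join(ref_seq[s:e] for s, e in pieces)
                mism = sum(1 for r, q in zip(ref_concat, fwd) if r != q)
                est_id = f"{chrom}.i{iso_idx}.e{j}"
                est_seqs[est_id] = _revcomp(fwd) if strand == "-" else fwd
                alignments.append(
                    SplicedAlignment(
                        est_id=est_id,
                        chrom=chrom,
                        strand=strand,
                        blocks=tuple(pieces),
                        coverage=1.0,
                        identity=1.0 - mism / L,
                        source_tag="sim",
                    )
                )
                est_rows.append(
                    {
                        "est_id": est_id,
                        "gene_id": chrom,
                        "isoform": iso_idx,
                        "allele": allele,
                        "n_errors": int(n_err),
                    }
                )

        gff_lines.extend(
            _gene_model_gff(chrom, strand, blocks1, config.utr5_len, config.utr3_len)
        )

    result = SimResult(
        genome=genome,
        est_seqs=est_seqs,
        alignments=alignments,
        truth_events=pd.DataFrame(ev_rows),
        truth_snps=pd.DataFrame(snp_rows),
        truth_ests=pd.DataFrame(est_rows),
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        result.paths = _write_outputs(result, gff_lines, out_dir)
    return result


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base.upper()]
    return choices[int(rng.integers(0, 3))]


def _substitute(seq: str, subs: dict[int, str]) -> str:
    chars = list(seq)
    for pos, alt in subs.items():
        chars[pos] = alt
    return "".join(chars)


def _intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo < hi:
                out.append((lo, hi))
    return sorted(out)


def _subtract_intervals(a: Sequence[Interval], holes: Sequence[Interval]) -> list[Interval]:
    out = []
    for s, e in a:
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


def _gene_model_gff(
    chrom: str,
    strand: str,
    blocks: Sequence[Interval],
    utr5_len: int,
    utr3_len: int,
) -> list[str]:
    """GFF3 gene/mRNA/exon/CDS/UTR features for the reference isoform."""
    T = sum(e - s for s, e in blocks)
    u5 = min(utr5_len, T // 4)
    u3 = min(utr3_len, T // 4)
    cds_len = T - u5 - u3
    rem = cds_len % 3
    cds_len -= rem
    u3 += rem
    gene_id = f"{chrom}.gene"
    mrna_id = f"{chrom}.mRNA"
    lo, hi = blocks[0][0], blocks[-1][1]
    lines = [
        f"{chrom}\tsim\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\tID={gene_id}",
        f"{chrom}\tsim\tmRNA\t{lo + 1}\t{hi}\t.\t{strand}\t.\tID={mrna_id};Parent={gene_id}",
    ]
    for s, e in blocks:
        lines.append(
            f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={mrna_id}"
        )
    utr5_iv = _tx_to_genomic(blocks, strand, 0, u5)
    cds_iv = _tx_to_genomic(blocks, strand, u5, u5 + cds_len)
    utr3_iv = _tx_to_genomic(blocks, strand, u5 + cds_len, T)
    for ftype, ivs in (
        ("five_prime_UTR", utr5_iv),
        ("CDS", cds_iv),
        ("three_prime_UTR", utr3_iv),
    ):
        phase_ivs = ivs if strand == "+" else list(reversed(ivs))
        acc = 0
        for s, e in phase_ivs:
            phase = (3 - acc % 3) % 3 if ftype == "CDS" else "."
            acc += e - s
            lines.append(
                f"{chrom}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t"
                f"ID={mrna_id}.{ftype};Parent={mrna_id}"
            )
    # restore genomic order in the emitted file
    return lines


def _write_outputs(result: SimResult, gff_lines: list[str], out_dir: str) -> dict:
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "ests": os.path.join(out_dir, "ests.fa"),
        "alignments": os.path.join(out_dir, "alignments.bed12"),
        "gene_models": os.path.join(out_dir, "genes.gff3"),
        "truth_events": os.path.join(out_dir, "truth_events.tsv"),
        "truth_snps": os.path.join(out_dir, "truth_snps.tsv"),
        "truth_ests": os.path.join(out_dir, "truth_ests.tsv"),
    }
    _write_fasta(result.genome, paths["genome"])
    _write_fasta(result.est_seqs, paths["ests"])
    with open(paths["alignments"], "w") as fh:
        for a in result.alignments:
            sizes = ",".join(str(e - s) for s, e in a.blocks)
            starts = ",".join(str(s - a.start) for s, e in a.blocks)
            fh.write(
                "\t".join(
                    [
                        a.chrom,
                        str(a.start),
                        str(a.end),
                        a.est_id,
                        "0",
                        a.strand,
                        str(a.start),
                        str(a.end),
                        "0",
                        str(len(a.blocks)),
                        sizes,
                        starts,
                        f"{a.coverage:.6f}",
                        f"{a.identity:.6f}",
                    ]
                )
                + "\n"
            )
    with open(paths["gene_models"], "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    result.truth_events.to_csv(paths["truth_events"], sep="\t", index=False)
    result.truth_snps.to_csv(paths["truth_snps"], sep="\t", index=False)
    result.truth_ests.to_csv(paths["truth_ests"], sep="\t", index=False)
    return paths


def _write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# evaluation against truth


def end_to_end_truth_eval(
    events: Sequence[TsvEvent],
    source_calls,
    truth_events: pd.DataFrame,
) -> dict:
    """Per-stage accuracy of a pipeline run against the generator's truth.

    Detection matches a truth event when some detected event on the same
    chromosome has exactly the planted variable region; type accuracy and
    source-verdict accuracy (informative, i.e. determined, events only) are
    computed over the matched set.
    """
    by_chrom: dict[str, list[TsvEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    calls_by_event = {c.event_id: c for c in source_calls} if source_calls else {}

    n_truth = len(truth_events)
    matched = type_ok = 0
    determined = source_ok = 0
    n_allelic_verdict = n_as_verdict = 0
    matched_ids = set()
    for row in truth_events.itertuples():
        region = (row.region_start, row.region_end)
        hit = None
        for ev in by_chrom.get(row.chrom, []):
            if ev.variable_region == region:
                hit = ev
                break
        if hit is None:
            continue
        matched += 1
        matched_ids.add(hit.event_id)
        if hit.type == row.type:
            type_ok += 1
        call = calls_by_event.get(hit.event_id)
        if call is not None and call.verdict != "undetermined":
            determined += 1
            if call.verdict == "allelic":
                n_allelic_verdict += 1
            else:
                n_as_verdict += 1
            if call.verdict == row.source:
                source_ok += 1
    n_detected = len(events)
    det_denom = n_allelic_verdict + n_as_verdict
    return {
        "n_truth": n_truth,
        "n_detected": n_detected,
        "recall": matched / n_truth if n_truth else float("nan"),
        "precision": len(matched_ids) / n_detected if n_detected else float("nan"),
        "type_accuracy": type_ok / matched if matched else float("nan"),
        "n_informative": determined,
        "source_accuracy": source_ok / determined if determined else float("nan"),
        "estimated_allelic_fraction": (
            n_allelic_verdict / det_denom if det_denom else float("nan")
        ),
    }
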