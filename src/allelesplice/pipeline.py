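"""End-to-end orchestration: ingest -> detect -> (intersect) -> snps ->
classify -> impact, with a filter-count ledger and paper-style summary tables.

Defaults reproduce the study thresholds: coverage > 0.80 and identity > 0.95
(strict), uniexonic alignments removed, one best placement per EST, mSNP
support >= 2, zero intersection slack.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from allelesplice import alignment_io as aio
from allelesplice import allelic_classify as ac
from allelesplice import impact_annotate as ia
from allelesplice import snp_call as sc
from allelesplice import tsv_detect as td

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_events_gff3",
           "events_to_frame"]


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    alignments: str
    format: str = "bed12"
    source_tag: str = "set_a"
    alignments_b: Optional[str] = None  # second aligner's output, for intersection
    format_b: str = "bed12"
    source_tag_b: str = "set_b"
    genome: Optional[str] = None
    est_fasta: Optional[str] = None
    gene_models: Optional[str] = None
    min_coverage: float = 0.80
    min_identity: float = 0.95
    missing_policy: str = "reject"
    min_ests: int = 2
    slack: int = 0
    end_mask: int = 3
    gap_mask: int = 5
    near_end_fraction: float = 0.10
    out_dir: Optional[str] = None


@dataclass
class PipelineResult:
    clusters: list
    events: list
    all_snps: list = field(default_factory=list)
    msnps: list = field(default_factory=list)
    source_calls: list = field(default_factory=list)
    impacts: list = field(default_factory=list)
    type_frequencies: Optional[pd.DataFrame] = None
    location_frame: Optional[pd.DataFrame] = None
    allelic_fractions: Optional[pd.DataFrame] = None
    filter_ledger: list = field(default_factory=list)
    best_alignments: list = field(default_factory=list)


def _load_fasta(path: str):
    import pyfaidx

    return pyfaidx.Fasta(path, sequence_always_upper=True)


def ingest(
    path: str,
    format: str,
    source_tag: str,
    config: RunConfig,
    ledger: list,
) -> tuple[list, list]:
    """Read, filter, deduplicate and cluster one alignment set."""
    alns = aio.read_alignments(path, format, source_tag)
    n0 = len(alns)
    alns = aio.filter_alignments(
        alns, config.min_coverage, config.min_identity, config.missing_policy
    )
    ledger.append((source_tag, "coverage_identity_filter", n0, len(alns)))
    n1 = len(alns)
    alns = aio.drop_uniexonic(alns)
    ledger.append((source_tag, "drop_uniexonic", n1, len(alns)))
    n2 = len(alns)
    alns = aio.best_alignment_per_est(alns)
    ledger.append((source_tag, "best_alignment_per_est", n2, len(alns)))
    clusters = aio.cluster_alignments(alns)
    return alns, clusters


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage the inputs allow and assemble the summary tables.

    SNP calling and source classification run only when genome and EST FASTA
    are provided; impact annotation only when gene models are provided.
    Events of type Others are excluded from source classification (their
    structures are not interpretable as a two-isoform contrast).
    """
    ledger: list = []
    best_a, clusters = ingest(
        config.alignments, config.format, config.source_tag, config, ledger
    )
    events = [ev for cl in clusters for ev in td.detect_events(cl)]
    ledger.append((config.source_tag, "detect_events", len(clusters), len(events)))

    if config.alignments_b is not None:
        _, clusters_b = ingest(
            config.alignments_b, config.format_b, config.source_tag_b, config, ledger
        )
        events_b = [ev for cl in clusters_b for ev in td.detect_events(cl)]
        n0 = len(events)
        events = td.intersect_event_sets(events, events_b, config.slack)
        ledger.append(("both", "intersect_event_sets", n0, len(events)))

    result = PipelineResult(
        clusters=clusters,
        events=events,
        filter_ledger=ledger,
        best_alignments=best_a,
    )
    result.type_frequencies = td.event_type_frequencies(events)

    if config.genome and config.est_fasta:
        genome = _load_fasta(config.genome)
        ests = _load_fasta(config.est_fasta)
        singletons = []
        for aln in best_a:
            singletons.extend(
                sc.call_mismatches(
                    aln,
                    str(ests[aln.est_id]),
                    genome,
                    end_mask=config.end_mask,
                    gap_mask=config.gap_mask,
                )
            )
        result.all_snps = sc.aggregate_calls(singletons)
        result.msnps = sc.aggregate_and_filter(singletons, config.min_ests)
        ledger.append(("snps", "msnp_filter", len(result.all_snps), len(result.msnps)))

        msnps_by_chrom: dict[str, list] = {}
        for c in result.msnps:
            msnps_by_chrom.setdefault(c.chrom, []).append(c)
        alns_by_chrom: dict[str, list] = {}
        for a in best_a:
            alns_by_chrom.setdefault(a.chrom, []).append(a)
        for ev in events:
            if ev.type == "Others":
                continue
            g1, g2 = ac.build_groups(
                ev,
                alns_by_chrom.get(ev.chrom, []),
                msnps_by_chrom.get(ev.chrom, []),
            )
            result.source_calls.append(ac.classify_source(g1, g2, ev.event_id))
        result.allelic_fractions = ac.allelic_fraction_by_type(
            result.source_calls, events
        )

    if config.gene_models:
        models = ia.read_gene_models(config.gene_models)
        result.impacts = [
            ia.annotate_event(ev, models, config.near_end_fraction) for ev in events
        ]
        result.location_frame = ia.location_frame_summary(result.impacts)

    if config.out_dir:
        _write_bundle(result, config)
    return result


# ---------------------------------------------------------------------------
# output


def events_to_frame(events: Sequence[td.TsvEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "cluster_id": [e.cluster_id for e in events],
            "chrom": [e.chrom for e in events],
            "strand": [e.strand for e in events],
            "type": [e.type for e in events],
            "start": [e.variable_region[0] for e in events],
            "end": [e.variable_region[1] for e in events],
            "ests_a": [",".join(sorted(e.isoform_a_ests)) for e in events],
            "ests_b": [",".join(sorted(e.isoform_b_ests)) for e in events],
            "length_difference": [e.length_difference for e in events],
            "in_frame": [e.in_frame for e in events],
        }
    )


def write_events_gff3(events: Sequence[td.TsvEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in events:
            s, t = e.variable_region
            strand = e.strand if e.strand in ("+", "-") else "."
            attrs = (
                f"ID={e.event_id};type={e.type};"
                f"ests_a={','.join(sorted(e.isoform_a_ests))};"
                f"ests_b={','.join(sorted(e.isoform_b_ests))};"
                f"length_difference={e.length_difference};"
                f"in_frame={'true' if e.in_frame else 'false'}"
            )
            fh.write(
                f"{e.chrom}\tallelesplice\tTSV_event\t{s + 1}\t{t}\t.\t{strand}\t.\t{attrs}\n"
            )


def _write_bundle(result: PipelineResult, config: RunConfig) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    write_events_gff3(result.events, os.path.join(out, "events.gff3"))
    events_to_frame(result.events).to_csv(
        os.path.join(out, "events.tsv"), sep="\t", index=False
    )
    if result.msnps:
        sc.write_vcf(
            result.all_snps, os.path.join(out, "snps.vcf"), reference=config.genome or ""
        )
    if result.source_calls:
        pd.DataFrame(
            {
                "event_id": [c.event_id for c in result.source_calls],
                "verdict": [c.verdict for c in result.source_calls],
                "n_informative_pairs": [
                    c.n_informative_pairs for c in result.source_calls
                ],
            }
        ).to_csv(os.path.join(out, "verdicts.tsv"), sep="\t", index=False)
    if result.impacts:
        pd.DataFrame(
            {
                "event_id": [a.event_id for a in result.impacts],
                "region": [a.region for a in result.impacts],
                "in_frame": [a.in_frame for a in result.impacts],
                "gene_id": [a.gene_id for a in result.impacts],
                "distance_to_cds_end": [a.distance_to_cds_end for a in result.impacts],
                "near_cds_end": [a.near_cds_end for a in result.impacts],
            }
        ).to_csv(os.path.join(out, "impact.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "summary.txt"), "w") as fh:
        fh.write("# filter ledger (stage, in, out)\n")
        for tag, stage, n_in, n_out in result.filter_ledger:
            fh.write(f"{tag}\t{stage}\t{n_in}\t{n_out}\n")
        for title, frame in (
            ("event type frequencies", result.type_frequencies),
            ("location x frame", result.location_frame),
            ("allelic fractions", result.allelic_fractions),
        ):
            if frame is not None:
                fh.write(f"\n# {title}\n")
                fh.write(frame.to_string(index=False) + "\n")
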