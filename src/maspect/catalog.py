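"""Variant filtering, ancestor subtraction, clustering, and classification.

The mutation classes follow the standard MA-line taxonomy: a lone base
substitution is an SNM; two SNMs within the clustering distance (50 nt) are
one double-SNM event; three or more variants within chained 50-nt proximity
are one complex event; indels under 50 bp are small insertions/deletions;
deletions of 50-1000 bp are medium deletions and are treated as their own
class regardless of clustering.  Clustering is single-linkage on start
positions, so the events found are exactly the connected components of the
"within 50 nt" proximity graph.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, collapse_trinucleotide
from .vcfio import read_vcf_records

log = logging.getLogger(__name__)

EVENT_CLASSES = [
    "SNM",
    "insertion",
    "deletion",
    "double_SNM",
    "complex",
    "medium_deletion",
]

MEDIUM_DELETION_MIN = 50
MEDIUM_DELETION_MAX = 1000


@dataclass(frozen=True)
class VariantCall:
    """One filtered haploid variant call."""

    line_id: str
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    read_depth: int = 50
    alt_read_fraction: float = 1.0

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)

    @property
    def is_snm(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class MutationEvent:
    """A classified mutation event (one or more member variant calls)."""

    line_id: str
    event_class: str
    member_variants: list[VariantCall]
    chromosome: str
    start: int
    end: int
    net_length_change_bp: int
    snm_changes: list[tuple[str, str]] = field(default_factory=list)
    contexts: list[str | None] = field(default_factory=list)
    cpg_flags: list[bool | None] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_variants)


def read_variants(
    vcf_path,
    line_id: str,
    min_depth: int = 4,
    min_alt_fraction: float = 0.75,
    genome: ReferenceGenome | None = None,
) -> list[VariantCall]:
    """Read one line's VCF, applying the support filters.

    A call needs ``min_depth`` reads with at least ``min_alt_fraction`` of
    them backing the alternate allele (both thresholds inclusive).  Records
    inside excluded regions of ``genome`` are dropped; records without a
    usable depth field are rejected with a warning.
    """
    out = []
    for chrom, pos, ref, alt, depth, frac in read_vcf_records(vcf_path):
        if depth is None:
            log.warning(
                "%s: record %s:%d %s>%s has no depth field; rejected",
                vcf_path, chrom, pos, ref, alt,
            )
            continue
        if depth < min_depth or frac < min_alt_fraction:
            continue
        if genome is not None and not genome.mask[chrom][pos - 1]:
            continue
        out.append(
            VariantCall(
                line_id=line_id,
                chromosome=chrom,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                read_depth=depth,
                alt_read_fraction=frac,
            )
        )
    return out


def subtract_ancestor(line_variants, ancestor_variants) -> list[VariantCall]:
    """Drop calls identical (chrom, pos, ref, alt) to an ancestor call."""
    ancestral = {v.key for v in ancestor_variants}
    return [v for v in line_variants if v.key not in ancestral]


def _decompose_mnps(variants) -> list[VariantCall]:
    """Split same-length multi-base substitutions into per-base SNMs."""
    out = []
    for v in variants:
        if len(v.ref_allele) == len(v.alt_allele) and len(v.ref_allele) > 1:
            for i, (r, a) in enumerate(zip(v.ref_allele, v.alt_allele)):
                if r != a:
                    out.append(
                        VariantCall(
                            line_id=v.line_id,
                            chromosome=v.chromosome,
                            position=v.position + i,
                            ref_allele=r,
                            alt_allele=a,
                            read_depth=v.read_depth,
                            alt_read_fraction=v.alt_read_fraction,
                        )
                    )
        else:
            out.append(v)
    return out


def _singleton_class(v: VariantCall) -> str:
    if v.is_snm:
        return "SNM"
    change = v.length_change
    if change > 0:
        return "insertion"
    size = -change
    if MEDIUM_DELETION_MIN <= size <= MEDIUM_DELETION_MAX:
        return "medium_deletion"
    return "deletion"


def _make_event(line_id, members, event_class) -> MutationEvent:
    members = sorted(members, key=lambda v: v.position)
    return MutationEvent(
        line_id=line_id,
        event_class=event_class,
        member_variants=members,
        chromosome=members[0].chromosome,
        start=members[0].position,
        end=members[-1].position,
        net_length_change_bp=sum(v.length_change for v in members),
        snm_changes=[(v.ref_allele, v.alt_allele) for v in members if v.is_snm],
    )


def cluster_and_classify(variants, cluster_distance: int = 50) -> list[MutationEvent]:
    """Single-linkage clustering on start positions, then classification.

    Medium deletions (50-1000 bp) are pulled out before clustering and
    always form their own events.  A cluster of exactly two calls that is
    not two SNMs is not a defined class; its members are classified
    independently (and the occurrence logged).
    """
    variants = _decompose_mnps(variants)
    mediums = [v for v in variants if _singleton_class(v) == "medium_deletion"]
    rest = sorted(
        (v for v in variants if _singleton_class(v) != "medium_deletion"),
        key=lambda v: (v.chromosome, v.position, v.ref_allele, v.alt_allele),
    )

    events = [_make_event(v.line_id, [v], "medium_deletion") for v in mediums]

    clusters: list[list[VariantCall]] = []
    for v in rest:
        if (
            clusters
            and clusters[-1][-1].chromosome == v.chromosome
            and v.position - clusters[-1][-1].position <= cluster_distance
        ):
            clusters[-1].append(v)
        else:
            clusters.append([v])

    for members in clusters:
        line_id = members[0].line_id
        if len(members) == 1:
            events.append(_make_event(line_id, members, _singleton_class(members[0])))
        elif len(members) == 2:
            if all(v.is_snm for v in members):
                events.append(_make_event(line_id, members, "double_SNM"))
            else:
                log.info(
                    "2-variant cluster with an indel at %s:%d; members "
                    "classified independently",
                    members[0].chromosome, members[0].position,
                )
                for v in members:
                    events.append(_make_event(line_id, [v], _singleton_class(v)))
        else:
            events.append(_make_event(line_id, members, "complex"))
    events.sort(key=lambda e: (e.line_id, e.chromosome, e.start))
    return events


def annotate_context(event: MutationEvent, genome: ReferenceGenome) -> MutationEvent:
    """Attach trinucleotide class and CpG flag to each SNM member.

    CpG flag is strand-collapsed: true when the site is the C of a CpG on
    either strand (center C with 3' G, or center G with 5' C).
    """
    contexts, flags = [], []
    for v in event.member_variants:
        if not v.is_snm:
            continue
        tri = genome.context_at(v.chromosome, v.position)
        if tri is None:
            contexts.append(None)
            flags.append(None)
            continue
        contexts.append(collapse_trinucleotide(tri))
        flags.append(
            (tri[1] == "C" and tri[2] == "G") or (tri[1] == "G" and tri[0] == "C")
        )
    event.contexts = contexts
    event.cpg_flags = flags
    return event


def detect_cross_contamination(
    line_variants: dict[str, list[VariantCall]],
    seed: int = 2015,
) -> tuple[list[dict], set[str]]:
    """Flag line pairs sharing an identical new mutation; drop one per pair.

    Which member of a flagged pair is dropped is a seeded uniform draw (the
    original protocol used a coin flip).  Returns (pair reports, retained
    line ids).
    """
    if len(line_variants) < 2:
        return [], set(line_variants)
    rng = np.random.default_rng(seed)
    by_key = defaultdict(set)
    for line_id, variants in line_variants.items():
        for v in variants:
            by_key[v.key].add(line_id)
    shares = defaultdict(int)
    for key, lines in by_key.items():
        for a, b in itertools.combinations(sorted(lines), 2):
            shares[(a, b)] += 1
    retained = set(line_variants)
    reports = []
    for (a, b), n_shared in sorted(shares.items()):
        report = {"line_a": a, "line_b": b, "n_shared": n_shared, "dropped": None}
        if a in retained and b in retained:
            dropped = (a, b)[int(rng.integers(2))]
            retained.discard(dropped)
            report["dropped"] = dropped
        reports.append(report)
    return reports, retained


def catalog_summary(events) -> pd.DataFrame:
    """Per-line x per-class event count table (plus a 'total' row)."""
    lines = sorted({e.line_id for e in events})
    table = pd.DataFrame(0, index=lines + ["total"], columns=EVENT_CLASSES)
    for e in events:
        table.loc[e.line_id, e.event_class] += 1
        table.loc["total", e.event_class] += 1
    return table


def events_to_frame(events) -> pd.DataFrame:
    """Flatten events to a tidy table (one row per event)."""
    rows = []
    for e in events:
        rows.append(
            {
                "line_id": e.line_id,
                "class": e.event_class,
                "chrom": e.chromosome,
                "pos_start": e.start,
                "pos_end": e.end,
                "n_members": e.n_members,
                "net_length_change_bp": e.net_length_change_bp,
                "ref": e.member_variants[0].ref_allele,
                "alt": e.member_variants[0].alt_allele,
                "context": e.contexts[0] if e.contexts else None,
                "cpg_flag": e.cpg_flags[0] if e.cpg_flags else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "line_id", "class", "chrom", "pos_start", "pos_end", "n_members",
            "net_length_change_bp", "ref", "alt", "context", "cpg_flag",
        ],
    )
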