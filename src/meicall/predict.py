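"""Turning clustered events into filtered, merged, annotated predictions.

Filters annotate predictions with flags rather than deleting them; the
default report contains the flag-free ("pass") predictions, while every
prediction is retained in the audit file.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .cluster import MEIEvent
from .config import CallerConfig
from .extract import (
    ORIGIN_CLIPPED_TAIL,
    ORIGIN_DISCORDANT_MATE,
    ORIGIN_MULTIMAPPED_MATE,
    ORIGIN_UNMAPPED_MATE,
)
from .mobilome import FAMILIES

FLAG_LOW_SUPPORT = "low_support"
FLAG_REFERENCE_MEI = "reference_mei"
FLAG_SATELLITE = "satellite"
FLAG_SINGLE_CLUSTER = "single_cluster"

_SUPPORT_KEYS = (
    ("disc_unique", ORIGIN_DISCORDANT_MATE),
    ("disc_multimapped_mate", ORIGIN_MULTIMAPPED_MATE),
    ("clipped", ORIGIN_CLIPPED_TAIL),
    ("unmapped_mate", ORIGIN_UNMAPPED_MATE),
)

TSV_COLUMNS = (
    "chrom",
    "window_start",
    "window_end",
    "breakpoint",
    "family",
    "orientation",
    "tsd_bp",
    "support_total",
    "support_disc_unique",
    "support_disc_multimapped_mate",
    "support_clipped",
    "support_unmapped_mate",
    "polyA_side",
    "filters",
    "gene_component",
)

GENE_COMPONENTS = (
    "exonic",
    "splice",
    "ncRNA_exonic",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream_1kb",
    "downstream_1kb",
    "intergenic",
)


@dataclass
class Prediction:
    chrom: str
    window: tuple  # (start, end), 0-based half-open
    breakpoint: tuple  # (lo, hi), half-open; point when hi == lo+1
    family: str
    support_by_origin: dict = field(default_factory=dict)
    tsd_bp: Optional[int] = None
    polyA_side: str = "none"
    orientation: str = "unknown"
    flags: set = field(default_factory=set)
    gene_component: str = "."
    has_5p: bool = False
    has_3p: bool = False
    has_clipped: bool = False
    events: list = field(default_factory=list)
    context: Optional[str] = None  # 13 bp reference context around the breakpoint

    @property
    def support(self) -> int:
        return sum(self.support_by_origin.values())

    @property
    def passed(self) -> bool:
        return not self.flags


def predictions_from_events(events: Iterable[MEIEvent]) -> list[Prediction]:
    """Promote family-bearing events to predictions.

    Events without any family evidence (pure homopolymer or unmapped tags)
    cannot name an inserted element and are not promoted.
    """
    preds = []
    for event in events:
        family = event.family
        if family is None:
            continue
        support = {key: 0 for key, _ in _SUPPORT_KEYS}
        origin_of = dict((orig, key) for key, orig in _SUPPORT_KEYS)
        for anchor in event.anchors:
            support[origin_of[anchor.origin]] += 1
        pred = Prediction(
            chrom=event.chrom,
            window=event.window,
            breakpoint=event.breakpoint,
            family=family,
            support_by_origin=support,
            tsd_bp=event.tsd_bp,
            polyA_side=event.polyA_side,
            has_5p=event.has_5p_evidence,
            has_3p=event.has_3p_evidence,
            has_clipped=event.clip5 is not None or event.clip3 is not None,
            events=[event],
        )
        pred.orientation = determine_orientation(pred)
        preds.append(pred)
    return preds


def determine_orientation(pred: Prediction) -> str:
    """polyA on the 3' side -> '+', polyA (seen as polyT) on the 5' side -> '-'."""
    if pred.polyA_side == "3prime":
        return "+"
    if pred.polyA_side == "5prime":
        return "-"
    return "unknown"


# ---------------------------------------------------------------------------
# filters


def filter_support(preds: Iterable[Prediction], cfg: CallerConfig) -> list[Prediction]:
    for pred in preds:
        assert pred.support > 0, "prediction without supporting anchors"
        if pred.support < cfg.min_support:
            pred.flags.add(FLAG_LOW_SUPPORT)
    return list(preds)


@dataclass
class ReferenceMEAnnotation:
    """Reference-genome ME intervals from a BED4 file (name = family)."""

    intervals: dict  # chrom -> sorted list of (start, end, family)

    @classmethod
    def from_bed(cls, path: str) -> "ReferenceMEAnnotation":
        intervals: dict = defaultdict(list)
        with open(path, "rt", encoding="utf-8") as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                family = fields[3] if len(fields) > 3 else "Other"
                if family not in FAMILIES:
                    family = "Other"
                intervals[chrom].append((start, end, family))
        for chrom in intervals:
            intervals[chrom].sort()
        return cls(intervals=dict(intervals))


def _interval_gap(a_start, a_end, b_start, b_end) -> int:
    """Bases strictly between two half-open intervals; 0 when they overlap/abut."""
    if a_start >= b_end:
        return a_start - b_end
    if b_start >= a_end:
        return b_start - a_end
    return 0


def filter_reference_mei(
    preds: Iterable[Prediction], ann: ReferenceMEAnnotation, cfg: CallerConfig
) -> list[Prediction]:
    """Flag predictions within ``reference_mei_filter_window`` bp of a
    same-family annotated reference ME."""
    preds = list(preds)
    for pred in preds:
        ws, we = pred.window
        for start, end, family in ann.intervals.get(pred.chrom, ()):
            if family != pred.family:
                continue
            if _interval_gap(ws, we, start, end) <= cfg.reference_mei_filter_window:
                pred.flags.add(FLAG_REFERENCE_MEI)
                break
    return preds


def load_bed_intervals(path: str) -> dict:
    """chrom -> sorted [(start, end)] from a BED3+ file."""
    intervals: dict = defaultdict(list)
    with open(path, "rt", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals[fields[0]].append((int(fields[1]), int(fields[2])))
    for chrom in intervals:
        intervals[chrom].sort()
    return dict(intervals)


def filter_satellite(
    preds: Iterable[Prediction], satellite: Optional[dict]
) -> list[Prediction]:
    """Flag predictions whose window overlaps a satellite interval."""
    preds = list(preds)
    if not satellite:
        return preds
    for pred in preds:
        ws, we = pred.window
        for start, end in satellite.get(pred.chrom, ()):
            if ws < end and start < we:
                pred.flags.add(FLAG_SATELLITE)
                break
    return preds


def filter_double_cluster(
    preds: Iterable[Prediction], cfg: CallerConfig
) -> list[Prediction]:
    preds = list(preds)
    if not cfg.require_double_cluster:
        return preds
    for pred in preds:
        if not (pred.has_5p and pred.has_3p):
            pred.flags.add(FLAG_SINGLE_CLUSTER)
    return preds


def merge_predictions(
    preds: Iterable[Prediction], cfg: CallerConfig
) -> list[Prediction]:
    """Merge same-family predictions whose windows lie within
    ``prediction_merge_window`` bp (transitive closure)."""
    preds = list(preds)
    by_group: dict = defaultdict(list)
    for pred in preds:
        by_group[(pred.chrom, pred.family)].append(pred)
    merged: list[Prediction] = []
    for (_chrom, _family), members in sorted(by_group.items()):
        members.sort(key=lambda p: p.window)
        components: list[list[Prediction]] = []
        current = [members[0]]
        reach = members[0].window[1]
        for pred in members[1:]:
            if pred.window[0] - reach <= cfg.prediction_merge_window:
                current.append(pred)
            else:
                components.append(current)
                current = [pred]
            reach = max(reach, pred.window[1])
        components.append(current)
        for component in components:
            merged.append(_merge_component(component))
    merged.sort(key=lambda p: (p.chrom, p.window))
    return merged


def _merge_component(component: list) -> Prediction:
    if len(component) == 1:
        return component[0]
    clipped = [p for p in component if p.has_clipped]
    leader = (
        min(clipped, key=lambda p: (-p.support, p.window))
        if clipped
        else max(component, key=lambda p: (p.support, p.window[::-1]))
    )
    support = defaultdict(int)
    for pred in component:
        for key, value in pred.support_by_origin.items():
            support[key] += value
    return Prediction(
        chrom=leader.chrom,
        window=(
            min(p.window[0] for p in component),
            max(p.window[1] for p in component),
        ),
        breakpoint=leader.breakpoint,
        family=leader.family,
        support_by_origin=dict(support),
        tsd_bp=leader.tsd_bp,
        polyA_side=leader.polyA_side,
        orientation=leader.orientation,
        flags=set().union(*(p.flags for p in component)),
        has_5p=any(p.has_5p for p in component),
        has_3p=any(p.has_3p for p in component),
        has_clipped=bool(clipped),
        events=[e for p in component for e in p.events],
    )


# ---------------------------------------------------------------------------
# breakpoint context


def breakpoint_context(pred: Prediction, reference) -> Optional[str]:
    """13 bp of reference sequence around the strand-appropriate clip position.

    For '+' insertions the 3' clipped cluster position is used, for '-'
    insertions the 5' clipped cluster position (6 bases left, the position,
    6 bases right). ``reference`` maps chrom -> sequence string (or any
    object supporting ``[chrom]`` returning a sliceable sequence).
    """
    if pred.orientation == "unknown" or not pred.events:
        return None
    event = pred.events[0]
    cluster = event.clip3 if pred.orientation == "+" else event.clip5
    if cluster is None:
        return None
    pos = cluster.clip_mode_pos
    seq = reference[pred.chrom]
    lo, hi = pos - 6, pos + 7
    chunk = str(seq[max(0, lo) : hi]).upper()
    if lo < 0:
        chunk = "N" * -lo + chunk
    if len(chunk) < 13:
        chunk = chunk + "N" * (13 - len(chunk))
    return chunk


# ---------------------------------------------------------------------------
# gene annotation


@dataclass
class Transcript:
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list  # [(start, end)]

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start


@dataclass
class GeneModel:
    transcripts: list

    @classmethod
    def from_refflat(cls, path: str) -> "GeneModel":
        """Parse refFlat: geneName name chrom strand txStart txEnd cdsStart
        cdsEnd exonCount exonStarts exonEnds."""
        transcripts = []
        with open(path, "rt", encoding="utf-8") as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                starts = [int(x) for x in f[9].rstrip(",").split(",")]
                ends = [int(x) for x in f[10].rstrip(",").split(",")]
                transcripts.append(
                    Transcript(
                        name=f[0],
                        chrom=f[2],
                        strand=f[3],
                        tx_start=int(f[4]),
                        tx_end=int(f[5]),
                        cds_start=int(f[6]),
                        cds_end=int(f[7]),
                        exons=list(zip(starts, ends)),
                    )
                )
        return cls(transcripts=transcripts)


_SPLICE_PAD = 2


def annotate_gene_component(pred: Prediction, genes: GeneModel) -> str:
    """One component label per prediction, by decreasing priority:
    exons/splice sites, ncRNA, UTRs, introns, 1 kb flanks, intergenic."""
    ws, we = pred.window

    def overlaps(start, end):
        return ws < end and start < we

    found = set()
    for tx in genes.transcripts:
        if tx.chrom != pred.chrom:
            continue
        near = overlaps(tx.tx_start - 1000, tx.tx_end + 1000)
        if not near:
            continue
        if overlaps(tx.tx_start, tx.tx_end):
            for es, ee in tx.exons:
                if not overlaps(es, ee):
                    continue
                if not tx.is_coding:
                    found.add("ncRNA_exonic")
                    continue
                cds_lo, cds_hi = max(es, tx.cds_start), min(ee, tx.cds_end)
                if cds_hi > cds_lo and overlaps(cds_lo, cds_hi):
                    found.add("exonic")
                if min(ee, tx.cds_start) > es and overlaps(es, min(ee, tx.cds_start)):
                    found.add("UTR5" if tx.strand == "+" else "UTR3")
                if ee > max(es, tx.cds_end) and overlaps(max(es, tx.cds_end), ee):
                    found.add("UTR3" if tx.strand == "+" else "UTR5")
            for i in range(len(tx.exons) - 1):
                intron = (tx.exons[i][1], tx.exons[i + 1][0])
                if overlaps(*intron):
                    if overlaps(intron[0], intron[0] + _SPLICE_PAD) or overlaps(
                        intron[1] - _SPLICE_PAD, intron[1]
                    ):
                        found.add("splice")
                    found.add("intronic")
        else:
            upstream = (
                (tx.tx_start - 1000, tx.tx_start)
                if tx.strand == "+"
                else (tx.tx_end, tx.tx_end + 1000)
            )
            downstream = (
                (tx.tx_end, tx.tx_end + 1000)
                if tx.strand == "+"
                else (tx.tx_start - 1000, tx.tx_start)
            )
            if overlaps(*upstream):
                found.add("upstream_1kb")
            if overlaps(*downstream):
                found.add("downstream_1kb")
    for component in GENE_COMPONENTS:
        if component in found:
            return component
    return "intergenic"


# ---------------------------------------------------------------------------
# output


def _format_breakpoint(bp: tuple) -> str:
    lo, hi = bp
    return str(lo) if hi == lo + 1 else f"{lo}-{hi}"


def _parse_breakpoint(text: str) -> tuple:
    if "-" in text[1:]:
        lo, hi = text.split("-", 1)
        return (int(lo), int(hi))
    return (int(text), int(text) + 1)


def prediction_to_row(pred: Prediction) -> list:
    return [
        pred.chrom,
        str(pred.window[0]),
        str(pred.window[1]),
        _format_breakpoint(pred.breakpoint),
        pred.family,
        pred.orientation,
        "." if pred.tsd_bp is None else str(pred.tsd_bp),
        str(pred.support),
        str(pred.support_by_origin.get("disc_unique", 0)),
        str(pred.support_by_origin.get("disc_multimapped_mate", 0)),
        str(pred.support_by_origin.get("clipped", 0)),
        str(pred.support_by_origin.get("unmapped_mate", 0)),
        pred.polyA_side,
        ",".join(sorted(pred.flags)) if pred.flags else "PASS",
        pred.gene_component,
    ]


def write_predictions(
    preds: Iterable[Prediction],
    path: str,
    audit_path: Optional[str] = None,
    vcf_path: Optional[str] = None,
    reference_lengths: Optional[dict] = None,
) -> None:
    """Write the default (pass-only) TSV report, plus optional audit TSV and VCF."""
    preds = sorted(preds, key=lambda p: (p.chrom, p.window))
    header = "\t".join(TSV_COLUMNS) + "\n"
    with open(path, "wt", encoding="utf-8") as out:
        out.write(header)
        for pred in preds:
            if pred.passed:
                out.write("\t".join(prediction_to_row(pred)) + "\n")
    if audit_path is not None:
        with open(audit_path, "wt", encoding="utf-8") as out:
            out.write(header)
            for pred in preds:
                out.write("\t".join(prediction_to_row(pred)) + "\n")
    if vcf_path is not None:
        write_vcf(preds, vcf_path, reference_lengths or {})


def read_predictions(path: str) -> list[Prediction]:
    """Parse a prediction TSV back into Prediction objects (round-trip)."""
    preds = []
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        assert tuple(header) == TSV_COLUMNS, "unexpected prediction TSV header"
        for line in handle:
            f = line.rstrip("\n").split("\t")
            preds.append(
                Prediction(
                    chrom=f[0],
                    window=(int(f[1]), int(f[2])),
                    breakpoint=_parse_breakpoint(f[3]),
                    family=f[4],
                    orientation=f[5],
                    tsd_bp=None if f[6] == "." else int(f[6]),
                    support_by_origin={
                        "disc_unique": int(f[8]),
                        "disc_multimapped_mate": int(f[9]),
                        "clipped": int(f[10]),
                        "unmapped_mate": int(f[11]),
                    },
                    polyA_side=f[12],
                    flags=set() if f[13] == "PASS" else set(f[13].split(",")),
                    gene_component=f[14],
                )
            )
    return preds


_VCF_FAMILY = {"Alu": "ALU", "L1": "LINE1", "SVA": "SVA", "HERVK": "HERVK"}


def write_vcf(preds: Iterable[Prediction], path: str, reference_lengths: dict) -> None:
    """Minimal VCF 4.2 with symbolic INS:ME ALT alleles (pass-only)."""
    with open(path, "wt", encoding="utf-8") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        out.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Window end">\n')
        out.write(
            '##INFO=<ID=CIPOS,Number=2,Type=Integer,'
            'Description="Confidence interval around POS">\n'
        )
        out.write(
            '##INFO=<ID=TSD,Number=1,Type=String,'
            'Description="Signed target site duplication length">\n'
        )
        for family, label in _VCF_FAMILY.items():
            out.write(
                f'##ALT=<ID=INS:ME:{label},Description="{family} insertion">\n'
            )
        for chrom, length in sorted(reference_lengths.items()):
            out.write(f"##contig=<ID={chrom},length={length}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, pred in enumerate(sorted(preds, key=lambda p: (p.chrom, p.window))):
            if not pred.passed:
                continue
            pos = pred.window[0] + 1  # 1-based leftmost window coordinate
            info = (
                f"SVTYPE=INS;END={pred.window[1]};"
                f"CIPOS=0,{pred.window[1] - pred.window[0]}"
            )
            if pred.tsd_bp is not None:
                info += f";TSD={pred.tsd_bp}"
            out.write(
                f"{pred.chrom}\t{pos}\tMEI{i}\tN\t"
                f"<INS:ME:{_VCF_FAMILY[pred.family]}>\t.\tPASS\t{info}\n"
            )


def apply_filters(
    preds: list,
    cfg: CallerConfig,
    ref_mei: Optional[ReferenceMEAnnotation] = None,
    satellite: Optional[dict] = None,
) -> list:
    """Run every configured filter; order is immaterial (flags only)."""
    filter_support(preds, cfg)
    if ref_mei is not None:
        filter_reference_mei(preds, ref_mei, cfg)
    filter_satellite(preds, satellite)
    filter_double_cluster(preds, cfg)
    return preds
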