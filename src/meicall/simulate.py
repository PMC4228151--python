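"""Truth-driven simulation of mobile element insertions in short-read data.

Instead of running an external aligner over simulated reads, alignments are
emitted directly from the known donor structure: reads fully inside reference
sequence become proper pairs, reads spanning an insertion junction become
soft-clipped at the true junction, and reads fully inside the inserted
element are emitted as multi-mapped (MAPQ 0, placed at a reference decoy
copy of the same family) or unmapped records with an anchored mate. All
randomness flows from a single integer-seeded generator, so outputs are
deterministic for a given configuration.
"""

from __future__ import annotations

import bisect
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pysam

from .predict import Prediction

CHROM = "chr1"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_FAMILY_LENGTHS = {"Alu": 300, "L1": 1500, "SVA": 1100, "HERVK": 950}

#: duplication sizes 5-20 bp peaked at 13, deletions 1-15 bp peaked at 7,
#: with 93% duplications / 6% deletions / 1% blunt insertions
_DUP_SIZES = np.arange(5, 21)
_DUP_WEIGHTS = 1.0 / (1.0 + np.abs(_DUP_SIZES - 13))
_DEL_SIZES = np.arange(1, 16)
_DEL_WEIGHTS = 1.0 / (1.0 + np.abs(_DEL_SIZES - 7))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _squash_runs(seq: str, rng: np.random.Generator, max_run: int = 5) -> str:
    """Break homopolymer runs longer than ``max_run`` (keeps polyA detection
    honest when the sequence is used as a consensus)."""
    out = list(seq)
    run = 1
    for i in range(1, len(out)):
        if out[i] == out[i - 1]:
            run += 1
            if run > max_run:
                choices = [b for b in "ACGT" if b != out[i]]
                out[i] = choices[int(rng.integers(0, 3))]
                run = 1
        else:
            run = 1
    return "".join(out)


def make_mobilome(
    seed: int = 0, lengths: Optional[dict] = None
) -> list[tuple[str, str]]:
    """Synthetic consensus library: one random sequence per family."""
    rng = np.random.default_rng(seed)
    lengths = dict(DEFAULT_FAMILY_LENGTHS, **(lengths or {}))
    return [
        (f"{family}_consensus", _squash_runs(random_dna(rng, lengths[family]), rng))
        for family in ("Alu", "L1", "SVA", "HERVK")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


@dataclass
class SimConfig:
    seed: int
    genome_length: int = 2_000_000
    n_insertions: int = 100
    coverage: float = 10.0
    read_length: int = 100
    insert_median: int = 400
    insert_sd: int = 30
    base_error_rate: float = 0.001
    mode: str = "paired"
    zygosity: str = "hom"  # hom | het | mixed
    n_decoys: int = 12
    with_satellite: bool = True
    satellite_length: int = 3000
    frac_unmapped_mates: float = 0.2
    min_anchor: int = 20
    min_spacing: int = 2000
    decoy_margin: int = 200
    polyA_range: tuple = (12, 30)
    tsd_choices: Optional[list] = None  # override the default TSD distribution
    family_weights: dict = field(
        default_factory=lambda: {"Alu": 0.6, "L1": 0.25, "SVA": 0.15}
    )
    capture_targets: Optional[list] = None  # [(start, end)] reference intervals

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class TruthRecord:
    """A planted insertion: ``tsd_bp`` > 0 duplicates the ``tsd_bp`` reference
    bases left of the breakpoint, < 0 deletes ``-tsd_bp`` bases right of it."""

    chrom: str
    breakpoint: int
    family: str
    strand: str
    zygosity: str
    tsd_bp: int
    polyA_len: int
    truncation_5p: int = 0
    is_reference_me_decoy: bool = False

    @property
    def left_junction(self) -> int:
        """Reference position where right-clipped (5') reads clip."""
        return self.breakpoint

    @property
    def right_junction(self) -> int:
        """Reference position where left-clipped (3') reads clip."""
        return self.breakpoint - self.tsd_bp

    def insert_sequence(self, consensus: dict) -> str:
        body = consensus[self.family][self.truncation_5p :]
        ins = body + "A" * self.polyA_len
        return revcomp(ins) if self.strand == "-" else ins


@dataclass
class Reference:
    sequence: str
    decoys: list  # [(start, end, family)]
    satellites: list  # [(start, end)]


def make_reference(simcfg: SimConfig, mobilome: list) -> Reference:
    """Random genome with embedded reference-ME decoys and a satellite block."""
    rng = np.random.default_rng(simcfg.seed ^ 0xA5A5)
    consensus = {name.split("_")[0]: seq for name, seq in mobilome}
    genome = list(random_dna(rng, simcfg.genome_length))
    occupied: list[tuple[int, int]] = []
    satellites = []
    if simcfg.with_satellite:
        motif = "ACGGTC"
        sat = (motif * (simcfg.satellite_length // len(motif) + 1))[
            : simcfg.satellite_length
        ]
        pos = int(simcfg.genome_length * 0.45)
        genome[pos : pos + len(sat)] = list(sat)
        occupied.append((pos - simcfg.decoy_margin, pos + len(sat) + simcfg.decoy_margin))
        satellites.append((pos, pos + len(sat)))

    decoys = []
    families = list(consensus)
    attempts = 0
    while len(decoys) < simcfg.n_decoys and attempts < simcfg.n_decoys * 200:
        attempts += 1
        family = families[len(decoys) % len(families)]
        seq = consensus[family]
        if len(seq) + 2 * simcfg.decoy_margin >= simcfg.genome_length:
            raise ValueError("genome_length too small for decoy placement")
        pos = int(rng.integers(simcfg.decoy_margin, simcfg.genome_length - len(seq) - simcfg.decoy_margin))
        span = (pos - simcfg.decoy_margin, pos + len(seq) + simcfg.decoy_margin)
        if any(span[0] < e and s < span[1] for s, e in occupied):
            continue
        genome[pos : pos + len(seq)] = list(seq)
        occupied.append(span)
        decoys.append((pos, pos + len(seq), family))
    if len(decoys) < simcfg.n_decoys:
        raise ValueError("genome_length too small for requested decoys")
    decoys.sort()
    return Reference(sequence="".join(genome), decoys=decoys, satellites=satellites)


def _draw_tsd(rng: np.random.Generator, choices: Optional[list]) -> int:
    if choices is not None:
        return int(choices[int(rng.integers(0, len(choices)))])
    u = rng.random()
    if u < 0.93:
        return int(rng.choice(_DUP_SIZES, p=_DUP_WEIGHTS / _DUP_WEIGHTS.sum()))
    if u < 0.99:
        return -int(rng.choice(_DEL_SIZES, p=_DEL_WEIGHTS / _DEL_WEIGHTS.sum()))
    return 0


def plant_insertions(
    reference: Reference, mobilome: list, simcfg: SimConfig
) -> list[TruthRecord]:
    """Draw insertion sites and structures; sites are kept apart from each
    other, from decoys/satellites, and from the contig ends."""
    rng = np.random.default_rng(simcfg.seed ^ 0x5A5A)
    consensus = {name.split("_")[0]: seq for name, seq in mobilome}
    margin = 2 * simcfg.insert_median + simcfg.read_length
    blocked = [
        (s - simcfg.decoy_margin, e + simcfg.decoy_margin)
        for s, e, *_ in reference.decoys
    ] + [(s - simcfg.decoy_margin, e + simcfg.decoy_margin) for s, e in reference.satellites]
    families = sorted(simcfg.family_weights)
    weights = np.array([simcfg.family_weights[f] for f in families], dtype=float)
    weights /= weights.sum()

    positions: list[int] = []
    attempts = 0
    max_attempts = simcfg.n_insertions * 500
    lo, hi = margin, simcfg.genome_length - margin
    if simcfg.capture_targets:
        candidate_spans = [
            (max(lo, s), min(hi, e)) for s, e in simcfg.capture_targets
        ]
        candidate_spans = [(s, e) for s, e in candidate_spans if e > s]
    else:
        candidate_spans = [(lo, hi)]
    span_weights = np.array([e - s for s, e in candidate_spans], dtype=float)
    span_weights /= span_weights.sum()
    while len(positions) < simcfg.n_insertions and attempts < max_attempts:
        attempts += 1
        si = int(rng.choice(len(candidate_spans), p=span_weights))
        s, e = candidate_spans[si]
        pos = int(rng.integers(s, e))
        if any(abs(pos - p) < simcfg.min_spacing for p in positions):
            continue
        if any(bs < pos < be for bs, be in blocked):
            continue
        positions.append(pos)
    if len(positions) < simcfg.n_insertions:
        raise ValueError(
            "could not place insertions under the spacing constraints; "
            "increase genome_length or reduce n_insertions"
        )
    positions.sort()

    truths = []
    for pos in positions:
        family = families[int(rng.choice(len(families), p=weights))]
        truncation = 0
        if family == "L1" and rng.random() < 0.5:
            truncation = int(rng.integers(0, len(consensus[family]) - 300))
        if simcfg.zygosity == "mixed":
            zygosity = "hom" if rng.random() < 0.5 else "het"
        else:
            zygosity = simcfg.zygosity
        truths.append(
            TruthRecord(
                chrom=CHROM,
                breakpoint=pos,
                family=family,
                strand="+" if rng.random() < 0.5 else "-",
                zygosity=zygosity,
                tsd_bp=_draw_tsd(rng, simcfg.tsd_choices),
                polyA_len=int(rng.integers(*simcfg.polyA_range)),
                truncation_5p=truncation,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# donor construction


@dataclass
class _Segment:
    donor_start: int
    donor_end: int
    kind: str  # 'ref' | 'ins'
    ref_start: int = -1  # ref segments: reference position of donor_start
    truth_index: int = -1  # ins segments


@dataclass
class Donor:
    sequence: str
    segments: list  # sorted by donor_start
    _starts: list = None

    def __post_init__(self):
        self._starts = [s.donor_start for s in self.segments]

    def segment_at(self, donor_pos: int) -> _Segment:
        i = bisect.bisect_right(self._starts, donor_pos) - 1
        return self.segments[i]

    def overlapping(self, a: int, b: int) -> list:
        i = bisect.bisect_right(self._starts, a) - 1
        out = []
        while i < len(self.segments) and self.segments[i].donor_start < b:
            if self.segments[i].donor_end > a:
                out.append(self.segments[i])
            i += 1
        return out


def build_donor(reference: Reference, truths: list, consensus: dict) -> Donor:
    """Haplotype carrying every insertion in ``truths`` (sorted by position)."""
    parts = []
    segments = []
    cursor = 0  # reference position
    donor_pos = 0
    for idx, truth in enumerate(truths):
        b = truth.breakpoint
        chunk = reference.sequence[cursor:b]
        parts.append(chunk)
        segments.append(_Segment(donor_pos, donor_pos + len(chunk), "ref", ref_start=cursor))
        donor_pos += len(chunk)
        ins = truth.insert_sequence(consensus)
        parts.append(ins)
        segments.append(_Segment(donor_pos, donor_pos + len(ins), "ins", truth_index=idx))
        donor_pos += len(ins)
        cursor = b - truth.tsd_bp  # duplicate (tsd>0) or skip (tsd<0) bases
    chunk = reference.sequence[cursor:]
    parts.append(chunk)
    segments.append(_Segment(donor_pos, donor_pos + len(chunk), "ref", ref_start=cursor))
    return Donor(sequence="".join(parts), segments=segments)


# ---------------------------------------------------------------------------
# alignment emission


@dataclass
class _Aln:
    """Planned alignment of one read before record creation."""

    pos: int  # reference position (or mate pos for unmapped)
    mapq: int
    cigar: tuple  # pysam cigartuples; () for unmapped
    unmapped: bool
    fully_ref: bool


def _plan_alignment(
    donor: Donor,
    a: int,
    b: int,
    truths: list,
    decoys_by_family: dict,
    simcfg: SimConfig,
    rng: np.random.Generator,
) -> _Aln:
    segs = donor.overlapping(a, b)
    ref_parts = []
    ins_parts = []
    for seg in segs:
        lo, hi = max(a, seg.donor_start), min(b, seg.donor_end)
        if seg.kind == "ref":
            ref_parts.append((lo, hi, seg.ref_start + (lo - seg.donor_start)))
        else:
            ins_parts.append((lo, hi, seg.truth_index, lo - seg.donor_start))
    length = b - a
    if not ins_parts:
        return _Aln(pos=ref_parts[0][2], mapq=60, cigar=((0, length),), unmapped=False, fully_ref=True)

    lead = ref_parts[0] if ref_parts and ref_parts[0][0] == a else None
    trail = ref_parts[-1] if ref_parts and ref_parts[-1][1] == b else None
    lead_len = lead[1] - lead[0] if lead else 0
    trail_len = trail[1] - trail[0] if trail else 0
    anchor_len = max(lead_len, trail_len)
    if anchor_len >= simcfg.min_anchor:
        if lead_len >= trail_len:
            return _Aln(
                pos=lead[2],
                mapq=60,
                cigar=((0, lead_len), (4, length - lead_len)),
                unmapped=False,
                fully_ref=False,
            )
        return _Aln(
            pos=trail[2],
            mapq=60,
            cigar=((4, length - trail_len), (0, trail_len)),
            unmapped=False,
            fully_ref=False,
        )
    # read effectively inside the inserted element
    truth = truths[ins_parts[0][2]]
    decoys = decoys_by_family.get(truth.family)
    if decoys and rng.random() >= simcfg.frac_unmapped_mates:
        dstart, dend, _fam = decoys[int(rng.integers(0, len(decoys)))]
        offset = min(ins_parts[0][3], max(0, (dend - dstart) - length))
        return _Aln(pos=dstart + offset, mapq=0, cigar=((0, length),), unmapped=False, fully_ref=False)
    return _Aln(pos=-1, mapq=0, cigar=(), unmapped=True, fully_ref=False)


def _apply_errors(seq: str, k: int, rng: np.random.Generator) -> str:
    if k <= 0:
        return seq
    out = list(seq)
    positions = rng.choice(len(seq), size=min(k, len(seq)), replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def emit_alignments(
    reference: Reference,
    truths: list,
    mobilome: list,
    simcfg: SimConfig,
    bam_path: str,
    fastq_path: Optional[str] = None,
) -> str:
    """Sample reads from the donor haplotypes and write a sorted, indexed BAM.

    Returns the path of the sorted BAM. When ``fastq_path`` is given an
    interleaved FASTQ of the raw reads is written as well.
    """
    rng = np.random.default_rng(simcfg.seed)
    consensus = {name.split("_")[0]: seq for name, seq in mobilome}
    decoys_by_family: dict = {}
    for s, e, fam in reference.decoys:
        decoys_by_family.setdefault(fam, []).append((s, e, fam))

    hap_a = build_donor(reference, truths, consensus)
    hom_truths = [t for t in truths if t.zygosity == "hom"]
    hap_b = build_donor(reference, hom_truths, consensus)
    # hap_b segments index hom_truths; remap to global truth indices
    hom_index = {id(t): i for i, t in enumerate(truths)}
    for seg in hap_b.segments:
        if seg.kind == "ins":
            seg.truth_index = hom_index[id(hom_truths[seg.truth_index])]

    rl = simcfg.read_length
    header = {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": CHROM, "LN": len(reference.sequence)}]}
    tmp_path = bam_path + ".unsorted.bam"
    fastq = open(fastq_path, "wt", encoding="utf-8") if fastq_path else None
    qual_array = pysam.qualitystring_to_array("I" * rl)  # phred 40

    # donor target spans for exome-style capture (fragments must overlap one)
    def _donor_spans(donor: Donor):
        if not simcfg.capture_targets:
            return [(0, len(donor.sequence))]
        spans = []
        for seg in donor.segments:
            if seg.kind != "ref":
                continue
            for ts, te in simcfg.capture_targets:
                lo = max(seg.ref_start, ts)
                hi = min(seg.ref_start + (seg.donor_end - seg.donor_start), te)
                if hi > lo:
                    spans.append(
                        (seg.donor_start + lo - seg.ref_start, seg.donor_start + hi - seg.ref_start)
                    )
        return sorted(spans)

    with pysam.AlignmentFile(tmp_path, "wb", header=header) as out:
        read_serial = 0
        for hap_id, donor in (("A", hap_a), ("B", hap_b)):
            L = len(donor.sequence)
            spans = _donor_spans(donor)
            span_w = np.array([e - s for s, e in spans], dtype=float)
            span_w /= span_w.sum()
            n_frags = int(round(simcfg.coverage / 2 * L / (2 * rl)))
            frag_lens = np.maximum(
                rng.normal(simcfg.insert_median, simcfg.insert_sd, size=n_frags).round().astype(int),
                2 * rl + 2,
            )
            span_idx = rng.choice(len(spans), size=n_frags, p=span_w)
            start_u = rng.random(size=n_frags)
            r1_is_left = rng.random(size=n_frags) < 0.5
            err_counts = rng.binomial(rl, simcfg.base_error_rate, size=(n_frags, 2))
            for i in range(n_frags):
                flen = int(frag_lens[i])
                s_lo, s_hi = spans[span_idx[i]]
                lo = max(0, s_lo - flen + 1)
                hi = min(L - flen, s_hi - 1)
                if hi <= lo:
                    continue
                start = lo + int(start_u[i] * (hi - lo))
                end = start + flen
                read_serial += 1
                name = f"sim{hap_id}{read_serial}"
                # both kept in reference-forward orientation (BAM convention);
                # the FASTQ re-complements the reverse read below
                left_seq = _apply_errors(donor.sequence[start : start + rl], int(err_counts[i, 0]), rng)
                right_seq = _apply_errors(donor.sequence[end - rl : end], int(err_counts[i, 1]), rng)
                aln_l = _plan_alignment(donor, start, start + rl, truths, decoys_by_family, simcfg, rng)
                aln_r = _plan_alignment(donor, end - rl, end, truths, decoys_by_family, simcfg, rng)
                _write_pair(
                    out,
                    name,
                    left_seq,
                    right_seq,
                    aln_l,
                    aln_r,
                    bool(r1_is_left[i]),
                    qual_array,
                    simcfg,
                )
                if fastq is not None:
                    sequenced_right = revcomp(right_seq)
                    r1_seq, r2_seq = (
                        (left_seq, sequenced_right)
                        if r1_is_left[i]
                        else (sequenced_right, left_seq)
                    )
                    fastq.write(f"@{name}/1\n{r1_seq}\n+\n{'I' * rl}\n")
                    fastq.write(f"@{name}/2\n{r2_seq}\n+\n{'I' * rl}\n")
    if fastq is not None:
        fastq.close()
    pysam.sort("-o", bam_path, tmp_path)
    os.unlink(tmp_path)
    pysam.index(bam_path)
    return bam_path


def _write_pair(out, name, left_seq, right_seq, aln_l, aln_r, r1_is_left, quals, simcfg):
    rl = simcfg.read_length
    both_mapped = not aln_l.unmapped and not aln_r.unmapped
    if aln_l.unmapped and aln_r.unmapped:
        return  # neither end anchors anything; drop the pair entirely
    # reference-aligned span ends for tlen
    def _alen(aln):
        return sum(ln for op, ln in aln.cigar if op == 0)

    tlen = 0
    proper = False
    if both_mapped:
        left_end = aln_l.pos + _alen(aln_l)
        right_end = aln_r.pos + _alen(aln_r)
        lo = min(aln_l.pos, aln_r.pos)
        hi = max(left_end, right_end)
        tlen = hi - lo
        proper = (
            aln_l.fully_ref
            and aln_r.fully_ref
            and aln_l.pos <= aln_r.pos
            and tlen <= simcfg.insert_median + simcfg.insert_sd * 6
        )

    for is_left, seq, aln, mate in (
        (True, left_seq, aln_l, aln_r),
        (False, right_seq, aln_r, aln_l),
    ):
        rec = pysam.AlignedSegment()
        rec.query_name = name
        rec.query_sequence = seq
        rec.query_qualities = quals
        rec.is_paired = True
        rec.is_read1 = is_left == r1_is_left
        rec.is_read2 = not rec.is_read1
        rec.is_reverse = not is_left and not aln.unmapped
        rec.is_proper_pair = proper
        if aln.unmapped:
            rec.is_unmapped = True
            rec.reference_id = 0
            rec.reference_start = mate.pos
            rec.mapping_quality = 0
        else:
            rec.reference_id = 0
            rec.reference_start = aln.pos
            rec.mapping_quality = aln.mapq
            rec.cigartuples = aln.cigar
        if mate.unmapped:
            rec.mate_is_unmapped = True
            rec.next_reference_id = 0
            rec.next_reference_start = aln.pos if not aln.unmapped else 0
        else:
            rec.next_reference_id = 0
            rec.next_reference_start = mate.pos
            rec.mate_is_reverse = is_left  # mate of the left read is reversed
        if both_mapped:
            if aln.pos <= mate.pos:
                rec.template_length = tlen
            else:
                rec.template_length = -tlen
        out.write(rec)


# ---------------------------------------------------------------------------
# truth I/O and evaluation


TRUTH_COLUMNS = (
    "chrom",
    "breakpoint",
    "family",
    "strand",
    "zygosity",
    "tsd_bp",
    "polyA_len",
    "truncation_5p",
)


def write_truth(truths: Iterable[TruthRecord], path: str) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        out.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            out.write(
                f"{t.chrom}\t{t.breakpoint}\t{t.family}\t{t.strand}\t{t.zygosity}\t"
                f"{t.tsd_bp}\t{t.polyA_len}\t{t.truncation_5p}\n"
            )


def read_truth(path: str) -> list[TruthRecord]:
    truths = []
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        assert tuple(header) == TRUTH_COLUMNS, "unexpected truth TSV header"
        for line in handle:
            f = line.rstrip("\n").split("\t")
            truths.append(
                TruthRecord(
                    chrom=f[0],
                    breakpoint=int(f[1]),
                    family=f[2],
                    strand=f[3],
                    zygosity=f[4],
                    tsd_bp=int(f[5]),
                    polyA_len=int(f[6]),
                    truncation_5p=int(f[7]),
                )
            )
    return truths


@dataclass
class Evaluation:
    sensitivity: float
    ppv: Optional[float]  # None when there are no predictions
    n_truth: int
    n_predictions: int
    n_detected: int
    n_matched_predictions: int
    matches: list  # [(prediction index, truth index)]


def _pred_truth_distance(pred: Prediction, truth: TruthRecord) -> int:
    ws, we = pred.window
    b = truth.breakpoint
    if ws <= b < we:
        return 0
    return ws - b if b < ws else b - we + 1


def evaluate(
    preds: list, truths: list, window: int = 50, family_match: bool = True
) -> Evaluation:
    """Match pass predictions to planted truths within ``window`` bp.

    Each prediction matches at most one truth record (the nearest); a truth
    record is detected when at least one same-family prediction matches it.
    """
    passing = [p for p in preds if p.passed]
    matches = []
    detected: set = set()
    matched_preds = 0
    for pi, pred in enumerate(passing):
        best = None
        for ti, truth in enumerate(truths):
            if pred.chrom != truth.chrom:
                continue
            if family_match and pred.family != truth.family:
                continue
            dist = _pred_truth_distance(pred, truth)
            if dist <= window and (best is None or dist < best[0]):
                best = (dist, ti)
        if best is not None:
            matched_preds += 1
            detected.add(best[1])
            matches.append((pi, best[1]))
    return Evaluation(
        sensitivity=len(detected) / len(truths) if truths else 0.0,
        ppv=(matched_preds / len(passing)) if passing else None,
        n_truth=len(truths),
        n_predictions=len(passing),
        n_detected=len(detected),
        n_matched_predictions=matched_preds,
        matches=matches,
    )


def write_bed(intervals: Iterable[tuple], path: str, chrom: str = CHROM) -> None:
    """BED of (start, end[, name]) tuples on the simulated contig."""
    with open(path, "wt", encoding="utf-8") as out:
        for item in intervals:
            if len(item) >= 3:
                out.write(f"{chrom}\t{item[0]}\t{item[1]}\t{item[2]}\n")
            else:
                out.write(f"{chrom}\t{item[0]}\t{item[1]}\n")
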