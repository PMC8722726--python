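"""Fusion-allele construction, transcript splicing, and breakpoint inference.

Breakpoints live in gene-local sense coordinates: ``breakpoint_a`` is the
last retained base of gene A's sense sequence (0-based) and ``breakpoint_b``
the first retained base of gene B's.  The modeled class is intronic
breakpoints only; the mature fusion transcript joins annotated exon
boundaries.

When the two parental sequences share bases across the junction the placement
is ambiguous; the canonical placement assigns the shared bases to gene A and
the ambiguity span is reported as microhomology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .errors import FusionError
from .genome_model import GeneModel, GenomeSequence

DEFAULT_ANCHOR = 20
DEFAULT_MISMATCH_RATE = 0.01
# an anchor extension only counts if its terminal bases match exactly, so the
# mismatch budget absorbs isolated internal sequencing errors but cannot push
# the extension tip across the junction (single-base placement demands exact
# agreement near the junction; 15 clean bases make a chance overshoot ~4^-15)
TIP_EXACT = 15


@dataclass(frozen=True)
class FusionEvent:
    """Intronic breakpoints in two genes plus junction micro-features.

    ``insertion`` (untemplated junction bases) and microhomology are mutually
    exclusive by convention.
    """

    event_id: str
    gene_a_id: str
    gene_b_id: str
    breakpoint_a: int
    breakpoint_b: int
    insertion: str = ""
    microhomology_length: int = 0

    def __post_init__(self) -> None:
        if self.breakpoint_a < 0 or self.breakpoint_b < 0:
            raise FusionError("breakpoints must be non-negative")
        if self.insertion and self.microhomology_length:
            raise FusionError(
                "insertion and microhomology are mutually exclusive"
            )


@dataclass(frozen=True)
class FusionAllele:
    """The rearranged allele with its lifted exon annotation.

    Exon coordinates are 0-based half-open on ``sequence``; ``new_intron`` is
    the interval between the last retained A exon and the first retained B
    exon.
    """

    event: FusionEvent
    sequence: str
    retained_exons_a: tuple[tuple[int, int, int], ...]  # (exon_number, start, end)
    retained_exons_b: tuple[tuple[int, int, int], ...]
    new_intron: tuple[int, int]


@dataclass(frozen=True)
class FusionTranscript:
    """Spliced mature mRNA of the fusion allele.

    ``exon_list`` holds (gene_id, exon_number, start, end) on the mature
    sequence; ``junction`` is (last A exon number, first B exon number).
    """

    exon_list: tuple[tuple[str, int, int, int], ...]
    junction: tuple[int, int]
    mature_sequence: str


def _intron_index_containing(gene: GeneModel, pos: int) -> int:
    """1-based intron index containing local sense position ``pos``."""
    for k, (i1, i2) in enumerate(gene.intron_local_intervals(), start=1):
        if i1 <= pos < i2:
            return k
    raise FusionError(
        f"gene {gene.gene_id}: position {pos} is not intronic "
        "(exonic breakpoints are outside the modeled class)"
    )


def make_fusion_allele(
    genome: dict[str, GenomeSequence],
    gene_a: GeneModel,
    gene_b: GeneModel,
    event: FusionEvent,
) -> FusionAllele:
    """Build the rearranged allele sequence and lift the retained exons.

    sequence = senseA[0..breakpoint_a] + insertion + senseB[breakpoint_b..];
    exons truncated by a breakpoint are never retained (enforced by requiring
    intronic breakpoints).
    """
    if set(event.insertion) - set("ACGT"):
        raise FusionError(f"invalid insertion {event.insertion!r}")
    sense_a = gene_a.sense_sequence(genome[gene_a.contig_id])
    sense_b = gene_b.sense_sequence(genome[gene_b.contig_id])
    if event.breakpoint_a >= len(sense_a) or event.breakpoint_b >= len(sense_b):
        raise FusionError("breakpoint outside gene span")
    ka = _intron_index_containing(gene_a, event.breakpoint_a)
    kb = _intron_index_containing(gene_b, event.breakpoint_b)

    prefix = sense_a[: event.breakpoint_a + 1]
    suffix = sense_b[event.breakpoint_b :]
    sequence = prefix + event.insertion + suffix

    exons_a = gene_a.exon_local_intervals()[:ka]
    retained_a = tuple((n + 1, s, e) for n, (s, e) in enumerate(exons_a))
    shift = len(prefix) + len(event.insertion) - event.breakpoint_b
    exons_b = gene_b.exon_local_intervals()[kb:]
    retained_b = tuple(
        (kb + 1 + n, s + shift, e + shift) for n, (s, e) in enumerate(exons_b)
    )
    new_intron = (retained_a[-1][2], retained_b[0][1])
    return FusionAllele(
        event=event,
        sequence=sequence,
        retained_exons_a=retained_a,
        retained_exons_b=retained_b,
        new_intron=new_intron,
    )


def splice_fusion_transcript(allele: FusionAllele) -> FusionTranscript:
    """Remove all introns (native and new) from the fusion allele."""
    if not allele.retained_exons_a or not allele.retained_exons_b:
        raise FusionError("no retained exon on one side of the junction")
    pieces: list[tuple[str, int, int, int]] = []
    mature = []
    offset = 0
    for gene_id, exons in (
        (allele.event.gene_a_id, allele.retained_exons_a),
        (allele.event.gene_b_id, allele.retained_exons_b),
    ):
        for number, s, e in exons:
            mature.append(allele.sequence[s:e])
            pieces.append((gene_id, number, offset, offset + (e - s)))
            offset += e - s
    junction = (allele.retained_exons_a[-1][0], allele.retained_exons_b[0][0])
    return FusionTranscript(
        exon_list=tuple(pieces),
        junction=junction,
        mature_sequence="".join(mature),
    )


# ---------------------------------------------------------------------------
# breakpoint inference


@dataclass(frozen=True)
class BreakpointCall:
    """Result of junction-read inference.

    ``mappable`` is False when no split with sufficient anchors exists (this
    is a result, not an exception).  ``matched_a``/``matched_b`` are the
    anchor lengths supporting the call.
    """

    event: FusionEvent | None
    mappable: bool
    low_confidence: bool = False
    pos_a: int = -1  # start of the read's A anchor in sense_a
    pos_b: int = -1  # start of the read's B anchor in sense_b
    matched_a: int = 0
    matched_b: int = 0


def _allowed(length: int, rate: float) -> int:
    return int(length * rate)


def _seed_hits(seed: str, seq: str, max_mm: int) -> list[int]:
    k = len(seed)
    if max_mm == 0:
        hits, start = [], 0
        while True:
            idx = seq.find(seed, start)
            if idx < 0:
                return hits
            hits.append(idx)
            start = idx + 1
    hits = []
    for i in range(len(seq) - k + 1):
        mm = sum(1 for a, b in zip(seed, seq[i : i + k]) if a != b)
        if mm <= max_mm:
            hits.append(i)
    return hits


def _prefix_extension(read: str, seq: str, pa: int, rate: float) -> int:
    """Longest i with read[:i] aligning at seq[pa:] within the mismatch budget.

    The last ``TIP_EXACT`` bases of the reported extension must match exactly.
    """
    best = 0
    mm = 0
    run = 0  # current run of consecutive matches
    limit = min(len(read), len(seq) - pa)
    for i in range(limit):
        if read[i] != seq[pa + i]:
            mm += 1
            run = 0
        else:
            run += 1
        if mm <= _allowed(i + 1, rate) and run >= min(i + 1, TIP_EXACT):
            best = i + 1
    return best


def _suffix_extension(read: str, seq: str, q_end: int, rate: float) -> int:
    """Longest L with read[-L:] aligning to seq ending at q_end (tip-exact)."""
    best = 0
    mm = 0
    run = 0
    limit = min(len(read), q_end)
    for t in range(limit):
        if read[len(read) - 1 - t] != seq[q_end - 1 - t]:
            mm += 1
            run = 0
        else:
            run += 1
        if mm <= _allowed(t + 1, rate) and run >= min(t + 1, TIP_EXACT):
            best = t + 1
    return best


def infer_breakpoint(
    junction_read: str,
    sense_a: str,
    sense_b: str,
    k: int = DEFAULT_ANCHOR,
    mismatch_rate: float = DEFAULT_MISMATCH_RATE,
    event_id: str = "inferred",
    gene_a_id: str = "gene_a",
    gene_b_id: str = "gene_b",
) -> BreakpointCall:
    """Infer a fusion event from one junction-spanning read.

    Chooses the split maximizing matched bases as (prefix in A) + (suffix in
    B).  An unaligned middle is classified as untemplated insertion; if the
    two alignments overlap on the read, the overlap is microhomology and the
    shared bases are assigned to gene A.  Ties go to the leftmost A position.
    Anchors tolerate ``mismatch_rate`` mismatches per base (floor), which
    accommodates Sanger-quality reads.
    """
    read = junction_read.upper()
    m = len(read)
    if m < 2 * k:
        return BreakpointCall(event=None, mappable=False)
    seed_mm = _allowed(k, mismatch_rate)
    pa_hits = _seed_hits(read[:k], sense_a, seed_mm)
    qe_hits = [q + k for q in _seed_hits(read[-k:], sense_b, seed_mm)]
    best = None  # (total, pa, q_end, P, S)
    for pa in pa_hits:
        P = _prefix_extension(read, sense_a, pa, mismatch_rate)
        if P < k:
            continue
        for q_end in qe_hits:
            L = _suffix_extension(read, sense_b, q_end, mismatch_rate)
            if L < k:
                continue
            S = m - L
            total = P + L if S >= P else m  # overlapping anchors cover the read
            key = (-total, pa, q_end)
            if best is None or key < best[0]:
                best = (key, pa, q_end, P, S)
    if best is None:
        return BreakpointCall(event=None, mappable=False)
    _, pa, q_end, P, S = best
    pb_start = q_end - (m - S)  # B position of read[S]
    if S <= P:  # overlap: microhomology, shared bases assigned to A
        split = P
        bp_a = pa + P - 1
        bp_b = pb_start + (P - S)
        insertion = ""
        mh = P - S
    else:
        split = P
        bp_a = pa + P - 1
        bp_b = pb_start
        insertion = read[P:S]
        mh = 0
    event = FusionEvent(
        event_id=event_id,
        gene_a_id=gene_a_id,
        gene_b_id=gene_b_id,
        breakpoint_a=bp_a,
        breakpoint_b=bp_b,
        insertion=insertion,
        microhomology_length=mh,
    )
    return BreakpointCall(
        event=event,
        mappable=True,
        low_confidence=min(P, m - S) < k,
        pos_a=pa,
        pos_b=pb_start,
        matched_a=split,
        matched_b=m - max(S, P),
    )


def microhomology_at(event: FusionEvent, sense_a: str, sense_b: str) -> int:
    """Span over which the junction placement is ambiguous.

    Counts identical flanking bases on both sides of the junction: shifting
    the breakpoint pair left while ``A[bp_a+1-t] == B[bp_b-t]`` and right
    while ``A[bp_a+1+t] == B[bp_b+t]`` leaves the allele unchanged.  Events
    with an untemplated insertion have no shift ambiguity (0).
    """
    if event.insertion:
        return 0
    a, b = event.breakpoint_a, event.breakpoint_b
    left = 0
    while a - left >= 0 and b - 1 - left >= 0 and sense_a[a - left] == sense_b[b - 1 - left]:
        left += 1
    right = 0
    while (
        a + 1 + right < len(sense_a)
        and b + right < len(sense_b)
        and sense_a[a + 1 + right] == sense_b[b + right]
    ):
        right += 1
    return left + right


def canonicalize_event(event: FusionEvent, sense_a: str, sense_b: str) -> FusionEvent:
    """Rewrite an event into canonical form (same allele sequence).

    Junction bases that match the continuation of gene A are absorbed into
    the A side; insertion bases matching the tail of gene B are absorbed into
    the B side; remaining shift ambiguity is recorded as microhomology.
    """
    bp_a, bp_b, ins = event.breakpoint_a, event.breakpoint_b, event.insertion
    while ins and bp_a + 1 < len(sense_a) and sense_a[bp_a + 1] == ins[0]:
        bp_a += 1
        ins = ins[1:]
    while ins and bp_b > 0 and sense_b[bp_b - 1] == ins[-1]:
        bp_b -= 1
        ins = ins[:-1]
    mh = 0
    if not ins:
        while (
            bp_a + 1 < len(sense_a)
            and bp_b < len(sense_b)
            and sense_a[bp_a + 1] == sense_b[bp_b]
        ):
            bp_a += 1
            bp_b += 1
        left = 0
        while (
            bp_a - left >= 0
            and bp_b - 1 - left >= 0
            and sense_a[bp_a - left] == sense_b[bp_b - 1 - left]
        ):
            left += 1
        mh = left
    return replace(
        event,
        breakpoint_a=bp_a,
        breakpoint_b=bp_b,
        insertion=ins,
        microhomology_length=mh,
    )


# ---------------------------------------------------------------------------
# serialization


def event_report(event: FusionEvent, gene_a: GeneModel, gene_b: GeneModel) -> dict:
    """1-based single-coordinate report of an event (hg38 print style).

    The reported coordinate is the genomic position of the last retained base
    of A / first retained base of B (parameterizable upstream if the opposite
    convention is wanted).
    """
    ga = gene_a.local_to_genomic_pos(event.breakpoint_a)
    gb = gene_b.local_to_genomic_pos(event.breakpoint_b)
    return {
        "event_id": event.event_id,
        "gene_a": event.gene_a_id,
        "gene_b": event.gene_b_id,
        "breakpoint_a": f"{gene_a.contig_id}:{ga + 1}",
        "breakpoint_b": f"{gene_b.contig_id}:{gb + 1}",
        "insertion": event.insertion,
        "microhomology_length": event.microhomology_length,
    }


def events_to_json(events: list[FusionEvent]) -> str:
    return json.dumps([e.__dict__ for e in events], indent=2) + "\n"


def events_from_json(text: str) -> list[FusionEvent]:
    return [FusionEvent(**d) for d in json.loads(text)]


def events_to_bedpe(
    events: list[FusionEvent], gene_a: GeneModel, gene_b: GeneModel
) -> str:
    """BEDPE-style TSV: the two junction loci plus an insertion column."""
    lines = []
    for e in events:
        ga = gene_a.local_to_genomic_pos(e.breakpoint_a)
        gb = gene_b.local_to_genomic_pos(e.breakpoint_b)
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    gene_a.contig_id, ga, ga + 1,
                    gene_b.contig_id, gb, gb + 1,
                    e.event_id, 0, gene_a.strand, gene_b.strand,
                    e.insertion or ".", e.microhomology_length,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def allele_to_gff3(allele: FusionAllele, contig_id: str) -> str:
    """GFF3 of the lifted features on the fused allele sequence."""
    ev = allele.event
    rows = [f"##gff-version 3"]

    def row(kind: str, s: int, e: int, attr: str) -> str:
        return "\t".join(
            [contig_id, "stemfuse", kind, str(s + 1), str(e), ".", "+", ".", attr]
        )

    for num, s, e in allele.retained_exons_a:
        rows.append(row("exon", s, e, f"ID={ev.gene_a_id}.exon{num};gene={ev.gene_a_id}"))
    rows.append(row("intron", *allele.new_intron, f"ID=new_intron;note=junction intron"))
    for num, s, e in allele.retained_exons_b:
        rows.append(row("exon", s, e, f"ID={ev.gene_b_id}.exon{num};gene={ev.gene_b_id}"))
    return "\n".join(rows) + "\n"
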