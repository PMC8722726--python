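"""Discovery of imperfect complementary stems between two genes' introns.

A "stem" is a local alignment between the sense strand of an intron of gene A
and the reverse complement of the sense strand of an intron of gene B — i.e.
a window where the two sense strands could base-pair with each other.  The
search is run per intron pair so every reported stem is intronic by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import StemfuseError
from .genome_model import GeneModel, GenomeSequence, Interval, introns_of, revcomp, sense_sequence

logger = logging.getLogger(__name__)

_PAIR = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class StemParams:
    """Scoring and filtering parameters for the stem search.

    Gap convention: a gap of length k costs ``gap_open + k * gap_extend``
    (penalties are stored as positive numbers).  Defaults mirror common
    nucleotide-BLAST settings.
    """

    match_score: int = 2
    mismatch_penalty: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    min_length: int = 20
    min_identity: float = 0.7
    max_results: int = 20

    def __post_init__(self) -> None:
        if self.min_length < 8:
            raise StemfuseError("min_length must be >= 8")
        if not 0 < self.min_identity <= 1:
            raise StemfuseError("min_identity must be in (0, 1]")
        if self.max_results < 1:
            raise StemfuseError("max_results must be >= 1")


@dataclass(frozen=True)
class GenomicStem:
    """An imperfect pairing between sense-strand intronic windows of two genes.

    ``pairing`` lists aligned columns as (A sense base, B sense base, paired)
    where the B base is read 3'→5' so that paired columns are Watson–Crick
    complements; '-' marks a gap.
    """

    gene_a_id: str
    gene_b_id: str
    intron_a: int  # 1-based intron index within gene A
    intron_b: int
    window_a: Interval
    window_b: Interval
    aligned_length: int
    identity: float
    score: int
    pairing: tuple[tuple[str, str, bool], ...] = field(repr=False)

    def swapped(self) -> "GenomicStem":
        """The same stem viewed from gene B's side."""
        return GenomicStem(
            gene_a_id=self.gene_b_id,
            gene_b_id=self.gene_a_id,
            intron_a=self.intron_b,
            intron_b=self.intron_a,
            window_a=self.window_b,
            window_b=self.window_a,
            aligned_length=self.aligned_length,
            identity=self.identity,
            score=self.score,
            pairing=tuple((b, a, m) for a, b, m in self.pairing[::-1]),
        )

    def render(self) -> str:
        """Three-line text rendering of the stem pairing."""
        top = "".join(a for a, _, _ in self.pairing)
        mid = "".join("|" if m else " " for _, _, m in self.pairing)
        bot = "".join(b for _, b, _ in self.pairing)
        return f"A 5'-{top}-3'\n     {mid}\nB 3'-{bot}-5'"


def _make_aligner(params: StemParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            matrix[x, y] = params.match_score if x == y else -params.mismatch_penalty
    # N never participates in an alignment (mask / ambiguity)
    for x in "ACGTN":
        matrix[x, "N"] = -1000
        matrix["N", x] = -1000
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _alignment_columns(aln, seq_a: str, seq_b: str):
    """Walk an alignment into per-column (a_char, b_char) with '-' for gaps."""
    a_segs, b_segs = aln.aligned
    cols: list[tuple[str, str]] = []
    prev_a, prev_b = a_segs[0][0], b_segs[0][0]
    for (a0, a1), (b0, b1) in zip(a_segs, b_segs):
        for i in range(prev_a, a0):  # gap in B
            cols.append((seq_a[i], "-"))
        for j in range(prev_b, b0):  # gap in A
            cols.append(("-", seq_b[j]))
        for i, j in zip(range(a0, a1), range(b0, b1)):
            cols.append((seq_a[i], seq_b[j]))
        prev_a, prev_b = a1, b1
    a_span = (int(a_segs[0][0]), int(a_segs[-1][1]))
    b_span = (int(b_segs[0][0]), int(b_segs[-1][1]))
    return cols, a_span, b_span


def _offset_window_to_genomic(intron: Interval, o1: int, o2: int) -> Interval:
    """Map a sense-offset window within an intron to genomic coordinates."""
    if intron.strand == "+":
        return Interval(intron.contig_id, intron.start + o1, intron.start + o2, "+")
    return Interval(intron.contig_id, intron.end - o2, intron.end - o1, "-")


def _score_floor(params: StemParams) -> int:
    # the smallest ungapped score a threshold-passing stem can have
    floor = params.min_length * (
        params.min_identity * params.match_score
        - (1 - params.min_identity) * params.mismatch_penalty
    )
    return max(1, int(floor))


def find_stems(
    gene_a: GeneModel,
    gene_b: GeneModel,
    genome: dict[str, GenomeSequence],
    params: StemParams | None = None,
) -> list[GenomicStem]:
    """Rank complementary stems between introns of two genes.

    Equivalent to local alignment of each A-intron sense sequence against the
    reverse complement of each B-intron sense sequence.  Results are sorted by
    score (descending), then by A and B genomic coordinates; stems whose A- or
    B-window overlaps a higher-scoring stem's window by more than 50% are
    suppressed; at most ``max_results`` are returned.
    """
    params = params or StemParams()
    introns_a = introns_of(gene_a)
    introns_b = introns_of(gene_b)
    if not introns_a or not introns_b:
        logger.warning(
            "no introns in %s and/or %s; no stems possible",
            gene_a.gene_id,
            gene_b.gene_id,
        )
        return []

    aligner = _make_aligner(params)
    floor = _score_floor(params)
    raw: list[GenomicStem] = []
    for ia, intron_a in enumerate(introns_a, start=1):
        seq_a = sense_sequence(intron_a, genome[intron_a.contig_id])
        for ib, intron_b in enumerate(introns_b, start=1):
            seq_b = sense_sequence(intron_b, genome[intron_b.contig_id])
            raw.extend(
                _stems_for_intron_pair(
                    aligner, params, floor, gene_a, gene_b, ia, ib,
                    intron_a, intron_b, seq_a, seq_b,
                )
            )

    raw.sort(key=_stem_sort_key)
    kept: list[GenomicStem] = []
    for stem in raw:
        if any(_redundant(stem, k) for k in kept):
            continue
        kept.append(stem)
        if len(kept) >= params.max_results:
            break
    return kept


def _stem_sort_key(s: GenomicStem):
    return (-s.score, s.window_a.start, s.window_b.start)


def _redundant(stem: GenomicStem, kept: GenomicStem) -> bool:
    for w, kw in ((stem.window_a, kept.window_a), (stem.window_b, kept.window_b)):
        if w.overlap_length(kw) * 2 > w.length:
            return True
    return False


def _stems_for_intron_pair(
    aligner, params, floor, gene_a, gene_b, ia, ib, intron_a, intron_b, seq_a, seq_b
) -> list[GenomicStem]:
    rc_b = revcomp(seq_b)
    len_b = len(seq_b)
    work_a = seq_a
    stems: list[GenomicStem] = []
    consecutive_rejects = 0
    # iterative extraction with masking; scores are non-increasing
    for _ in range(params.max_results * 4):
        try:
            alns = aligner.align(work_a, rc_b)
            score = alns.score
        except Exception:
            break
        if score < floor:
            break
        aln = alns[0]
        cols, (a_lo, a_hi), (b_lo, b_hi) = _alignment_columns(aln, work_a, rc_b)
        work_a = work_a[:a_lo] + "N" * (a_hi - a_lo) + work_a[a_hi:]
        matches = sum(1 for a, b in cols if a != "-" and a == b)
        aligned_length = len(cols)
        identity = matches / aligned_length
        if aligned_length < params.min_length or identity < params.min_identity:
            # once only short/weak chance alignments remain, stop probing
            consecutive_rejects += 1
            if consecutive_rejects >= 3:
                break
            continue
        consecutive_rejects = 0
        window_a = _offset_window_to_genomic(intron_a, a_lo, a_hi)
        # rc_b window [b_lo, b_hi) maps to sense-B window [len_b-b_hi, len_b-b_lo)
        window_b = _offset_window_to_genomic(intron_b, len_b - b_hi, len_b - b_lo)
        # pairing columns: B char in rc space is the complement of the sense
        # base; store the sense base (read 3'→5' along the alignment)
        pairing = tuple(
            (a, _PAIR.get(b, "-") if b != "-" else "-", a != "-" and a == b)
            for a, b in cols
        )
        stems.append(
            GenomicStem(
                gene_a_id=gene_a.gene_id,
                gene_b_id=gene_b.gene_id,
                intron_a=ia,
                intron_b=ib,
                window_a=window_a,
                window_b=window_b,
                aligned_length=aligned_length,
                identity=identity,
                score=int(score),
                pairing=pairing,
            )
        )
    return stems


# ---------------------------------------------------------------------------
# reporting

_TSV_HEADER = [
    "rank", "gene_a", "intron_a", "contig_a", "start_a", "end_a",
    "gene_b", "intron_b", "contig_b", "start_b", "end_b",
    "aligned_length", "identity", "score",
]


def _stem_row(rank: int, s: GenomicStem) -> dict:
    a1, a2 = s.window_a.to_1based()
    b1, b2 = s.window_b.to_1based()
    return {
        "rank": rank,
        "gene_a": s.gene_a_id,
        "intron_a": s.intron_a,
        "contig_a": s.window_a.contig_id,
        "start_a": a1,
        "end_a": a2,
        "gene_b": s.gene_b_id,
        "intron_b": s.intron_b,
        "contig_b": s.window_b.contig_id,
        "start_b": b1,
        "end_b": b2,
        "aligned_length": s.aligned_length,
        "identity": round(s.identity, 4),
        "score": s.score,
    }


def stem_report(stems: list[GenomicStem], format: str = "tsv") -> str:
    """Serialize stems with 1-based inclusive coordinates.

    ``tsv`` gives one row per stem; ``json`` additionally embeds the rendered
    pairing of each stem.
    """
    rows = [_stem_row(i, s) for i, s in enumerate(stems, start=1)]
    if format == "tsv":
        lines = ["\t".join(_TSV_HEADER)]
        lines += ["\t".join(str(r[c]) for c in _TSV_HEADER) for r in rows]
        return "\n".join(lines) + "\n"
    if format == "json":
        for row, stem in zip(rows, stems):
            row["rendering"] = stem.render()
        return json.dumps(rows, indent=2) + "\n"
    raise StemfuseError(f"unknown report format {format!r}")


def stems_to_bed(stems: list[GenomicStem]) -> str:
    """BED6 export of stem windows (two rows per stem, 0-based half-open)."""
    lines = []
    for i, s in enumerate(stems, start=1):
        lines.append("\t".join(s.window_a.to_bed_fields(f"stem{i}_a")))
        lines.append("\t".join(s.window_b.to_bed_fields(f"stem{i}_b")))
    return "\n".join(lines) + ("\n" if lines else "")
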