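"""Two-arm chimeric RNA design against intronic windows flanking a genomic stem.

Each design targets a window adjacent to the stem in both genes.  The
antisense chimera is the reverse complement of the concatenated sense-strand
target windows, so each of its arms can hybridize to the sense (non-template)
strand of its gene, forming — together with the stem — a three-way junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .errors import CassetteError, DesignError
from .genome_model import (
    GeneModel,
    GenomeSequence,
    Interval,
    revcomp,
    sense_sequence,
)
from .stem_finder import GenomicStem, StemParams, find_stems

logger = logging.getLogger(__name__)

TERMINATOR = "TTTTTT"


@dataclass(frozen=True)
class ChimericRNA:
    """A designed two-arm RNA (stored as DNA alphabet, 5'→3').

    For ``orientation='antisense'`` the sequence restricted to each arm is the
    exact reverse complement of that arm's sense-strand target window; the
    sense orientation is the reverse complement of the antisense one.
    """

    chimera_id: str
    orientation: str  # 'antisense' | 'sense'
    arm_a_target: Interval
    arm_b_target: Interval
    arm_length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.orientation not in ("antisense", "sense"):
            raise DesignError(f"bad orientation {self.orientation!r}")
        if len(self.sequence) != 2 * self.arm_length:
            raise DesignError(
                f"{self.chimera_id}: sequence length {len(self.sequence)} != "
                f"2 x arm_length {self.arm_length}"
            )


@dataclass(frozen=True)
class ExpressionCassette:
    """Pol-III expression cassette: promoter label + insert + T-run terminator."""

    promoter_label: str
    insert: str
    terminator: str
    orientation: str

    def __post_init__(self) -> None:
        if "T" * 6 not in self.terminator or len(self.terminator) < 6:
            raise CassetteError("terminator must contain a run of >= 6 T")
        if TERMINATOR in self.insert:
            raise CassetteError(
                "insert contains an internal >= 6-T run on the transcribed "
                "strand; the transcript would terminate early"
            )

    @property
    def full_insert(self) -> str:
        return self.insert + self.terminator


@dataclass(frozen=True)
class ThreeWayJunctionReport:
    stem: GenomicStem
    hybrid_a: Interval
    hybrid_b: Interval
    rendering: str

    def __post_init__(self) -> None:
        pairs = [
            (self.hybrid_a, self.stem.window_a),
            (self.hybrid_b, self.stem.window_b),
            (self.hybrid_a, self.hybrid_b),
            (self.hybrid_a, self.stem.window_b),
            (self.hybrid_b, self.stem.window_a),
        ]
        for x, y in pairs:
            if x.overlaps(y):
                raise DesignError("three-way junction regions overlap")


@dataclass(frozen=True)
class DesignParams:
    """Placement parameters for chimera arms around a stem.

    ``side_a``/``side_b`` choose which intronic flank of each stem window the
    arm targets, in gene-sense orientation ('5p' = upstream of the stem).  The
    defaults put the A arm upstream and the B arm downstream, the two flanks
    that emanate from the same end of the stem duplex.
    """

    arm_length: int = 50
    offset: int = 0
    arm_order: str = "ab"  # 'ab': A arm 5' of B arm in the sense precursor
    side_a: str = "5p"
    side_b: str = "3p"
    check_unique: bool = True

    def __post_init__(self) -> None:
        if self.arm_length < 1 or self.offset < 0:
            raise DesignError("arm_length must be >= 1 and offset >= 0")
        if self.arm_order not in ("ab", "ba"):
            raise DesignError("arm_order must be 'ab' or 'ba'")
        if self.side_a not in ("5p", "3p") or self.side_b not in ("5p", "3p"):
            raise DesignError("sides must be '5p' or '3p'")


def _arm_window(
    gene: GeneModel,
    stem_window: Interval,
    intron_index: int,
    side: str,
    arm_length: int,
    offset: int,
) -> tuple[int, int]:
    """Arm target window in gene-local sense coordinates; checks intron fit."""
    s1, s2 = gene.genomic_to_local(stem_window)
    i1, i2 = gene.intron_local_intervals()[intron_index - 1]
    if side == "5p":
        w1, w2 = s1 - offset - arm_length, s1 - offset
        shortfall = i1 - w1
    else:
        w1, w2 = s2 + offset, s2 + offset + arm_length
        shortfall = w2 - i2
    if shortfall > 0:
        raise DesignError(
            f"gene {gene.gene_id}: intronic flank too short for a "
            f"{arm_length}-nt arm at offset {offset} ({shortfall} nt missing)"
        )
    return w1, w2


def _count_in_loci(kmer: str, locus_seqs: list[str]) -> int:
    total = 0
    for seq in locus_seqs:
        for probe in (kmer, revcomp(kmer)):
            start = 0
            while True:
                idx = seq.find(probe, start)
                if idx < 0:
                    break
                total += 1
                start = idx + 1
    return total


def design_chimera(
    stem: GenomicStem,
    gene_a: GeneModel,
    gene_b: GeneModel,
    genome: dict[str, GenomeSequence],
    arm_length: int = 50,
    offset: int = 0,
    arm_order: str = "ab",
    side_a: str = "5p",
    side_b: str = "3p",
    chimera_id: str = "chimera",
    check_unique: bool = True,
) -> ChimericRNA:
    """Design the antisense chimera for one stem.

    The sense-orientation precursor is the concatenation of the two
    sense-strand target windows (in ``arm_order``); the antisense chimera is
    its reverse complement.  Target windows abut the stem windows at distance
    ``offset`` on the configured flanks and never touch exons.
    """
    params = DesignParams(arm_length, offset, arm_order, side_a, side_b, check_unique)
    wa = _arm_window(gene_a, stem.window_a, stem.intron_a, side_a, arm_length, offset)
    wb = _arm_window(gene_b, stem.window_b, stem.intron_b, side_b, arm_length, offset)
    target_a = gene_a.local_to_genomic(*wa)
    target_b = gene_b.local_to_genomic(*wb)
    arm_a = sense_sequence(target_a, genome[target_a.contig_id])
    arm_b = sense_sequence(target_b, genome[target_b.contig_id])
    for gene, arm in ((gene_a, arm_a), (gene_b, arm_b)):
        if "N" in arm:
            raise DesignError(f"gene {gene.gene_id}: target window contains N")
    if check_unique:
        loci = [
            gene_a.sense_sequence(genome[gene_a.contig_id]),
            gene_b.sense_sequence(genome[gene_b.contig_id]),
        ]
        for gene, arm in ((gene_a, arm_a), (gene_b, arm_b)):
            n = _count_in_loci(arm, loci)
            if n != 1:
                raise DesignError(
                    f"gene {gene.gene_id}: arm target occurs {n} times in the "
                    "two-locus union (must be unique)"
                )
    precursor = arm_a + arm_b if params.arm_order == "ab" else arm_b + arm_a
    return ChimericRNA(
        chimera_id=chimera_id,
        orientation="antisense",
        arm_a_target=target_a,
        arm_b_target=target_b,
        arm_length=arm_length,
        sequence=revcomp(precursor),
    )


def sense_counterpart(chimera: ChimericRNA) -> ChimericRNA:
    """The same design in the opposite orientation (reverse complement)."""
    flipped = "sense" if chimera.orientation == "antisense" else "antisense"
    return replace(chimera, orientation=flipped, sequence=revcomp(chimera.sequence))


def build_cassette(chimera: ChimericRNA, promoter_label: str = "U6") -> ExpressionCassette:
    """Wrap a chimera insert into a pol-III cassette with a TTTTTT terminator."""
    if chimera.sequence and chimera.sequence[0] not in "GA":
        logger.warning(
            "%s: insert starts with %r; pol-III initiation favors G/A",
            chimera.chimera_id,
            chimera.sequence[0],
        )
    return ExpressionCassette(
        promoter_label=promoter_label,
        insert=chimera.sequence,
        terminator=TERMINATOR,
        orientation=chimera.orientation,
    )


def three_way_junction_report(stem: GenomicStem, chimera: ChimericRNA) -> ThreeWayJunctionReport:
    lines = [
        f"stem: {stem.gene_a_id} {stem.window_a.contig_id}:"
        f"{stem.window_a.to_1based()[0]}-{stem.window_a.to_1based()[1]} | "
        f"{stem.gene_b_id} {stem.window_b.contig_id}:"
        f"{stem.window_b.to_1based()[0]}-{stem.window_b.to_1based()[1]} "
        f"(len {stem.aligned_length}, id {stem.identity:.2f})",
        stem.render(),
        f"hybrid A: {chimera.arm_a_target.contig_id}:"
        f"{chimera.arm_a_target.to_1based()[0]}-{chimera.arm_a_target.to_1based()[1]}",
        f"hybrid B: {chimera.arm_b_target.contig_id}:"
        f"{chimera.arm_b_target.to_1based()[0]}-{chimera.arm_b_target.to_1based()[1]}",
    ]
    return ThreeWayJunctionReport(
        stem=stem,
        hybrid_a=chimera.arm_a_target,
        hybrid_b=chimera.arm_b_target,
        rendering="\n".join(lines),
    )


@dataclass(frozen=True)
class DesignCandidate:
    stem: GenomicStem
    antisense: ChimericRNA
    sense: ChimericRNA
    junction: ThreeWayJunctionReport


def design_candidates(
    gene_a: GeneModel,
    gene_b: GeneModel,
    genome: dict[str, GenomeSequence],
    stem_params: StemParams | None = None,
    design_params: DesignParams | None = None,
    id_prefix: str = "chim",
    stems: list[GenomicStem] | None = None,
) -> list[DesignCandidate]:
    """Batch design: one candidate per surviving stem, in stem rank order.

    Per-candidate design failures are logged and skipped; they never abort
    the batch.  Pass precomputed ``stems`` to skip the search.
    """
    dp = design_params or DesignParams()
    if stems is None:
        stems = find_stems(gene_a, gene_b, genome, stem_params)
    candidates: list[DesignCandidate] = []
    for rank, stem in enumerate(stems, start=1):
        try:
            antisense = design_chimera(
                stem,
                gene_a,
                gene_b,
                genome,
                arm_length=dp.arm_length,
                offset=dp.offset,
                arm_order=dp.arm_order,
                side_a=dp.side_a,
                side_b=dp.side_b,
                chimera_id=f"{id_prefix}{rank}",
                check_unique=dp.check_unique,
            )
        except DesignError as exc:
            logger.warning("stem %d: design failed: %s", rank, exc)
            continue
        candidates.append(
            DesignCandidate(
                stem=stem,
                antisense=antisense,
                sense=sense_counterpart(antisense),
                junction=three_way_junction_report(stem, antisense),
            )
        )
    return candidates


def design_sheet(candidates: list[DesignCandidate]) -> str:
    """TSV design sheet with 1-based target coordinates and both orientations."""
    header = [
        "chimera_id", "contig_a", "start_a", "end_a", "contig_b", "start_b",
        "end_b", "arm_length", "antisense_sequence", "sense_sequence",
        "stem_score", "stem_identity",
    ]
    lines = ["\t".join(header)]
    for c in candidates:
        a1, a2 = c.antisense.arm_a_target.to_1based()
        b1, b2 = c.antisense.arm_b_target.to_1based()
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    c.antisense.chimera_id,
                    c.antisense.arm_a_target.contig_id, a1, a2,
                    c.antisense.arm_b_target.contig_id, b1, b2,
                    c.antisense.arm_length,
                    c.antisense.sequence,
                    c.sense.sequence,
                    c.stem.score,
                    round(c.stem.identity, 4),
                ]
            )
        )
    return "\n".join(lines) + "\n"
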