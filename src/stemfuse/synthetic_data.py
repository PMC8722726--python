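"""Deterministic two-gene fixture genomes with planted stems and fusion events.

The default preset emulates a two-locus configuration with a 5-exon gene A
(large intron 3) and a 16-exon gene B (small intron 1) on separate contigs,
one planted imperfect complementary stem, and two planted fusion events (the
second carrying an untemplated "AA" junction insertion).  Intron sizes scale
down proportionally so the full-size preset is optional.

Everything is a pure function of (spec, seed): same inputs, identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import SpecError
from .fusion_model import FusionAllele, FusionEvent, make_fusion_allele
from .genome_model import (
    GeneModel,
    GenomeSequence,
    Interval,
    revcomp,
    write_fasta,
    write_gff3,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class StemPlan:
    """Where to plant the complementary stem (offsets within intron sense)."""

    intron_a: int  # 1-based intron index in gene A
    intron_b: int
    length: int
    mismatches: int
    offset_a: int
    offset_b: int


@dataclass(frozen=True)
class EventPlan:
    """A fusion breakpoint pair to plant (offsets within intron sense)."""

    event_id: str
    intron_a: int
    offset_a: int
    intron_b: int
    offset_b: int
    insertion: str = ""
    microhomology: int = 0

    def __post_init__(self) -> None:
        if self.insertion and self.microhomology:
            raise SpecError(
                f"event {self.event_id!r}: insertion and microhomology are "
                "mutually exclusive"
            )


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    gene_a_exons: tuple[int, ...]
    gene_a_introns: tuple[int, ...]
    gene_b_exons: tuple[int, ...]
    gene_b_introns: tuple[int, ...]
    gc_content: float = 0.42
    flank: int = 300
    planted_stem: StemPlan | None = None
    planted_events: tuple[EventPlan, ...] = ()
    read_length: int = 600
    n_reads_per_event: int = 3
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, exons, introns in (
            ("gene_a", self.gene_a_exons, self.gene_a_introns),
            ("gene_b", self.gene_b_exons, self.gene_b_introns),
        ):
            if len(introns) != len(exons) - 1:
                raise SpecError(f"{name}: need len(introns) == len(exons) - 1")
            if any(x <= 0 for x in exons + introns):
                raise SpecError(f"{name}: all feature lengths must be positive")
        if not 0 < self.gc_content < 1:
            raise SpecError("gc_content must be in (0, 1)")
        if self.planted_stem is not None:
            s = self.planted_stem
            for label, idx, off, introns in (
                ("planted_stem.intron_a", s.intron_a, s.offset_a, self.gene_a_introns),
                ("planted_stem.intron_b", s.intron_b, s.offset_b, self.gene_b_introns),
            ):
                if not 1 <= idx <= len(introns):
                    raise SpecError(f"{label}: intron index {idx} out of range")
                if off + s.length > introns[idx - 1]:
                    raise SpecError(f"{label}: stem does not fit inside the intron")
        for ev in self.planted_events:
            for label, idx, off, introns in (
                (f"event {ev.event_id} intron_a", ev.intron_a, ev.offset_a, self.gene_a_introns),
                (f"event {ev.event_id} intron_b", ev.intron_b, ev.offset_b, self.gene_b_introns),
            ):
                if not 1 <= idx <= len(introns):
                    raise SpecError(f"{label}: intron index {idx} out of range")
                margin = ev.microhomology + 2
                if not margin <= off < introns[idx - 1] - margin:
                    raise SpecError(
                        f"{label}: offset {off} leaves no room for junction fixups"
                    )


@dataclass
class TruthRecord:
    """Ground truth for all planted features, consistent with emitted files."""

    stem: dict | None
    events: list[dict]
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"stem": self.stem, "events": self.events, "manifest": self.manifest},
            indent=2,
        ) + "\n"


@dataclass
class SyntheticGenome:
    spec: SyntheticSpec
    genome: dict[str, GenomeSequence]
    gene_a: GeneModel
    gene_b: GeneModel
    events: list[FusionEvent]
    truth: TruthRecord

    @property
    def genes(self) -> list[GeneModel]:
        return [self.gene_a, self.gene_b]

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write FASTA/GFF3/truth JSON; returns {filename: sha256}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta({c: g.sequence for c, g in self.genome.items()}, outdir / "genome.fa")
        write_gff3(self.genes, outdir / "genes.gff3")
        manifest = {}
        for name in ("genome.fa", "genes.gff3"):
            manifest[name] = _sha256(outdir / name)
        self.truth.manifest.update(manifest)
        (outdir / "truth.json").write_text(self.truth.to_json())
        manifest["truth.json"] = _sha256(outdir / "truth.json")
        return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=p)


def _other_base(idx: int, *avoid: int) -> int:
    for cand in range(4):
        if cand != idx and cand not in avoid:
            return cand
    raise AssertionError("unreachable")


def _local_layout(exons: tuple[int, ...], introns: tuple[int, ...]):
    """(exon_local, intron_local) interval lists from feature lengths."""
    exon_local, intron_local = [], []
    pos = 0
    for i, ex in enumerate(exons):
        exon_local.append((pos, pos + ex))
        pos += ex
        if i < len(introns):
            intron_local.append((pos, pos + introns[i]))
            pos += introns[i]
    return exon_local, intron_local, pos


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Build the two-contig genome with all planted features."""
    rng = np.random.default_rng(spec.seed)
    exl_a, inl_a, len_a = _local_layout(spec.gene_a_exons, spec.gene_a_introns)
    exl_b, inl_b, len_b = _local_layout(spec.gene_b_exons, spec.gene_b_introns)
    seq_a = _random_seq(rng, len_a, spec.gc_content)
    seq_b = _random_seq(rng, len_b, spec.gc_content)

    occupied_a: list[tuple[int, int, str]] = []
    occupied_b: list[tuple[int, int, str]] = []

    stem_truth = None
    if spec.planted_stem is not None:
        s = spec.planted_stem
        a0 = inl_a[s.intron_a - 1][0] + s.offset_a
        b0 = inl_b[s.intron_b - 1][0] + s.offset_b
        window = seq_a[a0 : a0 + s.length]
        # B sense window := revcomp of the A window, then scatter mismatches
        planted = (3 - window)[::-1].copy()
        if s.mismatches:
            mut_pos = rng.choice(s.length, size=s.mismatches, replace=False)
            for p in sorted(mut_pos):
                planted[p] = _other_base(planted[p])
        seq_b[b0 : b0 + s.length] = planted
        occupied_a.append((a0, a0 + s.length, "planted_stem"))
        occupied_b.append((b0, b0 + s.length, "planted_stem"))
        stem_truth = {
            "intron_a": s.intron_a,
            "intron_b": s.intron_b,
            "length": s.length,
            "mismatches": s.mismatches,
            "local_a": [a0, a0 + s.length],
            "local_b": [b0, b0 + s.length],
        }

    events: list[FusionEvent] = []
    event_truth: list[dict] = []
    for plan in spec.planted_events:
        bp_a = inl_a[plan.intron_a - 1][0] + plan.offset_a
        bp_b = inl_b[plan.intron_b - 1][0] + plan.offset_b
        h = plan.microhomology
        if plan.insertion:
            ins0 = "ACGT".index(plan.insertion[0])
            ins1 = "ACGT".index(plan.insertion[-1])
            if seq_a[bp_a + 1] == ins0:
                seq_a[bp_a + 1] = _other_base(ins0)
            if seq_b[bp_b - 1] == ins1:
                seq_b[bp_b - 1] = _other_base(ins1)
            occupied_a.append((bp_a, bp_a + 2, plan.event_id))
            occupied_b.append((bp_b - 1, bp_b + 1, plan.event_id))
        else:
            # copy the shared bases into B, then cap both ends so the
            # canonical placement (shared bases assigned to A) is exact
            for t in range(1, h + 1):
                seq_b[bp_b - t] = seq_a[bp_a + 1 - t]
            if seq_b[bp_b] == seq_a[bp_a + 1]:
                seq_b[bp_b] = _other_base(seq_a[bp_a + 1])
            if seq_b[bp_b - h - 1] == seq_a[bp_a - h]:
                seq_b[bp_b - h - 1] = _other_base(seq_a[bp_a - h])
            occupied_a.append((bp_a - h, bp_a + 2, plan.event_id))
            occupied_b.append((bp_b - h - 1, bp_b + 1, plan.event_id))
        events.append(
            FusionEvent(
                event_id=plan.event_id,
                gene_a_id="geneA",
                gene_b_id="geneB",
                breakpoint_a=int(bp_a),
                breakpoint_b=int(bp_b),
                insertion=plan.insertion,
                microhomology_length=h,
            )
        )
        event_truth.append(
            {
                "event_id": plan.event_id,
                "breakpoint_a_local": int(bp_a),
                "breakpoint_b_local": int(bp_b),
                "insertion": plan.insertion,
                "microhomology_length": h,
            }
        )

    for occ, label in ((occupied_a, "gene A"), (occupied_b, "gene B")):
        occ.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(occ, occ[1:]):
            if s2 < e1:
                raise SpecError(
                    f"planted features {n1!r} and {n2!r} collide in {label}"
                )

    flank_l_a = _random_seq(rng, spec.flank, spec.gc_content)
    flank_r_a = _random_seq(rng, spec.flank, spec.gc_content)
    flank_l_b = _random_seq(rng, spec.flank, spec.gc_content)
    flank_r_b = _random_seq(rng, spec.flank, spec.gc_content)
    contig_a = "".join(_BASES[np.concatenate([flank_l_a, seq_a, flank_r_a])])
    contig_b = "".join(_BASES[np.concatenate([flank_l_b, seq_b, flank_r_b])])

    def build_gene(gene_id, contig_id, exon_local):
        exons = [
            Interval(contig_id, spec.flank + s, spec.flank + e, "+")
            for s, e in exon_local
        ]
        return GeneModel(gene_id, contig_id, "+", exons)

    gene_a = build_gene("geneA", "chrA", exl_a)
    gene_b = build_gene("geneB", "chrB", exl_b)
    genome = {
        "chrA": GenomeSequence("chrA", contig_a),
        "chrB": GenomeSequence("chrB", contig_b),
    }
    if stem_truth is not None:
        a0, a1 = stem_truth["local_a"]
        b0, b1 = stem_truth["local_b"]
        stem_truth["window_a"] = [spec.flank + a0, spec.flank + a1]
        stem_truth["window_b"] = [spec.flank + b0, spec.flank + b1]
    truth = TruthRecord(stem=stem_truth, events=event_truth)
    return SyntheticGenome(spec, genome, gene_a, gene_b, events, truth)


def generate_fusion_materials(
    synth: SyntheticGenome,
) -> tuple[list[FusionAllele], list[tuple[str, str]]]:
    """Fused alleles plus junction-spanning reads for every planted event.

    Reads keep at least read_length/3 bases on each side of the junction;
    substitution errors are injected at ``read_error_rate`` under the spec
    seed (offset so genome and reads use independent streams).
    """
    spec = synth.spec
    if not synth.events:
        raise SpecError("no planted events in this synthetic genome")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    alleles, reads = [], []
    L = spec.read_length
    side = -(-L // 3)  # ceil
    for event in synth.events:
        allele = make_fusion_allele(synth.genome, synth.gene_a, synth.gene_b, event)
        alleles.append(allele)
        j_lo = event.breakpoint_a + 1
        j_hi = j_lo + len(event.insertion)
        lo = max(0, j_hi + side - L)
        hi = min(len(allele.sequence) - L, j_lo - side)
        if hi < lo:
            raise SpecError(
                f"event {event.event_id!r}: allele too short for "
                f"{L}-nt junction reads"
            )
        starts = rng.integers(lo, hi + 1, size=spec.n_reads_per_event)
        for i, s in enumerate(starts, start=1):
            arr = np.frombuffer(
                allele.sequence[s : s + L].encode(), dtype=np.uint8
            ).copy()
            if spec.read_error_rate > 0:
                errs = np.nonzero(rng.random(L) < spec.read_error_rate)[0]
                lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
                for p in errs:
                    arr[p] = ord(lut[arr[p]][rng.integers(3)])
            reads.append((f"{event.event_id}_read{i}", arr.tobytes().decode()))
    return alleles, reads


def write_fusion_materials(
    synth: SyntheticGenome, outdir: str | Path
) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alleles, reads = generate_fusion_materials(synth)
    write_fasta(
        [(f"fusion_{a.event.event_id}", a.sequence) for a in alleles],
        outdir / "alleles.fa",
    )
    write_fasta(reads, outdir / "reads.fa")
    return {name: _sha256(outdir / name) for name in ("alleles.fa", "reads.fa")}


# ---------------------------------------------------------------------------
# presets


def preset(name: str = "jazf1-suz12-like", scale: float = 0.05, seed: int = 7) -> SyntheticSpec:
    """Named fixture configurations.

    The default emulates the two-locus architecture with a ~54 kb third
    intron in the 5-exon gene and a ~2.7 kb first intron in the 16-exon gene,
    shrunk by ``scale``, with one planted 30-nt stem (3 mismatches) and two
    planted fusion events "x" and "y" (event "y" carries an "AA" insertion).
    """
    if name != "jazf1-suz12-like":
        raise SpecError(f"unknown preset {name!r}")
    if not 0 < scale <= 1:
        raise SpecError("scale must be in (0, 1]")

    def sc(n: int) -> int:
        return max(60, round(n * scale))

    introns_a = (sc(6000), sc(8000), sc(54000), sc(5000))
    introns_b = (sc(2700),) + tuple(sc(1800) for _ in range(14))
    exons_a = (150, 120, 180, 140, 200)
    exons_b = (110,) + tuple(150 for _ in range(15))

    big_a = introns_a[2]
    small_b = introns_b[0]
    stem_len = 30
    stem = StemPlan(
        intron_a=3,
        intron_b=1,
        length=stem_len,
        mismatches=3,
        offset_a=big_a // 2,
        offset_b=(small_b - stem_len) // 2,
    )
    events = (
        EventPlan("x", 3, max(10, big_a // 4), 1, max(10, small_b // 6)),
        EventPlan(
            "y", 3, max(20, (3 * big_a) // 4), 1, max(12, small_b // 3),
            insertion="AA",
        ),
    )
    return SyntheticSpec(
        seed=seed,
        gene_a_exons=exons_a,
        gene_a_introns=introns_a,
        gene_b_exons=exons_b,
        gene_b_introns=introns_b,
        planted_stem=stem,
        planted_events=events,
    )


def spec_to_json(spec: SyntheticSpec) -> str:
    return json.dumps(asdict(spec), indent=2) + "\n"
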