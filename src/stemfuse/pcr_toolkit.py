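"""In-silico PCR, nested amplification, and multiplex tiling breakpoint scans.

Primer binding is pure sequence matching: up to ``max_mismatch`` mismatches
per site, but the 3'-terminal five bases must always match exactly and N never
matches.  No thermodynamics are modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import StemfuseError
from .genome_model import GenomeSequence, Interval, revcomp, sense_sequence

THREE_PRIME_EXACT = 5
MIN_PRIMER_LENGTH = 15


@dataclass(frozen=True)
class Primer:
    """A primer, 5'→3', at least 15 nt of pure ACGT."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_PRIMER_LENGTH:
            raise StemfuseError(
                f"primer {self.name!r}: length {len(self.sequence)} < {MIN_PRIMER_LENGTH}"
            )
        if set(self.sequence) - set("ACGT"):
            raise StemfuseError(f"primer {self.name!r}: alphabet must be ACGT")


@dataclass(frozen=True)
class Amplicon:
    """A predicted product on the plus strand of a template."""

    template_id: str
    start: int  # 0-based half-open on the template
    end: int
    forward: Primer
    reverse: Primer

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NestedScheme:
    """Ordered PCR rounds; each round is a list of (forward, reverse) pairs."""

    rounds: tuple[tuple[tuple[Primer, Primer], ...], ...]

    @staticmethod
    def from_pairs(rounds: list[list[tuple[Primer, Primer]]]) -> "NestedScheme":
        return NestedScheme(tuple(tuple(r) for r in rounds))


def _binding_sites(template: str, probe: str, max_mismatch: int) -> list[int]:
    """Plus-strand start positions where ``probe`` binds.

    The last THREE_PRIME_EXACT bases of the forward probe (first for a
    reverse-complemented probe — handled by the caller passing the probe in
    plus-strand orientation together with which end is 3') are checked by the
    caller; here we only enforce the mismatch budget and reject N.
    """
    k = len(probe)
    sites = []
    if max_mismatch == 0:
        start = 0
        while True:
            idx = template.find(probe, start)
            if idx < 0:
                return sites
            sites.append(idx)
            start = idx + 1
    for i in range(len(template) - k + 1):
        window = template[i : i + k]
        if "N" in window:
            continue
        mm = sum(1 for a, b in zip(window, probe) if a != b)
        if mm <= max_mismatch:
            sites.append(i)
    return sites


def _forward_sites(template: str, primer: Primer, max_mismatch: int) -> list[int]:
    seq = primer.sequence
    sites = _binding_sites(template, seq, max_mismatch)
    if max_mismatch == 0:
        return sites
    tail = seq[-THREE_PRIME_EXACT:]
    return [i for i in sites if template[i + len(seq) - THREE_PRIME_EXACT : i + len(seq)] == tail]


def _reverse_sites(template: str, primer: Primer, max_mismatch: int) -> list[int]:
    rc = revcomp(primer.sequence)
    sites = _binding_sites(template, rc, max_mismatch)
    if max_mismatch == 0:
        return sites
    head = rc[:THREE_PRIME_EXACT]  # 3' end of the reverse primer
    return [i for i in sites if template[i : i + THREE_PRIME_EXACT] == head]


def ispcr(
    template: str | GenomeSequence,
    forward: Primer,
    reverse: Primer,
    max_product: int = 5000,
    max_mismatch: int = 0,
    template_id: str = "template",
) -> list[Amplicon]:
    """All products of a primer pair on the plus strand of a template.

    A product requires a forward site on the plus strand and a reverse site
    (reverse complement of the reverse primer) strictly downstream of it, with
    product length ≤ ``max_product``.  Products are sorted by start, then end.
    """
    if isinstance(template, GenomeSequence):
        template_id = template.contig_id
        template = template.sequence
    fwd = _forward_sites(template, forward, max_mismatch)
    rev = _reverse_sites(template, reverse, max_mismatch)
    products = []
    for i in fwd:
        f_end = i + len(forward.sequence)
        for j in rev:
            end = j + len(reverse.sequence)
            if j >= f_end and end - i <= max_product:
                products.append(Amplicon(template_id, i, end, forward, reverse))
    products.sort(key=lambda a: (a.start, a.end))
    return products


def nested_pcr(
    template: str | GenomeSequence,
    scheme: NestedScheme,
    max_product: int = 5000,
    max_mismatch: int = 0,
    template_id: str = "template",
) -> list[list[Amplicon]]:
    """Run successive rounds, each on every product of the previous round.

    Coordinates are reported on the original template (products are exact
    substrings, so offsets compose).  An empty round propagates downstream as
    empty output, never an exception.
    """
    if isinstance(template, GenomeSequence):
        template_id = template.contig_id
        template = template.sequence
    current: list[tuple[int, str]] = [(0, template)]  # (absolute offset, sequence)
    per_round: list[list[Amplicon]] = []
    for pairs in scheme.rounds:
        produced: dict[tuple, Amplicon] = {}
        for offset, seq in current:
            for fwd, rev in pairs:
                for amp in ispcr(seq, fwd, rev, max_product, max_mismatch, template_id):
                    shifted = Amplicon(
                        template_id, amp.start + offset, amp.end + offset, fwd, rev
                    )
                    key = (shifted.start, shifted.end, fwd.name, rev.name)
                    produced[key] = shifted
        round_products = sorted(
            produced.values(), key=lambda a: (a.start, a.end, a.forward.name)
        )
        per_round.append(round_products)
        current = [(a.start, template[a.start : a.end]) for a in round_products]
    return per_round


# ---------------------------------------------------------------------------
# tiling design and breakpoint scanning


@dataclass(frozen=True)
class TilingSite:
    position: Interval  # genomic window of the primer site (sense strand of its gene)
    primer: Primer


@dataclass(frozen=True)
class TilingScheme:
    """Evenly spaced forward sites across intron A and reverse sites across intron B."""

    forward_sites: tuple[TilingSite, ...]
    reverse_sites: tuple[TilingSite, ...]
    spacing_forward: int
    spacing_reverse: int


def _unique_in_union(kmer: str, union_seqs: list[str]) -> bool:
    total = 0
    for seq in union_seqs:
        for probe in (kmer, revcomp(kmer)):
            start = 0
            while True:
                idx = seq.find(probe, start)
                if idx < 0:
                    break
                total += 1
                start = idx + 1
    return total == 1


def _place_sites(
    intron: Interval,
    genome: dict[str, GenomeSequence],
    n: int,
    union_seqs: list[str],
    site_length: int,
    reverse: bool,
    name_prefix: str,
) -> tuple[list[TilingSite], int]:
    length = intron.length
    if length < n * site_length:
        raise StemfuseError(
            f"intron of length {length} too short for {n} sites of {site_length} nt"
        )
    spacing = length // n
    sense = sense_sequence(intron, genome[intron.contig_id])
    sites = []
    for idx in range(n):
        target = min(idx * spacing, length - site_length)
        pos = _nearest_valid(sense, target, site_length, union_seqs)
        if pos is None:
            raise StemfuseError(
                f"no valid unique {site_length}-mer near offset {target} in intron"
            )
        kmer = sense[pos : pos + site_length]
        if intron.strand == "+":
            window = Interval(intron.contig_id, intron.start + pos, intron.start + pos + site_length, "+")
        else:
            window = Interval(intron.contig_id, intron.end - pos - site_length, intron.end - pos, "-")
        primer_seq = revcomp(kmer) if reverse else kmer
        sites.append(TilingSite(window, Primer(f"{name_prefix}{idx + 1}", primer_seq)))
    return sites, spacing


def _nearest_valid(sense: str, target: int, k: int, union_seqs: list[str]) -> int | None:
    limit = len(sense) - k
    for delta in range(limit + 1):
        for pos in ({target + delta, target - delta}):
            if 0 <= pos <= limit:
                kmer = sense[pos : pos + k]
                if "N" not in kmer and _unique_in_union(kmer, union_seqs):
                    return pos
    return None


def design_tiling(
    intron_a: Interval,
    intron_b: Interval,
    genome: dict[str, GenomeSequence],
    n_forward: int,
    n_reverse: int,
    site_length: int = 20,
    union_seqs: list[str] | None = None,
) -> TilingScheme:
    """Evenly spaced, locus-unique primer sites across the two introns.

    Sites whose k-mer is not unique within the two-locus union (or contains
    N) are shifted to the nearest valid position.  ``union_seqs`` defaults to
    the two intron sense sequences; pass the full locus sequences for a
    stricter screen.
    """
    if n_forward < 1 or n_reverse < 1:
        raise StemfuseError("n_forward and n_reverse must be >= 1")
    if union_seqs is None:
        union_seqs = [
            sense_sequence(intron_a, genome[intron_a.contig_id]),
            sense_sequence(intron_b, genome[intron_b.contig_id]),
        ]
    fwd, sp_f = _place_sites(
        intron_a, genome, n_forward, union_seqs, site_length, False, "F"
    )
    rev, sp_r = _place_sites(
        intron_b, genome, n_reverse, union_seqs, site_length, True, "R"
    )
    return TilingScheme(tuple(fwd), tuple(rev), sp_f, sp_r)


@dataclass(frozen=True)
class ScanResult:
    """Fusion-specific firing pairs and the implied breakpoint interval."""

    firing: tuple[tuple[Primer, Primer, Amplicon], ...]
    interval: tuple[int, int] | None  # on the fused allele, between innermost sites


def scan_breakpoint(
    allele_sequence: str,
    tiling: TilingScheme,
    wildtype_a: str,
    wildtype_b: str,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> ScanResult:
    """Cross all forward × reverse tiling pairs against the fused allele.

    A pair is fusion-specific when it amplifies the allele but yields no
    product on either wild-type locus.  The implied breakpoint interval spans
    from the end of the innermost firing forward site to the start of the
    innermost firing reverse site on the allele.
    """
    firing = []
    inner_left, inner_right = None, None
    for fs in tiling.forward_sites:
        for rs in tiling.reverse_sites:
            amps = ispcr(
                allele_sequence, fs.primer, rs.primer, max_product, max_mismatch,
                template_id="fusion_allele",
            )
            if not amps:
                continue
            if ispcr(wildtype_a, fs.primer, rs.primer, max_product, max_mismatch):
                continue
            if ispcr(wildtype_b, fs.primer, rs.primer, max_product, max_mismatch):
                continue
            amp = amps[0]
            firing.append((fs.primer, rs.primer, amp))
            f_end = amp.start + len(fs.primer.sequence)
            r_start = amp.end - len(rs.primer.sequence)
            inner_left = f_end if inner_left is None else max(inner_left, f_end)
            inner_right = r_start if inner_right is None else min(inner_right, r_start)
    interval = None
    if firing:
        interval = (inner_left, inner_right)
    return ScanResult(tuple(firing), interval)


# ---------------------------------------------------------------------------
# primer and amplicon I/O


def read_primers_tsv(path: str | Path) -> dict[str, Primer]:
    """TSV with columns: name, sequence (header optional)."""
    primers: dict[str, Primer] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise StemfuseError(f"bad primer line: {line!r}")
        name, seq = fields[0], fields[1].upper()
        if name.lower() == "name" and seq.lower() == "sequence":
            continue
        primers[name] = Primer(name, seq)
    return primers


def primers_to_tsv(primers: list[Primer]) -> str:
    lines = ["name\tsequence"]
    lines += [f"{p.name}\t{p.sequence}" for p in primers]
    return "\n".join(lines) + "\n"


def amplicons_to_tsv(amplicons: list[Amplicon]) -> str:
    """1-based inclusive coordinate report of amplicons."""
    lines = ["template\tstart\tend\tlength\tforward\treverse"]
    for a in amplicons:
        lines.append(
            f"{a.template_id}\t{a.start + 1}\t{a.end}\t{a.length}\t"
            f"{a.forward.name}\t{a.reverse.name}"
        )
    return "\n".join(lines) + "\n"


def scan_report(result: ScanResult) -> str:
    data = {
        "n_firing_pairs": len(result.firing),
        "breakpoint_interval": list(result.interval) if result.interval else None,
        "pairs": [
            {
                "forward": f.name,
                "reverse": r.name,
                "product_start": a.start + 1,
                "product_end": a.end,
                "product_length": a.length,
            }
            for f, r, a in result.firing
        ],
    }
    return json.dumps(data, indent=2) + "\n"
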