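"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python dynamic
programs, exhaustive enumerations and character-by-character scans.
"""

from __future__ import annotations

NEG = float("-inf")

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def sw_local(a, b, match=2, mismatch=3, gap_open=5, gap_extend=2):
    """Affine-gap Smith–Waterman (Gotoh), full O(n*m) table.

    Gap of length k costs gap_open + k * gap_extend.  Returns
    (best_score, n_best_cells, (a_start, a_end), (b_start, b_end)) where the
    coordinates trace back from the first best cell in row-major order;
    n_best_cells counts cells achieving the maximum (uniqueness probe).
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best, best_cell, n_best = 0.0, None, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else -mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_cell, n_best = H[i][j], (i, j), 1
            elif H[i][j] == best and best > 0:
                n_best += 1
    if best_cell is None:
        return 0, 0, None, None
    i, j = best_cell
    ai_end, bj_end = i, j
    state = "H"
    while H[i][j] > 0 or state != "H":
        if state == "H":
            s = match if a[i - 1] == b[j - 1] else -mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                break
        elif state == "E":
            if E[i][j] == H[i][j - 1] - gap_open - gap_extend:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:
            if F[i][j] == H[i - 1][j] - gap_open - gap_extend:
                i -= 1
                state = "H"
            else:
                i -= 1
    return int(best), n_best, (i, ai_end), (j, bj_end)


def brute_force_split(read: str, sense_a: str, sense_b: str, k: int = 20):
    """Exhaustive split-point enumeration with exact anchor matching.

    Tries all (i, j) with i <= j, i >= k, len(read)-j >= k such that
    read[:i] occurs in sense_a and read[j:] occurs in sense_b; maximizes
    matched bases i + (m - j), tie-broken toward the largest i (shared bases
    to gene A), then the leftmost occurrence in A, then in B.  Returns
    (bp_a, bp_b, insertion) or None.
    """
    m = len(read)
    best = None
    for i in range(k, m - k + 1):
        pa = sense_a.find(read[:i])
        if pa < 0:
            continue
        for j in range(i, m - k + 1):
            pb = sense_b.find(read[j:])
            if pb < 0:
                continue
            key = (i + (m - j), i, -pa, -pb)
            if best is None or key > best[0]:
                best = (key, pa + i - 1, pb, read[i:j])
    if best is None:
        return None
    return best[1], best[2], best[3]


def naive_ispcr(template: str, fwd: str, rev: str, max_product=5000, max_mismatch=0):
    """Quadratic sliding-window product enumeration mirroring the binding rules:
    mismatch budget, exact 3'-terminal 5 bases, N never matches, reverse site
    strictly downstream of the forward site, product length cap.
    """
    def mismatches(window: str, probe: str) -> int:
        total = 0
        for x, y in zip(window, probe):
            if x == "N" or x != y:
                total += 1
        return total

    rc_rev = rc(rev)
    fsites = []
    for i in range(len(template) - len(fwd) + 1):
        w = template[i : i + len(fwd)]
        if mismatches(w, fwd) <= max_mismatch and w[-5:] == fwd[-5:]:
            fsites.append(i)
    rsites = []
    for i in range(len(template) - len(rc_rev) + 1):
        w = template[i : i + len(rc_rev)]
        if mismatches(w, rc_rev) <= max_mismatch and w[:5] == rc_rev[:5]:
            rsites.append(i)
    out = []
    for i in fsites:
        for j in rsites:
            if j >= i + len(fwd) and (j + len(rc_rev)) - i <= max_product:
                out.append((i, j + len(rc_rev)))
    return sorted(out)


def ambiguity_span(sense_a: str, sense_b: str, bp_a: int, bp_b: int, max_shift=50):
    """Number of alternative junction placements producing the same allele,
    minus one — checked by literally rebuilding the allele at each shift."""
    ref = sense_a[: bp_a + 1] + sense_b[bp_b:]
    count = 0
    for t in range(-max_shift, max_shift + 1):
        if t == 0:
            continue
        a2, b2 = bp_a + t, bp_b + t
        if not (0 <= a2 < len(sense_a) and 0 < b2 <= len(sense_b)):
            continue
        if sense_a[: a2 + 1] + sense_b[b2:] == ref:
            count += 1
    return count


def count_fasta_records(path) -> int:
    """Line-scanner record count, independent of any FASTA parser."""
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                n += 1
    return n


def count_gff3_features(path, featuretype: str) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3 and fields[2] == featuretype:
                n += 1
    return n
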