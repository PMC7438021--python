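"""Independent brute-force oracles used only by the test suite.

Deliberately naive re-derivations (own lookup tables, quadratic scans) that
share no code with the implementation they check.
"""

from __future__ import annotations

import itertools

ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
                "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
                "B": "V", "V": "B", "D": "H", "H": "D"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_ORACLE_COMP[c] for c in reversed(seq))


def oracle_mismatches(primer: str, window: str) -> int:
    total = 0
    for p, b in zip(primer, window):
        if b == "N":
            ok = p == "N"
        else:
            ok = b in ORACLE_IUPAC[p]
        total += 0 if ok else 1
    return total


def oracle_scan(
    seq: str, fwd: str, rev: str, max_mm: int, max_product: int
) -> set[tuple]:
    """All-positions/all-strands amplicon enumeration.

    Returns tuples (fwd_start, fwd_end, rev_start, rev_end, product_length,
    fwd_mm, rev_mm, orientation) with 1-based inclusive plus-strand coords.
    """
    n = len(seq)
    hits: set[tuple] = set()
    layouts = [
        ("plus", fwd, oracle_revcomp(rev), True),
        ("minus", rev, oracle_revcomp(fwd), False),
    ]
    for orientation, left, right, left_is_fwd in layouts:
        left_sites = [
            (i, oracle_mismatches(left, seq[i : i + len(left)]))
            for i in range(n - len(left) + 1)
        ]
        right_sites = [
            (j, oracle_mismatches(right, seq[j : j + len(right)]))
            for j in range(n - len(right) + 1)
        ]
        for i, lmm in left_sites:
            if lmm > max_mm:
                continue
            for j, rmm in right_sites:
                if rmm > max_mm:
                    continue
                if j < i + len(left):
                    continue  # primers may not overlap
                product = j + len(right) - i
                if product > max_product:
                    continue
                left_span = (i + 1, i + len(left))
                right_span = (j + 1, j + len(right))
                if left_is_fwd:
                    f_span, r_span, fmm, rmm_ = left_span, right_span, lmm, rmm
                else:
                    f_span, r_span, fmm, rmm_ = right_span, left_span, rmm, lmm
                hits.add((*f_span, *r_span, product, fmm, rmm_, orientation))
    return hits


def oracle_motif_positions(protein: str, elements: list[str]) -> list[int]:
    """Full-expansion substring search: expand the motif to all words, find each.

    Only feasible for motifs with a small expansion set (wildcard X positions
    multiply the word count by 20 each); use the position-wise scan otherwise.
    """
    words = {"".join(w) for w in itertools.product(*elements)}
    positions = set()
    for word in words:
        start = protein.find(word)
        while start != -1:
            positions.add(start + 1)
            start = protein.find(word, start + 1)
    return sorted(positions)


def oracle_motif_positions_scan(protein: str, elements: list[str]) -> list[int]:
    """Position-wise brute force: check every start against every motif column."""
    width = len(elements)
    return [
        i + 1
        for i in range(len(protein) - width + 1)
        if all(protein[i + k] in elements[k] for k in range(width))
    ]


def oracle_mask(rows: dict[str, str], max_gap_fraction: float, min_block: int) -> list[int]:
    """0-based indices of retained columns under the gap/block mask."""
    genomes = list(rows)
    width = len(rows[genomes[0]])
    keep = [
        sum(rows[g][j] == "-" for g in genomes) / len(genomes) <= max_gap_fraction
        for j in range(width)
    ]
    kept, run = [], []
    for j in range(width + 1):
        if j < width and keep[j]:
            run.append(j)
        else:
            if len(run) >= min_block:
                kept.extend(run)
            run = []
    return kept
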