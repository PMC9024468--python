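"""Independent brute-force verifiers used to cross-check the scanner.

``naive_scan`` enumerates, for every start position, every spacer-length
combination allowed by the model and tests each motif by direct string
slicing against fully expanded concrete motif sets.  It shares no code
with the production scanner (which joins precomputed motif occurrence
lists), so agreement between the two is a meaningful check.
"""

from __future__ import annotations

from stwintron.models import StwintronSearchModel, expand_iupac


def _concrete_sets(model: StwintronSearchModel) -> list[set[str]]:
    out = []
    for motif in model.motifs():
        alts: set[str] = set()
        for a in motif.alternatives:
            alts |= expand_iupac(a)
        out.append(alts)
    return out


def naive_scan(seq: str, model: StwintronSearchModel) -> set[tuple[int, ...]]:
    """Every (p1..p5) motif placement satisfying the model, by brute force."""
    seq = seq.upper()
    motifs = model.motifs()
    lengths = [m.length for m in motifs]
    ranges = model.spacer_ranges()
    sets = _concrete_sets(model)
    n = len(seq)
    found: set[tuple[int, ...]] = set()
    for p1 in range(n):
        if seq[p1 : p1 + lengths[0]] not in sets[0]:
            continue
        for s1 in range(ranges[0][0], ranges[0][1] + 1):
            p2 = p1 + lengths[0] + s1
            if seq[p2 : p2 + lengths[1]] not in sets[1]:
                continue
            for s2 in range(ranges[1][0], ranges[1][1] + 1):
                p3 = p2 + lengths[1] + s2
                if seq[p3 : p3 + lengths[2]] not in sets[2]:
                    continue
                for s3 in range(ranges[2][0], ranges[2][1] + 1):
                    p4 = p3 + lengths[2] + s3
                    if seq[p4 : p4 + lengths[3]] not in sets[3]:
                        continue
                    for s4 in range(ranges[3][0], ranges[3][1] + 1):
                        p5 = p4 + lengths[3] + s4
                        if seq[p5 : p5 + lengths[4]] not in sets[4]:
                            continue
                        if "N" in seq[p1 : p5 + lengths[4]]:
                            continue
                        found.add((p1, p2, p3, p4, p5))
    return found


def placements_of(candidates) -> set[tuple[int, ...]]:
    """Convert scanner candidates to (p1..p5) placement tuples."""
    out = set()
    for c in candidates:
        out.add(tuple(c.start + s for _, s, _ in c.motif_spans))
    return out


def brute_force_palindromes(seq: str, min_len: int) -> bool:
    """Whether any window of seq equals its own reverse complement (len >= min_len)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def rc(s: str) -> str:
        return "".join(comp[c] for c in reversed(s))

    n = len(seq)
    for length in range(min_len, n + 1):
        for i in range(n - length + 1):
            w = seq[i : i + length]
            if all(c in comp for c in w) and w == rc(w):
                return True
    return False
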