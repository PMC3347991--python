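"""Independent brute-force oracles used to cross-check the package."""

from functools import lru_cache

from mirkit.folding import CANONICAL_PAIRS, energy_of
from mirkit.seqio import revcomp


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """All nested structures (as pair tuples) with canonical pairs only."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def structs(i: int, j: int):
        if i > j:
            return [()]
        out = list(structs(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            if (seq[i], seq[k]) in CANONICAL_PAIRS:
                for left in structs(i + 1, k - 1):
                    for right in structs(k + 1, j):
                        out.append(((i, k),) + left + right)
        return out

    return structs(0, n - 1)


def count_structures(seq: str, min_hairpin: int = 3) -> int:
    n = len(seq)

    @lru_cache(maxsize=None)
    def count(i: int, j: int) -> int:
        if i > j:
            return 1
        total = count(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if (seq[i], seq[k]) in CANONICAL_PAIRS:
                total += count(i + 1, k - 1) * count(k + 1, j)
        return total

    return count(0, n - 1)


def to_dotbracket(pairs, n: int) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def brute_force_mfe(seq: str, params=None) -> float:
    """Minimum energy over exhaustive enumeration, scored with energy_of."""
    best = 0.0  # the open chain
    for pairs in enumerate_structures(seq):
        e = energy_of(seq, to_dotbracket(pairs, len(seq)), params)
        if e < best:
            best = e
    return best


def naive_hits(transcript, reference, max_mismatch: int):
    """Every full-length ungapped placement on both strands, by direct scan.

    Returns a set of (mirna_id, plus_strand_start, strand, mismatches).
    """
    found = set()
    n = len(transcript.sequence)
    for ref in reference:
        L = len(ref.mature)
        for strand, s in (("+", transcript.sequence), ("-", revcomp(transcript.sequence))):
            for st in range(n - L + 1):
                mm = sum(1 for a, b in zip(s[st : st + L], ref.mature) if a != b)
                if mm <= max_mismatch:
                    plus = st if strand == "+" else n - st - L
                    found.add((ref.id, plus, strand, mm))
    return found
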