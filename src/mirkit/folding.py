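"""Minimum-free-energy RNA secondary structure prediction.

A Zuker-style dynamic program over a simplified nearest-neighbor model:
stacking energies for the canonical stacks plus length-dependent penalties
for hairpin/bulge/internal loops and an affine multiloop cost. The parameter
table is packaged as YAML and swappable. No dangles, no coaxial stacking, no
special tetraloops; lonely pairs are allowed; minimum hairpin loop is 3 nt.
Only the single MFE structure is reported.

Deterministic tie-breaking: during traceback a paired position is preferred
over an unpaired one at the leftmost point of divergence, then the smallest
pairing partner.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from ._zuker import INF, fill_matrices

BASES = "ACGU"
_ENC = {b: i for i, b in enumerate(BASES)}
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

MIN_FOLD_LEN = 10
MAX_FOLD_LEN = 1000
_EPS = 1e-6


def _can_matrix() -> np.ndarray:
    can = np.zeros((4, 4), dtype=np.bool_)
    for a, b in CANONICAL_PAIRS:
        can[_ENC[a], _ENC[b]] = True
    return can


_CAN = _can_matrix()


class EnergyParams:
    """A loaded nearest-neighbor parameter table."""

    def __init__(self, data: dict, max_len: int = MAX_FOLD_LEN + 2):
        self.min_hairpin = int(data["min_hairpin"])
        ml = data["multiloop"]
        self.ml_close = float(ml["closing"])
        self.ml_branch = float(ml["branch"])
        self.ml_unpaired = float(ml["unpaired"])
        coef = float(data["extrapolation_coef"])
        self.stack4 = np.full((4, 4, 4, 4), INF)
        for outer, inners in data["stack"].items():
            o1, o2 = _ENC[outer[0]], _ENC[outer[1]]
            for inner, e in inners.items():
                self.stack4[o1, o2, _ENC[inner[0]], _ENC[inner[1]]] = float(e)
        self.hairpin = self._loop_array(data["hairpin"], coef, max_len)
        self.bulge = self._loop_array(data["bulge"], coef, max_len)
        self.internal = self._loop_array(data["internal"], coef, max_len)

    @staticmethod
    def _loop_array(table: dict, coef: float, max_len: int) -> np.ndarray:
        arr = np.full(max_len, INF)
        lmax = max(table)
        for size, e in table.items():
            arr[int(size)] = float(e)
        for size in range(lmax + 1, max_len):
            arr[size] = table[lmax] + coef * math.log(size / lmax)
        return arr

    def stack_energy(self, a: str, b: str, c: str, d: str) -> float:
        e = self.stack4[_ENC[a], _ENC[b], _ENC[c], _ENC[d]]
        if e >= INF:
            raise ValueError(f"no stack energy for {a}{b}/{c}{d}")
        return float(e)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyParams":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "EnergyParams":
        text = resources.files("mirkit.data").joinpath("energy_params.yaml").read_text()
        return cls(yaml.safe_load(text))


@dataclass(frozen=True)
class SecondaryStructure:
    dotbracket: str
    mfe: float
    pairs: tuple[int, ...]  # partner index per position, -1 if unpaired

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j > i)

    @property
    def is_open_chain(self) -> bool:
        return all(p == -1 for p in self.pairs)


def pairs_from_dotbracket(dotbracket: str) -> tuple[int, ...]:
    """Partner array from a dot-bracket string; raises on imbalance."""
    pairs = [-1] * len(dotbracket)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced brackets")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced brackets")
    return tuple(pairs)


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENC[b] for b in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in sequence") from exc


def fold_mfe(
    sequence: str,
    params: EnergyParams | None = None,
    max_interior: int = 30,
) -> SecondaryStructure:
    """Predict the MFE structure of an RNA sequence.

    ``max_interior`` caps the total unpaired length of bulge/internal loops
    considered by the search (30 covers everything reachable for sequences
    up to ~35 nt, so the exhaustive-enumeration cross-check is exact).
    """
    if not MIN_FOLD_LEN <= len(sequence) <= MAX_FOLD_LEN:
        raise ValueError(
            f"sequence length {len(sequence)} outside "
            f"[{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]"
        )
    p = params or EnergyParams.default()
    enc = _encode(sequence)
    V, WM, Wl = fill_matrices(
        enc,
        _CAN,
        p.stack4,
        p.hairpin,
        p.bulge,
        p.internal,
        p.ml_close,
        p.ml_branch,
        p.ml_unpaired,
        p.min_hairpin,
        max_interior,
    )
    pairs = _traceback(enc, p, V, WM, Wl, max_interior)
    db = "".join(
        "(" if pairs[i] > i else ")" if pairs[i] != -1 else "." for i in range(len(pairs))
    )
    mfe = float(Wl[0])
    return SecondaryStructure(dotbracket=db, mfe=0.0 if abs(mfe) < _EPS else mfe, pairs=tuple(pairs))


def _traceback(enc, p: EnergyParams, V, WM, Wl, max_interior: int) -> list[int]:
    n = len(enc)
    pairs = [-1] * n
    min_span = p.min_hairpin + 2
    jobs: list[tuple[str, int, int]] = []
    # exterior loop, left to right, prefer paired
    i = 0
    while i < n:
        placed = False
        for j in range(i + min_span - 1, n):
            if V[i, j] < INF and abs(V[i, j] + Wl[j + 1] - Wl[i]) < _EPS:
                jobs.append(("V", i, j))
                i = j + 1
                placed = True
                break
        if not placed:
            i += 1
    while jobs:
        kind, i, j = jobs.pop()
        if kind == "V":
            pairs[i], pairs[j] = j, i
            target = V[i, j]
            if _trace_two_loop(enc, p, V, i, j, target, max_interior, jobs):
                continue
            if _trace_multi(p, WM, i, j, target, jobs):
                continue
            if abs(p.hairpin[j - i - 1] - target) < _EPS:
                continue
            raise RuntimeError(f"traceback failed at V[{i},{j}]")
        else:  # WM
            target = WM[i, j]
            if abs(V[i, j] + p.ml_branch - target) < _EPS:
                jobs.append(("V", i, j))
                continue
            done = False
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    if abs(WM[i, k - 1] + WM[k, j] - target) < _EPS:
                        jobs.append(("WM", i, k - 1))
                        jobs.append(("WM", k, j))
                        done = True
                        break
            if done:
                continue
            if j > i and abs(WM[i + 1, j] + p.ml_unpaired - target) < _EPS:
                jobs.append(("WM", i + 1, j))
                continue
            if j > i and abs(WM[i, j - 1] + p.ml_unpaired - target) < _EPS:
                jobs.append(("WM", i, j - 1))
                continue
            raise RuntimeError(f"traceback failed at WM[{i},{j}]")
    return pairs


def _trace_two_loop(enc, p, V, i, j, target, max_interior, jobs) -> bool:
    kmax = min(j - 1, i + max_interior + 1)
    for k in range(i + 1, kmax + 1):
        s1 = k - i - 1
        lmin = max(k + p.min_hairpin + 1, j - 1 - (max_interior - s1))
        for l in range(j - 1, lmin - 1, -1):
            if V[k, l] >= INF:
                continue
            s2 = j - l - 1
            if s1 == 0 and s2 == 0:
                e = p.stack4[enc[i], enc[j], enc[k], enc[l]]
            elif s1 == 0 or s2 == 0:
                e = p.bulge[s1 + s2]
            else:
                e = p.internal[s1 + s2]
            if abs(e + V[k, l] - target) < _EPS:
                jobs.append(("V", k, l))
                return True
    return False


def _trace_multi(p, WM, i, j, target, jobs) -> bool:
    for k in range(i + 2, j - 2):
        if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
            cand = p.ml_close + p.ml_branch + WM[i + 1, k] + WM[k + 1, j - 1]
            if abs(cand - target) < _EPS:
                jobs.append(("WM", i + 1, k))
                jobs.append(("WM", k + 1, j - 1))
                return True
    return False


def energy_of(
    sequence: str, dotbracket: str, params: EnergyParams | None = None
) -> float:
    """Total nearest-neighbor energy of exactly the given structure.

    Independent loop-decomposition scorer used both to re-score external
    structures and as part of the enumeration cross-check of :func:`fold_mfe`.
    """
    p = params or EnergyParams.default()
    if len(sequence) != len(dotbracket):
        raise ValueError("sequence/structure length mismatch")
    pairs = pairs_from_dotbracket(dotbracket)
    for i, j in enumerate(pairs):
        if j > i:
            if (sequence[i], sequence[j]) not in CANONICAL_PAIRS:
                raise ValueError(f"non-canonical pair {sequence[i]}:{sequence[j]} at ({i},{j})")
            if j - i - 1 < p.min_hairpin and all(
                pairs[k] == -1 for k in range(i + 1, j)
            ):
                raise ValueError(f"hairpin loop shorter than {p.min_hairpin} at ({i},{j})")
    total = 0.0
    for i, j in enumerate(pairs):
        if j <= i:
            continue
        children = _direct_children(pairs, i, j)
        if not children:
            total += p.hairpin[j - i - 1]
        elif len(children) == 1:
            (k, l), = children
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                total += p.stack_energy(sequence[i], sequence[j], sequence[k], sequence[l])
            elif s1 == 0 or s2 == 0:
                total += p.bulge[s1 + s2]
            else:
                total += p.internal[s1 + s2]
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += (
                p.ml_close
                + p.ml_branch * (len(children) + 1)
                + p.ml_unpaired * unpaired
            )
    return total


def _direct_children(pairs, i: int, j: int) -> list[tuple[int, int]]:
    children = []
    k = i + 1
    while k < j:
        if pairs[k] > k:
            children.append((k, pairs[k]))
            k = pairs[k] + 1
        else:
            k += 1
    return children


_VIENNA_RE = re.compile(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_external_fold(text: str) -> tuple[str, SecondaryStructure]:
    """Parse Vienna-dialect fold output: ``sequence\\nstructure (energy)``.

    A leading ``>name`` header line is tolerated. Returns the sequence and
    the parsed structure; brackets must balance and pair the sequence
    canonically.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise ValueError("expected sequence and structure lines")
    sequence = lines[0].upper().replace("T", "U")
    m = _VIENNA_RE.match(lines[1])
    if not m:
        raise ValueError(f"cannot parse structure line {lines[1]!r}")
    dotbracket, mfe = m.group(1), float(m.group(2))
    if len(dotbracket) != len(sequence):
        raise ValueError("sequence/structure length mismatch")
    pairs = pairs_from_dotbracket(dotbracket)
    for i, j in enumerate(pairs):
        if j > i and (sequence[i], sequence[j]) not in CANONICAL_PAIRS:
            raise ValueError(f"non-canonical pair at ({i},{j})")
    return sequence, SecondaryStructure(dotbracket=dotbracket, mfe=mfe, pairs=pairs)
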