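"""RNA secondary-structure prediction for hairpin screening.

The default backend is a base-pair-maximization (Nussinov-style) folder with
a deliberately simple, clearly non-Turner energy assignment: -3 kcal/mol per
G:C pair, -2 per A:U, -1 per G:U, no loop terms.  It is deterministic,
dependency-free, and exactly testable against brute-force enumeration.  The
default -40 kcal/mol precursor threshold in :class:`~plantsrna.config.RunConfig`
is calibrated for this model.  An external thermodynamic backend (``RNAfold``
from the ViennaRNA suite, if present on PATH) can be selected per call for
Turner-model energies.

Pairing rules: Watson-Crick (A:U, G:C) plus the G:U wobble; minimum hairpin
loop of 3 unpaired nucleotides.
"""

from __future__ import annotations

import shutil
import subprocess

import numpy as np
from numba import njit

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4, "T": 3}

# symmetric pair energy table; 0 = not pairable
_PAIR_E = np.zeros((5, 5), dtype=np.int8)
_PAIR_E[0, 3] = _PAIR_E[3, 0] = 2   # A:U
_PAIR_E[1, 2] = _PAIR_E[2, 1] = 3   # C:G
_PAIR_E[2, 3] = _PAIR_E[3, 2] = 1   # G:U

MIN_LOOP = 3  # unpaired nt enclosed by a closing pair


def encode(seq: str) -> np.ndarray:
    return np.array([_ENC[c] for c in seq.upper()], dtype=np.int8)


# Lexicographic objective: _BIG * (#pairs) + secondary weight, where the
# secondary weight is the summed pair energies plus _STACK per stacked pair.
# The primary objective is exactly base-pair maximization; ties resolve
# toward Watson-Crick-rich contiguous helices, which is what thermodynamic
# folding would produce for a miRNA duplex.
_BIG = 8192
_STACK = 4


@njit(cache=False)
def _fill(enc, pair_e, min_loop):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    M = np.zeros((n, n), dtype=np.int32)   # best over all structures on i..j
    C = np.full((n, n), -1, dtype=np.int32)  # best with (i,j) paired
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            w = pair_e[enc[i], enc[j]]
            if w > 0 and j - i > min_loop:
                inner = 0
                if j - 1 >= i + 1:
                    inner = M[i + 1, j - 1]
                    if C[i + 1, j - 1] + _STACK > inner:
                        inner = C[i + 1, j - 1] + _STACK
                C[i, j] = _BIG + w + inner
            best = M[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if C[i, k] >= 0:
                    v = C[i, k]
                    if k + 1 <= j:
                        v += M[k + 1, j]
                    if v > best:
                        best = v
            M[i, j] = best
    return M, C


def _traceback(enc: np.ndarray, M: np.ndarray,
               C: np.ndarray) -> list[tuple[int, int]]:
    """Deterministic traceback; within a closed pair the stacked
    continuation is preferred, reconstructing duplexes contiguously."""
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int, bool]] = [(0, enc.shape[0] - 1, False)]
    while stack:
        i, j, closed = stack.pop()
        while i < j:
            if closed:
                pairs.append((i, j))
                if j - 1 < i + 1:
                    break
                if (C[i + 1, j - 1] >= 0
                        and C[i, j] == _BIG + int(_PAIR_E[enc[i], enc[j]])
                        + C[i + 1, j - 1] + _STACK):
                    i, j = i + 1, j - 1          # stacked continuation
                    continue
                i, j, closed = i + 1, j - 1, False
                continue
            if M[i, j] == M[i + 1, j]:
                i += 1
                continue
            for k in range(j, i + MIN_LOOP, -1):
                if C[i, k] < 0:
                    continue
                v = C[i, k] + (M[k + 1, j] if k + 1 <= j else 0)
                if v == M[i, j]:
                    if k + 1 <= j:
                        stack.append((k + 1, j, False))
                    j, closed = k, True
                    break
            else:
                i += 1
    return pairs


_RNAFOLD_PATH: str | None | bool = False  # False = not looked up yet


def rnafold_available() -> bool:
    global _RNAFOLD_PATH
    if _RNAFOLD_PATH is False:
        _RNAFOLD_PATH = shutil.which("RNAfold")
    return _RNAFOLD_PATH is not None


def fold(sequence: str, backend: str = "auto") -> tuple[str, float]:
    """Fold a sequence; return (dot-bracket structure, energy in kcal/mol).

    ``backend="auto"`` uses the thermodynamic ``RNAfold`` binary when it is
    on PATH (faithful Turner-model stems) and the internal pair-maximization
    folder otherwise.  With fewer than 3 achievable pairs the sequence is
    reported hairpin-free (all dots, energy 0).
    """
    if backend == "auto":
        backend = "rnafold" if rnafold_available() else "nussinov"
    if backend == "rnafold":
        return fold_rnafold(sequence)
    if backend != "nussinov":
        raise ValueError(f"unknown folding backend {backend!r}")
    n = len(sequence)
    if n < MIN_LOOP + 2:
        return "." * n, 0.0
    enc = encode(sequence)
    M, C = _fill(enc, _PAIR_E, MIN_LOOP)
    if M[0, n - 1] // _BIG < 3:
        return "." * n, 0.0
    pairs = _traceback(enc, M, C)
    structure = ["."] * n
    energy = 0.0
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
        energy -= float(_PAIR_E[enc[i], enc[j]])
    return "".join(structure), energy


def max_pairs(sequence: str) -> int:
    """Maximum number of nested base pairs (the folder's objective)."""
    n = len(sequence)
    if n < MIN_LOOP + 2:
        return 0
    enc = encode(sequence)
    return int(_fill(enc, _PAIR_E, MIN_LOOP)[0][0, n - 1]) // _BIG


def partner_map(structure: str) -> list[int]:
    """Dot-bracket -> partner index per position (-1 if unpaired)."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            partner[i] = j
            partner[j] = i
    if stack:
        raise ValueError("unbalanced structure")
    return partner


def fold_rnafold(sequence: str) -> tuple[str, float]:
    """Fold with the external ViennaRNA ``RNAfold`` binary (Turner model)."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold not found on PATH")
    out = subprocess.run(
        [exe, "--noPS"], input=sequence + "\n", text=True,
        capture_output=True, check=True,
    ).stdout.splitlines()
    structure, _, tail = out[1].partition(" ")
    energy = float(tail.strip().strip("()"))
    return structure, energy
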