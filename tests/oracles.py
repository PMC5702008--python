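"""Independent reference implementations used only to cross-check the package.

The local-alignment oracle enumerates every local alignment path explicitly
(exponential, usable for sequences up to ~8 residues) with affine gap costs,
sharing no code with the dynamic-programming implementation under test.
"""
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best local alignment score by exhaustive path enumeration."""

    def extend(i: int, j: int, last: str | None) -> float:
        best = 0.0  # stopping here is always allowed (local alignment)
        if i < len(a) and j < len(b):
            pair = 0.0 if "X" in (a[i], b[j]) else float(_BLOSUM62[a[i], b[j]])
            best = max(best, pair + extend(i + 1, j + 1, "M"))
        if j < len(b):
            cost = gap_extend if last == "E" else gap_open + gap_extend
            best = max(best, -cost + extend(i, j + 1, "E"))
        if i < len(a):
            cost = gap_extend if last == "F" else gap_open + gap_extend
            best = max(best, -cost + extend(i + 1, j, "F"))
        return best

    return int(
        max(
            extend(i0, j0, None)
            for i0 in range(len(a))
            for j0 in range(len(b))
        )
    )
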