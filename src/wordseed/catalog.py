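"""Catalog of designed low-dispersion word sets and subset-seed patterns.

The word sets below are written over the binary ry alphabet (r = purine,
y = pyrimidine) and minimize a variance-to-mean ratio at their sparsity and
word length; applied to DNA, each ry word stands for the 2**k DNA words
obtained by expanding r to {a, g} and y to {c, t}.  Sparsity is the
reciprocal of the per-position occurrence probability: a sparsity-4 set of
length-k ry words has 2**k / 4 members.

The seed patterns are transition-tolerant subset-seed patterns anchored on
an ry or ryy word prefix, one per integer weight from 5 to 14.  They were
designed externally for detecting homologs at PAM distance 20 with
transition/transversion ratio 3, and are shipped here as a ready-to-use
library; this package evaluates patterns (sparsity, weight, matching) but
does not design them.
"""

from __future__ import annotations

__all__ = [
    "LOW_VMR_WORD_SETS",
    "MINIMIZER_COMPARISON_WORDS",
    "RY_SEED_PATTERNS",
    "RYY_SEED_PATTERNS",
]

#: Minimal-VMR ry word sets, keyed by (sparsity, word length).
#: At sparsity 4 the VMR1-optimal sets up to k=6; at sparsity 8 up to k=8.
LOW_VMR_WORD_SETS: dict[tuple[int, int], tuple[str, ...]] = {
    (4, 2): ("ry",),
    (4, 3): ("ryr", "ryy"),  # = ryn
    (4, 4): ("rrry", "ryrr", "ryyr", "yyyr"),
    (4, 5): (
        "rrrry", "rryrr", "ryryr", "ryyrr",
        "ryyry", "ryyyy", "yyyrr", "yyyry",
    ),
    (4, 6): (
        "rrrrry", "rryrry", "rryryy", "ryrrrr",
        "ryrrry", "ryryry", "ryyrrr", "ryyrry",
        "ryyryr", "ryyryy", "ryyyry", "ryyyyy",
        "yryrry", "yyyrrr", "yyyrry", "yyyyry",
    ),
    (8, 3): ("ryy",),
    (8, 5): ("rrrry", "yrrry", "yrryy", "yryyy"),
    (8, 6): (
        "rrrrry", "yrrrry", "yrrryr", "yrrryy",
        "yrryry", "yrryyy", "yyryry", "yyryyy",
    ),
    (8, 7): (
        "rrryrrr", "rrryryr", "rryrryr", "rryyrrr",
        "rryyrry", "rryyryr", "rryyyrr", "rryyyyr",
        "ryryyrr", "ryyyryr", "ryyyyyr", "ryyyyyy",
        "yryyryr", "yryyyrr", "yryyyyr", "yyryyrr",
    ),
    (8, 8): (
        "rrrrrrry", "rryrrryy", "ryrrrryr", "ryrrrryy",
        "ryrrryry", "yrrrrrry", "yrrrrryr", "yrrrrryy",
        "yrrryrry", "yrryrryr", "yrryrryy", "yryrrryy",
        "yryrryry", "yryrryyr", "yryrryyy", "yryryryy",
        "yyrrrryr", "yyrrrryy", "yyrrryry", "yyrrryyr",
        "yyrrryyy", "yyrryryr", "yyrryryy", "yyrryyry",
        "yyrryyyr", "yyrryyyy", "yyryryyr", "yyryryyy",
        "yyryyryy", "yyyryyyr", "yyyryyyy", "yyyyyyyr",
    ),
}

#: Twelve length-6 ry words minimizing VMR2 (density 12/2**6 = 0.1875),
#: chosen to match the density of a w=10 hash minimizer scheme for
#: like-for-like comparisons against minimap-style seeding.
MINIMIZER_COMPARISON_WORDS: tuple[str, ...] = (
    "rrrrry", "rryrrr", "rryrry", "rryyrr",
    "rryyry", "ryryrr", "ryyyrr", "ryyyry",
    "ryyyyr", "yryyrr", "yryyry", "yyyyyr",
)

#: ry-anchored subset-seed patterns (sparsity 4), keyed by weight.
RY_SEED_PATTERNS: dict[int, str] = {
    5: "RYNN@@",
    6: "RY@@@@NN",
    7: "RYN@@@@NN",
    8: "RYN@@@@NNN",
    9: "RYN@@@@@@NNN",
    10: "RYN@@@nnNN@@@NN",
    11: "RYN@@@nnNN@@@NNN",
    12: "RYN@@@@NNnn@@@@NNN",
    13: "RYN@@@@NN@nn@@@NNNN",
    14: "RYN@@@@NN@nn@@@@NNNN@",
}

#: ryy-anchored subset-seed patterns (sparsity 8), keyed by weight.
RYY_SEED_PATTERNS: dict[int, str] = {
    5: "RYY@@@@",
    6: "RYYN@@@@",
    7: "RYYN@@@@@@",
    8: "RYYNN@@@@@@",
    9: "RYY@@@@@@@@NN",
    10: "RYY@@@@@@@@NNN",
    11: "RYYN@@@@@@@@NNN",
    12: "RYYN@@@@@@@@@@NNN",
    13: "RYYN@@@@@@@@@@NNNN",
    14: "RYYN@@@@@@@@@@NNNNN",
}
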