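"""File formats: FASTA sequences, plain-text word lists, fixture generation.

Word lists are one word per line; blank lines and lines starting with '#'
are ignored.  FASTA goes through Biopython.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DNA, RY, Alphabet
from .catalog import (
    LOW_VMR_WORD_SETS,
    MINIMIZER_COMPARISON_WORDS,
    RY_SEED_PATTERNS,
    RYY_SEED_PATTERNS,
)
from .words import WordSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_word_list",
    "write_word_list",
    "read_word_set",
    "generate_fixtures",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences from a FASTA file (order-preserving dict)."""
    path = Path(path)
    records = {}
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records[rec.id] = str(rec.seq).lower()
    if not records:
        warnings.warn(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_word_list(path: str | Path) -> tuple[str, ...]:
    """Words from a plain-text file, one per line; '#' lines are comments."""
    words = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line.lower())
    return tuple(words)


def write_word_list(words, path: str | Path, header: str | None = None) -> None:
    lines = [f"# {header}"] if header else []
    lines.extend(words)
    Path(path).write_text("\n".join(lines) + "\n")


def read_word_set(path: str | Path, alphabet: Alphabet | None = None) -> WordSet:
    """Word set from a word-list file; the alphabet is inferred from the
    letters used (ry -> binary, otherwise DNA) unless given."""
    words = read_word_list(path)
    if alphabet is None:
        letters = set("".join(words))
        alphabet = RY if letters <= {"r", "y"} else DNA
    return WordSet(words, alphabet)


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> Path:
    """Deterministically write the test fixtures: catalog word sets, the
    pattern library with design weights, small random DNA, and a
    hand-constructed pair carrying one conserved ry-prefixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (spars, k), words in sorted(LOW_VMR_WORD_SETS.items()):
        write_word_list(
            words, out / f"min_vmr_s{spars}_k{k}.txt", header=f"sparsity {spars}, k={k}"
        )
    write_word_list(
        MINIMIZER_COMPARISON_WORDS,
        out / "minimizer_comparison_k6.txt",
        header="12 length-6 ry words, density 0.1875",
    )
    lines = ["# block\tweight\tpattern"]
    for weight, pat in sorted(RY_SEED_PATTERNS.items()):
        lines.append(f"ry\t{weight}\t{pat}")
    for weight, pat in sorted(RYY_SEED_PATTERNS.items()):
        lines.append(f"ryy\t{weight}\t{pat}")
    (out / "seed_patterns.tsv").write_text("\n".join(lines) + "\n")

    rng = np.random.default_rng(seed)
    letters = np.array(list("acgt"))
    seqs = {
        f"random{i}": "".join(rng.choice(letters, size=2000)) for i in range(2)
    }
    write_fasta(seqs, out / "random_dna.fasta")

    # a pair differing everywhere except a conserved ry-prefixed 8-mer at 17
    core = "acgtacgt"  # starts with "ac" = an ry word
    offset = 17
    a = "".join(rng.choice(letters, size=60))
    swap = {"a": "c", "c": "a", "g": "t", "t": "g"}  # transversions: never matches
    b = "".join(swap[c] for c in a)
    a = a[:offset] + core + a[offset + len(core) :]
    b = b[:offset] + core + b[offset + len(core) :]
    write_fasta({"pair/1": a, "pair/2": b}, out / "conserved_pair.fasta")
    return out
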