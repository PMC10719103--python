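"""Error-robust MERFISH barcode codebooks.

A MERFISH codebook is a set of fixed-length binary words with constant
Hamming weight 4 and pairwise Hamming distance >= 4, so that any single bit
error can be detected and corrected.  A maximum-size such code on ``n``
bits is equivalent to a Steiner quadruple system SQS(n) — a family of
4-subsets of ``n`` points covering every 3-subset exactly once — and has
exactly ``C(n, 3) / 4`` words.  We build it with the classical doubling
construction: SQS(2n) is assembled from two relabeled copies of SQS(n)
plus cross blocks that pair same-index one-factors of the complete graph
on each copy.

Words not assigned to genes are kept as "blank" barcodes; counts decoded
to blanks measure the false-positive rate of a MERFISH experiment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np


Word = frozenset  # a codeword as the set of its "1" bit positions


def _round_robin_one_factorization(n: int) -> list[list[tuple[int, int]]]:
    """One-factorization of the complete graph K_n (n even) by the circle method.

    Returns ``n - 1`` factors, each a perfect matching of ``n`` points.
    Point ``n - 1`` is fixed; the others rotate.
    """
    if n % 2:
        raise ValueError("one-factorization requires an even number of points")
    factors = []
    for r in range(n - 1):
        factor = [(r, n - 1)]
        for i in range(1, n // 2):
            a = (r + i) % (n - 1)
            b = (r - i) % (n - 1)
            factor.append((min(a, b), max(a, b)))
        factors.append(sorted(factor))
    return factors


def build_max_codebook(n_bits: int) -> set[Word]:
    """Maximum constant-weight-4, minimum-distance-4 code on ``n_bits`` bits.

    ``n_bits`` must be a power of two >= 4.  The result has
    ``C(n_bits, 3) / 4`` words (the Steiner quadruple system bound); every
    3-subset of bit positions is contained in exactly one word.
    """
    if n_bits < 4 or n_bits & (n_bits - 1):
        raise ValueError(f"n_bits must be a power of two >= 4, got {n_bits}")
    if n_bits == 4:
        return {frozenset({0, 1, 2, 3})}
    half = n_bits // 2
    sub = build_max_codebook(half)
    blocks: set[Word] = set(sub)
    blocks |= {frozenset(p + half for p in w) for w in sub}
    # cross blocks: same-index one-factors of K_half on each copy
    for factor in _round_robin_one_factorization(half):
        for a, b in factor:
            for c, d in factor:
                blocks.add(frozenset({a, b, c + half, d + half}))
    assert len(blocks) == comb(n_bits, 3) // 4
    return blocks


def word_to_bits(word: Word, n_bits: int) -> str:
    """Render a word as a bit string, MSB = bit 1."""
    return "".join("1" if i in word else "0" for i in range(n_bits))


def hamming_distance(a: Word, b: Word) -> int:
    return len(a ^ b)


@dataclass
class Codebook:
    """Named barcode assignment over a fixed-length binary code."""

    entries: dict[str, Word]
    n_bits: int
    weight: int = 4
    min_distance: int = 4

    @property
    def blank_names(self) -> list[str]:
        return [n for n in self.entries if n.startswith("Blank-")]

    @property
    def gene_names(self) -> list[str]:
        return [n for n in self.entries if not n.startswith("Blank-")]

    def to_csv(self, path: str | Path) -> None:
        lines = [f"# n_bits={self.n_bits}, weight={self.weight}, min_distance={self.min_distance}"]
        lines.append("name,barcode")
        for name, word in self.entries.items():
            lines.append(f"{name},{word_to_bits(word, self.n_bits)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Codebook":
        lines = Path(path).read_text().splitlines()
        header = lines[0].lstrip("# ").replace(" ", "")
        meta = dict(kv.split("=") for kv in header.split(","))
        entries = {}
        for line in lines[2:]:
            name, bits = line.split(",")
            entries[name] = frozenset(i for i, b in enumerate(bits) if b == "1")
        return cls(entries=entries, n_bits=int(meta["n_bits"]),
                   weight=int(meta["weight"]), min_distance=int(meta["min_distance"]))


def verify_codebook(codebook: Codebook | set[Word], n_bits: int | None = None,
                    weight: int = 4, min_distance: int = 4) -> dict:
    """Exhaustively check weight and pairwise-distance invariants.

    Violations are reported, not raised.  O(size^2), fine up to a few
    thousand words.
    """
    if isinstance(codebook, Codebook):
        words = list(codebook.entries.values())
        weight, min_distance = codebook.weight, codebook.min_distance
    else:
        words = list(codebook)
    if not words:
        raise ValueError("empty codebook")
    weight_ok = all(len(w) == weight for w in words)
    min_pairwise = min(
        (hamming_distance(a, b) for a, b in itertools.combinations(words, 2)),
        default=2 * weight,
    )
    return {
        "weight_ok": weight_ok,
        "distance_ok": min_pairwise >= min_distance,
        "min_pairwise_distance": min_pairwise,
        "size": len(words),
    }


def _canonical_order(words: set[Word], n_bits: int) -> list[Word]:
    return sorted(words, key=lambda w: word_to_bits(w, n_bits))


def assign_barcodes(genes: list[str], words: set[Word], seed: int = 0,
                    n_bits: int | None = None) -> Codebook:
    """Assign each gene a distinct word at random; leftovers become blanks.

    Blanks are named ``Blank-1..Blank-k`` in canonical word order.  Raises
    a capacity error when there are more genes than words.
    """
    if len(set(genes)) != len(genes):
        raise ValueError("gene names must be unique")
    if len(genes) > len(words):
        raise ValueError(
            f"capacity exceeded: {len(genes)} genes but only {len(words)} barcodes"
        )
    if n_bits is None:
        n_bits = max((max(w) for w in words if w), default=0) + 1
    ordered = _canonical_order(words, n_bits)
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(ordered), size=len(genes), replace=False)
    entries = {g: ordered[i] for g, i in zip(genes, picks)}
    picked = set(int(i) for i in picks)
    leftovers = [w for i, w in enumerate(ordered) if i not in picked]
    for k, w in enumerate(leftovers, start=1):
        entries[f"Blank-{k}"] = w
    return Codebook(entries=entries, n_bits=n_bits)


def reassign_from_blanks(codebook: Codebook, new_genes: list[str], seed: int = 0) -> Codebook:
    """Give late-added genes barcodes drawn at random from the blank pool."""
    blanks = codebook.blank_names
    if len(new_genes) > len(blanks):
        raise ValueError(
            f"capacity exceeded: {len(new_genes)} new genes but only {len(blanks)} blanks"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(blanks), size=len(new_genes), replace=False)
    entries = dict(codebook.entries)
    for gene, i in zip(new_genes, picked):
        entries[gene] = entries.pop(blanks[i])
    # renumber remaining blanks in canonical order
    remaining = sorted(
        (w for n, w in entries.items() if n.startswith("Blank-")),
        key=lambda w: word_to_bits(w, codebook.n_bits),
    )
    entries = {n: w for n, w in entries.items() if not n.startswith("Blank-")}
    for k, w in enumerate(remaining, start=1):
        entries[f"Blank-{k}"] = w
    return Codebook(entries=entries, n_bits=codebook.n_bits,
                    weight=codebook.weight, min_distance=codebook.min_distance)
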