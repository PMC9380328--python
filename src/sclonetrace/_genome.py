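"""Synthetic genome coordinate model: 22 autosomes + X, hg19-like sizes.

Coordinates are 0-based half-open internally; user-facing tables that need
1-based inclusive positions convert at the I/O boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Length of the circular mitochondrial reference (rCRS-style, 1-based sites).
MT_GENOME_LENGTH = 16_569

#: Approximate hg19 chromosome lengths, megabases -> bp.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 103_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000, "X": 155_000_000,
}

_CHROM_ORDER = {c: i for i, c in enumerate(
    [str(i) for i in range(1, 23)] + ["X", "Y", "MT"])}


def chrom_sort_key(chrom: str) -> int:
    """Natural chromosome order 1..22, X, Y, MT; unknown names sort last."""
    c = chrom.removeprefix("chr")
    return _CHROM_ORDER.get(c, len(_CHROM_ORDER))


def order_genes(var: pd.DataFrame) -> pd.Index:
    """Index of ``var`` (chrom/start/end columns) sorted by genome position."""
    key = var["chrom"].map(chrom_sort_key)
    order = np.lexsort((var["start"].to_numpy(), key.to_numpy()))
    return var.index[order]


def place_genes(n_genes: int, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Spread ``n_genes`` across chromosomes proportionally to length.

    Genes are evenly spaced within each chromosome; each gene spans half the
    inter-gene spacing. Returns a DataFrame indexed by gene id with columns
    ``chrom``, ``start``, ``end`` (0-based half-open).
    """
    if n_genes < len(chrom_lengths):
        raise ValueError(
            f"n_genes={n_genes} is fewer than {len(chrom_lengths)} chromosomes")
    total = sum(chrom_lengths.values())
    raw = {c: n_genes * ln / total for c, ln in chrom_lengths.items()}
    counts = {c: max(1, int(np.floor(x))) for c, x in raw.items()}
    # largest-remainder top-up to hit n_genes exactly
    remainder = sorted(chrom_lengths, key=lambda c: raw[c] - np.floor(raw[c]),
                       reverse=True)
    i = 0
    while sum(counts.values()) < n_genes:
        counts[remainder[i % len(remainder)]] += 1
        i += 1
    while sum(counts.values()) > n_genes:
        c = remainder[-1 - (i % len(remainder))]
        if counts[c] > 1:
            counts[c] -= 1
        i += 1

    rows = []
    for chrom in chrom_lengths:
        n = counts[chrom]
        spacing = chrom_lengths[chrom] // (n + 1)
        for j in range(n):
            start = spacing * (j + 1)
            rows.append((chrom, start, start + max(spacing // 2, 1)))
    var = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    var.index = pd.Index(
        [f"GENE{i:05d}" for i in range(len(var))], name="gene_id")
    return var
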