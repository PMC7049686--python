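"""Sequence encoding and file I/O shared by every stage.

Conventions, fixed across the package:

* coordinates are BED-style 0-based half-open;
* one-hot base order is A, C, G, T (so reverse complementing a one-hot
  matrix is a flip of both axes);
* regression targets are ``log(RPKM + pseudocount)`` with natural log and
  pseudocount 1 by default.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "GenomicRegion",
    "LabelledExample",
    "ReadIndex",
    "one_hot_encode",
    "one_hot_decode",
    "reverse_complement",
    "read_regions",
    "read_tables",
    "read_read_positions",
]


@dataclass
class GenomicRegion:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str = "+"
    identifier: str = ""
    sequence: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.identifier}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"region {self.identifier}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LabelledExample:
    region: GenomicRegion
    class_label: str
    regression_targets: np.ndarray  # per-replicate log-RPKM
    onehot: np.ndarray | None = None


def one_hot_encode(seq: str, target_length: int) -> np.ndarray:
    """Encode a DNA string as a 4 x target_length binary matrix.

    The sequence is centred: shorter sequences are symmetrically zero-padded
    (one extra base of padding on the right for odd remainders); longer ones
    are centre-cropped.  ``N`` and any other non-ACGT character becomes an
    all-zero column.
    """
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    seq = seq.upper()
    L = target_length
    if len(seq) > L:
        off = (len(seq) - L) // 2
        seq = seq[off:off + L]
        pad_left = 0
    else:
        pad_left = (L - len(seq)) // 2
    mat = np.zeros((4, L), dtype=np.float64)
    for i, base in enumerate(seq):
        j = _BASE_INDEX.get(base)
        if j is not None:
            mat[j, pad_left + i] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for the retained subsequence:
    unit columns map back to bases, zero columns to ``N`` (padding at the
    two ends is stripped)."""
    sums = mat.sum(axis=0)
    nz = np.nonzero(sums)[0]
    if nz.size == 0:
        return ""
    chars = []
    for i in range(nz[0], nz[-1] + 1):
        chars.append(BASES[int(mat[:, i].argmax())] if sums[i] > 0 else "N")
    return "".join(chars)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A, C, G, T, N} alphabet."""
    s = seq.upper()
    if any(c not in "ACGTN" for c in s):
        bad = sorted({c for c in s if c not in "ACGTN"})
        raise ValueError(f"unexpected characters in sequence: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def read_regions(bed_path: str | Path, fasta_path: str | Path) -> list[GenomicRegion]:
    """Load BED intervals and attach their sequences from a FASTA.

    Minus-strand regions are reverse complemented.  Out-of-bounds intervals
    and unknown contigs raise.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    regions: list[GenomicRegion] = []
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      usecols=range(6), dtype={"chrom": str, "name": str})
    for row in bed.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in fasta:
            raise KeyError(f"contig {chrom!r} absent from FASTA")
        clen = len(fasta[chrom])
        start, end = int(row.start), int(row.end)
        if start < 0 or end > clen:
            raise ValueError(f"interval {chrom}:{start}-{end} outside contig (len {clen})")
        strand = row.strand if row.strand in ("+", "-") else "+"
        seq = fasta[chrom][start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        name = row.name if isinstance(row.name, str) and row.name else f"{chrom}:{start}-{end}"
        regions.append(GenomicRegion(chrom, start, end, strand, name, seq))
    return regions


def read_tables(rpkm_tsv: str | Path, labels_tsv: str | Path,
                pseudocount: float = 1.0) -> tuple[list[str], list[str], np.ndarray, list[str]]:
    """Join the per-replicate RPKM matrix with per-region class labels.

    Returns ``(region_ids, replicate_names, log_rpkm, labels)`` with
    ``log_rpkm[i, j] = log(RPKM[i, j] + pseudocount)``.  Every RPKM region
    must have a label; RPKM values must be non-negative.
    """
    rpkm = pd.read_csv(rpkm_tsv, sep="\t", index_col=0)
    labels = pd.read_csv(labels_tsv, sep="\t", index_col=0)
    missing = rpkm.index.difference(labels.index)
    if len(missing):
        raise KeyError(f"{len(missing)} region id(s) missing from labels, e.g. {missing[0]!r}")
    values = rpkm.to_numpy(dtype=np.float64)
    if (values < 0).any():
        raise ValueError("negative RPKM values")
    ordered = labels.loc[rpkm.index, labels.columns[0]].tolist()
    return (list(rpkm.index), list(rpkm.columns),
            np.log(values + pseudocount), ordered)


@dataclass
class ReadIndex:
    """Sorted single-base read positions per chromosome with O(log n)
    interval counting; positions arrive as BED single-base intervals."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of reads with position in [start, end)."""
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))


def read_read_positions(bed_path: str | Path) -> ReadIndex:
    """Load single-base read anchor positions from a BED file into a
    binary-searchable index (position = the interval start)."""
    by_chrom: dict[str, list[int]] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{lineno}: malformed BED line")
            try:
                start = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: malformed BED line") from exc
            by_chrom.setdefault(parts[0], []).append(start)
    return ReadIndex({c: np.sort(np.asarray(v, dtype=np.int64))
                      for c, v in by_chrom.items()})
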