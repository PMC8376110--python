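"""Genomic region and sequence handling.

All coordinates are 0-based half-open (BED convention) throughout the
package. This module reads BED and FASTA inputs, tiles a genome into
fixed-length windows, assigns multi-hot class labels by fractional
overlap with per-class region sets, one-hot encodes sequences, and
splits datasets by held-out chromosomes so that no chromosome leaks
between train, validation and test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
IUPAC_EXTRA = frozenset("RYSWKMBDHV")  # folded to N on FASTA ingestion

#: column order of the one-hot encoding
BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


class BedParseError(ValueError):
    """Raised for malformed BED lines; message names the line number."""


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start (bp).
    end : int
        0-based exclusive end (bp).
    name : str, optional
        Free-text label (e.g. BED column 4).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region {self.chrom}:{self.start}-{self.end}: end must be > start"
            )
        if self.start < 0:
            raise ValueError(f"region {self.chrom}: negative start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class LabeledDataset:
    """Fixed-length sequences with multi-hot class labels.

    ``labels`` is an (N, C) binary matrix; a row may be all-zero
    (active in no class). ``provenance`` optionally records the genomic
    origin of each sequence, which enables chromosome-held-out splits.
    """

    sequences: list[str]
    labels: np.ndarray
    class_names: list[str]
    provenance: list[GenomicRegion] | None = None
    window_length: int = 100

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(self.sequences):
            raise ValueError("labels must be (n_sequences, n_classes)")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if self.labels.shape[1] != len(self.class_names):
            raise ValueError("label width does not match class_names")
        for i, s in enumerate(self.sequences):
            if len(s) != self.window_length:
                raise ValueError(
                    f"sequence {i} has length {len(s)}, expected {self.window_length}"
                )
        if self.provenance is not None and len(self.provenance) != len(self.sequences):
            raise ValueError("provenance length must match sequences")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        prov = [self.provenance[i] for i in idx] if self.provenance is not None else None
        return LabeledDataset(
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            provenance=prov,
            window_length=self.window_length,
        )

    def encoded(self) -> np.ndarray:
        """One-hot encode all sequences into an (N, L, 4) array."""
        return np.stack([one_hot(s) for s in self.sequences]) if self.sequences else (
            np.zeros((0, self.window_length, 4))
        )


@dataclass
class DatasetSplit:
    """Train/validation/test partition of a :class:`LabeledDataset`."""

    train: LabeledDataset
    validation: LabeledDataset
    test: LabeledDataset
    held_out_chroms: dict[str, list[str]] = field(default_factory=dict)


def read_bed(path) -> list[GenomicRegion]:
    """Read a BED file (>=3 tab-separated columns) into regions.

    Extra columns beyond the optional name (column 4) are ignored.
    Malformed lines raise :class:`BedParseError` naming the line number.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = cols[3] if len(cols) > 3 else None
            try:
                regions.append(GenomicRegion(cols[0], start, end, name))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return regions


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping.

    Sequences are uppercased; multi-line records are concatenated;
    ambiguity codes other than N are folded to N. Duplicate record
    names and non-nucleotide characters raise ``ValueError``.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad - IUPAC_EXTRA:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-nucleotide characters "
                f"{sorted(bad - IUPAC_EXTRA)}"
            )
        if bad:
            seq = "".join(c if c in DNA_ALPHABET else "N" for c in seq)
        out[rec.id] = seq
    return out


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def make_windows(chrom_sizes: dict[str, int], window: int) -> list[GenomicRegion]:
    """Tile each chromosome into non-overlapping fixed windows.

    The trailing partial window (< ``window`` bp) is dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    windows = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size - window + 1, window):
            windows.append(GenomicRegion(chrom, start, start + window))
    return windows


def _merge_intervals(regions: list[GenomicRegion]) -> dict[str, np.ndarray]:
    """Merge per-chromosome intervals into disjoint sorted (start, end) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out: list[list[int]] = []
        for s, e in ivals:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def label_windows(
    windows: list[GenomicRegion],
    peak_sets: dict[str, list[GenomicRegion]],
) -> np.ndarray:
    """Label windows 1 where they overlap a class's region union by > L/2 bp.

    The overlap is computed against the union of the class's regions
    (merged intervals), so the result is invariant to peak order and to
    splitting a peak into abutting pieces. The inequality is strict:
    exactly half-overlap yields 0.
    """
    if not windows:
        return np.zeros((0, len(peak_sets)), dtype=np.int8)
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("all windows must have equal length")
    labels = np.zeros((len(windows), len(peak_sets)), dtype=np.int8)
    for ci, (_cls, peaks) in enumerate(peak_sets.items()):
        merged = _merge_intervals(peaks)
        for wi, w in enumerate(windows):
            ivals = merged.get(w.chrom)
            if ivals is None:
                continue
            starts, ends = ivals[:, 0], ivals[:, 1]
            # disjoint sorted intervals: clip each against the window and sum
            lo = np.maximum(starts, w.start)
            hi = np.minimum(ends, w.end)
            overlap = np.clip(hi - lo, 0, None).sum()
            if overlap * 2 > length:
                labels[wi, ci] = 1
    return labels


def extract_sequences(regions: list[GenomicRegion], genome_fasta) -> list[str]:
    """Extract forward-strand sequences for regions from an indexed FASTA."""
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    seqs = []
    for r in regions:
        if r.chrom not in genome:
            raise KeyError(f"chromosome {r.chrom!r} not in {genome_fasta}")
        if r.end > len(genome[r.chrom]):
            raise ValueError(
                f"region {r.chrom}:{r.start}-{r.end} beyond contig end "
                f"({len(genome[r.chrom])} bp)"
            )
        seqs.append(str(genome[r.chrom][r.start : r.end]))
    return seqs


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode a DNA string into an (L, 4) matrix, columns A,C,G,T.

    N is encoded as 0.25 in every channel so every row sums to 1.
    """
    seq = sequence.upper()
    mat = np.zeros((len(seq), 4))
    for i, base in enumerate(seq):
        if base == "N":
            mat[i] = 0.25
        else:
            try:
                mat[i, _BASE_INDEX[base]] = 1.0
            except KeyError:
                raise ValueError(f"invalid nucleotide {base!r} at position {i}") from None
    return mat


def split_by_chromosome(
    dataset: LabeledDataset,
    validation_chroms: list[str],
    test_chroms: list[str],
) -> DatasetSplit:
    """Partition a dataset into train/validation/test by provenance chromosome.

    Sequences without provenance go to train. Overlapping validation and
    test chromosome lists are an error.
    """
    overlap = set(validation_chroms) & set(test_chroms)
    if overlap:
        raise ValueError(f"validation/test chromosomes overlap: {sorted(overlap)}")
    if dataset.provenance is None:
        raise ValueError("dataset has no provenance; cannot split by chromosome")
    val_set, test_set = set(validation_chroms), set(test_chroms)
    buckets: dict[str, list[int]] = {"train": [], "validation": [], "test": []}
    for i, region in enumerate(dataset.provenance):
        chrom = region.chrom if region is not None else None
        if chrom in val_set:
            buckets["validation"].append(i)
        elif chrom in test_set:
            buckets["test"].append(i)
        else:
            buckets["train"].append(i)
    if not buckets["validation"] or not buckets["test"]:
        warnings.warn(
            "empty validation or test split: held-out chromosomes absent from data",
            stacklevel=2,
        )
    return DatasetSplit(
        train=dataset.subset(np.asarray(buckets["train"], dtype=int)),
        validation=dataset.subset(np.asarray(buckets["validation"], dtype=int)),
        test=dataset.subset(np.asarray(buckets["test"], dtype=int)),
        held_out_chroms={"validation": list(validation_chroms), "test": list(test_chroms)},
    )


def class_prior(dataset: LabeledDataset, class_name: str) -> float:
    """Empirical fraction of sequences labeled 1 for a class: (1/N) sum 1[y_n = 1]."""
    if len(dataset) == 0:
        raise ValueError("class_prior undefined for an empty dataset")
    ci = dataset.class_names.index(class_name)
    return float(dataset.labels[:, ci].mean())


def read_label_table(path) -> tuple[list[str], np.ndarray]:
    """Read a tab-separated label table: header of class names, 0/1 rows."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [
            [int(v) for v in line.rstrip("\n").split("\t")]
            for line in fh
            if line.strip()
        ]
    labels = np.asarray(rows, dtype=np.int8) if rows else np.zeros((0, len(header)), np.int8)
    if labels.size and labels.shape[1] != len(header):
        raise ValueError(f"{path}: row width does not match header")
    return header, labels


def write_label_table(path, class_names: list[str], labels: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(class_names) + "\n")
        for row in np.asarray(labels, dtype=int):
            fh.write("\t".join(str(v) for v in row) + "\n")
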