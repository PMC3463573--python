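"""Alignment and metadata I/O, haplotype collapsing, pairwise distances.

All downstream statistics operate on *retained* alignment columns: by
default every column that contains a gap, an ``N`` or an IUPAC ambiguity
code in any sequence is removed before anything is computed (complete
deletion).  This keeps segregating sites, nucleotide diversity and the
haplotype distance matrix mutually coherent, at the cost of discarding a
column for the whole sample whenever a single individual is unresolved.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, DegenerateInputError, InputError

UNAMBIGUOUS = frozenset(b"ACGT")
#: Symbols accepted in input alignments (after upper-casing; U is mapped to T).
VALID_SYMBOLS = frozenset(b"ACGTN-RYSWKMBDHV")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of haploid sequences with unique sample ids."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise InputError("alignment contains no sequences")
        if len(self.ids) != len(set(self.ids)):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample ids: {dup}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            bad = next(i for i, s in zip(self.ids, self.seqs) if len(s) != len(self.seqs[0]))
            raise AlignmentError(f"ragged alignment: record {bad!r} has a different length")
        if self.length == 0:
            raise AlignmentError("alignment has zero columns")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix of ASCII codes."""
        return np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8).reshape(
            self.n, self.length
        )

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = set(ids)
        pairs = [(i, s) for i, s in zip(self.ids, self.seqs) if i in keep]
        missing = keep - {i for i, _ in pairs}
        if missing:
            raise KeyError(f"sample ids not in alignment: {sorted(missing)}")
        return Alignment(tuple(i for i, _ in pairs), tuple(s for _, s in pairs))

    def checksum(self) -> str:
        h = hashlib.sha256()
        for i, s in zip(self.ids, self.seqs):
            h.update(i.encode())
            h.update(b"\0")
            h.update(s.encode())
        return h.hexdigest()


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with observed counts and member sample ids.

    Haplotype identity is exact sequence match over the retained columns;
    ids are assigned ``H001, H002, ...`` in order of first occurrence.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    counts: tuple[int, ...]
    members: tuple[tuple[str, ...], ...]

    @property
    def k(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class DistanceMatrix:
    """Hamming distances (nt differences) between haplotypes on retained sites."""

    ids: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if d.shape != (len(self.ids), len(self.ids)):
            raise InputError("distance matrix shape does not match id count")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; normalise case and map U to T."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    ids, seqs = [], []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        raw = seq.encode()
        bad = [i for i, c in enumerate(raw) if c not in VALID_SYMBOLS]
        if bad:
            raise InputError(
                f"record {rec.id!r} has invalid symbol {seq[bad[0]]!r} at position {bad[0] + 1}"
            )
        ids.append(rec.id)
        seqs.append(seq)
    return Alignment(tuple(ids), tuple(seqs))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(aln.ids, aln.seqs):
            fh.write(f">{i}\n{s}\n")


METADATA_COLUMNS = ("sample_id", "site_id", "lat", "lon", "lineage")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated sample table (sample_id, site_id[, lat, lon, lineage])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str})
    for col in ("sample_id", "site_id"):
        if col not in df.columns:
            raise InputError(f"metadata file {path} lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample_id in metadata: {dup}")
    return df


def prune_one_per_site(aln: Alignment, meta: pd.DataFrame, seed: int) -> Alignment:
    """Keep one randomly chosen individual per collection site.

    The choice is a deterministic function of ``seed`` and of the sorted
    sample ids within each site, so reruns (and alignments given in a
    different record order) select the same individuals.
    """
    site_of = dict(zip(meta["sample_id"], meta["site_id"]))
    missing = [s for s in aln.ids if s not in site_of]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    by_site: dict[str, list[str]] = {}
    for s in aln.ids:
        by_site.setdefault(site_of[s], []).append(s)
    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    for site in sorted(by_site):
        members = sorted(by_site[site])
        chosen.add(members[int(rng.integers(len(members)))])
    return aln.subset(chosen)


def retained_columns(seqs: Sequence[str]) -> np.ndarray:
    """Indices of columns where every sequence has an unambiguous A/C/G/T."""
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    acgt = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    return np.nonzero(acgt.all(axis=0))[0]


def retained_matrix(aln: Alignment) -> np.ndarray:
    """(n, L') uint8 matrix restricted to retained columns."""
    cols = retained_columns(aln.seqs)
    if cols.size == 0:
        raise DegenerateInputError("complete deletion removed every alignment column")
    return aln.matrix()[:, cols]


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Collapse identical sequences (over retained columns) into haplotypes."""
    cols = retained_columns(aln.seqs)
    if cols.size == 0:
        raise DegenerateInputError("complete deletion removed every alignment column")
    key_of = {}
    order: list[bytes] = []
    members: dict[bytes, list[str]] = {}
    rep: dict[bytes, str] = {}
    mat = aln.matrix()[:, cols]
    for row, sample, full in zip(mat, aln.ids, aln.seqs):
        key = row.tobytes()
        if key not in members:
            order.append(key)
            members[key] = []
            rep[key] = full
        members[key].append(sample)
        key_of[sample] = key
    ids = tuple(f"H{i + 1:03d}" for i in range(len(order)))
    return HaplotypeTable(
        ids=ids,
        seqs=tuple(rep[k] for k in order),
        counts=tuple(len(members[k]) for k in order),
        members=tuple(tuple(members[k]) for k in order),
    )


def pairwise_distance_matrix(ht: HaplotypeTable) -> DistanceMatrix:
    """Hamming distances between haplotype sequences after complete deletion."""
    cols = retained_columns(ht.seqs)
    if cols.size == 0:
        raise DegenerateInputError("complete deletion removed every alignment column")
    mat = np.frombuffer("".join(ht.seqs).encode(), dtype=np.uint8).reshape(
        len(ht.seqs), -1
    )[:, cols]
    d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(np.int64)
    return DistanceMatrix(ids=ht.ids, d=d)


def pairwise_differences(aln: Alignment) -> np.ndarray:
    """(n, n) Hamming distance matrix over individuals on retained sites."""
    mat = retained_matrix(aln)
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(np.int64)
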