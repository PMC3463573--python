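"""Polymorphism statistics for haploid sequence samples.

Implements the classical per-lineage summary: number of segregating sites
S, haplotype count K, haplotype diversity H, and nucleotide diversity pi
— total, synonymous (pi_s) and nonsynonymous (pi_n).  Synonymous and
nonsynonymous sites and differences are partitioned by unweighted
Nei–Gojobori (1986) pathway counting, and pairwise p-distances are
corrected for multiple hits with the Jukes–Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``, applied per pair before averaging.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .errors import (
    CodonError,
    DegenerateInputError,
    DomainError,
    FrameError,
    InputError,
)
from .seq_io import Alignment, HaplotypeTable, collapse_haplotypes, retained_matrix

#: NCBI translation table for invertebrate mitochondrial DNA.
INVERTEBRATE_MITO = 5

BASES = "ACGT"


@dataclass(frozen=True)
class DiversityStats:
    """One lineage's polymorphism summary (one row of a diversity table)."""

    n: int
    k: int
    h: float
    s: int
    pi_total: float
    pi_total_uncorrected: float
    pi_s: float | None
    pi_n: float | None
    code: int
    frame_offset: int | None

    def tsv_row(self, lineage: str) -> str:
        fmt = lambda x: "NA" if x is None else f"{x:.4f}"
        return "\t".join(
            [lineage, str(self.n), str(self.k), f"{self.h:.2f}", str(self.s),
             fmt(self.pi_s), fmt(self.pi_n)]
        )


def segregating_sites(aln: Alignment) -> int:
    """Number of retained columns with more than one nucleotide state."""
    if aln.n < 2:
        raise InputError("segregating sites require at least 2 sequences")
    mat = retained_matrix(aln)
    return int(((mat != mat[0]).any(axis=0)).sum())


def haplotype_diversity(ht: HaplotypeTable) -> float:
    """H = n/(n-1) * (1 - sum p_i^2): chance two random alleles differ."""
    n = ht.n
    if n < 2:
        raise InputError("haplotype diversity requires n >= 2")
    p = np.asarray(ht.counts, dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a p-distance."""
    if not 0.0 <= p < 0.75:
        raise DomainError(f"Jukes-Cantor correction undefined for p = {p}")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def nucleotide_diversity(aln: Alignment, jc_correct: bool = True) -> float:
    """Mean per-site pairwise difference over all unordered sequence pairs."""
    if aln.n < 2:
        raise InputError("nucleotide diversity requires at least 2 sequences")
    mat = retained_matrix(aln)
    nsites = mat.shape[1]
    diffs = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    iu = np.triu_indices(aln.n, k=1)
    p = diffs[iu] / nsites
    if jc_correct:
        return float(np.mean([jukes_cantor(x) for x in p]))
    return float(np.mean(p))


@lru_cache(maxsize=16)
def _table(code: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code]


def _translate(codon: str, code: int) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    t = _table(code)
    if codon in t.stop_codons:
        return None
    return t.forward_table[codon]


def ng_site_counts(codon: str, code: int = INVERTEBRATE_MITO) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site counts for one sense codon.

    Each position contributes the fraction of its three possible single-base
    changes that preserve the amino acid; changes to stop codons count as
    nonsynonymous, so the two counts always sum to exactly 3.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise CodonError(f"ambiguous or malformed codon {codon!r}")
    aa = _translate(codon, code)
    if aa is None:
        raise CodonError(f"stop codon {codon!r} has no site counts")
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if _translate(mutant, code) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_path_diffs(c1: str, c2: str, code: int) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two sense codons.

    Averages over all orderings of the differing positions (minimal
    mutational pathways); pathways passing through a stop codon are
    excluded when at least one stop-free pathway exists, otherwise every
    pathway is used with stop-involving steps counted as nonsynonymous.
    """
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (syn, nonsyn, stop_free)
    for order in itertools.permutations(pos):
        cur = c1
        syn = nonsyn = 0.0
        stop_free = True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            aa_cur, aa_nxt = _translate(cur, code), _translate(nxt, code)
            if aa_cur is None or aa_nxt is None:
                stop_free = False
                nonsyn += 1.0
            elif aa_cur == aa_nxt:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        paths.append((syn, nonsyn, stop_free))
    good = [p for p in paths if p[2]] or paths
    syn = sum(p[0] for p in good) / len(good)
    nonsyn = sum(p[1] for p in good) / len(good)
    return syn, nonsyn


def _codon_strings(row: np.ndarray, frame_offset: int) -> list[str]:
    s = row.tobytes().decode()[frame_offset:]
    s = s[: len(s) - len(s) % 3]
    return [s[i : i + 3] for i in range(0, len(s), 3)]


def pi_by_site_class(
    aln: Alignment, code: int = INVERTEBRATE_MITO, frame_offset: int = 0
) -> tuple[float, float]:
    """Jukes–Cantor-corrected synonymous and nonsynonymous diversity.

    Works on the raw alignment in the given reading frame; codon pairs in
    which either codon carries a gap/ambiguity or is a stop codon are
    skipped for that pair (pairwise codon deletion).  The consensus frame
    must be free of internal stop codons.
    """
    if aln.n < 2:
        raise InputError("pi_s/pi_n require at least 2 sequences")
    if frame_offset not in (0, 1, 2):
        raise InputError("frame_offset must be 0, 1 or 2")
    mat = aln.matrix()
    # consensus frame sanity check: majority base per column, stops flagged
    consensus = []
    for col in mat.T:
        vals, counts = np.unique(col, return_counts=True)
        keep = [(c, v) for v, c in zip(vals, counts) if chr(v) in BASES]
        consensus.append(chr(max(keep)[1]) if keep else "N")
    cons_codons = _codon_strings(
        np.frombuffer("".join(consensus).encode(), dtype=np.uint8), frame_offset
    )
    for idx, codon in enumerate(cons_codons[:-1]):
        if all(b in BASES for b in codon) and _translate(codon, code) is None:
            raise FrameError(f"internal stop codon at codon index {idx} in consensus frame")

    codon_rows = [_codon_strings(row, frame_offset) for row in mat]
    n = aln.n
    ds_vals, dn_vals = [], []
    for i in range(n):
        for j in range(i + 1, n):
            syn_sites = nonsyn_sites = syn_d = nonsyn_d = 0.0
            for c1, c2 in zip(codon_rows[i], codon_rows[j]):
                if any(b not in BASES for b in c1 + c2):
                    continue
                if _translate(c1, code) is None or _translate(c2, code) is None:
                    continue
                s1 = ng_site_counts(c1, code)
                s2 = ng_site_counts(c2, code)
                syn_sites += 0.5 * (s1[0] + s2[0])
                nonsyn_sites += 0.5 * (s1[1] + s2[1])
                if c1 != c2:
                    a, b = sorted((c1, c2))
                    sd, nd = _codon_path_diffs(a, b, code)
                    syn_d += sd
                    nonsyn_d += nd
            if syn_sites == 0 or nonsyn_sites == 0:
                raise DegenerateInputError("no comparable codons in a sequence pair")
            ds_vals.append(jukes_cantor(syn_d / syn_sites))
            dn_vals.append(jukes_cantor(nonsyn_d / nonsyn_sites))
    return float(np.mean(ds_vals)), float(np.mean(dn_vals))


def diversity_stats(
    aln: Alignment,
    code: int = INVERTEBRATE_MITO,
    frame_offset: int | None = None,
) -> DiversityStats:
    """Full per-lineage summary; pi_s/pi_n are computed only when a reading
    frame is supplied (the coding statistics are meaningless without one)."""
    ht = collapse_haplotypes(aln)
    pi_s = pi_n = None
    if frame_offset is not None:
        pi_s, pi_n = pi_by_site_class(aln, code=code, frame_offset=frame_offset)
    return DiversityStats(
        n=aln.n,
        k=ht.k,
        h=haplotype_diversity(ht),
        s=segregating_sites(aln),
        pi_total=nucleotide_diversity(aln, jc_correct=True),
        pi_total_uncorrected=nucleotide_diversity(aln, jc_correct=False),
        pi_s=pi_s,
        pi_n=pi_n,
        code=code,
        frame_offset=frame_offset,
    )
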