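"""Codon-level Ka/Ks (Nei-Gojobori) and the pairwise Fisher exact test.

The genetic code defaults to the invertebrate mitochondrial code (NCBI
translation table 5), appropriate for beetle mtDNA. Site counting and
difference counting follow the original Nei-Gojobori method: potential
synonymous/nonsynonymous sites are enumerated from the 3 possible changes at
each codon position (changes to stop codons excluded from the denominator),
and codons differing at several positions are averaged over all orderings of
single-nucleotide steps with equal weight, discarding pathways that pass
through a stop codon.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import fisher_exact

from bridgehead.alignment_io import MitogenomeAlignment, build_coordinate_map

logger = logging.getLogger(__name__)

INVERTEBRATE_MITO = 5
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


class FrameError(ValueError):
    """Reading-frame problem (internal stop, length not divisible by 3)."""


@lru_cache(maxsize=None)
def _code(code_table: int) -> dict[str, str]:
    """codon -> amino acid, with '*' for stops."""
    table = CodonTable.unambiguous_dna_by_id[code_table]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def translate(codon: str, code_table: int = INVERTEBRATE_MITO) -> str:
    return _code(code_table)[codon.upper()]


@dataclass
class GeneAnnotation:
    """A protein-coding gene on the ungapped reference (1-based inclusive)."""

    gene: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            raise ValueError(f"{self.gene}: end < start")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return [
        GeneAnnotation(str(r.gene), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


@dataclass
class NGCounts:
    """Nei-Gojobori site and difference counts for one sequence pair."""

    S: float  # potential synonymous sites
    N: float  # potential nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    codons_compared: int = 0
    codons_skipped: int = 0

    def __add__(self, other: "NGCounts") -> "NGCounts":
        return NGCounts(
            self.S + other.S,
            self.N + other.N,
            self.Sd + other.Sd,
            self.Nd + other.Nd,
            self.codons_compared + other.codons_compared,
            self.codons_skipped + other.codons_skipped,
        )


@dataclass
class KaKsResult:
    Ka: float
    Ks: float
    ratio: float | None  # None when Ks == 0


@lru_cache(maxsize=None)
def _codon_sites(codon: str, code_table: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one sense codon.

    Each position contributes 1 site split by the fraction of its possible
    changes that are synonymous; changes producing a stop codon are removed
    from the denominator. A position whose 3 changes all create stops counts
    as 1 nonsynonymous site (logged by the caller at pair level).
    """
    code = _code(code_table)
    aa = code[codon]
    if aa == "*":
        raise FrameError(f"stop codon {codon} has no site decomposition")
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if code[alt] == "*":
                continue
            valid += 1
            if code[alt] == aa:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str, code_table: int) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All orderings of the single-nucleotide steps are weighted equally;
    pathways passing through a stop codon are discarded. Returns None when no
    stop-free pathway exists (the codon pair must then be skipped).
    """
    code = _code(code_table)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code[nxt] == "*":
                ok = False
                break
            if code[nxt] == code[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = float(np.mean([t[0] for t in totals]))
    nd = float(np.mean([t[1] for t in totals]))
    return sd, nd


def ng_counts(seq1: str, seq2: str, code_table: int = INVERTEBRATE_MITO) -> NGCounts:
    """Nei-Gojobori counts for a pair of aligned coding sequences.

    Codons containing N or a gap in either sequence are skipped; potential
    sites are averaged between the two sequences over the compared codons.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be equal length")
    if len(seq1) % 3:
        raise FrameError(f"length {len(seq1)} not divisible by 3")
    code = _code(code_table)
    S = N = Sd = Nd = 0.0
    compared = skipped = 0
    for i in range(0, len(seq1), 3):
        a, b = seq1[i : i + 3], seq2[i : i + 3]
        if any(ch not in _BASES for ch in a + b):
            skipped += 1
            continue
        if code[a] == "*" or code[b] == "*":
            skipped += 1
            continue
        d = _codon_differences(a, b, code_table)
        if d is None:
            skipped += 1
            logger.info("codon pair %s/%s skipped: all pathways hit stops", a, b)
            continue
        s1, n1 = _codon_sites(a, code_table)
        s2, n2 = _codon_sites(b, code_table)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        Sd += d[0]
        Nd += d[1]
        compared += 1
    return NGCounts(S, N, Sd, Nd, compared, skipped)


def kaks(counts: NGCounts, correction: str = "none") -> KaKsResult:
    """Ka and Ks from Nei-Gojobori counts, optionally Jukes-Cantor corrected."""
    if counts.S <= 0 or counts.N <= 0:
        raise ValueError("need positive potential site counts")
    ps, pn = counts.Sd / counts.S, counts.Nd / counts.N
    if correction == "none":
        ka, ks = pn, ps
    elif correction == "jukes_cantor":
        for name, p in (("Ks", ps), ("Ka", pn)):
            if p >= 0.75:
                raise ValueError(f"{name}: proportion {p:.3f} >= 3/4, JC correction saturated")
        ka = -0.75 * np.log1p(-4.0 * pn / 3.0)
        ks = -0.75 * np.log1p(-4.0 * ps / 3.0)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    ratio = None if ks == 0 else ka / ks
    return KaKsResult(float(ka), float(ks), ratio)


def fisher_positive_selection(counts: NGCounts) -> float:
    """One-tailed Fisher exact p for an excess of nonsynonymous differences.

    The 2x2 table is [[Nd, N-Nd], [Sd, S-Sd]] with fractional entries rounded
    to the nearest integer; the p-value is the hypergeometric tail probability
    of an enrichment at least as extreme as observed.
    """
    nd, n_rest = round(counts.Nd), round(counts.N - counts.Nd)
    sd, s_rest = round(counts.Sd), round(counts.S - counts.Sd)
    if min(nd + n_rest, sd + s_rest) <= 0 or nd + sd == 0:
        warnings.warn("degenerate 2x2 table: p = 1", stacklevel=2)
        return 1.0
    _, p = fisher_exact([[nd, n_rest], [sd, s_rest]], alternative="greater")
    return float(p)


def _revcomp(chars: np.ndarray) -> np.ndarray:
    out = chars[..., ::-1].copy()
    view = out.view(np.uint8)
    lut = np.arange(256, dtype=np.uint8)
    for a, b in _COMPLEMENT.items():
        lut[ord(a)] = ord(b)
    view[...] = lut[view]
    return out


def extract_coding(
    aln: MitogenomeAlignment,
    annotations: list[GeneAnnotation],
    reference_id: str,
    code_table: int = INVERTEBRATE_MITO,
) -> dict[str, np.ndarray]:
    """Per-gene codon alignments plus their concatenation.

    Gene coordinates refer to ungapped reference positions. Minus-strand genes
    are reverse-complemented; a trailing incomplete codon and a terminal stop
    codon (in the reference frame) are trimmed. An internal stop in the
    reference frame raises FrameError naming the gene and codon index.
    Returns a dict gene -> (n_sequences, gene_length) character matrix, with
    key "concatenated" for all genes joined in annotation order.
    """
    cmap = build_coordinate_map(aln, reference_id)
    ref_row = aln.sequence_ids.index(reference_id)
    code = _code(code_table)
    out: dict[str, np.ndarray] = {}
    pieces = []
    for ann in annotations:
        if not (1 <= ann.start <= ann.end <= cmap.reference_length):
            raise IndexError(f"{ann.gene}: interval outside reference")
        cols = cmap.columns[ann.start - 1 : ann.end] - 1
        block = aln.sites[:, cols]
        if ann.strand == "-":
            block = _revcomp(block)
        n_codons = block.shape[1] // 3
        block = block[:, : n_codons * 3]
        ref = block[ref_row].tobytes().decode()
        codons = [ref[i : i + 3] for i in range(0, len(ref), 3)]
        for idx, codon in enumerate(codons[:-1]):
            if all(c in _BASES for c in codon) and code[codon] == "*":
                raise FrameError(f"{ann.gene}: internal stop at codon {idx + 1}")
        if codons and all(c in _BASES for c in codons[-1]) and code[codons[-1]] == "*":
            block = block[:, :-3]
        out[ann.gene] = block
        pieces.append(block)
    out["concatenated"] = np.concatenate(pieces, axis=1) if pieces else np.empty((aln.n_sequences, 0), dtype="S1")
    return out


def pairwise_selection_scan(
    codon_matrix: np.ndarray,
    sequence_ids: list[str],
    gene: str = "concatenated",
    code_table: int = INVERTEBRATE_MITO,
    correction: str = "none",
) -> pd.DataFrame:
    """Ka/Ks and Fisher exact p for every sequence pair of one codon alignment."""
    rows = []
    seqs = [codon_matrix[i].tobytes().decode() for i in range(codon_matrix.shape[0])]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            c = ng_counts(seqs[i], seqs[j], code_table)
            if c.S > 0 and c.N > 0:
                r = kaks(c, correction)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = fisher_positive_selection(c)
            else:
                r, p = KaKsResult(0.0, 0.0, None), 1.0
            rows.append(
                {
                    "gene": gene,
                    "pair": f"{sequence_ids[i]}|{sequence_ids[j]}",
                    "S": c.S,
                    "N": c.N,
                    "Sd": c.Sd,
                    "Nd": c.Nd,
                    "Ka": r.Ka,
                    "Ks": r.Ks,
                    "ratio": np.nan if r.ratio is None else r.ratio,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
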