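"""Alignment I/O, control-region excision, haplotype collapsing, tandem repeats.

Alignments are held as a byte matrix over the six-character alphabet
``{A, C, G, T, N, -}`` with one row per sequence and a region label per row.
All user-facing coordinates are 1-based and inclusive at both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = b"ACGTN-"
_ALPHABET_SET = frozenset(ALPHABET)


class AlignmentError(ValueError):
    """Rows of unequal length or otherwise malformed alignment."""


class MetadataError(ValueError):
    """Metadata table inconsistent with the FASTA records."""


class AlignmentParseError(ValueError):
    """Characters outside the {A,C,G,T,N,-} alphabet."""


@dataclass
class MitogenomeAlignment:
    """An aligned set of mitogenomes with per-sequence region labels.

    Attributes
    ----------
    sequence_ids : list of str
        Unique row identifiers, in input order.
    regions : dict
        Map id -> region label (e.g. sampling region along an invasion chain).
    sites : numpy.ndarray
        Byte matrix of shape ``(n_sequences, n_columns)``, dtype ``S1``.
    """

    sequence_ids: list[str]
    regions: dict[str, str]
    sites: np.ndarray

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype="S1")
        if self.sites.ndim != 2:
            raise AlignmentError("sites must be a 2-D character matrix")
        if len(self.sequence_ids) != self.sites.shape[0]:
            raise AlignmentError(
                f"{len(self.sequence_ids)} ids for {self.sites.shape[0]} rows"
            )
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise AlignmentError("duplicate sequence ids")
        missing = [s for s in self.sequence_ids if s not in self.regions]
        if missing:
            raise MetadataError(f"ids without region label: {missing}")

    @property
    def n_sequences(self) -> int:
        return self.sites.shape[0]

    @property
    def n_columns(self) -> int:
        return self.sites.shape[1]

    def row(self, sequence_id: str) -> np.ndarray:
        return self.sites[self.sequence_ids.index(sequence_id)]

    def sequence(self, sequence_id: str) -> str:
        return self.row(sequence_id).tobytes().decode()

    def subset(self, ids: list[str]) -> "MitogenomeAlignment":
        """Row subset preserving the order given in `ids`."""
        index = {s: i for i, s in enumerate(self.sequence_ids)}
        rows = [index[s] for s in ids]
        return MitogenomeAlignment(
            list(ids), {s: self.regions[s] for s in ids}, self.sites[rows]
        )

    def region_partition(self) -> dict[str, list[str]]:
        """Map region -> ids, regions in first-seen order over rows."""
        part: dict[str, list[str]] = {}
        for s in self.sequence_ids:
            part.setdefault(self.regions[s], []).append(s)
        return part


def _validate_characters(ids: list[str], sites: np.ndarray) -> None:
    codes = sites.view(np.uint8)
    ok = np.isin(codes, np.frombuffer(ALPHABET, dtype=np.uint8))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        ch = chr(codes[r, c])
        raise AlignmentParseError(
            f"invalid character {ch!r} in sequence {ids[r]!r} at column {c + 1}"
        )


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> MitogenomeAlignment:
    """Read an aligned multi-FASTA plus a delimited metadata table.

    The metadata table (comma- or tab-delimited, with header) must contain
    columns ``id`` and ``region``; a ``site`` column is accepted and ignored
    here. Sequences are uppercased and U is mapped to T.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal aligned lengths in {fasta_path}: {sorted(lengths)}")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper().replace("U", "T") for r in records]
    sites = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)

    meta = pd.read_csv(metadata_path, sep=None, engine="python", dtype=str)
    meta.columns = [c.strip().lower() for c in meta.columns]
    for col in ("id", "region"):
        if col not in meta.columns:
            raise MetadataError(f"metadata {metadata_path} lacks a {col!r} column")
    regions = dict(zip(meta["id"], meta["region"]))
    missing = [s for s in ids if s not in regions]
    if missing:
        raise MetadataError(f"FASTA ids missing from metadata: {missing}")

    _validate_characters(ids, sites)
    return MitogenomeAlignment(ids, {s: regions[s] for s in ids}, sites)


def write_alignment(
    aln: MitogenomeAlignment, fasta_path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write FASTA and (optionally) the id/region metadata table."""
    records = [
        SeqRecord(Seq(aln.sites[i].tobytes().decode()), id=s, description="")
        for i, s in enumerate(aln.sequence_ids)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if metadata_path is not None:
        pd.DataFrame(
            {"id": aln.sequence_ids, "region": [aln.regions[s] for s in aln.sequence_ids]}
        ).to_csv(metadata_path, sep="\t", index=False)


@dataclass
class ReferenceCoordinateMap:
    """1-based ungapped reference position -> 1-based alignment column."""

    reference_id: str
    columns: np.ndarray  # columns[p-1] = 1-based alignment column of position p

    @property
    def reference_length(self) -> int:
        return len(self.columns)

    def column_of_position(self, position: int) -> int:
        if not 1 <= position <= len(self.columns):
            raise IndexError(
                f"position {position} outside reference 1..{len(self.columns)}"
            )
        return int(self.columns[position - 1])


def build_coordinate_map(aln: MitogenomeAlignment, reference_id: str) -> ReferenceCoordinateMap:
    """Map every non-gap character of the reference row to its alignment column."""
    if reference_id not in aln.sequence_ids:
        raise KeyError(f"unknown reference id {reference_id!r}")
    row = aln.row(reference_id)
    cols = np.flatnonzero(row != b"-") + 1
    return ReferenceCoordinateMap(reference_id, cols)


def excise_reference_interval(
    aln: MitogenomeAlignment, ref_id: str, start: int, end: int
) -> MitogenomeAlignment:
    """Remove all alignment columns spanned by reference positions start..end.

    Columns between the alignment column of `start` and that of `end`
    (both inclusive, including any gap-only columns that fall inside the
    interval) are dropped; row order and labels are preserved.
    """
    cmap = build_coordinate_map(aln, ref_id)
    if not (1 <= start <= end <= cmap.reference_length):
        raise IndexError(
            f"interval {start}..{end} outside reference 1..{cmap.reference_length}"
        )
    c1 = cmap.column_of_position(start) - 1
    c2 = cmap.column_of_position(end) - 1
    keep = np.ones(aln.n_columns, dtype=bool)
    keep[c1 : c2 + 1] = False
    return MitogenomeAlignment(list(aln.sequence_ids), dict(aln.regions), aln.sites[:, keep])


@dataclass
class HaplotypeTable:
    """Distinct sequences with multiplicities, members and region occupancy.

    Sorted by descending count, ties broken by first occurrence in the input.
    Haplotype identity is exact string equality (including N and gaps): the
    intended inputs are complete, fully resolved mitogenomes.
    """

    haplotypes: list[str]
    counts: list[int]
    members: list[list[str]]
    region_counts: list[dict[str, int]]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_sequences(self) -> int:
        return sum(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": [f"H{i + 1}" for i in range(self.n_haplotypes)],
                "count": self.counts,
                "members": [";".join(m) for m in self.members],
                "regions": [
                    ";".join(f"{r}:{c}" for r, c in sorted(rc.items()))
                    for rc in self.region_counts
                ],
            }
        )


def collapse_haplotypes(aln: MitogenomeAlignment) -> HaplotypeTable:
    """Collapse identical rows of the alignment into haplotype classes."""
    if aln.n_sequences == 0:
        raise AlignmentError("empty alignment")
    classes: dict[bytes, list[str]] = {}
    for i, sid in enumerate(aln.sequence_ids):
        classes.setdefault(aln.sites[i].tobytes(), []).append(sid)
    order = sorted(
        classes, key=lambda h: (-len(classes[h]), aln.sequence_ids.index(classes[h][0]))
    )
    haplotypes, counts, members, region_counts = [], [], [], []
    for h in order:
        ids = classes[h]
        haplotypes.append(h.decode())
        counts.append(len(ids))
        members.append(ids)
        rc: dict[str, int] = {}
        for s in ids:
            rc[aln.regions[s]] = rc.get(aln.regions[s], 0) + 1
        region_counts.append(rc)
    return HaplotypeTable(haplotypes, counts, members, region_counts)


@dataclass
class RepeatAnnotation:
    """A tandem-repeat array: >= 2 copies of a unit, plus an optional partial copy.

    `start`/`end` are 1-based inclusive coordinates of the full copies;
    `partial_length` is the length (bp) of a trailing partial copy beyond
    `end`; `max_unit_divergence` is the largest Hamming distance between any
    full copy and the array consensus unit.
    """

    unit_length: int
    copy_number: int
    start: int
    end: int
    partial_length: int
    max_unit_divergence: int
    consensus: str

    def __post_init__(self) -> None:
        if self.copy_number < 2:
            raise ValueError("a tandem array needs at least two copies")
        if self.end - self.start + 1 != self.unit_length * self.copy_number:
            raise ValueError("span inconsistent with unit_length x copy_number")

    def to_row(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "unit_length": self.unit_length,
            "copy_number": self.copy_number,
            "partial_length": self.partial_length,
            "max_unit_divergence": self.max_unit_divergence,
            "consensus": self.consensus,
        }


def _consensus(blocks: np.ndarray) -> np.ndarray:
    """Per-column majority over an array of unit copies; ties -> first copy."""
    cons = blocks[0].copy()
    if blocks.shape[0] > 1:
        for j in range(blocks.shape[1]):
            vals, cnt = np.unique(blocks[:, j], return_counts=True)
            best = cnt.max()
            if best > (blocks[:, j] == cons[j]).sum():
                cons[j] = vals[np.argmax(cnt)]
    return cons


def _partial_copy_length(seq: np.ndarray, pos: int, cons: np.ndarray, budget: int) -> int:
    """Longest prefix of the consensus continuing at `pos` within a pro-rated budget."""
    u = len(cons)
    avail = min(u - 1, len(seq) - pos)
    if avail <= 0:
        return 0
    mism = np.cumsum(seq[pos : pos + avail] != cons[:avail])
    allowed = (budget * np.arange(1, avail + 1)) // u
    ok = np.flatnonzero(mism <= allowed)
    return int(ok[-1] + 1) if ok.size else 0


def find_tandem_repeats(
    seq: str,
    unit_min: int = 2,
    unit_max: int = 200,
    max_mismatch_per_copy: int = 2,
) -> list[RepeatAnnotation]:
    """Detect maximal tandem-repeat arrays in an ungapped sequence.

    An array is a run of >= 2 consecutive unit-length blocks, each within
    `max_mismatch_per_copy` substitutions of the array consensus, that cannot
    be extended by a further copy on either side. Overlapping candidates are
    resolved in favour of more copies, then longer unit, then leftmost start.
    A trailing partial copy is reported with a budget pro-rated to its length.

    Designed for mitochondrial control regions (a few kb); the scan is
    exhaustive over unit lengths and phases.
    """
    if unit_min < 2:
        raise ValueError("unit_min must be >= 2")
    if not seq:
        raise ValueError("empty sequence")
    if "-" in seq:
        raise ValueError("sequence must be ungapped")
    s = np.frombuffer(seq.upper().encode(), dtype="S1")
    L = len(s)
    candidates: list[RepeatAnnotation] = []
    for u in range(unit_min, min(unit_max, L // 2) + 1):
        neq = (s[:-u] != s[u:]).astype(np.int32)
        # adjacent-block mismatch count per phase, via sliding-window sums
        win = np.concatenate([[0], np.cumsum(neq)])
        n_starts = L - 2 * u + 1
        if n_starts <= 0:
            continue
        adj = win[u : u + n_starts] - win[:n_starts]
        seeds = np.flatnonzero(adj <= max_mismatch_per_copy)
        covered = np.zeros(L, dtype=bool)
        for i in seeds:
            if covered[i]:
                continue
            blocks = [s[i : i + u], s[i + u : i + 2 * u]]
            cons = _consensus(np.array(blocks))
            # grow right
            j = i + 2 * u
            while j + u <= L:
                nxt = s[j : j + u]
                if int((nxt != cons).sum()) > max_mismatch_per_copy:
                    break
                blocks.append(nxt)
                cons = _consensus(np.array(blocks))
                j += u
            # grow left
            left = i
            while left - u >= 0:
                prv = s[left - u : left]
                if int((prv != cons).sum()) > max_mismatch_per_copy:
                    break
                blocks.insert(0, prv)
                cons = _consensus(np.array(blocks))
                left -= u
            arr = np.array(blocks)
            cons = _consensus(arr)
            div = (arr != cons).sum(axis=1)
            # trim ends that violate the budget under the refined consensus
            lo, hi = 0, len(blocks)
            while hi - lo >= 2 and div[lo] > max_mismatch_per_copy:
                lo += 1
            while hi - lo >= 2 and div[hi - 1] > max_mismatch_per_copy:
                hi -= 1
            if hi - lo < 2 or div[lo:hi].max() > max_mismatch_per_copy:
                continue
            a_start = left + lo * u
            k = hi - lo
            covered[a_start : a_start + k * u] = True
            cons = _consensus(arr[lo:hi])
            div = (arr[lo:hi] != cons).sum(axis=1)
            partial = _partial_copy_length(
                s, a_start + k * u, cons, max_mismatch_per_copy
            )
            candidates.append(
                RepeatAnnotation(
                    unit_length=u,
                    copy_number=k,
                    start=a_start + 1,
                    end=a_start + k * u,
                    partial_length=partial,
                    max_unit_divergence=int(div.max()),
                    consensus=cons.tobytes().decode(),
                )
            )
    # resolve overlaps: more copies first, then longer unit, then leftmost
    candidates.sort(key=lambda r: (-r.copy_number, -r.unit_length, r.start))
    chosen: list[RepeatAnnotation] = []
    taken = np.zeros(L, dtype=bool)
    for cand in candidates:
        span = slice(cand.start - 1, cand.end + cand.partial_length)
        if taken[span].any():
            continue
        taken[span] = True
        chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


def repeats_to_frame(repeats: list[RepeatAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in repeats])
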