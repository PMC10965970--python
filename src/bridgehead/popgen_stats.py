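"""Per-region diversity statistics and the 20-component ABC summary vector.

Haplotype diversity uses the n/(n-1) sample-size correction; nucleotide
diversity uses pairwise-complete comparison: for each sequence pair, columns
where either member holds N or a gap are dropped for that pair only, and the
per-pair denominator is the number of compared sites. Mean pairwise
differences are absolute counts (not per site), the convention of
coalescent-sampler summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bridgehead.alignment_io import MitogenomeAlignment, collapse_haplotypes

#: Canonical region order for reports and summary vectors. The first matching
#: scheme is used; unknown regions keep first-seen order after the known ones.
REGION_ORDER = (
    "Japan",
    "USA+Canada",
    "USA",
    "Azores",
    "Italy+Ticino",
    "Italy",
)


@dataclass
class DiversitySummary:
    """One region's row of the diversity report."""

    region: str
    n: int
    k: int
    Hd: float
    pi: float


def haplotype_diversity(counts) -> float:
    """Haplotype (gene) diversity Hd = (n/(n-1)) * (1 - sum p_i^2).

    `counts` are the haplotype multiplicities; n = sum(counts) must be >= 2.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0 or (counts < 1).any():
        raise ValueError("counts must be non-empty positive multiplicities")
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    return float(n / (n - 1.0) * (1.0 - np.square(counts / n).sum()))


def _pair_matrices(sites: np.ndarray):
    """(differences, compared_sites) matrices over all row pairs.

    Comparison is pairwise-complete: a column counts for a pair only when both
    members hold one of A, C, G, T. Computed with one-hot matrix products so
    the cost is 5 BLAS calls rather than an n^2 x L scan.
    """
    valid = np.zeros(sites.shape, dtype=np.float32)
    onehot = []
    for b in (b"A", b"C", b"G", b"T"):
        x = (sites == b).astype(np.float32)
        onehot.append(x)
        valid += x
    compared = valid @ valid.T
    matches = np.zeros_like(compared)
    for x in onehot:
        matches += x @ x.T
    return compared - matches, compared


def nucleotide_diversity(aln_or_sites) -> float:
    """Nucleotide diversity: mean over unordered pairs of per-site distance."""
    sites = aln_or_sites.sites if isinstance(aln_or_sites, MitogenomeAlignment) else np.asarray(aln_or_sites, dtype="S1")
    n = sites.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    diffs, compared = _pair_matrices(sites)
    iu = np.triu_indices(n, 1)
    comp = compared[iu]
    if (comp == 0).any():
        raise ValueError("a sequence pair shares no comparable sites")
    return float(np.mean(diffs[iu] / comp))


def mean_pairwise_differences(group_a, group_b=None) -> float:
    """Mean number of absolute differences among sequence pairs.

    Within-mode (group_b is None): average over unordered pairs of group_a.
    Between-mode: average over all cross pairs (a in group_a, b in group_b).
    """
    a = group_a.sites if isinstance(group_a, MitogenomeAlignment) else np.asarray(group_a, dtype="S1")
    if group_b is None:
        if a.shape[0] < 2:
            raise ValueError("within-group mode needs >= 2 sequences")
        diffs, _ = _pair_matrices(a)
        iu = np.triu_indices(a.shape[0], 1)
        return float(np.mean(diffs[iu]))
    b = group_b.sites if isinstance(group_b, MitogenomeAlignment) else np.asarray(group_b, dtype="S1")
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("between-group mode needs >= 1 sequence per group")
    stacked = np.concatenate([a, b], axis=0)
    diffs, _ = _pair_matrices(stacked)
    na = a.shape[0]
    return float(np.mean(diffs[:na, na:]))


def order_regions(regions) -> list[str]:
    """Fixed report order: native range first, then the invasion chain."""
    regions = list(dict.fromkeys(regions))
    known = [r for r in REGION_ORDER if r in regions]
    return known + [r for r in regions if r not in known]


def regional_diversity_report(
    aln: MitogenomeAlignment, partition: dict[str, list[str]] | None = None
) -> list[DiversitySummary]:
    """n, unique haplotypes, Hd and pi for each region of the sample."""
    if partition is None:
        partition = aln.region_partition()
    out = []
    for region in order_regions(partition):
        ids = partition[region]
        if not ids:
            raise ValueError(f"region {region!r} has no sequences")
        sub = aln.subset(ids)
        table = collapse_haplotypes(sub)
        k = table.n_haplotypes
        if len(ids) >= 2:
            hd = haplotype_diversity(table.counts)
            pi = nucleotide_diversity(sub)
        else:
            hd, pi = 0.0, 0.0
        out.append(DiversitySummary(region, len(ids), k, hd, pi))
    return out


def report_to_frame(report: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [r.region for r in report],
            "individuals": [r.n for r in report],
            "unique_mitogenomes": [r.k for r in report],
            "haplotype_diversity": [round(r.Hd, 5) for r in report],
            "nucleotide_diversity": [round(r.pi, 5) for r in report],
        }
    )


@dataclass
class SummaryStatVector:
    """The 20 ABC summary statistics, in a fixed documented order.

    For each of the 4 populations (in `order_regions` order): number of
    haplotypes, then mean within-population pairwise differences. For each of
    the 6 population pairs (lexicographic in the same order): number of
    haplotypes in the pooled two-population sample, then mean
    between-population pairwise differences.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != 20 or self.values.shape != (20,):
            raise ValueError("summary vector must have exactly 20 components")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dict(zip(self.names, self.values))])


# fast integer-coded path shared with the ABC simulator ----------------------

def _haplotype_count_codes(codes: np.ndarray) -> int:
    view = np.ascontiguousarray(codes).view(
        np.dtype((np.void, codes.dtype.itemsize * codes.shape[1]))
    )
    return len(np.unique(view))


def summary_from_codes(codes: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """20-vector from a gap/N-free integer-coded matrix and 4 row-index groups.

    Only segregating columns enter the pairwise-difference products, which
    keeps the per-simulation cost low inside ABC reference-table builds.
    """
    if len(groups) != 4:
        raise ValueError("exactly 4 populations required")
    n = codes.shape[0]
    seg = np.flatnonzero((codes != codes[0]).any(axis=0))
    # rows identical on segregating columns are identical everywhere, so both
    # haplotype counts and differences only need the segregating sub-matrix
    sub = np.ascontiguousarray(codes[:, seg])
    if seg.size:
        diffs = np.zeros((n, n), dtype=np.float32)
        for b in range(4):
            x = (sub == b).astype(np.float32)
            diffs += x @ x.T
        diffs = seg.size - diffs
    else:
        diffs = np.zeros((n, n), dtype=np.float32)
        sub = np.zeros((n, 1), dtype=codes.dtype)
    vals: list[float] = []
    for g in groups:
        vals.append(float(_haplotype_count_codes(sub[g])))
        block = diffs[np.ix_(g, g)]
        iu = np.triu_indices(len(g), 1)
        vals.append(float(block[iu].mean()) if len(g) >= 2 else 0.0)
    for i in range(4):
        for j in range(i + 1, 4):
            gi, gj = groups[i], groups[j]
            pooled = np.concatenate([gi, gj])
            vals.append(float(_haplotype_count_codes(sub[pooled])))
            vals.append(float(diffs[np.ix_(gi, gj)].mean()))
    return np.asarray(vals)


def summary_stat_names(region_order: list[str]) -> tuple[str, ...]:
    names = []
    for r in region_order:
        names += [f"nhap_{r}", f"mpd_{r}"]
    for i in range(4):
        for j in range(i + 1, 4):
            a, b = region_order[i], region_order[j]
            names += [f"nhap_{a}+{b}", f"mpd_{a}x{b}"]
    return tuple(names)


def summary_statistics(
    aln: MitogenomeAlignment, partition: dict[str, list[str]] | None = None
) -> SummaryStatVector:
    """The 20 one- and two-sample summary statistics used for ABC.

    Requires exactly 4 non-empty populations. On alignments containing N or
    gaps, differences are counted with pairwise-complete comparison (absolute
    counts over compared sites); haplotype counts use exact string identity.
    """
    if partition is None:
        partition = aln.region_partition()
    regions = order_regions(partition)
    if len(regions) != 4 or any(not partition[r] for r in regions):
        raise ValueError("summary statistics require exactly 4 non-empty regions")

    clean = np.isin(aln.sites, np.array([b"A", b"C", b"G", b"T"])).all()
    index = {s: i for i, s in enumerate(aln.sequence_ids)}
    groups = [np.array([index[s] for s in partition[r]]) for r in regions]
    if clean:
        lut = np.zeros(256, dtype=np.uint8)
        for code, b in enumerate(b"ACGT"):
            lut[b] = code
        codes = lut[aln.sites.view(np.uint8)]
        values = summary_from_codes(codes, groups)
    else:
        diffs, _ = _pair_matrices(aln.sites)
        vals: list[float] = []
        for g in groups:
            vals.append(float(collapse_haplotypes(aln.subset([aln.sequence_ids[i] for i in g])).n_haplotypes))
            iu = np.triu_indices(len(g), 1)
            vals.append(float(diffs[np.ix_(g, g)][iu].mean()) if len(g) >= 2 else 0.0)
        for i in range(4):
            for j in range(i + 1, 4):
                gi, gj = groups[i], groups[j]
                ids = [aln.sequence_ids[x] for x in np.concatenate([gi, gj])]
                vals.append(float(collapse_haplotypes(aln.subset(ids)).n_haplotypes))
                vals.append(float(diffs[np.ix_(gi, gj)].mean()))
        values = np.asarray(vals)
    return SummaryStatVector(summary_stat_names(regions), values)
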