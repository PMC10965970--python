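import numpy as np
import pytest

from bridgehead.alignment_io import MitogenomeAlignment


def make_alignment(rows: dict[str, str], regions: dict[str, str] | None = None) -> MitogenomeAlignment:
    """Build an alignment from {id: sequence}; default everyone to one region."""
    ids = list(rows)
    if regions is None:
        regions = {s: "Japan" for s in ids}
    sites = np.frombuffer("".join(rows[s] for s in ids).encode(), dtype="S1").reshape(
        len(ids), -1
    )
    return MitogenomeAlignment(ids, regions, sites.copy())


@pytest.fixture
def toy_alignment() -> MitogenomeAlignment:
    return make_alignment(
        {
            "s1": "ACGTACGTAC",
            "s2": "ACGTACGTAC",
            "s3": "ACGTTCGTAC",
            "s4": "ACGTTCGAAC",
        },
        {"s1": "Japan", "s2": "Japan", "s3": "USA", "s4": "USA"},
    )


def write_fasta(path, rows: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in rows.items():
            fh.write(f">{name}\n{seq}\n")


def write_metadata(path, regions: dict[str, str], sep="\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["id", "site", "region"]) + "\n")
        for name, region in regions.items():
            fh.write(sep.join([name, f"site_{name}", region]) + "\n")
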