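import numpy as np
import pytest
from hypothesis import settings

from kdrphylo.haplotypes import FragmentLayout, build_record

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# --------------------------------------------------------------------------
# A 15-haplotype intron-sharing fixture with eight intron-identity columns
# (A..H).  The intron 20-mers are synthetic stand-ins — only column
# membership and the 918/1014 codon states matter for the tests.
TABLE1_COLUMNS = {
    "A": ["kdr1", "super-kdr3"],
    "B": ["kdr2", "super-kdr1", "kdr-his4", "v39"],
    "C": ["kdr3", "super-kdr2"],
    "D": ["kdr4", "v40"],
    "E": ["kdr5", "v85"],
    "F": ["kdr-his1", "v54"],
    "G": ["kdr-his2", "v41"],
    "H": ["kdr-his3", "v42"],
}

_INTRON_PREFIX = {
    "A": "AA", "B": "AC", "C": "AG", "D": "AT",
    "E": "CA", "F": "CC", "G": "CG", "H": "CT",
}

_CLASS_CODONS = {
    "v": ("ATG", "TTA"),
    "kdr": ("ATG", "TTT"),
    "kdr-his": ("ATG", "CAT"),
    "super-kdr": ("ACG", "TTT"),
}


def _class_of(name: str) -> str:
    for prefix in ("super-kdr", "kdr-his", "kdr", "v"):
        if name.startswith(prefix):
            return prefix
    raise ValueError(name)


@pytest.fixture(scope="session")
def table1_layout():
    # toy fragment: codon918 | codon1014 | one spacer codon | 20-nt intron
    return FragmentLayout(
        codon918_offset=0,
        codon1014_offset=3,
        intron_start=9,
        intron_end=29,
        canonical_geometry=True,
    )


@pytest.fixture(scope="session")
def table1_records(table1_layout):
    """The 15 haplotypes of the intron-sharing fixture, in a discovery
    order that reproduces their kdr / kdr-his / super-kdr numbering."""
    seq_of = {}
    for col, members in TABLE1_COLUMNS.items():
        intron = _INTRON_PREFIX[col] + "ACGTACGTACGTACGTAC"
        assert len(intron) == 20
        for name in members:
            c918, c1014 = _CLASS_CODONS[_class_of(name)]
            seq_of[name] = c918 + c1014 + "GGA" + intron
    order = (
        [f"kdr{i}" for i in range(1, 6)]
        + [f"kdr-his{i}" for i in range(1, 5)]
        + [f"super-kdr{i}" for i in range(1, 4)]
        + ["v39", "v40", "v41", "v42", "v54", "v85"]
    )
    return [build_record(name, seq_of[name], table1_layout) for name in order]


@pytest.fixture
def rng():
    return np.random.default_rng(20120)
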