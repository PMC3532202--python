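"""Vssc haplotype classification and naming.

Resistance alleles of the house-fly voltage-sensitive sodium channel are
defined by the deduced amino acids at codons 918 and 1014: M918+L1014 is
susceptible, M918+F1014 is kdr, M918+H1014 is kdr-his and T918+F1014 is
super-kdr.  Haplotypes are named by allele class plus a number in discovery
order (kdr1, kdr-his2, super-kdr1, v17, ...), and grouped by exact identity
of the intron immediately downstream of codon 1014 — the hypervariable
marker that individualizes allele lineages.

Codon positions are supplied as fragment-local offsets through
:class:`FragmentLayout` because amplicon coordinates vary between studies;
the canonical fragment geometry (intron starting one codon, i.e. three
bases, downstream of codon 1014) can be asserted with a flag.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

ALLELE_CLASSES = ("susceptible", "kdr", "kdr-his", "super-kdr", "other")
RESISTANT_CLASSES = ("kdr", "kdr-his", "super-kdr")

_NAME_PREFIX = {
    "susceptible": "v",
    "kdr": "kdr",
    "kdr-his": "kdr-his",
    "super-kdr": "super-kdr",
    "other": "other",
}

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_VALID_CHARS = set("ACGTUMRWSYKVHDBN")


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentLayout:
    """Fragment-local coordinates of the functional codons and the intron.

    All offsets are 0-based columns of the aligned fragment;
    ``intron_start``/``intron_end`` delimit a half-open interval.  With
    ``canonical_geometry`` the layout is checked against the expected
    arrangement in which the intron begins three bases (one codon)
    downstream of codon 1014.
    """

    codon1014_offset: int
    intron_start: int
    intron_end: int
    codon918_offset: int | None = None
    canonical_geometry: bool = False

    def __post_init__(self):
        if self.intron_start >= self.intron_end:
            raise LayoutError("intron_start must be < intron_end")
        offsets = [self.codon1014_offset, self.intron_start]
        if self.codon918_offset is not None:
            offsets.append(self.codon918_offset)
        if any(o < 0 for o in offsets):
            raise LayoutError("offsets must be non-negative")
        if self.canonical_geometry and self.intron_start != self.codon1014_offset + 6:
            raise LayoutError(
                "canonical geometry requires the intron to start 6 bases "
                "(codon 1014 plus one codon) after codon1014_offset"
            )

    def check_bounds(self, seq_len: int) -> None:
        if self.codon1014_offset + 3 > seq_len or self.intron_end > seq_len:
            raise LayoutError(f"layout exceeds sequence length {seq_len}")
        if self.codon918_offset is not None and self.codon918_offset + 3 > seq_len:
            raise LayoutError(f"codon918 offset exceeds sequence length {seq_len}")


@dataclass
class HaplotypeRecord:
    """One sequenced allele with its deduced functional states."""

    label: str
    sequence: str
    aa918: str
    aa1014: str
    allele_class: str
    intron: str
    codon918: str
    codon1014: str
    name: str | None = None


def translate_codon(codon: str) -> str:
    """Translate a 3-mer under the standard genetic code.

    IUPAC-ambiguous codons are translated if every resolution agrees;
    codons containing gaps, or ambiguities with conflicting translations,
    give ``'?'``.  Non-nucleotide characters are an input error.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    codon = codon.upper().replace("U", "T")
    for ch in codon:
        if ch == "-":
            return "?"
        if ch not in _VALID_CHARS:
            raise ValueError(f"invalid nucleotide {ch!r} in codon {codon!r}")
    aas = {
        _CODON_TABLE["".join(c)]
        for c in itertools.product(*(ambiguous_dna_values[ch] for ch in codon))
    }
    return aas.pop() if len(aas) == 1 else "?"


def classify_allele(aa918: str, aa1014: str) -> str:
    """Map deduced amino-acid states to the allele class (total function)."""
    key = (aa918, aa1014)
    if key == ("M", "L"):
        return "susceptible"
    if key == ("M", "F"):
        return "kdr"
    if key == ("M", "H"):
        return "kdr-his"
    if key == ("T", "F"):
        return "super-kdr"
    return "other"


def extract_features(sequence: str, layout: FragmentLayout):
    """(aa918, aa1014, intron) from one aligned sequence.

    The intron is the aligned slice, gaps retained verbatim: intron
    identity is defined on the aligned coordinate system.  A missing
    codon-918 fragment yields aa918 = '?'.
    """
    layout.check_bounds(len(sequence))
    c1014 = sequence[layout.codon1014_offset : layout.codon1014_offset + 3]
    aa1014 = translate_codon(c1014)
    if layout.codon918_offset is not None:
        c918 = sequence[layout.codon918_offset : layout.codon918_offset + 3]
        aa918 = translate_codon(c918)
    else:
        aa918 = "?"
    intron = sequence[layout.intron_start : layout.intron_end]
    return aa918, aa1014, intron


def build_record(label: str, sequence: str, layout: FragmentLayout) -> HaplotypeRecord:
    """Classify one sequence into a :class:`HaplotypeRecord`."""
    sequence = sequence.upper()
    aa918, aa1014, intron = extract_features(sequence, layout)
    c918 = (
        sequence[layout.codon918_offset : layout.codon918_offset + 3]
        if layout.codon918_offset is not None
        else "---"
    )
    c1014 = sequence[layout.codon1014_offset : layout.codon1014_offset + 3]
    return HaplotypeRecord(
        label=label,
        sequence=sequence,
        aa918=aa918,
        aa1014=aa1014,
        allele_class=classify_allele(aa918, aa1014),
        intron=intron,
        codon918=c918,
        codon1014=c1014,
    )


def group_by_intron(records) -> list:
    """Partition records by exact intron string identity.

    Groups are ordered by their first-discovered member; each group is the
    list of records in discovery order.  The output is a partition: every
    record appears in exactly one group.
    """
    groups: dict[str, list] = {}
    for rec in records:
        groups.setdefault(rec.intron, []).append(rec)
    return list(groups.values())


@dataclass
class HaplotypeCatalog:
    """Registry of named haplotypes with stable discovery-order numbering.

    Identity is (intron string, codon-918 state, codon-1014 state): a
    resubmitted identical haplotype reuses its name; a novel one receives
    the class prefix plus the next integer for that class.  The catalog is
    an explicit input/output so numbering survives across input batches.
    """

    entries: list = field(default_factory=list)
    _index: dict = field(default_factory=dict, repr=False)
    _counters: dict = field(default_factory=dict, repr=False)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @property
    def names(self):
        return [e.name for e in self.entries]

    def _key(self, rec: HaplotypeRecord):
        return (rec.intron, rec.codon918, rec.codon1014)

    def assign(self, rec: HaplotypeRecord) -> str:
        """Name one record (idempotent); returns the name."""
        key = self._key(rec)
        name = self._index.get(key)
        if name is None:
            cls = rec.allele_class
            self._counters[cls] = self._counters.get(cls, 0) + 1
            name = f"{_NAME_PREFIX[cls]}{self._counters[cls]}"
            self._index[key] = name
            entry = HaplotypeRecord(**{**rec.__dict__, "name": name})
            self.entries.append(entry)
        rec.name = name
        return name

    def intron_groups(self) -> list:
        """Intron-identity partition of the catalog as lists of names."""
        return [
            [r.name for r in grp] for grp in group_by_intron(self.entries)
        ]

    def to_frame(self):
        import pandas as pd

        groups = self.intron_groups()
        gid = {}
        for i, grp in enumerate(groups, start=1):
            for name in grp:
                gid[name] = i
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "class": [e.allele_class for e in self.entries],
                "aa918": [e.aa918 for e in self.entries],
                "aa1014": [e.aa1014 for e in self.entries],
                "intron_group": [gid[e.name] for e in self.entries],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def unique_haplotypes_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.name}\n{e.sequence}\n")


def assign_names(new_records, catalog: HaplotypeCatalog) -> HaplotypeCatalog:
    """Assign (or look up) names for ``new_records`` in discovery order,
    updating and returning the catalog."""
    for rec in new_records:
        catalog.assign(rec)
    return catalog
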