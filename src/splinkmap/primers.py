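"""Splinkerette-adapter and piggyBac-ITR primer sets.

A splinkerette library is amplified with a hairpin adapter pair
(``splinkerette_top`` / ``splinkerette_hairpin``), a primary PCR anchored in
each inverted terminal repeat (ITR) of the transposon (``primary_5TR`` /
``primary_3TR``), and a secondary *nested* PCR (``nested_5TR`` /
``nested_3TR``).  The nested primers dominate the sequenced product, so they
are what read trimming looks for and what assigns a junction read to the
5'TR (left) or 3'TR (right) side of the insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

from ._seq import validate_dna


@dataclass(frozen=True)
class PrimerSet:
    """The six primer sequences used for trimming and side assignment.

    All sequences are normalized to uppercase A/C/G/T on construction.
    """

    splinkerette_top: str
    splinkerette_hairpin: str
    primary_5TR: str
    primary_3TR: str
    nested_5TR: str
    nested_3TR: str

    def __post_init__(self) -> None:
        for f in fields(self):
            object.__setattr__(
                self, f.name, validate_dna(getattr(self, f.name), f.name)
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PrimerSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown primer keys: {sorted(unknown)}")
        merged = {f.name: d.get(f.name, getattr(DEFAULT_PRIMERS, f.name)) for f in fields(cls)}
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str) -> "PrimerSet":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


# Default primers of the piggyBac splinkerette protocol this package models:
# HMSpAa/HMSpBb splinkerette adapter strands, PB-L/R-Sp1 primary and
# PB-L/R-Sp2 nested ITR primers.
DEFAULT_PRIMERS = PrimerSet(
    splinkerette_top=(
        "CGAAGAGTAACCGTTGCTAGGAGAGACCGTGGCTGAATGAGACTGGTGTCGACACTAGTGG"
    ),
    splinkerette_hairpin="GATCCCACTAGTGTCGACACCAGTCTCTAATTTTTTTTTTCAAAAAAA",
    primary_5TR="GCGTGCTTGTCAATGCGGTAAGTGTCACTG",
    primary_3TR="CCTCGATATACAGACCGATAAAACACATGC",
    nested_5TR="ACGCATGCATTCTTGAAATATTGCTCTCTC",
    nested_3TR="ACGCATGATTATCTTTAACGTACGTCACAA",
)
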