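"""smFISH probe sets.

A single mRNA is tiled by tens of short singly-labelled DNA oligos; the
brightness of one diffraction-limited spot is therefore set by how many
probes actually hybridized.  The probe list is the anchor of the synthetic
brightness model (see :mod:`smfishq.simulate`), and validating the printed
set (count, lengths) is the first sanity check of any quantification run.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

__all__ = ["ProbeSet", "make_probe_set", "validate_probe_set", "CLN2_QUASAR570_PROBES"]

#: Published Stellaris probe set against the S. cerevisiae CLN2 mRNA,
#: conjugated to Quasar 570; 48 oligos, nominally 20 nt each.
CLN2_QUASAR570_PROBES = """\
ttgatgacgagtcccatacg,cggatagtagtccggtttag,attctgcattagatagctca,
ttcttgcagcatttcgaagt,aacattggtggagatttctt,gctggtctattagttttgga,
taatgttggaccttgtttcc,ccacagacagctcgaacaaa,ataccatttgtcactcgagt,
ctcttggaacaatagcggtc,acaaccaatttggcttggtc,agccaaccagagacaagtag,
atgatgtgattacaaccgcc,ccagtagggatgactacatt,gggttgggaccataaaatct,
cagagagtcgaggtatacgt,gaccatcaccacagtaatga,gtctagtatatgtctttcca,
gactgacgtttttcagagca,tctacagtggcatcactatc,tttaagtcttcttcttcttc,
ctaagtaagtcgtactgcca,gagaatatgccgtgcgatac,aaaggaccgtggtcttgatt,
gctttctgatgtcattggag,atgccgttcattaaggtact,cttccatcaaggagttagga,
agaacaccattgaccgtttt,caagtgatattctttcact,gttggatgcaatttgcagtt,
gatatggtaagctttctcga,ttcgaaagagcatgatgggg,gcgaaggaatggatgtgcta,
gagtgtggctttgagatgag,atcagagagtgagctcatgt,catattccggctgaaaacgc,
cttggagtgattggtgatga,ctgctgaccaaattggtaca,gtgctaccacatatactgtt,
ttcaccagactattcacact,tttgttcgtagatcctttgt,atcattggttgcgttattgc,
ttggttttccttgttagact,attgaggtaatgcgccgttg,ggggaacattccatggttaa,
ctatttatggtcccagttgg,gatgaggcactgctagattt,ggtattgcccataccaaaag
"""

_VALID = frozenset("acgt")


@dataclass(frozen=True)
class ProbeSet:
    """An ordered list of lowercase DNA probe sequences."""

    probes: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("ProbeSet must contain at least one probe")
        for i, p in enumerate(self.probes):
            bad = set(p) - _VALID
            if bad:
                raise ValueError(
                    f"probe {i} ({p!r}) contains non-acgt character(s): {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def lengths(self) -> tuple[int, ...]:
        """Per-probe length, in probe order."""
        return tuple(len(p) for p in self.probes)


def make_probe_set(raw_text: str, name: str = "") -> ProbeSet:
    """Parse a comma- or newline-separated probe list into a :class:`ProbeSet`.

    Tokens are stripped of surrounding whitespace; empty tokens are ignored.
    Raises ``ValueError`` for empty input or for a token with characters
    outside ``acgt`` (the error names the offending token index).
    """
    tokens = [
        tok.strip()
        for chunk in raw_text.split("\n")
        for tok in chunk.split(",")
        if tok.strip()
    ]
    if not tokens:
        raise ValueError("no probe sequences found in input")
    for i, tok in enumerate(tokens):
        bad = set(tok) - _VALID
        if bad:
            raise ValueError(
                f"token {i} ({tok!r}) contains invalid character(s): {sorted(bad)}"
            )
    return ProbeSet(probes=tuple(tokens), name=name)


def validate_probe_set(pset: ProbeSet) -> dict:
    """Report structural statistics of a probe set.

    Returns a dict with ``n_probes``, ``median_length``, and
    ``off_length_probes`` — the (index, sequence, length) of every probe whose
    length differs from the median.  Off-length probes are reported, never
    silently corrected: a 19-mer in a nominally 20-nt set is worth a look at
    the source.
    """
    lengths = pset.lengths
    med = int(statistics.median(lengths))
    off = [
        {"index": i, "sequence": p, "length": len(p)}
        for i, p in enumerate(pset.probes)
        if len(p) != med
    ]
    return {
        "n_probes": len(pset),
        "median_length": med,
        "min_length": min(lengths),
        "max_length": max(lengths),
        "off_length_probes": off,
    }
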