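"""Degenerate cis-element scanning of 3' UTR sequences.

Patterns are IUPAC strings over the RNA alphabet (degenerate codes allowed in
patterns only; sequences are concrete A/C/G/U, with T mapped to U on input).
Matching is on the sense strand, counting every start offset including
overlapping occurrences, so the per-kilobase density statistic does not depend
on greedy match consumption.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

__all__ = [
    "IUPAC_RNA",
    "UTRRecord",
    "MotifPattern",
    "expand_iupac",
    "scan",
    "variant_patterns",
    "density_table",
    "read_utrs_fasta",
]

IUPAC_RNA: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "U": "U",
    "T": "U",
    "R": "AG",
    "Y": "CU",
    "S": "CG",
    "W": "AU",
    "K": "GU",
    "M": "AC",
    "B": "CGU",
    "D": "AGU",
    "H": "ACU",
    "V": "ACG",
    "N": "ACGU",
}


@dataclass(frozen=True)
class UTRRecord:
    """A 3' UTR sequence over {A, C, G, U}."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC-degenerate motif, e.g. UAUAUAUGUW for the modified NRE."""

    name: str
    iupac: str
    variant_position: str | None = None

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty pattern")
        for ch in self.iupac.upper():
            if ch not in IUPAC_RNA:
                raise ValueError(f"invalid IUPAC code {ch!r} in pattern {self.name!r}")

    def regex(self) -> re.Pattern:
        body = "".join(
            s if len(s := IUPAC_RNA[ch]) == 1 else f"[{s}]"
            for ch in self.iupac.upper()
        )
        # lookahead so overlapping occurrences are all counted
        return re.compile(f"(?=({body}))")


def expand_iupac(pattern: MotifPattern | str) -> set[str]:
    """All concrete strings matching the pattern (cartesian expansion)."""
    iupac = pattern.iupac if isinstance(pattern, MotifPattern) else pattern
    MotifPattern(name="_", iupac=iupac)  # validates
    choices = [IUPAC_RNA[ch] for ch in iupac.upper()]
    return {"".join(p) for p in itertools.product(*choices)}


def scan(utr: UTRRecord, pattern: MotifPattern) -> int:
    """Number of (overlapping) start offsets at which the pattern matches."""
    if len(pattern.iupac) > utr.length:
        return 0
    return sum(1 for _ in pattern.regex().finditer(utr.sequence))


def variant_patterns(
    base: MotifPattern, position: int, label: str | None = None
) -> list[MotifPattern]:
    """The four single-nucleotide substitutions at one pattern position.

    `position` is a 0-based index into the pattern; the substitution equal to
    the base letter reproduces the base pattern.  Names follow the
    "<label><X>" convention (default label "+<position>"), e.g. "+4U".
    """
    if not 0 <= position < len(base.iupac):
        raise ValueError(
            f"position {position} out of range for pattern of length {len(base.iupac)}"
        )
    label = label if label is not None else f"+{position}"
    out = []
    for nt in "AUGC":
        iupac = base.iupac[:position] + nt + base.iupac[position + 1 :]
        out.append(
            MotifPattern(name=f"{label}{nt}", iupac=iupac, variant_position=label)
        )
    return out


def density_table(
    utrs: list[UTRRecord],
    patterns: list[MotifPattern],
    length_cap: int | None = None,
) -> pd.DataFrame:
    """Per gene x pattern site counts, presence and density (sites/kb).

    `length_cap` optionally excludes UTRs longer than the cap (useful for
    motif-discovery-adjacent analyses where rare very long UTRs dominate);
    density and presence analyses use all UTRs by default.
    """
    rows = []
    for utr in utrs:
        if length_cap is not None and utr.length > length_cap:
            continue
        for pat in patterns:
            n = scan(utr, pat)
            rows.append(
                {
                    "gene_id": utr.gene_id,
                    "pattern": pat.name,
                    "site_count": n,
                    "length": utr.length,
                    "density": n / (utr.length / 1000.0),
                    "present": n >= 1,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "pattern", "site_count", "length", "density", "present"]
    )


def read_utrs_fasta(path) -> list[UTRRecord]:
    """Read 3' UTRs from FASTA; headers carry gene ids, T is mapped to U."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        records.append(UTRRecord(gene_id=rec.id, sequence=seq))
    return records
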