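"""Companion resources: known-germline sites, human somatic mutations, codon maps.

Three lookups drive tumor-only discrimination without a matched normal:

* a known-germline site database (exact chrom/pos/ref/alt match);
* a human somatic mutation database keyed by gene + protein change, used to
  rescue rare canine mutations whose human orthologous mutation is an
  established somatic event;
* per-gene canine→human codon maps (identity, constant offset such as
  BRAF +12 so canine V588 lands on human V600, or an explicit codon-pair
  table derived from a pairwise protein alignment).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .variant_io import Key

_PROTEIN_CHANGE_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


def parse_protein_change(change: str) -> tuple[str, int, str] | None:
    """Split ``V588E`` into (ref_aa, codon, alt_aa); None for non-substitutions."""
    m = _PROTEIN_CHANGE_RE.match(change)
    if m is None:
        return None
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class KnownGermlineDB:
    """Exact-match site list of known germline variants."""

    sites: frozenset[Key]
    provenance: str = ""

    def __contains__(self, key: Key) -> bool:
        return key in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def from_table(cls, path: str | Path, provenance: str = "") -> "KnownGermlineDB":
        sites = set()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["chrom", "pos", "ref", "alt"]:
                raise ValueError(f"{path}: expected chrom/pos/ref/alt columns")
            for line in fh:
                chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
                sites.add((chrom, int(pos), ref, alt))
        return cls(frozenset(sites), provenance or str(path))

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\n")
            for chrom, pos, ref, alt in sorted(self.sites):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def is_known_germline(db: KnownGermlineDB, key: Key) -> bool:
    """True iff the exact (chrom, pos, ref, alt) key is in the database."""
    return key in db


@dataclass(frozen=True)
class HumanSomaticDB:
    """Human somatic mutations keyed by (gene, human protein change).

    ``codons`` is derived from the substitution-style entries and supports the
    optional codon-level matching mode (any amino-acid change at the codon).
    """

    entries: frozenset[tuple[str, str]]
    codons: frozenset[tuple[str, int]] = field(default=frozenset())

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, str]]) -> "HumanSomaticDB":
        entries = frozenset(entries)
        codons = set()
        for gene, change in entries:
            parsed = parse_protein_change(change)
            if parsed is not None:
                codons.add((gene, parsed[1]))
        return cls(entries, frozenset(codons))

    @classmethod
    def from_table(cls, path: str | Path) -> "HumanSomaticDB":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["gene", "protein_change"]:
                raise ValueError(f"{path}: expected gene/protein_change columns")
            for line in fh:
                gene, change = line.rstrip("\n").split("\t")[:2]
                rows.append((gene, change))
        return cls.from_entries(rows)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tprotein_change\n")
            for gene, change in sorted(self.entries):
                fh.write(f"{gene}\t{change}\n")

    def __len__(self) -> int:
        return len(self.entries)


class CodonMap:
    """Per-gene canine→human codon mapping.

    Each gene maps through either a constant offset (0 = identity) or an
    explicit codon-pair table. Genes absent from the map translate to no
    human codon (``None``), never an error.
    """

    def __init__(
        self,
        offsets: dict[str, int] | None = None,
        tables: dict[str, dict[int, int]] | None = None,
    ):
        self.offsets = dict(offsets or {})
        self.tables = {g: dict(t) for g, t in (tables or {}).items()}
        for gene, table in self.tables.items():
            if len(set(table.values())) != len(table):
                raise ValueError(f"codon map for {gene} is not injective")

    def map_codon(self, gene: str, canine_codon: int) -> int | None:
        if gene in self.tables:
            return self.tables[gene].get(canine_codon)
        if gene in self.offsets:
            return canine_codon + self.offsets[gene]
        return None

    def inverse(self, gene: str, human_codon: int) -> int | None:
        if gene in self.tables:
            for k, v in self.tables[gene].items():
                if v == human_codon:
                    return k
            return None
        if gene in self.offsets:
            return human_codon - self.offsets[gene]
        return None

    @classmethod
    def from_table(cls, path: str | Path) -> "CodonMap":
        """Read a table with rows ``gene<TAB>canine_codon<TAB>human_codon``.

        A row with canine_codon ``*`` declares a constant offset in the
        human_codon column (0 = identity over the whole gene).
        """
        offsets: dict[str, int] = {}
        tables: dict[str, dict[int, int]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["gene", "canine_codon", "human_codon"]:
                raise ValueError(f"{path}: expected gene/canine_codon/human_codon columns")
            for line in fh:
                gene, canine, human = line.rstrip("\n").split("\t")[:3]
                if canine == "*":
                    offsets[gene] = int(human)
                else:
                    tables.setdefault(gene, {})[int(canine)] = int(human)
        return cls(offsets, tables)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tcanine_codon\thuman_codon\n")
            for gene in sorted(self.offsets):
                fh.write(f"{gene}\t*\t{self.offsets[gene]}\n")
            for gene in sorted(self.tables):
                for canine, human in sorted(self.tables[gene].items()):
                    fh.write(f"{gene}\t{canine}\t{human}\n")

    @classmethod
    def from_protein_alignment(
        cls, gene: str, canine_seq: str, human_seq: str
    ) -> "CodonMap":
        """Derive an explicit codon-pair table from a global protein alignment.

        Uses BLOSUM62 with affine gaps (open -11, extend -1); aligned
        non-gap column pairs define the mapping (1-based codons).
        """
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        alignment = max(
            aligner.align(canine_seq, human_seq),
            key=lambda a: sum(
                1
                for (s1, e1), (s2, _) in zip(*a.aligned)
                for i in range(e1 - s1)
                if canine_seq[s1 + i] == human_seq[s2 + i]
            ),
        )
        table: dict[int, int] = {}
        for (s1, e1), (s2, _e2) in zip(*alignment.aligned):
            for i in range(e1 - s1):
                table[s1 + i + 1] = s2 + i + 1
        return cls(tables={gene: table})


def map_codon(codon_map: CodonMap, gene: str, canine_codon: int) -> int | None:
    return codon_map.map_codon(gene, canine_codon)


def is_known_human_somatic(
    db: HumanSomaticDB,
    codon_map: CodonMap,
    gene: str | None,
    protein_change: str | None,
    codon_level: bool = False,
) -> bool:
    """Is the canine mutation's human counterpart a known human somatic mutation?

    The canine protein change is translated through the codon map before
    lookup. With ``codon_level=True`` any recorded change at the mapped human
    codon matches (e.g. canine H1047L matches a database holding only
    H1047R); the default requires the exact amino-acid change. Unannotated or
    unmappable mutations never match.
    """
    if gene is None or protein_change is None:
        return False
    parsed = parse_protein_change(protein_change)
    if parsed is None:
        # non-substitution changes (indels) use the raw string, identity codons
        return (gene, protein_change) in db.entries
    ref_aa, canine_codon, alt_aa = parsed
    human_codon = codon_map.map_codon(gene, canine_codon)
    if human_codon is None:
        return False
    if codon_level:
        return (gene, human_codon) in db.codons
    return (gene, f"{ref_aa}{human_codon}{alt_aa}") in db.entries
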