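"""Variant input/output, QC filtering, pooling and minimal protein annotation.

Variant calls are read from per-sample VCFs (v4.2, with ``DP``/``AD`` FORMAT
fields and ``FS``/``QD`` INFO annotations as emitted by common germline
callers) into :class:`VariantCall` records, one per ALT allele. Record-level
filters reject calls with strand bias FS > 30.0, quality-by-depth QD < 2.0,
or total read coverage < 10. Calls from many samples are pooled into
:class:`UniqueMutation` keys (site + alleles) carrying the per-sample VAF
sample that downstream germline/somatic discrimination operates on.

Annotation is deliberately minimal: a transcript model supplies per-gene CDS
intervals, strand and the spliced coding sequence, from which codon numbers
and protein changes (e.g. ``V588E``) are derived with the standard codon
table. Splice sites, UTRs and full consequence prediction are out of scope.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

MUTATION_CLASSES = ("substitution", "in_frame_indel", "frameshift", "truncation", "other")

#: site + alleles key identifying a mutation across samples
Key = tuple[str, int, str, str]


class VcfFormatError(ValueError):
    """A VCF record is missing a required field or cannot be parsed."""


class TranscriptModelError(ValueError):
    """The transcript model is internally inconsistent (e.g. overlapping CDS)."""


@dataclass
class VariantCall:
    """One called variant in one sample.

    Positions are 1-based as in VCF. ``vaf`` is ``alt_depth / depth``.
    ``fs`` / ``qd`` may be absent (None); absent annotations pass the
    corresponding QC sub-filter. Annotation fields are filled by
    :func:`annotate` and stay None for calls outside the transcript model.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_depth: int
    fs: float | None = None
    qd: float | None = None
    gene: str | None = None
    codon: int | None = None
    protein_change: str | None = None
    mutation_class: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> Key:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass
class UniqueMutation:
    """A pooled mutation key with its carrier samples and aligned VAFs."""

    key: Key
    carriers: tuple[str, ...]
    vafs: tuple[float, ...]
    gene: str | None = None
    codon: int | None = None
    protein_change: str | None = None
    mutation_class: str = "other"

    def __post_init__(self) -> None:
        if len(self.carriers) != len(self.vafs) or not self.carriers:
            raise ValueError("carriers and vafs must be non-empty and aligned")
        if len(set(self.carriers)) != len(self.carriers):
            raise ValueError(f"duplicate carriers for {self.key}")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


# ---------------------------------------------------------------------------
# VCF reading / writing


def read_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantCall]:
    """Read one sample's VCF into VariantCall records, one per ALT allele.

    Multi-allelic records are split; the VAF of allele *i* is ``AD[i+1]/DP``.
    ``sample_id`` defaults to the (single) sample name in the VCF header.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    calls: list[VariantCall] = []
    with vf:
        samples = list(vf.header.samples)
        if sample_id is None:
            if len(samples) != 1:
                raise VcfFormatError(f"{path}: expected one sample, found {samples}")
            sample_id = samples[0]
        for rec in vf:
            sdat = rec.samples[samples[0]] if samples else None
            if sdat is None or sdat.get("DP") is None or sdat.get("AD") is None:
                raise VcfFormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks DP/AD"
                )
            depth = int(sdat["DP"])
            ad = sdat["AD"]
            fs = rec.info.get("FS")
            qd = rec.info.get("QD")
            for i, alt in enumerate(rec.alts or ()):
                alt_depth = int(ad[i + 1]) if ad[i + 1] is not None else 0
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=depth,
                        alt_depth=min(alt_depth, depth),
                        fs=float(fs) if fs is not None else None,
                        qd=float(qd) if qd is not None else None,
                    )
                )
    return calls


def _vcf_header(contigs: Iterable[str], sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">')
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_sample(sample_id)
    return header


def write_vcf(path: str | Path, calls: Sequence[VariantCall], contigs: Sequence[str] | None = None) -> None:
    """Write one sample's calls as an uncompressed VCF v4.2.

    All calls must share one ``sample_id``. Calls are written sorted by
    (contig order, position, alt) so output is deterministic.
    """
    if not calls:
        raise ValueError("cannot write an empty call list (sample unknown)")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise ValueError(f"write_vcf expects a single sample, got {sorted(sample_ids)}")
    if contigs is None:
        contigs = sorted({c.chrom for c in calls})
    order = {c: i for i, c in enumerate(contigs)}
    header = _vcf_header(contigs, calls[0].sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (order[c.chrom], c.pos, c.alt)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            if call.fs is not None:
                rec.info["FS"] = call.fs
            if call.qd is not None:
                rec.info["QD"] = call.qd
            sdat = rec.samples[call.sample_id]
            sdat["GT"] = (0, 1)
            sdat["DP"] = call.depth
            sdat["AD"] = (call.depth - call.alt_depth, call.alt_depth)
            out.write(rec)


# ---------------------------------------------------------------------------
# QC filtering


def qc_filter(
    calls: Sequence[VariantCall],
    max_fs: float = 30.0,
    min_qd: float = 2.0,
    min_depth: int = 10,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split calls into (passing, rejected) by record-level QC.

    A call is rejected iff FS > 30.0 or QD < 2.0 or depth < 10 (strict
    inequalities; boundary values pass). Absent FS/QD annotations pass their
    sub-filter. Input order is preserved in both outputs.
    """
    passing: list[VariantCall] = []
    rejected: list[VariantCall] = []
    for call in calls:
        bad = (
            (call.fs is not None and call.fs > max_fs)
            or (call.qd is not None and call.qd < min_qd)
            or call.depth < min_depth
        )
        (rejected if bad else passing).append(call)
    return passing, rejected


# ---------------------------------------------------------------------------
# Pooling


def pool_unique(calls: Sequence[VariantCall]) -> list[UniqueMutation]:
    """Pool per-sample calls into unique mutations keyed by (chrom, pos, ref, alt).

    Duplicate (sample, key) pairs are collapsed keeping the max-depth call,
    with a logged warning. Total mutation count = sum over unique mutations of
    their carrier counts; unique count = number of keys.
    """
    per_key: dict[Key, dict[str, VariantCall]] = {}
    key_order: list[Key] = []
    for call in calls:
        bucket = per_key.get(call.key)
        if bucket is None:
            bucket = per_key[call.key] = {}
            key_order.append(call.key)
        prev = bucket.get(call.sample_id)
        if prev is not None:
            logger.warning(
                "duplicate call for sample %s at %s; keeping max-depth record",
                call.sample_id,
                call.key,
            )
            if call.depth <= prev.depth:
                continue
        bucket[call.sample_id] = call
    pooled: list[UniqueMutation] = []
    for key in key_order:
        bucket = per_key[key]
        carriers = tuple(bucket)
        annotated = next((c for c in bucket.values() if c.gene is not None), next(iter(bucket.values())))
        pooled.append(
            UniqueMutation(
                key=key,
                carriers=carriers,
                vafs=tuple(bucket[s].vaf for s in carriers),
                gene=annotated.gene,
                codon=annotated.codon,
                protein_change=annotated.protein_change,
                mutation_class=annotated.mutation_class,
            )
        )
    return pooled


# ---------------------------------------------------------------------------
# Transcript model and annotation


@dataclass(frozen=True)
class Transcript:
    """A single-isoform CDS model: exon intervals plus the spliced coding sequence.

    ``exons`` are genomic 1-based inclusive intervals sorted by start;
    ``cds_seq`` is the coding-orientation sequence (reverse-complemented
    relative to the genome for minus-strand genes).
    """

    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise TranscriptModelError(f"{self.gene}: strand must be + or -")
        total = sum(e - s + 1 for s, e in self.exons)
        if total != len(self.cds_seq):
            raise TranscriptModelError(
                f"{self.gene}: exon span {total} != CDS length {len(self.cds_seq)}"
            )
        if total % 3 != 0:
            raise TranscriptModelError(f"{self.gene}: CDS length {total} not divisible by 3")
        last_end = 0
        for s, e in self.exons:
            if s <= last_end or e < s:
                raise TranscriptModelError(f"{self.gene}: exons not sorted/disjoint")
            last_end = e

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3

    def cds_offset(self, pos: int) -> int | None:
        """0-based coding-orientation offset of genomic position ``pos``, or None."""
        cum = 0
        for s, e in self.exons:
            if s <= pos <= e:
                plus_off = cum + (pos - s)
                if self.strand == "+":
                    return plus_off
                return len(self.cds_seq) - 1 - plus_off
            cum += e - s + 1
        return None

    def genomic_pos(self, offset: int) -> int:
        """Inverse of :meth:`cds_offset`."""
        if not 0 <= offset < len(self.cds_seq):
            raise ValueError(f"{self.gene}: offset {offset} outside CDS")
        plus_off = offset if self.strand == "+" else len(self.cds_seq) - 1 - offset
        cum = 0
        for s, e in self.exons:
            width = e - s + 1
            if plus_off < cum + width:
                return s + (plus_off - cum)
            cum += width
        raise AssertionError("unreachable")


class TranscriptModel:
    """Lookup table from genomic position to transcript, with overlap validation."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: dict[str, Transcript] = {}
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for tx in transcripts:
            if tx.gene in self.transcripts:
                raise TranscriptModelError(f"duplicate gene {tx.gene}")
            self.transcripts[tx.gene] = tx
            span = (tx.exons[0][0], tx.exons[-1][1], tx.gene)
            by_chrom.setdefault(tx.chrom, []).append(span)
        self._index: dict[str, tuple[list[int], list[tuple[int, int, str]]]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1, g1), (s2, _e2, g2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise TranscriptModelError(
                        f"overlapping transcripts {g1}/{g2} on {chrom}"
                    )
            self._index[chrom] = ([s for s, _, _ in spans], spans)

    def __contains__(self, gene: str) -> bool:
        return gene in self.transcripts

    def __getitem__(self, gene: str) -> Transcript:
        return self.transcripts[gene]

    def genes(self) -> list[str]:
        return list(self.transcripts)

    def locate(self, chrom: str, pos: int) -> Transcript | None:
        entry = self._index.get(chrom)
        if entry is None:
            return None
        starts, spans = entry
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        s, e, gene = spans[i]
        return self.transcripts[gene] if s <= pos <= e else None

    # -- serialization (tab-separated, one row per transcript) --

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tchrom\tstrand\texon_starts\texon_ends\tcds_seq\n")
            for gene in sorted(self.transcripts):
                tx = self.transcripts[gene]
                starts = ",".join(str(s) for s, _ in tx.exons)
                ends = ",".join(str(e) for _, e in tx.exons)
                fh.write(f"{tx.gene}\t{tx.chrom}\t{tx.strand}\t{starts}\t{ends}\t{tx.cds_seq}\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "TranscriptModel":
        txs = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("gene\t"):
                raise TranscriptModelError(f"{path}: unexpected header {header!r}")
            for line in fh:
                gene, chrom, strand, starts, ends, seq = line.rstrip("\n").split("\t")
                exons = tuple(
                    (int(s), int(e))
                    for s, e in zip(starts.split(","), ends.split(","))
                )
                txs.append(Transcript(gene, chrom, strand, exons, seq))
        return cls(txs)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def annotate(calls: Sequence[VariantCall], model: TranscriptModel) -> list[VariantCall]:
    """Attach gene/codon/protein_change to calls that fall inside the model.

    Calls outside any transcript are retained unannotated. SNVs get a protein
    change like ``V588E`` (codon = ceil(CDS position / 3)); a stop-gain is
    classed ``truncation``. Indels are classed by length: net length divisible
    by 3 → ``in_frame_indel``, else ``frameshift``, with a coordinate-style
    protein change (e.g. ``1038_1040del``).
    """
    for call in calls:
        tx = model.locate(call.chrom, call.pos)
        if call.is_snv:
            call.mutation_class = "substitution"
        else:
            net = abs(len(call.alt) - len(call.ref))
            call.mutation_class = "in_frame_indel" if net % 3 == 0 else "frameshift"
        if tx is None:
            continue
        offset = tx.cds_offset(call.pos)
        if offset is None:  # intronic
            continue
        call.gene = tx.gene
        codon_idx = offset // 3
        call.codon = codon_idx + 1
        if call.is_snv:
            within = offset % 3
            ref_codon = tx.cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
            coding_ref = call.ref if tx.strand == "+" else _revcomp(call.ref)
            coding_alt = call.alt if tx.strand == "+" else _revcomp(call.alt)
            if ref_codon[within].upper() != coding_ref.upper():
                warnings.warn(
                    f"reference mismatch for {call.chrom}:{call.pos} in {tx.gene}; "
                    "left unannotated at protein level"
                )
                call.protein_change = None
                continue
            alt_codon = ref_codon[:within] + coding_alt + ref_codon[within + 1 :]
            aa_ref = str(Seq(ref_codon).translate())
            aa_alt = str(Seq(alt_codon).translate())
            call.protein_change = f"{aa_ref}{call.codon}{aa_alt}"
            if aa_alt == "*" and aa_ref != "*":
                call.mutation_class = "truncation"
        else:
            net = len(call.alt) - len(call.ref)
            if net < 0:
                # deleted bases start after the anchor base
                first = tx.cds_offset(call.pos + 1)
                last = tx.cds_offset(call.pos - net)
                if first is not None and last is not None:
                    c1, c2 = sorted((first // 3 + 1, last // 3 + 1))
                    call.codon = c1
                    call.protein_change = f"{c1}_{c2}del"
            else:
                call.protein_change = f"{call.codon}ins"
    return list(calls)


# ---------------------------------------------------------------------------
# Tabular output


def calls_to_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write one row per sample-variant (annotated variant table)."""
    cols = (
        "sample_id\tchrom\tpos\tref\talt\tdepth\talt_depth\tvaf\tfs\tqd"
        "\tgene\tcodon\tprotein_change\tmutation_class\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.depth}"
                f"\t{c.alt_depth}\t{c.vaf:.6g}\t{'' if c.fs is None else f'{c.fs:.4g}'}"
                f"\t{'' if c.qd is None else f'{c.qd:.4g}'}"
                f"\t{c.gene or ''}\t{c.codon or ''}\t{c.protein_change or ''}"
                f"\t{c.mutation_class}\n"
            )
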