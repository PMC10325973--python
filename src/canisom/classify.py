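"""Germline–somatic discrimination for tumor-only panel sequencing.

Without a matched normal, germline variants are removed in three stages:

1. exact-match filtering against a known-germline site database;
2. for mutations recurrent in >= 5 dogs, inspection of the across-carrier
   VAF sample — heterozygous germline clusters around 0.5, homozygous
   germline near 1.0, while somatic VAFs are broadly ("randomly")
   distributed;
3. for rare mutations (< 5 dogs), rescue as somatic when the human
   orthologous mutation is a known human somatic mutation; the remainder is
   unclassifiable and excluded from downstream somatic analyses.

"Clustered around 50% / near 100%" is operationalized as a median-within-
window plus dispersion bound: heterozygous if median VAF lies in
[0.5 - delta, 0.5 + delta] and the interquartile range is <= iqr_max;
homozygous if median VAF >= hom_min. Defaults (delta=0.1, iqr_max=0.15,
hom_min=0.9) keep true heterozygous variants inside the window with
probability > 0.99 under binomial sampling noise at depth >= 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .resources import CodonMap, HumanSomaticDB, KnownGermlineDB, is_known_human_somatic
from .variant_io import UniqueMutation, VariantCall, pool_unique

GERMLINE_STATUSES = ("germline_known_db", "germline_het_vaf", "germline_hom_vaf")
SOMATIC_STATUSES = ("somatic_vaf_random", "somatic_human_match")
STATUSES = GERMLINE_STATUSES + SOMATIC_STATUSES + ("unclassifiable",)


def rollup_of(status: str) -> str:
    """Collapse a pipeline status to germline / somatic / unclassifiable."""
    if status.startswith("germline"):
        return "germline"
    if status.startswith("somatic"):
        return "somatic"
    return "unclassifiable"


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable thresholds of the discrimination pipeline.

    ``recurrence_threshold``: minimum number of carrier dogs for the VAF
    branch (the ">= 5 dogs" split; exactly 5 goes to the VAF branch).
    ``het_delta`` / ``het_iqr_max``: half-width of the heterozygous median
    window around 0.5 and its dispersion bound. ``hom_min``: minimum median
    VAF for the homozygous call. ``codon_level_match``: match human somatic
    mutations at codon rather than exact-change granularity.
    """

    recurrence_threshold: int = 5
    het_delta: float = 0.1
    het_iqr_max: float = 0.15
    hom_min: float = 0.9
    codon_level_match: bool = False

    def __post_init__(self) -> None:
        if self.recurrence_threshold < 1:
            raise ValueError("recurrence_threshold must be >= 1")
        for name in ("het_delta", "het_iqr_max"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        if not 0.5 <= self.hom_min <= 1:
            raise ValueError(f"hom_min must be in [0.5, 1], got {self.hom_min}")


@dataclass
class ClassifiedVariant:
    """A unique mutation with its pipeline decision and branch evidence."""

    mutation: UniqueMutation
    status: str
    evidence: dict = field(default_factory=dict)

    @property
    def rollup(self) -> str:
        return rollup_of(self.status)


@dataclass
class PipelineCounts:
    """Total (sum over carriers) and unique mutation counts per pipeline stage."""

    stages: dict[str, tuple[int, int]] = field(default_factory=dict)

    def add(self, stage: str, mutations: Sequence[UniqueMutation]) -> None:
        self.stages[stage] = (
            sum(m.n_carriers for m in mutations),
            len(mutations),
        )

    def check_conservation(self) -> None:
        """input = germline + somatic + unclassifiable, for totals and uniques."""
        for i in (0, 1):
            got = sum(
                self.stages.get(s, (0, 0))[i]
                for s in ("germline", "somatic", "unclassifiable")
            )
            if got != self.stages.get("input", (0, 0))[i]:
                kind = ("total", "unique")[i]
                raise AssertionError(
                    f"pipeline {kind} counts do not reconcile: "
                    f"{got} != input {self.stages.get('input')}"
                )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: {"total": t, "unique": u} for k, (t, u) in self.stages.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def classify_recurrent_vaf(
    mutation: UniqueMutation, params: ClassifierParams = ClassifierParams()
) -> str:
    """VAF-distribution decision for a mutation recurrent in >= threshold dogs."""
    if mutation.n_carriers < params.recurrence_threshold:
        raise ValueError(
            f"{mutation.key}: {mutation.n_carriers} carriers is below the "
            f"recurrence threshold {params.recurrence_threshold}"
        )
    vafs = np.asarray(mutation.vafs, dtype=float)
    median = float(np.median(vafs))
    q25, q75 = np.percentile(vafs, [25, 75])
    iqr = float(q75 - q25)
    if abs(median - 0.5) <= params.het_delta and iqr <= params.het_iqr_max:
        return "germline_het_vaf"
    if median >= params.hom_min:
        return "germline_hom_vaf"
    return "somatic_vaf_random"


def classify_rare(
    mutation: UniqueMutation,
    human_db: HumanSomaticDB,
    codon_map: CodonMap,
    params: ClassifierParams = ClassifierParams(),
) -> str:
    """Rare-branch decision: somatic if the human counterpart is known somatic."""
    if is_known_human_somatic(
        human_db,
        codon_map,
        mutation.gene,
        mutation.protein_change,
        codon_level=params.codon_level_match,
    ):
        return "somatic_human_match"
    return "unclassifiable"


def _vaf_summary(mutation: UniqueMutation) -> dict:
    vafs = np.asarray(mutation.vafs, dtype=float)
    q25, q75 = np.percentile(vafs, [25, 75])
    return {
        "n_carriers": mutation.n_carriers,
        "median_vaf": float(np.median(vafs)),
        "iqr_vaf": float(q75 - q25),
    }


def run_pipeline(
    calls: Sequence[VariantCall] | Sequence[UniqueMutation],
    germline_db: KnownGermlineDB,
    human_db: HumanSomaticDB,
    codon_map: CodonMap,
    params: ClassifierParams = ClassifierParams(),
) -> tuple[list[ClassifiedVariant], PipelineCounts]:
    """Run the full discrimination pipeline on QC-filtered calls.

    Accepts per-sample calls (pooled internally) or pre-pooled unique
    mutations. Stage order: known-germline DB filter, recurrence split, VAF
    branch for recurrent mutations, human-counterpart branch for rare ones.
    Returns one :class:`ClassifiedVariant` per unique mutation plus the
    per-stage count report, whose conservation invariant is verified.
    """
    if calls and isinstance(calls[0], UniqueMutation):
        mutations = list(calls)  # type: ignore[arg-type]
    else:
        mutations = pool_unique(calls)  # type: ignore[arg-type]

    counts = PipelineCounts()
    counts.add("input", mutations)

    classified: list[ClassifiedVariant] = []
    known, remaining = [], []
    for m in mutations:
        (known if m.key in germline_db else remaining).append(m)
    for m in known:
        classified.append(
            ClassifiedVariant(m, "germline_known_db", {"n_carriers": m.n_carriers})
        )
    counts.add("known_germline_db", known)
    counts.add("post_db_filter", remaining)

    recurrent = [m for m in remaining if m.n_carriers >= params.recurrence_threshold]
    rare = [m for m in remaining if m.n_carriers < params.recurrence_threshold]
    counts.add("recurrent", recurrent)
    counts.add("rare", rare)

    for m in recurrent:
        status = classify_recurrent_vaf(m, params)
        classified.append(ClassifiedVariant(m, status, _vaf_summary(m)))
    for m in rare:
        status = classify_rare(m, human_db, codon_map, params)
        evidence = {
            "n_carriers": m.n_carriers,
            "human_match": status == "somatic_human_match",
        }
        classified.append(ClassifiedVariant(m, status, evidence))

    for status in STATUSES:
        counts.add(status, [c.mutation for c in classified if c.status == status])
    for roll in ("germline", "somatic", "unclassifiable"):
        counts.add(roll, [c.mutation for c in classified if c.rollup == roll])
    counts.check_conservation()
    return classified, counts


# ---------------------------------------------------------------------------
# Tabular output


def classified_to_table(classified: Sequence[ClassifiedVariant], path: str | Path) -> None:
    """One row per unique mutation with status, rollup and branch evidence."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tgene\tcodon\tprotein_change\tmutation_class"
            "\tn_carriers\tmedian_vaf\tstatus\trollup\n"
        )
        for cv in classified:
            m = cv.mutation
            med = cv.evidence.get("median_vaf")
            fh.write(
                f"{m.key[0]}\t{m.key[1]}\t{m.key[2]}\t{m.key[3]}"
                f"\t{m.gene or ''}\t{m.codon or ''}\t{m.protein_change or ''}"
                f"\t{m.mutation_class}\t{m.n_carriers}"
                f"\t{'' if med is None else f'{med:.4f}'}\t{cv.status}\t{cv.rollup}\n"
            )


def classified_by_sample(classified: Sequence[ClassifiedVariant]):
    """Explode classifications to one row per (sample, mutation) as a DataFrame."""
    import pandas as pd

    rows = []
    for cv in classified:
        m = cv.mutation
        for sample, vaf in zip(m.carriers, m.vafs):
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": m.key[0],
                    "pos": m.key[1],
                    "ref": m.key[2],
                    "alt": m.key[3],
                    "gene": m.gene,
                    "codon": m.codon,
                    "protein_change": m.protein_change,
                    "mutation_class": m.mutation_class,
                    "vaf": vaf,
                    "status": cv.status,
                    "rollup": cv.rollup,
                }
            )
    return pd.DataFrame(rows)
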