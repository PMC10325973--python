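"""Panel tumor mutation burden and codon-level mutational hotspots.

TMB is somatic mutations per megabase of callable panel sequence:
``TMB = n_somatic / (callable_bases / 1e6)``. Samples with fewer than
11,143 callable bases are excluded as unreliable denominators.

A hotspot is a gene codon mutated in recurrently more samples than the
gene's background rate. Mutations at different nucleotide offsets within a
codon, and different substitutions (synonymous or not), pool into one
candidate; recurrence counts distinct samples. Candidates with recurrence
>= 4 samples are tested against a simplified positional background: under
the null, a gene's n sample-codon mutation events fall uniformly over its L
codons, so a codon with k carriers scores p = P(X >= k), X ~ Binomial(n,
1/L), with Benjamini–Hochberg correction across candidates. Cross-species
status is annotated by mapping the canine codon to its human counterpart
and looking it up in a human hotspot list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binom

from .resources import CodonMap
from .variant_io import TranscriptModel, VariantCall

MIN_CALLABLE_BASES = 11_143


@dataclass(frozen=True)
class TMBResult:
    """Per-sample panel tumor mutation burden (mutations per megabase)."""

    sample_id: str
    n_somatic: int
    callable_bases: int
    tmb: float | None
    excluded: bool
    reason: str = ""


def tmb(
    sample_id: str,
    somatic_calls: Sequence[VariantCall] | int,
    callable_bases: int,
    min_callable: int = MIN_CALLABLE_BASES,
) -> TMBResult:
    """Compute one sample's TMB; excluded iff callable_bases < min_callable.

    ``somatic_calls`` may be the sample's somatic call list or a pre-computed
    count.
    """
    if callable_bases < 0:
        raise ValueError("callable_bases must be >= 0")
    n = somatic_calls if isinstance(somatic_calls, int) else len(somatic_calls)
    if callable_bases < min_callable:
        reason = "no callable bases" if callable_bases == 0 else (
            f"callable bases {callable_bases} < {min_callable}"
        )
        return TMBResult(sample_id, n, callable_bases, None, True, reason)
    return TMBResult(sample_id, n, callable_bases, n / (callable_bases / 1e6), False)


def tmb_table(
    somatic_by_sample: pd.DataFrame,
    callable_bases: dict[str, int] | pd.Series,
    sample_ids: Iterable[str] | None = None,
    min_callable: int = MIN_CALLABLE_BASES,
) -> pd.DataFrame:
    """TMB for every sample (zero mutations counted for unmutated samples)."""
    counts = (
        somatic_by_sample.groupby("sample_id").size()
        if len(somatic_by_sample)
        else pd.Series(dtype=int)
    )
    if sample_ids is None:
        sample_ids = sorted(dict(callable_bases))
    rows = []
    for sid in sample_ids:
        res = tmb(sid, int(counts.get(sid, 0)), int(callable_bases[sid]), min_callable)
        rows.append(
            {
                "sample_id": res.sample_id,
                "n_somatic": res.n_somatic,
                "callable_bases": res.callable_bases,
                "tmb": res.tmb,
                "excluded": res.excluded,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HotspotResult:
    """A recurrently mutated gene codon with its significance and species status."""

    gene: str
    codon: int
    recurrence: int
    aa_changes: tuple[str, ...]
    gene_events: int
    gene_codons: int
    p: float
    adj_p: float | None = None
    human_codon: int | None = None
    status: str = "unmapped"


def call_hotspots(
    somatic_calls: Sequence[VariantCall],
    model: TranscriptModel,
    min_recurrence: int = 4,
) -> list[HotspotResult]:
    """Detect codon-level hotspots among annotated somatic calls.

    All mutations in the same codon of a gene are considered together; a
    sample mutating a codon through several calls counts once. Candidates
    with recurrence >= ``min_recurrence`` are tested against the per-gene
    uniform background and BH-adjusted across candidates; results sort by
    adjusted p, then recurrence (desc), then gene/codon.
    """
    carriers: dict[tuple[str, int], set[str]] = {}
    changes: dict[tuple[str, int], set[str]] = {}
    gene_events: dict[str, set[tuple[str, int]]] = {}
    for call in somatic_calls:
        if call.gene is None or call.codon is None:
            continue
        key = (call.gene, call.codon)
        carriers.setdefault(key, set()).add(call.sample_id)
        if call.protein_change:
            changes.setdefault(key, set()).add(call.protein_change)
        gene_events.setdefault(call.gene, set()).add((call.sample_id, call.codon))

    candidates = []
    for (gene, codon), samples in carriers.items():
        k = len(samples)
        if k < min_recurrence:
            continue
        n = len(gene_events[gene])
        length = model[gene].n_codons if gene in model else max(codon, 1)
        p = float(binom.sf(k - 1, n, 1.0 / length))
        candidates.append(
            HotspotResult(
                gene=gene,
                codon=codon,
                recurrence=k,
                aa_changes=tuple(sorted(changes.get((gene, codon), ()))),
                gene_events=n,
                gene_codons=length,
                p=p,
            )
        )
    if not candidates:
        return []
    from .cohort_stats import bh_adjust

    adj = bh_adjust([c.p for c in candidates])
    results = [replace(c, adj_p=a) for c, a in zip(candidates, adj)]
    results.sort(key=lambda h: (h.adj_p, -h.recurrence, h.gene, h.codon))
    return results


def compare_species(
    hotspots: Sequence[HotspotResult],
    codon_map: CodonMap,
    human_hotspots: Iterable[tuple[str, int]],
) -> list[HotspotResult]:
    """Annotate hotspots as shared / canine_specific / unmapped vs a human list.

    ``shared`` iff the mapped human codon appears in the human hotspot list
    for the same gene; genes without a codon mapping are ``unmapped``.
    """
    human = set(human_hotspots)
    out = []
    for h in hotspots:
        human_codon = codon_map.map_codon(h.gene, h.codon)
        if human_codon is None:
            status = "unmapped"
        elif (h.gene, human_codon) in human:
            status = "shared"
        else:
            status = "canine_specific"
        out.append(replace(h, human_codon=human_codon, status=status))
    return out


def hotspots_to_table(hotspots: Sequence[HotspotResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tcanine_codon\thuman_codon\taa_changes\trecurrence"
            "\tgene_events\tgene_codons\tp\tadj_p\tstatus\n"
        )
        for h in hotspots:
            fh.write(
                f"{h.gene}\t{h.codon}\t{'' if h.human_codon is None else h.human_codon}"
                f"\t{','.join(h.aa_changes)}\t{h.recurrence}\t{h.gene_events}"
                f"\t{h.gene_codons}\t{h.p:.3e}"
                f"\t{'' if h.adj_p is None else f'{h.adj_p:.3e}'}\t{h.status}\n"
            )


def lollipop_table(
    somatic_calls: Sequence[VariantCall], codon_map: CodonMap
) -> pd.DataFrame:
    """Per-gene (human codon, carrier count) table for lollipop-style plots.

    The x-axis is the amino-acid position in the human protein; codons of
    unmapped genes are reported on the canine scale with ``mapped=False``.
    """
    carriers: dict[tuple[str, int], set[str]] = {}
    for call in somatic_calls:
        if call.gene is None or call.codon is None:
            continue
        carriers.setdefault((call.gene, call.codon), set()).add(call.sample_id)
    rows = []
    for (gene, codon), samples in sorted(carriers.items()):
        human_codon = codon_map.map_codon(gene, codon)
        rows.append(
            {
                "gene": gene,
                "canine_codon": codon,
                "position": human_codon if human_codon is not None else codon,
                "mapped": human_codon is not None,
                "count": len(samples),
            }
        )
    return pd.DataFrame(rows)
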