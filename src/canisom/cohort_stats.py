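"""Cohort-level statistics: Fisher-exact enrichment/depletion of mutations
across tumor supertypes, types, breeds, age and weight groups; pairwise
co-occurrence / mutual exclusivity; and oncoprint-style summary tables.

Each (feature, group) pair is scored from the 2x2 table of mutated vs
non-mutated samples inside vs outside the group with a two-sided Fisher
exact test, Benjamini–Hochberg correction over all tests of the scan, and a
signed enrichment score -log10(adjusted p): positive when the odds ratio
exceeds 1 (enrichment), negative for depletion.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "tumor_type", "supertype", "location", "breed", "age", "weight", "sex")


def percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage rounded half-up to ``decimals`` places (22.5 for 151/671)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    scale = 10 ** decimals
    return math.floor(100.0 * numerator / denominator * scale + 0.5) / scale


def fisher_two_sided(table: Sequence[Sequence[int]]) -> tuple[float, float, bool]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p, degenerate). The two-sided p sums hypergeometric
    probabilities of tables (at fixed margins) no more likely than the
    observed one. The sample odds ratio is (a*d)/(b*c); with a zero cell the
    Haldane-corrected ratio is reported. A zero margin makes the test
    undefined: p = 1 and odds ratio 1 are reported with ``degenerate=True``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0, 1.0, True
    _, p = _scipy_fisher(t, alternative="two-sided")
    if b * c == 0 or a * d == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p), False


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


@dataclass(frozen=True)
class EnrichmentResult:
    """A (feature, group) Fisher test with its signed enrichment score."""

    feature: str
    group_kind: str
    group: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    adj_p: float
    score: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseResult:
    """Co-occurrence / mutual exclusivity of a gene pair within a subset."""

    gene_a: str
    gene_b: str
    subset: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    direction: str  # "co_occurrence" | "mutual_exclusion"


def _signed_score(adj_p: float, odds_ratio: float) -> float:
    magnitude = -math.log10(max(adj_p, 1e-300))
    return magnitude if odds_ratio > 1 else -magnitude


def _check_samples(somatic: pd.DataFrame, metadata: pd.DataFrame) -> None:
    known = set(metadata["sample_id"])
    unknown = sorted(set(somatic["sample_id"]) - known)
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown}")


def _default_groups(
    metadata: pd.DataFrame,
    min_group_n: int,
    age_bins: tuple[float, float] = (7.0, 10.0),
) -> list[tuple[str, str, set[str]]]:
    """(kind, label, sample set) for every tested group.

    Supertypes and age/weight bins are always tested; tumor types and breeds
    only when strictly larger than ``min_group_n`` samples. Mixed-breed dogs
    form their own breed group.
    """
    groups: list[tuple[str, str, set[str]]] = []
    for supertype, sub in metadata.groupby("supertype"):
        groups.append(("supertype", str(supertype), set(sub["sample_id"])))
    for tumor_type, sub in metadata.groupby("tumor_type"):
        if len(sub) > min_group_n:
            groups.append(("tumor_type", str(tumor_type), set(sub["sample_id"])))
    if "breed" in metadata:
        for breed, sub in metadata.groupby("breed"):
            if len(sub) > min_group_n:
                groups.append(("breed", str(breed), set(sub["sample_id"])))
    if "age" in metadata:
        lo, hi = age_bins
        age = metadata["age"]
        for label, mask in (
            (f"<{lo:g}y", age < lo),
            (f"{lo:g}-{hi:g}y", (age >= lo) & (age <= hi)),
            (f">{hi:g}y", age > hi),
        ):
            groups.append(("age", label, set(metadata.loc[mask, "sample_id"])))
    if "weight" in metadata:
        quartiles = metadata["weight"].quantile([0.25, 0.5, 0.75]).to_numpy()
        edges = [-np.inf, *quartiles, np.inf]
        for i in range(4):
            mask = (metadata["weight"] > edges[i]) & (metadata["weight"] <= edges[i + 1])
            groups.append(("weight", f"Q{i + 1}", set(metadata.loc[mask, "sample_id"])))
    return groups


def enrichment_scan(
    somatic_by_sample: pd.DataFrame,
    metadata: pd.DataFrame,
    feature: str = "gene",
    min_gene_dogs: int = 5,
    min_group_n: int = 20,
    age_bins: tuple[float, float] = (7.0, 10.0),
) -> list[EnrichmentResult]:
    """Scan features x groups for mutation enrichment/depletion.

    ``somatic_by_sample`` holds one row per (sample, somatic mutation) with
    at least ``sample_id`` and ``gene`` columns (``protein_change`` when
    ``feature="mutation"``). Only features mutated in strictly more than
    ``min_gene_dogs`` dogs are tested, and tumor-type/breed groups need
    strictly more than ``min_group_n`` samples. BH correction spans every
    test in the scan.
    """
    _check_samples(somatic_by_sample, metadata)
    all_samples = set(metadata["sample_id"])

    df = somatic_by_sample.dropna(subset=["gene"])
    if feature == "gene":
        df = df.assign(feature=df["gene"])
    elif feature == "mutation":
        df = df.dropna(subset=["protein_change"])
        df = df.assign(feature=df["gene"] + " " + df["protein_change"])
    else:
        raise ValueError(f"unknown feature level {feature!r}")

    mutated: dict[str, set[str]] = {
        str(feat): set(sub["sample_id"]) for feat, sub in df.groupby("feature")
    }
    features = sorted(f for f, samples in mutated.items() if len(samples) > min_gene_dogs)
    groups = _default_groups(metadata, min_group_n, age_bins)

    tests = []
    for feat in features:
        pos = mutated[feat]
        for kind, label, members in groups:
            a = len(pos & members)
            b = len(members) - a
            c = len(pos - members)
            d = len(all_samples - members - pos)
            tests.append((feat, kind, label, ((a, b), (c, d))))
    if not tests:
        return []
    stats = [fisher_two_sided(t[3]) for t in tests]
    adj = bh_adjust([s[1] for s in stats])
    results = []
    for (feat, kind, label, table), (odds, p, degen), ap in zip(tests, stats, adj):
        results.append(
            EnrichmentResult(
                feature=feat,
                group_kind=kind,
                group=label,
                table=table,
                odds_ratio=odds,
                p=p,
                adj_p=ap,
                score=_signed_score(ap, odds),
                degenerate=degen,
            )
        )
    results.sort(key=lambda r: (r.adj_p, r.feature, r.group_kind, r.group))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Long-format heatmap-ready table (feature, group, score)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "group_kind": r.group_kind,
                "group": r.group,
                "n_mutated_in_group": r.table[0][0],
                "n_group": r.table[0][0] + r.table[0][1],
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "adj_p": r.adj_p,
                "score": r.score,
            }
            for r in results
        ]
    )


def pairwise_cooccurrence(
    somatic_by_sample: pd.DataFrame,
    metadata: pd.DataFrame,
    subset: Iterable[str] | None,
    genes: Sequence[str],
    subset_label: str = "subset",
) -> list[PairwiseResult]:
    """Co-occurrence / mutual exclusivity for every gene pair within a subset.

    ``subset`` is the sample-id collection to restrict to (None = whole
    cohort). Genes with no mutated sample in the subset are skipped with a
    warning. Direction is co_occurrence iff the (Haldane-corrected, for zero
    cells) odds ratio exceeds 1.
    """
    _check_samples(somatic_by_sample, metadata)
    samples = set(subset) if subset is not None else set(metadata["sample_id"])
    if not samples:
        raise ValueError("subset is empty")
    df = somatic_by_sample[somatic_by_sample["sample_id"].isin(samples)]
    mutated = {g: set(df.loc[df["gene"] == g, "sample_id"]) for g in genes}
    usable = []
    for g in genes:
        if not mutated[g]:
            logger.warning("gene %s has no mutated sample in %s; skipped", g, subset_label)
        else:
            usable.append(g)
    results = []
    for ga, gb in itertools.combinations(usable, 2):
        both = len(mutated[ga] & mutated[gb])
        a_only = len(mutated[ga] - mutated[gb])
        b_only = len(mutated[gb] - mutated[ga])
        neither = len(samples) - both - a_only - b_only
        odds, p, _ = fisher_two_sided([[both, a_only], [b_only, neither]])
        results.append(
            PairwiseResult(
                gene_a=ga,
                gene_b=gb,
                subset=subset_label,
                table=((both, a_only), (b_only, neither)),
                odds_ratio=odds,
                p=p,
                direction="co_occurrence" if odds > 1 else "mutual_exclusion",
            )
        )
    return results


def oncoprint_table(
    somatic_by_sample: pd.DataFrame,
    metadata: pd.DataFrame,
    tmb: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x gene oncoprint matrix plus per-gene mutation frequencies.

    Matrix cells hold the mutation class, ``multi_hit`` for samples with
    several mutations in a gene, and "" for wild type. Genes sort by
    mutated-sample count (desc, ties by name); samples group by supertype
    then tumor type. A per-sample TMB column is attached when supplied.
    Returns (matrix, gene_summary).
    """
    _check_samples(somatic_by_sample, metadata)
    meta = metadata.sort_values(["supertype", "tumor_type", "sample_id"])
    sample_order = list(meta["sample_id"])
    df = somatic_by_sample.dropna(subset=["gene"])

    per_gene: dict[str, dict[str, str]] = {}
    for (gene, sample), sub in df.groupby(["gene", "sample_id"]):
        cell = "multi_hit" if len(sub) > 1 else str(sub["mutation_class"].iloc[0])
        per_gene.setdefault(str(gene), {})[str(sample)] = cell
    gene_order = sorted(per_gene, key=lambda g: (-len(per_gene[g]), g))

    matrix = pd.DataFrame("", index=sample_order, columns=gene_order)
    for gene, cells in per_gene.items():
        for sample, cell in cells.items():
            matrix.loc[sample, gene] = cell
    matrix.index.name = "sample_id"
    matrix.insert(0, "supertype", meta.set_index("sample_id")["supertype"])
    matrix.insert(1, "tumor_type", meta.set_index("sample_id")["tumor_type"])
    if tmb is not None:
        matrix = matrix.join(tmb.set_index("sample_id")["tmb"], how="left")

    n = len(sample_order)
    summary = pd.DataFrame(
        {
            "gene": gene_order,
            "n_mutated": [len(per_gene[g]) for g in gene_order],
            "frequency": [len(per_gene[g]) / n for g in gene_order],
        }
    )
    return matrix, summary
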