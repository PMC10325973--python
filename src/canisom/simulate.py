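"""Synthetic tumor-only panel cohorts with known germline/somatic truth.

The generator emulates the statistical structure that tumor-only
discrimination exploits: heterozygous germline VAFs cluster symmetrically
around 0.5 and homozygous germline VAFs above 0.9 (Beta latent VAFs plus
binomial read-sampling noise at negative-binomial depths averaging 500x);
somatic VAFs spread broadly over [0.05, 0.95]; germline sites recur across
dogs under a Beta(0.3, 0.3) population-allele-frequency sharing model while
somatic mutations are mostly private; the somatic substitution spectrum is
dominated by C>T (G>A) changes; and codon hotspots (a BRAF V588E-like
mutation concentrated in urothelial carcinoma, PIK3CA H1047R in
hemangiosarcoma, ...) are planted with tumor-type-specific per-sample
probabilities. Companion resources — the known-germline site list covering
a configurable fraction of true germline sites, the human somatic mutation
database, canine→human codon maps, and per-sample callable-base counts —
are emitted alongside.

Truth labels live in a sidecar table, never in the VCFs, so the classifier
cannot cheat. Outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import variant_io
from .classify import ClassifiedVariant
from .resources import CodonMap, HumanSomaticDB, KnownGermlineDB, parse_protein_change
from .variant_io import Transcript, TranscriptModel, VariantCall, _revcomp

__all__ = [
    "CohortConfig",
    "PlantedHotspot",
    "Cohort",
    "ConfigError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "truth_confusion",
]


class ConfigError(ValueError):
    """A cohort configuration field violates its invariant."""


# Panel genes with approximate protein lengths (codons); a desk-scale subset
# of a 59-gene canine oncology panel.
PANEL_GENES: dict[str, int] = {
    "TP53": 381,
    "ARID1A": 2285,
    "KMT2D": 5537,
    "KMT2C": 4911,
    "PIK3CA": 1068,
    "SETD2": 2564,
    "BRAF": 766,
    "CREBBP": 2442,
    "ERBB2": 1255,
    "EGFR": 1210,
    "KIT": 976,
    "KRAS": 189,
    "NRAS": 189,
    "FBXW7": 707,
    "PTEN": 403,
    "ATM": 3056,
    "NF1": 2839,
    "FLT3": 993,
    "MET": 1390,
    "RB1": 928,
    "SMAD4": 552,
    "CDKN2A": 156,
    "JAK2": 1132,
    "HRAS": 189,
}

#: canine→human codon offsets for panel genes (0 = identical numbering)
CODON_OFFSETS: dict[str, int] = {g: 0 for g in PANEL_GENES} | {"BRAF": 12, "FBXW7": -5}

TUMOR_TYPES: dict[str, tuple[str, float]] = {
    # tumor type: (supertype, default cohort weight)
    "hemangiosarcoma": ("sarcoma", 0.25),
    "soft_tissue_sarcoma": ("sarcoma", 0.14),
    "osteosarcoma": ("sarcoma", 0.08),
    "histiocytic_sarcoma": ("sarcoma", 0.04),
    "melanoma": ("other", 0.07),
    "lymphoma": ("other", 0.05),
    "mast_cell_tumor": ("other", 0.05),
    "plasma_cell_tumor": ("other", 0.02),
    "anal_sac_carcinoma": ("carcinoma", 0.05),
    "urothelial_carcinoma": ("carcinoma", 0.05),
    "pulmonary_adenocarcinoma": ("carcinoma", 0.04),
    "thyroid_carcinoma": ("carcinoma", 0.04),
    "mammary_carcinoma": ("carcinoma", 0.05),
    "squamous_cell_carcinoma": ("carcinoma", 0.04),
    "hepatocellular_carcinoma": ("carcinoma", 0.03),
}

BREEDS: dict[str, float] = {
    "Golden Retriever": 0.11,
    "Labrador Retriever": 0.11,
    "German Shepherd": 0.05,
    "American Pit Bull Terrier": 0.05,
    "Boxer": 0.04,
    "Beagle": 0.03,
    "Poodle": 0.03,
    "Rottweiler": 0.03,
    "Australian Shepherd": 0.03,
    "Mixed": 0.32,
    "Other": 0.20,
}

SEXES: dict[str, float] = {"MN": 0.48, "FS": 0.45, "MI": 0.05, "FI": 0.02}

DEFAULT_SOMATIC_SPECTRUM = {
    "C>A": 0.08, "C>G": 0.06, "C>T": 0.55, "T>A": 0.08, "T>C": 0.15, "T>G": 0.08,
}
DEFAULT_GERMLINE_SPECTRUM = {
    "C>A": 0.12, "C>G": 0.08, "C>T": 0.30, "T>A": 0.10, "T>C": 0.30, "T>G": 0.10,
}

#: human-only hotspot codons included in the emitted human hotspot list
HUMAN_ONLY_HOTSPOTS: tuple[tuple[str, int], ...] = (
    ("PIK3CA", 542),
    ("PIK3CA", 545),
    ("ERBB2", 310),
    ("EGFR", 858),
)


@dataclass(frozen=True)
class PlantedHotspot:
    """A codon hotspot planted with tumor-type-specific carrier probability."""

    gene: str
    codon: int
    protein_change: str  # canine numbering, e.g. "V588E"
    tumor_type: str
    p_in: float
    p_out: float


DEFAULT_HOTSPOTS: tuple[PlantedHotspot, ...] = (
    PlantedHotspot("BRAF", 588, "V588E", "urothelial_carcinoma", 0.35, 0.002),
    PlantedHotspot("PIK3CA", 1047, "H1047R", "hemangiosarcoma", 0.12, 0.005),
    PlantedHotspot("NRAS", 61, "Q61R", "hemangiosarcoma", 0.06, 0.002),
    PlantedHotspot("ERBB2", 659, "V659E", "pulmonary_adenocarcinoma", 0.50, 0.002),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic tumor-only cohort.

    Defaults describe the reference cohort: 300 dogs, ~90 germline plus ~3
    somatic calls per sample (~28k calls), 500x mean depth, 95% of germline
    sites present in the known-germline database and 95% of somatic
    mutations with a human-database counterpart.
    """

    n_samples: int = 300
    tumor_type_weights: dict[str, float] = field(
        default_factory=lambda: {t: w for t, (_, w) in TUMOR_TYPES.items()}
    )
    mean_germline_het: float = 60.0
    mean_germline_hom: float = 30.0
    mean_somatic: float = 3.0
    het_vaf_sd: float = 0.05
    hom_vaf_mean: float = 0.97
    hom_vaf_sd: float = 0.02
    somatic_beta: tuple[float, float] = (1.2, 1.2)
    somatic_vaf_range: tuple[float, float] = (0.05, 0.95)
    somatic_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SOMATIC_SPECTRUM)
    )
    germline_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GERMLINE_SPECTRUM)
    )
    germline_sharing_beta: tuple[float, float] = (0.3, 0.3)
    planted_hotspots: tuple[PlantedHotspot, ...] = DEFAULT_HOTSPOTS
    germline_db_coverage: float = 0.95
    human_db_coverage: float = 0.95
    qc_fail_rate: float = 0.05
    depth_mean: float = 500.0
    depth_shape: float = 10.0
    callable_log_mean: float = math.log(200_000)
    callable_log_sd: float = 0.25
    intergenic_germline_fraction: float = 0.10
    somatic_indel_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be a positive integer")
        for name in ("mean_germline_het", "mean_germline_hom", "mean_somatic"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.mean_germline_het + self.mean_germline_hom <= 0:
            raise ConfigError("mean_germline_het + mean_germline_hom must be positive")
        for name in (
            "germline_db_coverage",
            "human_db_coverage",
            "qc_fail_rate",
            "intergenic_germline_fraction",
            "somatic_indel_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("tumor_type_weights", "somatic_spectrum", "germline_spectrum"):
            vec = getattr(self, name)
            if any(w < 0 for w in vec.values()):
                raise ConfigError(f"{name} has negative entries")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 within 1e-9")
        unknown = set(self.tumor_type_weights) - set(TUMOR_TYPES)
        if unknown:
            raise ConfigError(f"tumor_type_weights names unknown types {sorted(unknown)}")
        for hs in self.planted_hotspots:
            if hs.gene not in PANEL_GENES:
                raise ConfigError(f"planted_hotspots gene {hs.gene} not on the panel")
            if not (0 <= hs.p_in <= 1 and 0 <= hs.p_out <= 1):
                raise ConfigError("planted_hotspots probabilities must lie in [0, 1]")
            if not 1 <= hs.codon <= PANEL_GENES[hs.gene]:
                raise ConfigError(f"planted_hotspots codon {hs.codon} outside {hs.gene}")
        if self.depth_mean <= 0 or self.depth_shape <= 0:
            raise ConfigError("depth_mean and depth_shape must be positive")
        if self.het_vaf_sd <= 0 or self.hom_vaf_sd <= 0:
            raise ConfigError("het_vaf_sd and hom_vaf_sd must be positive")
        if not 0.5 < self.hom_vaf_mean < 1.0:
            raise ConfigError("hom_vaf_mean must lie in (0.5, 1)")


@dataclass
class Cohort:
    """An in-memory synthetic cohort plus its companion resources."""

    calls: list[VariantCall]
    metadata: pd.DataFrame
    truth: pd.DataFrame
    germline_db: KnownGermlineDB
    human_db: HumanSomaticDB
    codon_map: CodonMap
    model: TranscriptModel
    callable_bases: dict[str, int]
    human_hotspots: set[tuple[str, int]]
    config: CohortConfig


# ---------------------------------------------------------------------------
# helpers

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_AA_OF = {c: str(Seq(c).translate()) for c in _CODONS}


def _codon_pair_for_change(ref_aa: str, alt_aa: str) -> tuple[str, str, int]:
    """A (ref codon, alt codon, differing offset) realizing a 1-bp aa change."""
    for rc in _CODONS:
        if _AA_OF[rc] != ref_aa:
            continue
        for ac in _CODONS:
            if _AA_OF[ac] != alt_aa:
                continue
            diffs = [i for i in range(3) if rc[i] != ac[i]]
            if len(diffs) == 1:
                return rc, ac, diffs[0]
    raise ValueError(f"no single-base codon change realizes {ref_aa}->{alt_aa}")


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    common = mean * (1 - mean) / var - 1
    if common <= 0:
        raise ConfigError("VAF spread too large for a Beta model")
    return mean * common, (1 - mean) * common


def _build_panel(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[TranscriptModel, dict[str, str]]:
    """Random panel genome: one single-exon transcript per gene, planted
    hotspot codons engineered to encode the required reference amino acid."""
    hotspot_codons: dict[tuple[str, int], str] = {}
    for hs in config.planted_hotspots:
        parsed = parse_protein_change(hs.protein_change)
        if parsed is None:
            raise ConfigError(f"unparseable hotspot change {hs.protein_change}")
        ref_aa, codon, _alt = parsed
        if codon != hs.codon:
            raise ConfigError(f"hotspot codon mismatch in {hs.protein_change}")
        rc, _, _ = _codon_pair_for_change(ref_aa, parsed[2])
        hotspot_codons[(hs.gene, hs.codon)] = rc

    transcripts = []
    genomes: dict[str, str] = {}
    chrom_cursor: dict[str, int] = {}
    for i, (gene, n_codons) in enumerate(PANEL_GENES.items()):
        chrom = f"chr{i % 10 + 1}"
        start = chrom_cursor.get(chrom, 0) * 1_000_000 + 100_001
        chrom_cursor[chrom] = chrom_cursor.get(chrom, 0) + 1
        strand = "+" if i % 2 == 0 else "-"
        seq = rng.choice(_BASES, size=n_codons * 3)
        cds = "".join(seq)
        for (g, codon), ref_codon in hotspot_codons.items():
            if g == gene:
                k = (codon - 1) * 3
                cds = cds[:k] + ref_codon + cds[k + 3 :]
        end = start + n_codons * 3 - 1
        transcripts.append(Transcript(gene, chrom, strand, ((start, end),), cds))
        genomes[gene] = cds if strand == "+" else _revcomp(cds)
    return TranscriptModel(transcripts), genomes


def _position_index(genomes: dict[str, str], model: TranscriptModel) -> dict[str, dict[str, np.ndarray]]:
    """Per gene, genomic positions of each base letter."""
    index: dict[str, dict[str, np.ndarray]] = {}
    for gene, seq in genomes.items():
        start = model[gene].exons[0][0]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        index[gene] = {
            b: start + np.flatnonzero(arr == b.encode()) for b in "ACGT"
        }
    return index


def _alleles_for_class(sub_class: str, genomic_ref: str) -> str:
    """Alt allele realizing a pyrimidine-collapsed class at a genomic ref base."""
    pyr, alt = sub_class.split(">")
    if genomic_ref == pyr:
        return alt
    if genomic_ref == _COMP[pyr]:
        return _COMP[alt]
    raise ValueError(f"base {genomic_ref} cannot host class {sub_class}")


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: CohortConfig = CohortConfig()) -> Cohort:
    """Generate a cohort with calls, metadata, truth labels and resources.

    Deterministic given ``config.seed``. Emitted calls are annotated against
    the generated transcript model; truth labels are per (sample, variant).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    model, genomes = _build_panel(config, rng)
    base_index = _position_index(genomes, model)
    genes = list(PANEL_GENES)
    gene_weights = np.array([PANEL_GENES[g] for g in genes], dtype=float)
    gene_weights /= gene_weights.sum()

    # --- samples ---
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    types = list(config.tumor_type_weights)
    type_probs = np.array([config.tumor_type_weights[t] for t in types])
    type_probs = type_probs / type_probs.sum()
    tumor_types = rng.choice(types, size=n, p=type_probs)
    locations = [
        ("splenic" if rng.random() < 0.78 else "non_splenic")
        if t == "hemangiosarcoma"
        else "other"
        for t in tumor_types
    ]
    breeds = rng.choice(list(BREEDS), size=n, p=np.array(list(BREEDS.values())))
    sexes = rng.choice(list(SEXES), size=n, p=np.array(list(SEXES.values())))
    ages = np.clip(np.round(rng.normal(9.9, 2.8, size=n), 1), 1.0, 16.0)
    weights = np.clip(np.round(rng.normal(25.5, 13.5, size=n), 1), 1.0, 91.0)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tumor_type": tumor_types,
            "supertype": [TUMOR_TYPES[t][0] for t in tumor_types],
            "location": locations,
            "breed": breeds,
            "age": ages,
            "weight": weights,
            "sex": sexes,
        }
    )
    callable_bases = {
        sid: int(rng.lognormal(config.callable_log_mean, config.callable_log_sd))
        for sid in sample_ids
    }

    # --- latent VAF models ---
    het_a, het_b = _beta_params(0.5, config.het_vaf_sd)
    hom_a, hom_b = _beta_params(config.hom_vaf_mean, config.hom_vaf_sd)
    som_a, som_b = config.somatic_beta
    som_lo, som_hi = config.somatic_vaf_range

    def depth_draw() -> int:
        r = config.depth_shape
        p = r / (r + config.depth_mean)
        return max(int(rng.negative_binomial(r, p)), 30)

    def somatic_vaf() -> float:
        return som_lo + (som_hi - som_lo) * rng.beta(som_a, som_b)

    spectrum_classes = list(DEFAULT_SOMATIC_SPECTRUM)

    # --- germline site pool ---
    share_a, share_b = config.germline_sharing_beta
    mean_af = share_a / (share_a + share_b)
    n_sites = max(
        1, round((config.mean_germline_het + config.mean_germline_hom) / mean_af)
    )
    q_hom = config.mean_germline_hom / (
        config.mean_germline_het + config.mean_germline_hom
    )
    germ_probs = np.array([config.germline_spectrum[c] for c in spectrum_classes])
    som_probs = np.array([config.somatic_spectrum[c] for c in spectrum_classes])

    # planted hotspot variant definitions (no randomness); their positions are
    # reserved so germline/somatic background never collides with a hotspot
    hotspot_variants: dict[PlantedHotspot, tuple[str, int, str, str]] = {}
    for hs in config.planted_hotspots:
        parsed = parse_protein_change(hs.protein_change)
        assert parsed is not None
        rc, ac, off = _codon_pair_for_change(parsed[0], parsed[2])
        tx = model[hs.gene]
        offset = (hs.codon - 1) * 3 + off
        pos = tx.genomic_pos(offset)
        if tx.strand == "+":
            ref, alt = rc[off], ac[off]
        else:
            ref, alt = _COMP[rc[off]], _COMP[ac[off]]
        hotspot_variants[hs] = (tx.chrom, pos, ref, alt)

    used_positions: set[tuple[str, int]] = {
        (chrom, pos) for chrom, pos, _ref, _alt in hotspot_variants.values()
    }
    germline_sites = []  # (chrom, pos, ref, alt, af, is_hom, in_db)
    for _ in range(n_sites):
        af = float(rng.beta(share_a, share_b))
        is_hom = bool(rng.random() < q_hom)
        sub_class = spectrum_classes[int(rng.choice(6, p=germ_probs))]
        if rng.random() < config.intergenic_germline_fraction:
            while True:
                pos = int(rng.integers(1, 10_000_000))
                if ("chrU", pos) not in used_positions:
                    break
            chrom = "chrU"
            pyr, _ = sub_class.split(">")
            ref = pyr if rng.random() < 0.5 else _COMP[pyr]
        else:
            gene = genes[int(rng.choice(len(genes), p=gene_weights))]
            pyr, _ = sub_class.split(">")
            tx = model[gene]
            while True:
                base = pyr if rng.random() < 0.5 else _COMP[pyr]
                positions = base_index[gene][base]
                pos = int(positions[int(rng.integers(len(positions)))])
                if (tx.chrom, pos) not in used_positions:
                    break
            chrom = tx.chrom
            ref = base
        used_positions.add((chrom, pos))
        alt = _alleles_for_class(sub_class, ref)
        in_db = bool(rng.random() < config.germline_db_coverage)
        germline_sites.append((chrom, pos, ref, alt, af, is_hom, in_db))

    # --- emit calls ---
    calls: list[VariantCall] = []
    truth_rows: list[dict] = []
    emitted: set[tuple[str, tuple]] = set()

    def emit(
        sample: str,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        latent_class: str,
        vaf: float,
        hotspot: bool = False,
        in_germline_db: bool = False,
    ) -> None:
        key = (sample, (chrom, pos, ref, alt))
        if key in emitted:
            return
        emitted.add(key)
        depth = depth_draw()
        qc_fail = rng.random() < config.qc_fail_rate
        fs: float | None = min(float(rng.exponential(3.0)), 29.9)
        qd: float | None = float(rng.uniform(2.5, 35.0))
        if qc_fail:
            mode = int(rng.integers(3))
            if mode == 0:
                fs = float(rng.uniform(30.5, 60.0))
            elif mode == 1:
                qd = float(rng.uniform(0.0, 1.9))
            else:
                depth = int(rng.integers(1, 10))
        alt_depth = int(np.clip(rng.binomial(depth, vaf), 1, depth))
        calls.append(
            VariantCall(
                sample_id=sample,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                depth=depth,
                alt_depth=alt_depth,
                fs=round(fs, 3),
                qd=round(qd, 2),
            )
        )
        truth_rows.append(
            {
                "sample_id": sample,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "latent_class": latent_class,
                "hotspot": hotspot,
                "in_germline_db": in_germline_db,
                "qc_fail": qc_fail,
            }
        )

    # germline: carriers per site under the sharing model; zygosity is a
    # site-level property so each site's VAF sample forms one cluster
    for chrom, pos, ref, alt, af, is_hom, in_db in germline_sites:
        carrier_mask = rng.random(n) < af
        for idx in np.flatnonzero(carrier_mask):
            vaf = (
                float(rng.beta(hom_a, hom_b))
                if is_hom
                else float(rng.beta(het_a, het_b))
            )
            emit(
                sample_ids[idx],
                chrom,
                pos,
                ref,
                alt,
                "germline_hom" if is_hom else "germline_het",
                vaf,
                in_germline_db=in_db,
            )

    # somatic: private mutations plus planted hotspots
    for i, sample in enumerate(sample_ids):
        for hs in config.planted_hotspots:
            p = hs.p_in if tumor_types[i] == hs.tumor_type else hs.p_out
            if rng.random() < p:
                chrom, pos, ref, alt = hotspot_variants[hs]
                emit(sample, chrom, pos, ref, alt, "somatic", somatic_vaf(), hotspot=True)
        for _ in range(rng.poisson(config.mean_somatic)):
            gene = genes[int(rng.choice(len(genes), p=gene_weights))]
            tx = model[gene]
            if rng.random() < config.somatic_indel_fraction:
                codon = int(rng.integers(2, PANEL_GENES[gene]))
                g0 = min(tx.genomic_pos((codon - 1) * 3), tx.genomic_pos(codon * 3 - 1))
                start = tx.exons[0][0]
                anchor = g0 - 1
                if anchor < start:
                    continue
                seq = genomes[gene]
                ref = seq[anchor - start : anchor - start + 4]
                alt = ref[0]
                emit(sample, tx.chrom, anchor, ref, alt, "somatic", somatic_vaf())
            else:
                sub_class = spectrum_classes[int(rng.choice(6, p=som_probs))]
                pyr, _ = sub_class.split(">")
                base = pyr if rng.random() < 0.5 else _COMP[pyr]
                positions = base_index[gene][base]
                # keep somatic positions off germline sites so truth classes
                # never mix within one variant key
                while True:
                    pos = int(positions[int(rng.integers(len(positions)))])
                    if (tx.chrom, pos) not in used_positions:
                        break
                alt = _alleles_for_class(sub_class, base)
                emit(sample, tx.chrom, pos, base, alt, "somatic", somatic_vaf())

    variant_io.annotate(calls, model)

    # --- companion databases ---
    germline_db = KnownGermlineDB(
        frozenset(
            (chrom, pos, ref, alt)
            for chrom, pos, ref, alt, _af, _is_hom, in_db in germline_sites
            if in_db
        ),
        provenance="synthetic known-germline site list",
    )

    codon_map = CodonMap(offsets=dict(CODON_OFFSETS))

    annotated_by_key: dict[tuple, VariantCall] = {}
    for call in calls:
        annotated_by_key.setdefault((call.chrom, call.pos, call.ref, call.alt), call)
    somatic_keys = sorted(
        {
            (r["chrom"], r["pos"], r["ref"], r["alt"])
            for r in truth_rows
            if r["latent_class"] == "somatic"
        }
    )
    hotspot_keys = {hotspot_variants[hs] for hs in config.planted_hotspots}

    def human_change(call: VariantCall) -> str | None:
        if call.gene is None or call.protein_change is None:
            return None
        parsed = parse_protein_change(call.protein_change)
        offset = CODON_OFFSETS.get(call.gene, 0)
        if parsed is None:
            # coordinate-style indel change: shift codon numbers
            if "_" in call.protein_change and call.protein_change.endswith("del"):
                c1, c2 = call.protein_change[:-3].split("_")
                return f"{int(c1) + offset}_{int(c2) + offset}del"
            return call.protein_change
        return f"{parsed[0]}{parsed[1] + offset}{parsed[2]}"

    human_entries: set[tuple[str, str]] = set()
    in_human_db_keys: set[tuple] = set()
    for key in somatic_keys:
        call = annotated_by_key[key]
        change = human_change(call)
        if change is None:
            continue
        if key in hotspot_keys or rng.random() < config.human_db_coverage:
            human_entries.add((call.gene, change))
            in_human_db_keys.add(key)
    # human-specific entries (hotspots absent from the canine cohort)
    human_entries |= {("PIK3CA", "E545K"), ("PIK3CA", "E542K"), ("ERBB2", "S310F")}
    human_db = HumanSomaticDB.from_entries(human_entries)

    human_hotspots = set(HUMAN_ONLY_HOTSPOTS)
    for hs in config.planted_hotspots:
        mapped = codon_map.map_codon(hs.gene, hs.codon)
        if mapped is not None and hs.gene != "ERBB2":  # ERBB2 V659 is canine-specific
            human_hotspots.add((hs.gene, mapped))
    human_hotspots.add(("KRAS", 12))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id", "chrom", "pos", "ref", "alt",
            "latent_class", "hotspot", "in_germline_db", "qc_fail",
        ],
    )
    if len(truth):
        truth["in_human_db"] = [
            (r.chrom, r.pos, r.ref, r.alt) in in_human_db_keys
            for r in truth.itertuples()
        ]
    else:
        truth["in_human_db"] = pd.Series(dtype=bool)

    return Cohort(
        calls=calls,
        metadata=metadata,
        truth=truth,
        germline_db=germline_db,
        human_db=human_db,
        codon_map=codon_map,
        model=model,
        callable_bases=callable_bases,
        human_hotspots=human_hotspots,
        config=config,
    )


# ---------------------------------------------------------------------------
# disk round trip


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write VCFs (one per sample) and all companion tables under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    contigs = sorted({c.chrom for c in cohort.calls}) or ["chrU"]
    by_sample: dict[str, list[VariantCall]] = {}
    for call in cohort.calls:
        by_sample.setdefault(call.sample_id, []).append(call)
    for sid in cohort.metadata["sample_id"]:
        if sid in by_sample:
            variant_io.write_vcf(outdir / "vcf" / f"{sid}.vcf", by_sample[sid], contigs)
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cohort.germline_db.to_table(outdir / "germline_db.tsv")
    cohort.human_db.to_table(outdir / "human_db.tsv")
    cohort.codon_map.to_table(outdir / "codon_map.tsv")
    cohort.model.to_table(outdir / "transcripts.tsv")
    with open(outdir / "callable_bases.tsv", "w") as fh:
        fh.write("sample_id\tcallable_bases\n")
        for sid in cohort.metadata["sample_id"]:
            fh.write(f"{sid}\t{cohort.callable_bases[sid]}\n")
    with open(outdir / "human_hotspots.tsv", "w") as fh:
        fh.write("gene\thuman_codon\n")
        for gene, codon in sorted(cohort.human_hotspots):
            fh.write(f"{gene}\t{codon}\n")


def read_cohort(outdir: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (truth included if present)."""
    outdir = Path(outdir)
    metadata = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    model = TranscriptModel.from_table(outdir / "transcripts.tsv")
    calls: list[VariantCall] = []
    for sid in metadata["sample_id"]:
        path = outdir / "vcf" / f"{sid}.vcf"
        if path.exists():
            calls.extend(variant_io.read_vcf(path, sample_id=str(sid)))
    variant_io.annotate(calls, model)
    truth_path = outdir / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    )
    callable_df = pd.read_csv(outdir / "callable_bases.tsv", sep="\t")
    human_hotspots = set()
    hh_path = outdir / "human_hotspots.tsv"
    if hh_path.exists():
        hh = pd.read_csv(hh_path, sep="\t")
        human_hotspots = {(r.gene, int(r.human_codon)) for r in hh.itertuples()}
    return Cohort(
        calls=calls,
        metadata=metadata,
        truth=truth,
        germline_db=KnownGermlineDB.from_table(outdir / "germline_db.tsv"),
        human_db=HumanSomaticDB.from_table(outdir / "human_db.tsv"),
        codon_map=CodonMap.from_table(outdir / "codon_map.tsv"),
        model=model,
        callable_bases=dict(
            zip(callable_df["sample_id"], callable_df["callable_bases"])
        ),
        human_hotspots=human_hotspots,
        config=CohortConfig(),
    )


# ---------------------------------------------------------------------------
# truth harness


_CLASS_ORDER = ("germline_het", "germline_hom", "somatic")


def truth_confusion(
    classified: Sequence[ClassifiedVariant], truth: pd.DataFrame
) -> pd.DataFrame:
    """Confusion matrix: pipeline rollup (rows) x latent truth class (columns).

    The per-(sample, variant) truth is reduced to one class per unique
    mutation by majority vote over carriers (ties resolved toward the
    earlier of het < hom < somatic). Raises if no keys overlap.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    per_key: dict[tuple, str] = {}
    grouped = truth.groupby(["chrom", "pos", "ref", "alt"])["latent_class"]
    for key, classes in grouped:
        counts = classes.value_counts()
        best = max(
            _CLASS_ORDER,
            key=lambda c: (counts.get(c, 0), -_CLASS_ORDER.index(c)),
        )
        per_key[key] = best
    rows = ("germline", "somatic", "unclassifiable")
    matrix = pd.DataFrame(0, index=rows, columns=list(_CLASS_ORDER))
    matched = 0
    for cv in classified:
        latent = per_key.get(cv.mutation.key)
        if latent is None:
            continue
        matched += 1
        matrix.loc[cv.rollup, latent] += 1
    if classified and matched == 0:
        raise ValueError("no overlap between classified mutations and truth keys")
    return matrix
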