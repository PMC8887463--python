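"""Synthetic proximity-labeling experiments with a known truth table.

The generator emulates the statistical structure of an input/pulldown RNA
labeling experiment at desk scale: a toy genome and annotation with several
gene classes (protein-coding, lncRNA, snRNA, snoRNA, mitochondrial), paired
negative-binomial count observations for input and streptavidin-pulldown
fractions, spliced/unspliced isoform mixtures, promoter-proximal upstream
antisense companions, two treatment conditions with a planted pulldown-side
ratio shift on a subset of genes, and 3' UTRs carrying planted AU-rich
kmers and HuR-like binding sites.

Every planted feature is recorded in a truth table whose flags are computed
by re-scanning the emitted sequences, so truth and output can never drift
apart.  All randomness is drawn from per-gene generators seeded as
``(seed, gene_index, stream)``: adding genes to a configuration never
perturbs the draws of existing genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import TranscriptModel

GENE_CLASSES = ("protein_coding", "lncRNA", "snRNA", "snoRNA", "Mt")

#: HuR-like binding site planted into 3' UTRs (U-rich, ARE-overlapping).
HUR_SITE = "TATTTAT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic labeling experiment.

    Defaults describe a nuclear-marker pulldown: nuclear RNA classes
    (lncRNA, snRNA, snoRNA) enriched, mitochondrial RNA depleted, unspliced
    and antisense fractions higher in the pulldown than in the input, and a
    condition-dependent nuclear-retention shift (export block) planted on a
    subset of genes whose 3' UTRs preferentially carry an AU-rich kmer.
    """

    n_genes: int = 2000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.70,
            "lncRNA": 0.15,
            "snRNA": 0.05,
            "snoRNA": 0.05,
            "Mt": 0.05,
        }
    )
    n_replicates: int = 3
    mean_expression_log_mu: float = 5.0
    mean_expression_log_sigma: float = 1.0
    dispersion: dict[str, float] = field(
        default_factory=lambda: {c: 0.05 for c in GENE_CLASSES}
    )
    enrichment_effects: dict[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.0,
            "lncRNA": 1.0,
            "snRNA": 1.5,
            "snoRNA": 1.0,
            "Mt": -1.0,
        }
    )
    planted_fraction_enriched: float = 0.1
    planted_effect_size: float = 2.0
    unspliced_fraction_input: float = 0.1
    unspliced_fraction_pulldown: float = 0.3
    antisense_fraction_of_sense: dict[str, float] = field(
        default_factory=lambda: {"input": 0.05, "pulldown": 0.15}
    )
    shift_target_fraction: float = 0.1
    shift_effect_size: float = 1.0
    planted_kmer: str = "ATTTTA"
    planted_kmer_prevalence_target: float = 0.5
    planted_kmer_prevalence_background: float = 0.05
    hur_site_rate: float = 1.0
    hur_effect_per_site: float = 0.0
    size_factor_log_sigma: float = 0.2
    seed: int = 0
    # toy genome geometry
    utr_length: int = 300
    exon_length_range: tuple[int, int] = (100, 250)
    intron_length_range: tuple[int, int] = (60, 200)
    ua_length: int = 500
    intergenic_gap: int = 800

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < len(self.class_proportions):
            raise ConfigurationError(
                f"n_genes={self.n_genes} is smaller than the number of gene "
                f"classes ({len(self.class_proportions)})"
            )
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must sum to 1")
        fractions = [
            self.planted_fraction_enriched,
            self.unspliced_fraction_input,
            self.unspliced_fraction_pulldown,
            self.shift_target_fraction,
            self.planted_kmer_prevalence_target,
            self.planted_kmer_prevalence_background,
            *self.class_proportions.values(),
            *self.antisense_fraction_of_sense.values(),
        ]
        if any(f < 0 or f > 1 for f in fractions):
            raise ConfigurationError("all fractions must lie in [0, 1]")
        if any(a < 0 for a in self.dispersion.values()):
            raise ConfigurationError("dispersion must be non-negative")
        if set(self.planted_kmer) - set("ACGT"):
            raise ConfigurationError("planted_kmer must be over {A,C,G,T}")
        if self.utr_length < max(len(self.planted_kmer), len(HUR_SITE)):
            raise ConfigurationError(
                "planted features cannot fit: utr_length shorter than planted "
                "kmer / HuR site"
            )
        if self.n_replicates < 1 or self.n_genes < 1:
            raise ConfigurationError("n_genes and n_replicates must be positive")
        if self.intergenic_gap < self.ua_length:
            raise ConfigurationError(
                "intergenic_gap must accommodate the upstream antisense companion"
            )


def _gene_rng(config: SimulationConfig, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, index, stream])


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _count_overlapping(seq: str, sub: str) -> int:
    count = start = 0
    while True:
        i = seq.find(sub, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _design_utr(
    rng: np.random.Generator, config: SimulationConfig, kmer_wanted: bool
) -> str:
    """Build one UTR sequence; guarantee planted-kmer presence/absence."""
    arr = _random_bases(rng, config.utr_length)
    n_hur = rng.poisson(config.hur_site_rate)
    site = np.frombuffer(HUR_SITE.encode(), dtype="S1")
    for _ in range(n_hur):
        pos = int(rng.integers(0, config.utr_length - len(HUR_SITE) + 1))
        arr[pos : pos + len(site)] = site
    seq = arr.tobytes().decode()
    kmer = config.planted_kmer
    if kmer_wanted:
        if kmer not in seq:
            pos = int(rng.integers(0, config.utr_length - len(kmer) + 1))
            arr[pos : pos + len(kmer)] = np.frombuffer(kmer.encode(), dtype="S1")
            seq = arr.tobytes().decode()
    else:
        # scrub: a G in the middle of an occurrence can neither recreate the
        # (G-free) planted kmer nor form a HuR site
        while kmer in seq:
            i = seq.find(kmer)
            arr[i + len(kmer) // 2] = b"G"
            seq = arr.tobytes().decode()
    return seq


@dataclass
class _GeneStructure:
    exon_lengths: list[int]  # transcript orientation
    intron_lengths: list[int]
    strand: str


def _draw_structure(
    rng: np.random.Generator, config: SimulationConfig, gene_class: str
) -> _GeneStructure:
    lo, hi = config.exon_length_range
    ilo, ihi = config.intron_length_range
    if gene_class == "protein_coding":
        n_exons = int(rng.integers(2, 5))
    elif gene_class == "lncRNA":
        n_exons = int(rng.integers(1, 4))
    else:
        n_exons = 1
    exon_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_exons)]
    if gene_class == "protein_coding":
        # transcript-final exon must hold the whole 3' UTR
        exon_lengths[-1] = config.utr_length + int(rng.integers(30, 121))
    intron_lengths = [int(rng.integers(ilo, ihi + 1)) for _ in range(n_exons - 1)]
    strand = "+" if rng.random() < 0.5 else "-"
    return _GeneStructure(exon_lengths, intron_lengths, strand)


def generate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel], pd.DataFrame]:
    """Generate (genome, annotation, truth) for one configuration.

    The genome holds one main chromosome plus ``chrM`` for mitochondrial
    genes.  Each gene gets one transcript; protein-coding genes carry a 3'
    UTR whose sequence is written into the genome so that re-extraction
    reproduces the designed (feature-planted) sequence exactly.  Each gene
    also gets a single-exon upstream antisense companion on the opposite
    strand, immediately upstream of its TSS.
    """
    config.validate()
    classes = sorted(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])

    rows = []
    structures: list[_GeneStructure] = []
    utr_seqs: list[str | None] = []
    for i in range(config.n_genes):
        rng = _gene_rng(config, i, 0)
        gene_class = classes[int(rng.choice(len(classes), p=probs))]
        mu = float(rng.lognormal(config.mean_expression_log_mu, config.mean_expression_log_sigma))
        planted = bool(
            gene_class == "protein_coding"
            and rng.random() < config.planted_fraction_enriched
        )
        planted_effect = float(
            config.planted_effect_size * (1 if rng.random() < 0.5 else -1)
        ) if planted else 0.0
        shifted = bool(rng.random() < config.shift_target_fraction)
        structure = _draw_structure(rng, config, gene_class)
        structures.append(structure)
        if gene_class == "protein_coding":
            prev = (
                config.planted_kmer_prevalence_target
                if shifted
                else config.planted_kmer_prevalence_background
            )
            kmer_wanted = bool(rng.random() < prev)
            utr_seq = _design_utr(rng, config, kmer_wanted)
        else:
            utr_seq = None
        utr_seqs.append(utr_seq)
        hur_sites = _count_overlapping(utr_seq, HUR_SITE) if utr_seq else 0
        rows.append(
            {
                "gene_id": f"G{i:05d}",
                "gene_class": gene_class,
                "mu": mu,
                "class_log2_enrichment": config.enrichment_effects.get(gene_class, 0.0),
                "planted_enriched": planted,
                "planted_log2_effect": planted_effect,
                "log2_enrichment": config.enrichment_effects.get(gene_class, 0.0)
                + planted_effect
                + config.hur_effect_per_site * hur_sites,
                "unspliced_fraction_input": config.unspliced_fraction_input,
                "unspliced_fraction_pulldown": config.unspliced_fraction_pulldown,
                "antisense_fraction_input": config.antisense_fraction_of_sense["input"],
                "antisense_fraction_pulldown": config.antisense_fraction_of_sense["pulldown"],
                "shifted": shifted,
                "shift_delta": config.shift_effect_size if shifted else 0.0,
                "has_utr": utr_seq is not None,
                "kmer_present": bool(utr_seq and config.planted_kmer in utr_seq),
                "are_present": bool(utr_seq and "ATTTA" in utr_seq),
                "hur_sites": hur_sites,
            }
        )

    truth = pd.DataFrame(rows)

    # sequential layout; chrM for mitochondrial genes, chr1 for the rest
    cursors = {"chr1": 0, "chrM": 0}
    models: list[TranscriptModel] = []
    planted_patches: list[tuple[str, int, str]] = []  # (chrom, start, sequence)
    for i, (row, st) in enumerate(zip(rows, structures)):
        chrom = "chrM" if row["gene_class"] == "Mt" else "chr1"
        span = sum(st.exon_lengths) + sum(st.intron_lengths)
        gstart = cursors[chrom] + config.intergenic_gap
        gend = gstart + span
        cursors[chrom] = gend + config.intergenic_gap

        # exon intervals: genomic order is transcript order on +, reversed on -
        lengths = list(zip(st.exon_lengths, st.intron_lengths + [0]))
        if st.strand == "-":
            lengths = [
                (e, i_)
                for e, i_ in zip(
                    st.exon_lengths[::-1], (st.intron_lengths[::-1] + [0])
                )
            ]
        exons = []
        pos = gstart
        for exon_len, intron_len in lengths:
            exons.append((pos, pos + exon_len))
            pos += exon_len + intron_len

        utr3 = None
        if row["has_utr"]:
            if st.strand == "+":
                utr3 = (gend - config.utr_length, gend)
            else:
                utr3 = (gstart, gstart + config.utr_length)
            seq = utr_seqs[i]
            assert seq is not None
            if st.strand == "-":
                seq = _revcomp(seq)
            planted_patches.append((chrom, utr3[0], seq))

        gid = row["gene_id"]
        models.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                chrom=chrom,
                strand=st.strand,
                exons=exons,
                utr3=utr3,
                gene_class=row["gene_class"],
            )
        )
        # promoter-proximal upstream antisense companion, opposite strand
        if st.strand == "+":
            ua_exon = (gstart - config.ua_length, gstart)
            ua_strand = "-"
        else:
            ua_exon = (gend, gend + config.ua_length)
            ua_strand = "+"
        models.append(
            TranscriptModel(
                transcript_id=f"{gid}|ua.t1",
                gene_id=f"{gid}|ua",
                chrom=chrom,
                strand=ua_strand,
                exons=[ua_exon],
                utr3=None,
                gene_class="uaRNA",
            )
        )

    genome: dict[str, str] = {}
    for chrom_idx, chrom in enumerate(("chr1", "chrM")):
        length = cursors[chrom] + config.intergenic_gap
        rng = np.random.default_rng([config.seed, chrom_idx, 2])
        arr = _random_bases(rng, length)
        genome[chrom] = arr
    for chrom, start, seq in planted_patches:
        genome[chrom][start : start + len(seq)] = np.frombuffer(
            seq.encode(), dtype="S1"
        )
    genome_str = {c: a.tobytes().decode() for c, a in genome.items()}
    return genome_str, models, truth


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def make_design(
    n_replicates: int = 3,
    conditions: Sequence[str] = ("untreated", "LMB"),
    fractions: Sequence[str] = ("input", "pulldown"),
) -> pd.DataFrame:
    """Sample sheet with one row per (fraction, condition, replicate)."""
    rows = [
        {
            "sample_id": f"{f}_{c}_{r + 1}",
            "fraction": f,
            "condition": c,
            "replicate": r + 1,
        }
        for f in fractions
        for c in conditions
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    config: SimulationConfig, truth: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Draw the NB count matrix implied by a truth table and a design.

    Per gene and sample the sense transcript mean is
    ``s_j * mu_g * 2**effect`` where the effect collects the class-level and
    gene-specific pulldown enrichments and, in non-reference conditions, the
    planted pulldown-side shift.  The sense mean is split into spliced and
    unspliced components by the per-fraction unspliced fraction; the upstream
    antisense companion's mean is a per-fraction fraction of the sense mean.
    Rows are keyed ``<gene>|spliced``, ``<gene>|unspliced``, ``<gene>|ua``.
    """
    cells = design.groupby(["fraction", "condition"]).size()
    if (cells < 2).any():
        raise ValueError("design must have >=2 replicates per (fraction, condition)")
    if truth["gene_id"].duplicated().any():
        raise ValueError("input inconsistency: duplicate gene_ids in truth table")

    conditions = list(dict.fromkeys(design["condition"]))
    ref_condition = conditions[0]
    sf_rng = np.random.default_rng([config.seed, 7, 3])
    size_factors = np.exp(
        sf_rng.normal(0.0, config.size_factor_log_sigma, size=len(design))
    )

    is_pulldown = (design["fraction"] == "pulldown").to_numpy()
    is_shifted_cond = (design["condition"] != ref_condition).to_numpy()
    unspliced_frac = np.where(
        is_pulldown, config.unspliced_fraction_pulldown, config.unspliced_fraction_input
    )
    ua_frac = np.array(
        [config.antisense_fraction_of_sense[f] for f in design["fraction"]]
    )

    index: list[str] = []
    data = np.empty((3 * len(truth), len(design)), dtype=np.int64)
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = _gene_rng(config, i, 1)
        alpha = config.dispersion.get(row.gene_class, 0.1)
        log2eff = np.where(
            is_pulldown,
            row.log2_enrichment + np.where(is_shifted_cond, row.shift_delta, 0.0),
            0.0,
        )
        sense_mean = size_factors * row.mu * np.exp2(log2eff)
        data[3 * i] = _nb_draw(rng, sense_mean * (1 - unspliced_frac), alpha)
        data[3 * i + 1] = _nb_draw(rng, sense_mean * unspliced_frac, alpha)
        data[3 * i + 2] = _nb_draw(rng, sense_mean * ua_frac, alpha)
        index += [f"{row.gene_id}|spliced", f"{row.gene_id}|unspliced", f"{row.gene_id}|ua"]
    return pd.DataFrame(data, index=pd.Index(index, name="feature_id"), columns=list(design["sample_id"]))


def simulate_dataset(
    config: SimulationConfig,
    conditions: Sequence[str] = ("untreated", "LMB"),
) -> dict:
    """One-call convenience wrapper: genome, annotation, truth, design, counts."""
    genome, models, truth = generate_annotation(config)
    design = make_design(config.n_replicates, conditions=conditions)
    counts = simulate_counts(config, truth, design)
    return {
        "genome": genome,
        "annotation": models,
        "truth": truth,
        "design": design,
        "counts": counts,
    }
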