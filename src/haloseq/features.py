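"""Sequence-feature enrichment over 3' UTRs: kmers, RBP motifs, AU-rich elements.

A target gene set (e.g. transcripts whose nuclear export is drug-sensitive)
is compared against a background set by presence/absence 2x2 tables: for
each feature (a kmer, a position-weight-matrix motif, or an ARE) the table
counts target UTRs with/without the feature against background UTRs
with/without it, scored by a two-sided Fisher exact test with
Haldane-corrected (+0.5) log2 odds ratios and BH adjustment.

Kmer counting is strand-specific (UTRs are already in transcript
orientation) and overlapping; windows containing N are skipped.  AREs are
detected as clusters of ATTTA pentamers, or loaded from a precomputed BED
(which takes precedence, mirroring database-derived ARE annotations).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

ARE_PENTAMER = "ATTTA"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
ALPHABET = "ACGT"


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all valid (N-free) overlapping k-windows."""
    codes = _encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    return (windows[valid] * powers).sum(axis=1)


def count_kmers(
    sequences: Mapping[str, str], k: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sequence kmer presence and total overlapping occurrence counts.

    Returns ``(presence, totals)``: a boolean (sequences x 4^k) frame and a
    Series of summed occurrence counts over all sequences, both indexed by
    kmer string in lexicographic order.
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8]")
    if not sequences:
        raise ValueError("input error: empty sequence set")
    kmers = all_kmers(k)
    presence = np.zeros((len(sequences), 4**k), dtype=bool)
    totals = np.zeros(4**k, dtype=np.int64)
    names = list(sequences)
    for i, name in enumerate(names):
        codes = _kmer_codes(sequences[name], k)
        if codes.size:
            counts = np.bincount(codes, minlength=4**k)
            presence[i] = counts > 0
            totals += counts
    presence_df = pd.DataFrame(presence, index=pd.Index(names, name="gene_id"), columns=kmers)
    return presence_df, pd.Series(totals, index=kmers, name="count")


def _presence_enrichment(
    target_presence: pd.DataFrame, background_presence: pd.DataFrame
) -> pd.DataFrame:
    """2x2 Fisher enrichment records from two presence tables (shared columns)."""
    n_t = len(target_presence)
    n_b = len(background_presence)
    a = target_presence.sum(axis=0).to_numpy()
    c = background_presence.sum(axis=0).to_numpy()
    b = n_t - a
    d = n_b - c
    log2_or = np.log2(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
    pvalues = np.ones(len(a))
    cache: dict[tuple[int, int], float] = {}
    for i, (ai, ci) in enumerate(zip(a, c)):
        if ai == 0 and ci == 0:
            continue
        key = (int(ai), int(ci))
        if key not in cache:
            cache[key] = sps.fisher_exact(
                [[ai, n_t - ai], [ci, n_b - ci]], alternative="two-sided"
            )[1]
        pvalues[i] = cache[key]
    records = pd.DataFrame(
        {
            "feature": target_presence.columns,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "log2_odds_ratio": log2_or,
            "pvalue": pvalues,
            "padj": bh_adjust(pvalues),
        }
    )
    records = records.sort_values(
        ["padj", "log2_odds_ratio"],
        key=lambda s: s if s.name == "padj" else -s.abs(),
        kind="mergesort",
    ).reset_index(drop=True)
    return records


def kmer_enrichment(
    target: Mapping[str, str], background: Mapping[str, str], k: int = 6
) -> pd.DataFrame:
    """Per-kmer presence enrichment of target UTRs over background UTRs.

    BH adjustment runs across the full 4^k kmer universe (never-observed
    kmers contribute p = 1 rows), keeping the denominator deterministic.
    """
    if not target or not background:
        raise ValueError("input error: empty target or background set")
    overlap = set(target) & set(background)
    if overlap:
        raise ValueError(
            f"target and background gene sets must be disjoint ({len(overlap)} shared)"
        )
    target_presence, _ = count_kmers(target, k)
    background_presence, _ = count_kmers(background, k)
    return _presence_enrichment(target_presence, background_presence)


@dataclass
class PWM:
    """Position probability matrix over ACGT (RNA motifs unified by U -> T)."""

    motif_id: str
    matrix: np.ndarray  # (w, 4), rows sum to 1
    floor: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be (w, 4)")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(
                f"malformed matrix for motif {self.motif_id}: rows must sum to 1"
            )
        floored = np.clip(self.matrix, self.floor, None)
        self._probs = floored / floored.sum(axis=1, keepdims=True)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2 probability ratio against a uniform 0.25 background."""
        return np.log2(self._probs / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def degenerate(self) -> bool:
        """True when no positive score is attainable (e.g. uniform matrix)."""
        return self.max_score <= 0.0

    def scan(self, seq: str, score_fraction: float = 0.8) -> int:
        """Number of offsets scoring >= score_fraction * max attainable score."""
        if not 0.0 < score_fraction <= 1.0:
            raise ValueError("score_fraction must be in (0, 1]")
        codes = _encode(seq)
        w = self.length
        if len(codes) < w:
            return 0
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            return 0
        lo = self.log_odds
        scores = lo[np.arange(w), windows[valid]].sum(axis=1)
        threshold = score_fraction * self.max_score
        return int((scores >= threshold).sum())


#: identifier of the built-in HuR-like motif
HUR_PWM_ID = "HuR_like"


def hur_pwm(consensus: str = "TATTTAT", weight: float = 0.91) -> PWM:
    """Built-in HuR-like U-rich motif as a sharply peaked PWM.

    With ``score_fraction=1.0`` scanning reduces to exact consensus matching,
    which is how the synthetic truth defines a HuR binding site.
    """
    matrix = np.full((len(consensus), 4), (1.0 - weight) / 3.0)
    for i, base in enumerate(consensus):
        matrix[i, ALPHABET.index(base)] = weight
    return PWM(motif_id=HUR_PWM_ID, matrix=matrix)


def read_meme(path: str | Path, floor: float = 1e-3) -> list[PWM]:
    """Load motifs from minimal MEME format; RNA alphabets are mapped to DNA."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        letters = list(m.alphabet)
        columns = {letter.replace("U", "T"): np.asarray(m.pwm[letter]) for letter in letters}
        matrix = np.column_stack([columns[b] for b in ALPHABET])
        out.append(PWM(motif_id=m.name, matrix=matrix, floor=floor))
    return out


def write_meme(motifs: Sequence[PWM], path: str | Path, alphabet: str = "ACGT") -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} 0.25" for b in alphabet) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.length} nsites= 1000000 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def scan_pwm(
    sequences: Mapping[str, str],
    motifs: Sequence[PWM],
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Hit counts per gene (rows) and motif (columns)."""
    degenerate = [m.motif_id for m in motifs if m.degenerate]
    if degenerate:
        logger.warning("scan_pwm: degenerate motifs (max score <= 0): %s", degenerate)
    data = {
        m.motif_id: [m.scan(seq, score_fraction) for seq in sequences.values()]
        for m in motifs
    }
    return pd.DataFrame(data, index=pd.Index(list(sequences), name="gene_id"))


def motif_enrichment(
    target: Mapping[str, str],
    background: Mapping[str, str],
    motifs: Sequence[PWM],
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-motif presence (>=1 hit) enrichment of target over background."""
    if not target or not background:
        raise ValueError("input error: empty target or background set")
    target_hits = scan_pwm(target, motifs, score_fraction) > 0
    background_hits = scan_pwm(background, motifs, score_fraction) > 0
    return _presence_enrichment(target_hits, background_hits)


def _find_overlapping(seq: str, sub: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = seq.find(sub, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def detect_ares(sequences: Mapping[str, str]) -> pd.DataFrame:
    """ATTTA-pentamer cluster detection in UTR-space coordinates.

    Pentamers overlapping by at least one base or separated by at most two
    bases merge into one cluster; a cluster's class is min(#pentamers, 5),
    echoing the class logic of curated ARE databases.
    """
    rows = []
    w = len(ARE_PENTAMER)
    for gene_id, seq in sequences.items():
        hits = _find_overlapping(seq.upper(), ARE_PENTAMER)
        if not hits:
            continue
        cluster = [hits[0]]
        clusters = []
        for pos in hits[1:]:
            if pos - (cluster[-1] + w) <= 2:
                cluster.append(pos)
            else:
                clusters.append(cluster)
                cluster = [pos]
        clusters.append(cluster)
        for cl in clusters:
            rows.append(
                {
                    "gene_id": gene_id,
                    "start": cl[0],
                    "end": cl[-1] + w,
                    "n_pentamers": len(cl),
                    "are_class": min(len(cl), 5),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "n_pentamers", "are_class"])


def load_ares(bed_path: str | Path) -> pd.DataFrame:
    """Load precomputed ARE spans from 6-column BED (gene-space coordinates).

    Columns: gene_id, start, end, name, pentamer count, strand.  When both
    detected and loaded spans are available, the loaded ones take precedence
    (they represent the curated, database-derived annotation route).
    """
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"parse error at BED line {lineno}: expected 6 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                n_pent = int(float(parts[4]))
            except ValueError as exc:
                raise ValueError(f"parse error at BED line {lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"parse error at BED line {lineno}: empty interval")
            rows.append(
                {
                    "gene_id": parts[0],
                    "start": start,
                    "end": end,
                    "n_pentamers": n_pent,
                    "are_class": min(n_pent, 5),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "n_pentamers", "are_class"])


def annotate_genes_with_features(
    genes: Iterable[str],
    are_spans: pd.DataFrame | None = None,
    hur_site_counts: Mapping[str, int] | pd.Series | None = None,
    hur_bin_edges: Sequence[int] = (0, 1, 2, 3),
) -> pd.DataFrame:
    """Per-gene feature bins for grouped enrichment comparisons.

    Returns a frame indexed by gene with ``has_are`` (bool), ``hur_sites``
    (int) and ``hur_bin`` (top bin open-ended, default 0 / 1 / 2 / >=3).
    Genes absent from the feature tables get (False, 0).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("id-scheme mismatch: empty gene universe")
    are_genes = set(are_spans["gene_id"]) if are_spans is not None and len(are_spans) else set()
    hur = pd.Series(hur_site_counts, dtype=float) if hur_site_counts is not None else pd.Series(dtype=float)
    if (are_spans is not None and len(are_spans)) or len(hur):
        known = are_genes | set(hur.index)
        if known and not (known & set(genes)):
            raise ValueError("id-scheme mismatch: feature tables share no genes with input")
    edges = sorted(hur_bin_edges)
    top = edges[-1]

    def hur_bin(n: int) -> str:
        for lo, hi in zip(edges, edges[1:]):
            if lo <= n < hi:
                return str(lo)
        return f"{top}+" if n >= top else str(edges[0])

    rows = []
    matched = 0
    for g in genes:
        sites = int(hur.get(g, 0))
        if g in are_genes or g in hur.index:
            matched += 1
        rows.append(
            {
                "gene_id": g,
                "has_are": g in are_genes,
                "hur_sites": sites,
                "hur_bin": hur_bin(sites),
            }
        )
    logger.info(
        "annotate_genes_with_features: %d/%d genes matched a feature table",
        matched, len(genes),
    )
    return pd.DataFrame(rows).set_index("gene_id")
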