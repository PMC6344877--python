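"""Promoter -10 region analysis around transcription start sites.

Workflow: keep primary TSS, extract strand-aware windows at TSS-relative
offsets (inclusive on both ends, TSS itself at offset 0), anchor a 6-mer
motif (a TANNNT pattern or a position-weight matrix with exact enumeration
P-values), classify each anchored site by the two bases immediately 5' of
the anchor (GG / G / noG), compare the observed GG count against the
genome-wide overlapping-dinucleotide frequency, and test dependent vs
independent site classes with Fisher's exact test.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "TSSRecord",
    "PromoterWindow",
    "PromoterSite",
    "EnrichmentResult",
    "read_tss_table",
    "read_genome_fasta",
    "write_genome_fasta",
    "filter_primary_tss",
    "extract_windows",
    "scan_motif",
    "classify_gg",
    "genome_gg_frequency",
    "expected_gg_sites",
    "fisher_gg_enrichment",
]

logger = logging.getLogger(__name__)

TSS_CATEGORIES = ("primary", "secondary", "internal", "antisense", "orphan")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class TSSRecord:
    chrom: str
    position: int  # 1-based
    strand: str
    category: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("TSS position must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.category not in TSS_CATEGORIES:
            raise ValueError(f"unknown TSS category {self.category!r}")


@dataclass(frozen=True)
class PromoterWindow:
    """A TSS-relative sequence window; ``from_off`` maps to seq[0]."""

    tss: TSSRecord
    sequence: str
    from_off: int
    to_off: int


@dataclass(frozen=True)
class PromoterSite:
    """A motif-anchored window with its -14/-13 class.

    ``anchor_off`` is the TSS-relative offset of the motif's first base
    (nominally -12); ``gg_class`` classifies the two bases immediately 5' of
    the anchor; ``base_at_anchor`` is the first motif base's position value
    reported for the nominal -12 tally.
    """

    window: PromoterWindow
    anchor_off: int
    motif: str
    gg_class: str  # GG | G | noG
    upstream_dinucleotide: str
    base_at_minus12: str
    p_value: float | None = None


@dataclass
class EnrichmentResult:
    counts: dict[str, int]
    n_sites: int
    genome_gg_frequency: float
    expected_gg: float
    expected_gg_rounded: int
    table: tuple[tuple[int, int], tuple[int, int]] | None = None
    fisher_p: float | None = None


def read_tss_table(path) -> list[TSSRecord]:
    """TSV with columns chrom, position, strand, category, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    return [TSSRecord(chrom=row.chrom, position=int(row.position),
                      strand=row.strand, category=row.category,
                      gene_id=row.gene_id)
            for row in df.itertuples()]


def write_tss_table(records: list[TSSRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t",
                                                       index=False)


def read_genome_fasta(path) -> dict[str, str]:
    """Plain FASTA reader returning upper-cased contig sequences."""
    genome: dict[str, list[str]] = {}
    name = None
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                genome[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence before header")
                genome[name].append(line.upper())
    return {k: "".join(v) for k, v in genome.items()}


def write_genome_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def filter_primary_tss(records: list[TSSRecord]) -> list[TSSRecord]:
    """Keep records labelled 'primary', preserving order."""
    return [r for r in records if r.category == "primary"]


def extract_windows(records: list[TSSRecord], genome: dict[str, str],
                    from_off: int = -20, to_off: int = 0) -> list[PromoterWindow]:
    """Strand-aware windows at inclusive TSS-relative offsets.

    Offset 0 is the TSS base itself; negative offsets are upstream.  The
    window length is ``to_off - from_off + 1`` and - strand windows are
    reverse-complemented so upstream always reads 5'->3' toward the TSS.
    Windows falling outside their contig are skipped with a warning.
    """
    if from_off > to_off:
        raise ValueError("from_off must be <= to_off")
    windows = []
    for rec in records:
        seq = genome.get(rec.chrom)
        if seq is None:
            raise ValueError(f"TSS on unknown contig {rec.chrom!r}")
        if rec.strand == "+":
            lo = rec.position + from_off   # 1-based genomic
            hi = rec.position + to_off
        else:
            lo = rec.position - to_off
            hi = rec.position - from_off
        if lo < 1 or hi > len(seq):
            logger.warning("window for TSS %s:%d%s outside contig; skipped",
                           rec.chrom, rec.position, rec.strand)
            continue
        sub = seq[lo - 1:hi]
        if rec.strand == "-":
            sub = reverse_complement(sub)
        windows.append(PromoterWindow(tss=rec, sequence=sub,
                                      from_off=from_off, to_off=to_off))
    return windows


def _classify_pair(pair: str) -> str:
    g_count = pair.count("G")
    return "GG" if g_count == 2 else ("G" if g_count == 1 else "noG")


def _pattern_to_regex(pattern: str) -> re.Pattern:
    return re.compile("".join("." if c == "N" else re.escape(c)
                              for c in pattern.upper()))


def _site_from_anchor(window: PromoterWindow, pos: int, length: int,
                      p_value: float | None = None) -> PromoterSite | None:
    if pos < 2:
        logger.warning("anchor at %s:%d too close to window edge; skipped",
                       window.tss.chrom, window.tss.position)
        return None
    motif = window.sequence[pos:pos + length]
    pair = window.sequence[pos - 2:pos]
    return PromoterSite(
        window=window,
        anchor_off=window.from_off + pos,
        motif=motif,
        gg_class=_classify_pair(pair),
        upstream_dinucleotide=pair,
        base_at_minus12=motif[0],
        p_value=p_value,
    )


def scan_motif(windows: list[PromoterWindow], motif: str = "TANNNT",
               pwm: np.ndarray | None = None,
               background: np.ndarray | None = None,
               p_max: float = 0.05) -> list[PromoterSite]:
    """Anchor a 6-position motif inside each window; drop windows without one.

    Pattern mode anchors the leftmost match of a degenerate pattern such as
    TANNNT.  PWM mode takes a 4 x 6 matrix (rows A, C, G, T of per-position
    probabilities), scores every window position by log-likelihood ratio
    against ``background`` (uniform by default), keeps the best position, and
    computes its exact P-value by enumerating all 4^6 hexamers; sites with
    P >= ``p_max`` are dropped.
    """
    sites: list[PromoterSite] = []
    if pwm is None:
        regex = _pattern_to_regex(motif)
        length = len(motif)
        for window in windows:
            match = regex.search(window.sequence)
            if match is None:
                continue
            site = _site_from_anchor(window, match.start(), length)
            if site is not None:
                sites.append(site)
        return sites

    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape != (4, 6):
        raise ValueError("PWM must be a 4 x 6 matrix (rows A, C, G, T)")
    if np.any(pwm < 0) or np.any(~np.isfinite(pwm)):
        raise ValueError("malformed PWM")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        logodds = np.log(np.maximum(pwm, 1e-300)) - np.log(background)[:, None]
    base_index = {b: i for i, b in enumerate("ACGT")}

    # exact null distribution over all 4096 hexamers under the background
    grids = np.meshgrid(*[np.arange(4)] * 6, indexing="ij")
    combo = np.stack([g.ravel() for g in grids], axis=1)  # (4096, 6)
    scores_all = logodds[combo, np.arange(6)].sum(axis=1)
    probs_all = background[combo].prod(axis=1)

    length = 6
    for window in windows:
        seq = window.sequence
        best_pos, best_score = None, -np.inf
        for pos in range(len(seq) - length + 1):
            hexamer = seq[pos:pos + length]
            if any(b not in base_index for b in hexamer):
                continue
            idx = [base_index[b] for b in hexamer]
            score = float(logodds[idx, np.arange(6)].sum())
            if score > best_score:
                best_pos, best_score = pos, score
        if best_pos is None:
            continue
        p_value = float(probs_all[scores_all >= best_score - 1e-12].sum())
        if p_value >= p_max:
            continue
        site = _site_from_anchor(window, best_pos, length, p_value)
        if site is not None:
            sites.append(site)
    return sites


def classify_gg(sites: list[PromoterSite]) -> dict[str, dict[str, int]]:
    """Tally GG/G/noG classes and the base at the motif anchor (nominal -12)."""
    class_counts = {"GG": 0, "G": 0, "noG": 0}
    base_counts = {b: 0 for b in "ACGT"}
    for site in sites:
        class_counts[site.gg_class] += 1
        if site.base_at_minus12 in base_counts:
            base_counts[site.base_at_minus12] += 1
    return {"classes": class_counts, "base_at_minus12": base_counts}


def genome_gg_frequency(genome: dict[str, str] | str) -> float:
    """Overlapping GG dinucleotide frequency: count(GG) / sum(len - 1).

    Counted on the given strand only; 'GGG' contributes two occurrences.
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    total_gg = 0
    total_len = 0
    for seq in genome.values():
        if not seq:
            continue
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        is_g = arr == ord("G")
        total_gg += int(np.count_nonzero(is_g[:-1] & is_g[1:]))
        total_len += len(seq) - 1
    if total_len <= 0:
        raise ValueError("empty genome")
    return total_gg / total_len


def expected_gg_sites(f_gg: float, n_sites: int) -> tuple[float, int]:
    """Expected chance count of GG-bearing sites: f_GG * n_sites (raw, rounded)."""
    if not (0.0 <= f_gg <= 1.0):
        raise ValueError("f_gg must lie in [0, 1]")
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    raw = f_gg * n_sites
    return raw, int(round(raw))


def fisher_gg_enrichment(dep_gg: int, dep_not: int, ind_gg: int, ind_not: int,
                         alternative: str = "two-sided") -> float:
    """Fisher exact P for the 2x2 table (dependent/independent x GG/not-GG)."""
    cells = (dep_gg, dep_not, ind_gg, ind_not)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    _, p = fisher_exact([[dep_gg, dep_not], [ind_gg, ind_not]],
                        alternative=alternative)
    return float(p)


def enrichment_report(dep_sites: list[PromoterSite],
                      ind_sites: list[PromoterSite],
                      genome: dict[str, str]) -> EnrichmentResult:
    """Assemble counts, expected-by-chance GG sites and the Fisher test."""
    tallies = classify_gg(dep_sites)["classes"]
    n_sites = len(dep_sites)
    f_gg = genome_gg_frequency(genome)
    raw, rounded = expected_gg_sites(f_gg, n_sites)
    dep_gg = tallies["GG"]
    ind_tallies = classify_gg(ind_sites)["classes"]
    ind_gg = ind_tallies["GG"]
    table = ((dep_gg, n_sites - dep_gg),
             (ind_gg, len(ind_sites) - ind_gg))
    p = (fisher_gg_enrichment(*table[0], *table[1])
         if (n_sites and len(ind_sites)) else None)
    return EnrichmentResult(counts=tallies, n_sites=n_sites,
                            genome_gg_frequency=f_gg, expected_gg=raw,
                            expected_gg_rounded=rounded, table=table,
                            fisher_p=p)
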