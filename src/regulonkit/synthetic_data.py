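"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* regulator/cofactor profiles — smooth positive unimodal curves, the
  regulator peaking early and slowly decaying, the cofactor peaking late,
  so that the two regulated models become distinguishable;
* target expression series — forward simulation of chosen kinetic models on
  the sampling grid with multiplicative log-normal noise;
* genomic fixtures — a random-composition genome with planted promoter
  units (TSS, TANNNT motif at offsets -12..-7, controlled -14/-13
  dinucleotide, gene start codon, ChIP peak), operon membership, and truth
  tables recording every planted feature.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_data
from .expression_data import ExpressionMatrix, SmoothedProfile
from .kinetic_models import KineticParams, simulate
from .promoter_analysis import TSSRecord, reverse_complement, write_tss_table
from .regulon_mapping import GeneModel, Peak, write_peaks_xls

__all__ = [
    "SimulationConfig",
    "GenomicFixtures",
    "make_regulator_profiles",
    "default_param_sets",
    "simulate_targets",
    "make_genomic_fixtures",
    "write_fixtures",
]

# default sampling grid: 32 irregular hourly samples between 20 and 60 h
DEFAULT_TIME_GRID = (
    20, 21, 22, 23, 24, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36,
    37, 38, 39, 40, 41, 42, 43, 44, 46, 48, 50, 52, 54, 56, 58, 60,
)


@dataclass
class SimulationConfig:
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    noise_sd: float = 0.05
    seed: int = 0
    # targets per generating model
    n_constant: int = 5
    n_direct: int = 5
    n_cooperative: int = 5
    # regulator (early peak, slow decay) and cofactor (late peak) shapes
    regulator_peak_time: float = 26.0
    regulator_width: float = 12.0
    regulator_amplitude: float = 8.0
    regulator_baseline: float = 1.0
    cofactor_peak_time: float = 52.0
    cofactor_width: float = 7.0
    cofactor_amplitude: float = 8.0
    cofactor_baseline: float = 1.0
    # genomic fixture knobs
    genome_length: int = 80000
    gc_fraction: float = 0.6
    motif_plant_rate: float = 1.0
    gg_rate_dependent: float = 0.5
    gg_rate_independent: float = 0.1
    n_promoters_dependent: int = 20
    n_promoters_independent: int = 20
    n_secondary_tss: int = 4
    n_operons: int = 4
    operon_size: int = 3
    frac_unassignable: float = 0.15
    n_insignificant_peaks: int = 3
    chrom: str = "chr"

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        for name in ("motif_plant_rate", "gg_rate_dependent",
                     "gg_rate_independent", "gc_fraction",
                     "frac_unassignable"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.time_grid, dtype=float)


def _bump_profile(name: str, times: np.ndarray, peak: float, width: float,
                  amplitude: float, baseline: float) -> SmoothedProfile:
    dense = np.linspace(times[0], times[-1], 201)
    values = baseline + amplitude * np.exp(-0.5 * ((dense - peak) / width) ** 2)
    return SmoothedProfile.from_samples(name, dense, values)


def make_regulator_profiles(
        config: SimulationConfig) -> tuple[SmoothedProfile, SmoothedProfile]:
    """Strictly positive unimodal regulator (early) and cofactor (late) curves."""
    times = config.times
    reg = _bump_profile("regulator", times, config.regulator_peak_time,
                        config.regulator_width, config.regulator_amplitude,
                        config.regulator_baseline)
    cof = _bump_profile("cofactor", times, config.cofactor_peak_time,
                        config.cofactor_width, config.cofactor_amplitude,
                        config.cofactor_baseline)
    return reg, cof


def _sigmoid_center(profile: SmoothedProfile, times: np.ndarray) -> tuple[float, float]:
    vals = profile(times, clip_negative=True)
    return float(vals.min()), float(vals.max())


def default_param_sets(config: SimulationConfig,
                       regulators: tuple[SmoothedProfile, SmoothedProfile],
                       ) -> list[tuple[str, KineticParams]]:
    """Random-but-reasonable parameter sets for each requested model kind.

    Constant genes sit at their steady state (flat series).  Regulated
    genes get weights/biases scaled so the sigmoid actually swings over the
    regulator's observed range, producing series a constant model cannot
    absorb.
    """
    rng = np.random.default_rng([config.seed, 11])
    times = config.times
    reg, cof = regulators
    out: list[tuple[str, KineticParams]] = []

    for i in range(config.n_constant):
        k2 = rng.uniform(0.3, 1.0)
        level = rng.uniform(2.0, 10.0)
        out.append((f"const_{i:03d}", KineticParams(
            model_kind="constant", k1=level * k2, k2=k2, x0=level)))

    def regulated(name: str, kind: str, driver_lo: float, driver_hi: float,
                  q: float | None):
        k2 = rng.uniform(0.3, 0.8)
        k1 = rng.uniform(3.0, 10.0) * k2
        w = rng.uniform(1.2, 2.5) * 8.0 / max(driver_hi - driver_lo, 1e-6)
        b = -w * 0.5 * (driver_lo + driver_hi)
        kw = {"q": q} if kind == "cooperative" else {}
        # start at the quasi-steady level for the initial driver value
        if kind == "direct":
            y0 = reg(times[0], clip_negative=True)
        else:
            from .kinetic_models import complex_concentration
            y0 = complex_concentration(reg(times[0], clip_negative=True),
                                       cof(times[0], clip_negative=True), q)
        x0 = k1 / (1.0 + np.exp(-(w * y0 + b))) / k2
        return (name, KineticParams(model_kind=kind, k1=k1, k2=k2, w=w, b=b,
                                    x0=float(x0), **kw))

    reg_lo, reg_hi = _sigmoid_center(reg, times)
    for i in range(config.n_direct):
        out.append(regulated(f"direct_{i:03d}", "direct", reg_lo, reg_hi, None))

    from .kinetic_models import complex_concentration
    q_values = rng.uniform(0.0, 0.5, size=config.n_cooperative)
    comp_vals = complex_concentration(reg(times, clip_negative=True),
                                      cof(times, clip_negative=True), 0.1)
    comp_lo, comp_hi = float(np.min(comp_vals)), float(np.max(comp_vals))
    for i in range(config.n_cooperative):
        out.append(regulated(f"coop_{i:03d}", "cooperative", comp_lo, comp_hi,
                             float(q_values[i])))
    return out


def simulate_targets(config: SimulationConfig,
                     params: list[tuple[str, KineticParams]],
                     regulators: tuple[SmoothedProfile, SmoothedProfile],
                     ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Forward-simulate each gene and apply multiplicative log-normal noise.

    Returns the noisy expression matrix on the config grid and a truth table
    with the generating model and parameters per gene.
    """
    rng = np.random.default_rng([config.seed, 23])
    times = config.times
    reg, cof = regulators
    series = []
    truth_rows = []
    for gene_id, p in params:
        regs = {"constant": (), "direct": (reg,),
                "cooperative": (reg, cof)}[p.model_kind]
        clean = simulate(p, regs, times)
        noisy = clean * np.exp(rng.normal(0.0, config.noise_sd, size=times.size))
        series.append(noisy)
        truth_rows.append({
            "gene_id": gene_id, "model_kind": p.model_kind, "k1": p.k1,
            "k2": p.k2, "w": p.w, "b": p.b, "q": p.q, "x0": p.x0,
        })
    matrix = ExpressionMatrix(gene_ids=[g for g, _ in params], times=times,
                              values=np.array(series))
    return matrix, pd.DataFrame(truth_rows)


@dataclass
class GenomicFixtures:
    genome: dict[str, str]
    genes: list[GeneModel]
    gene_records: pd.DataFrame  # gene_id, chrom, type, start, end, strand, operon_id
    tss: list[TSSRecord]
    peaks: list[Peak]
    operons: pd.DataFrame
    promoter_truth: pd.DataFrame
    peak_truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


_NON_T = "ACG"


def _random_pair(rng: np.random.Generator) -> str:
    # any dinucleotide except GG (the planted negative class) and TA (which
    # could create a spurious TANNNT anchor upstream of the planted motif)
    while True:
        pair = "".join(rng.choice(list("ACGT"), size=2))
        if pair not in ("GG", "TA"):
            return pair


def make_genomic_fixtures(config: SimulationConfig) -> GenomicFixtures:
    """Random genome with planted promoter units and full truth tables.

    Each promoter unit occupies its own genome slot and contributes a gene
    (start codon anchored), a primary TSS upstream of the start codon, an
    optional planted TANNNT motif at TSS offsets -12..-7 with a controlled
    -14/-13 dinucleotide, and (for the dependent class) a ChIP peak whose
    summit distance to the start codon is recorded.  The -20..+1 window
    around each TSS is otherwise T-free so that planted motifs are the only
    anchors, making scan round-trips exact.
    """
    rng = np.random.default_rng([config.seed, 47])
    margin = 120
    member_len = 90
    # member genes sit > max_upstream + summit jitter away from the lead
    # gene's peak, so only operon expansion (never direct assignment) can
    # reach them
    member_gap = 400
    slot = 900 + member_gap * (config.operon_size - 1)
    n_units = config.n_promoters_dependent + config.n_promoters_independent
    needed = 2 * margin + n_units * slot
    if config.genome_length < needed:
        raise ValueError(
            f"genome_length {config.genome_length} too small for {n_units} "
            f"promoter units (need >= {needed})")

    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                        size=config.genome_length, p=probs).copy()

    def plant(pos1: int, seq: str) -> None:
        # pos1 is 1-based leftmost genomic coordinate
        genome[pos1 - 1:pos1 - 1 + len(seq)] = np.frombuffer(
            seq.encode(), dtype=np.uint8)

    def plant_tss_relative(tss: int, strand: str, off_lo: int, off_hi: int,
                           seq: str) -> None:
        """Plant ``seq`` at inclusive TSS-relative offsets on the given strand."""
        if strand == "+":
            plant(tss + off_lo, seq)
        else:
            plant(tss - off_hi, reverse_complement(seq))

    genes: list[GeneModel] = []
    gene_rows = []
    tss_records: list[TSSRecord] = []
    peaks: list[Peak] = []
    operon_rows = []
    promoter_rows = []
    peak_rows = []

    unit_classes = (["dependent"] * config.n_promoters_dependent
                    + ["independent"] * config.n_promoters_independent)
    n_unassignable = int(round(config.frac_unassignable
                               * config.n_promoters_dependent))
    operon_units = list(range(min(config.n_operons,
                                  config.n_promoters_dependent)))
    extra_types = ["sRNA", "tRNA", "rRNA", "misc_RNA"]

    peak_counter = 0
    for unit, klass in enumerate(unit_classes):
        s = margin + unit * slot
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(25, 60))
        if strand == "+":
            start_codon = s + 500
            tss_pos = start_codon - gap
        else:
            start_codon = s + slot - 500
            tss_pos = start_codon + gap
        gene_id = f"{klass[:3]}_{unit:03d}"

        # overwrite the -20..+1 window with T-free sequence, then plant
        window_seq = "".join(rng.choice(list(_NON_T), size=22))
        plant_tss_relative(tss_pos, strand, -20, 1, window_seq)
        gg_rate = (config.gg_rate_dependent if klass == "dependent"
                   else config.gg_rate_independent)
        motif_planted = bool(rng.random() < config.motif_plant_rate)
        pair = ""
        gg_class = ""
        if motif_planted:
            motif = "TA" + "".join(rng.choice(list("ACGT"), size=3)) + "T"
            plant_tss_relative(tss_pos, strand, -12, -7, motif)
            pair = "GG" if rng.random() < gg_rate else _random_pair(rng)
            plant_tss_relative(tss_pos, strand, -14, -13, pair)
            gg_class = {2: "GG", 1: "G", 0: "noG"}[pair.count("G")]

        operon_id = f"op_{unit:03d}" if unit in operon_units and \
            klass == "dependent" else None
        genes.append(GeneModel(gene_id=gene_id, chrom=config.chrom,
                               strand=strand, start_codon_pos=start_codon,
                               feature_type="CDS", operon_id=operon_id))
        if strand == "+":
            g_start, g_end = start_codon, start_codon + member_len - 1
        else:
            g_start, g_end = start_codon - member_len + 1, start_codon
        gene_rows.append({"gene_id": gene_id, "chrom": config.chrom,
                          "type": "CDS", "start": g_start, "end": g_end,
                          "strand": strand, "operon_id": operon_id or ""})
        tss_records.append(TSSRecord(chrom=config.chrom, position=tss_pos,
                                     strand=strand, category="primary",
                                     gene_id=gene_id))

        # operon members downstream of the lead gene
        if operon_id is not None:
            operon_rows.append({"operon_id": operon_id, "gene_id": gene_id,
                                "rank": 1})
            for j in range(1, config.operon_size):
                member_id = f"{gene_id}_m{j}"
                delta = member_gap * j
                m_codon = start_codon + delta if strand == "+" else \
                    start_codon - delta
                ftype = extra_types[(unit + j) % len(extra_types)] \
                    if j == config.operon_size - 1 else "CDS"
                genes.append(GeneModel(gene_id=member_id, chrom=config.chrom,
                                       strand=strand, start_codon_pos=m_codon,
                                       feature_type=ftype, operon_id=operon_id))
                if strand == "+":
                    m_start, m_end = m_codon, m_codon + member_len - 1
                else:
                    m_start, m_end = m_codon - member_len + 1, m_codon
                gene_rows.append({"gene_id": member_id, "chrom": config.chrom,
                                  "type": ftype, "start": m_start,
                                  "end": m_end, "strand": strand,
                                  "operon_id": operon_id})
                operon_rows.append({"operon_id": operon_id,
                                    "gene_id": member_id, "rank": j + 1})

        # ChIP peak for the dependent class
        assignable = None
        distance = None
        if klass == "dependent":
            assignable = unit >= n_unassignable  # first few planted too far
            if assignable:
                distance = int(rng.integers(0, 301))
            else:
                distance = int(rng.integers(301, 390))
            summit = start_codon - distance if strand == "+" else \
                start_codon + distance
            peak_counter += 1
            peaks.append(Peak(
                chrom=config.chrom, start=max(summit - 75, 1),
                end=summit + 75, summit=summit,
                p_value=float(10.0 ** -rng.uniform(2.0, 8.0)),
                fold_enrichment=float(rng.uniform(2.0, 10.0)),
                name=f"peak_{peak_counter:03d}"))
            peak_rows.append({"peak_name": f"peak_{peak_counter:03d}",
                              "gene_id": gene_id, "distance": distance,
                              "assignable": assignable,
                              "passes_filters": True})

        promoter_rows.append({
            "gene_id": gene_id, "tss_pos": tss_pos, "strand": strand,
            "class": klass, "motif_planted": motif_planted,
            "gg_pair": pair, "gg_class": gg_class,
            "operon_id": operon_id or "",
        })

    # peaks that must be removed by the statistical filters; their summits
    # sit in assignable range so filtering genuinely changes the outcome
    dependent_truth = [r for r in peak_rows if r["assignable"]]
    for j in range(config.n_insignificant_peaks):
        if not dependent_truth:
            break
        target = dependent_truth[j % len(dependent_truth)]
        gene = next(g for g in genes if g.gene_id == target["gene_id"])
        d = int(rng.integers(0, 301))
        summit = gene.start_codon_pos - d if gene.strand == "+" else \
            gene.start_codon_pos + d
        peak_counter += 1
        if j % 2 == 0:
            p_val, fe = float(rng.uniform(0.06, 0.5)), float(rng.uniform(2, 8))
        else:
            p_val, fe = float(10.0 ** -rng.uniform(2, 6)), \
                float(rng.uniform(1.0, 1.9))
        peaks.append(Peak(chrom=config.chrom, start=max(summit - 75, 1),
                          end=summit + 75, summit=summit, p_value=p_val,
                          fold_enrichment=fe,
                          name=f"peak_{peak_counter:03d}"))
        peak_rows.append({"peak_name": f"peak_{peak_counter:03d}",
                          "gene_id": gene.gene_id, "distance": d,
                          "assignable": True, "passes_filters": False})

    # secondary TSS records re-using existing promoter units
    for j in range(config.n_secondary_tss):
        base = tss_records[j % len(tss_records)]
        shift = 5 if base.strand == "+" else -5
        tss_records.append(TSSRecord(chrom=base.chrom,
                                     position=base.position + shift,
                                     strand=base.strand, category="secondary",
                                     gene_id=base.gene_id))

    genome_str = genome.tobytes().decode()
    return GenomicFixtures(
        genome={config.chrom: genome_str},
        genes=genes,
        gene_records=pd.DataFrame(gene_rows),
        tss=tss_records,
        peaks=peaks,
        operons=pd.DataFrame(operon_rows,
                             columns=["operon_id", "gene_id", "rank"]),
        promoter_truth=pd.DataFrame(promoter_rows),
        peak_truth=pd.DataFrame(peak_rows,
                                columns=["peak_name", "gene_id", "distance",
                                         "assignable", "passes_filters"]),
        config=config,
    )


def write_fixtures(fixtures: GenomicFixtures, outdir) -> dict[str, Path]:
    """Write all fixture files (plain-text formats) and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "tss": outdir / "tss.tsv",
        "peaks": outdir / "peaks.tsv",
        "operons": outdir / "operons.tsv",
        "promoter_truth": outdir / "promoter_truth.tsv",
        "peak_truth": outdir / "peak_truth.tsv",
    }
    from .promoter_analysis import write_genome_fasta
    write_genome_fasta(fixtures.genome, paths["genome"])
    with open(paths["genes"], "w") as handle:
        handle.write("##gff-version 3\n")
        for row in fixtures.gene_records.itertuples():
            attrs = f"ID={row.gene_id}"
            if row.operon_id:
                attrs += f";operon_id={row.operon_id}"
            handle.write("\t".join([
                row.chrom, "regulonkit", row.type, str(row.start),
                str(row.end), ".", row.strand, ".", attrs]) + "\n")
    write_tss_table(fixtures.tss, paths["tss"])
    write_peaks_xls(fixtures.peaks, paths["peaks"])
    fixtures.operons.to_csv(paths["operons"], sep="\t", index=False)
    fixtures.promoter_truth.to_csv(paths["promoter_truth"], sep="\t",
                                   index=False)
    fixtures.peak_truth.to_csv(paths["peak_truth"], sep="\t", index=False)
    return paths


def write_expression_bundle(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write the expression side of the fixture bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg, cof = make_regulator_profiles(config)
    params = default_param_sets(config, (reg, cof))
    matrix, truth = simulate_targets(config, params, (reg, cof))
    times = config.times
    # prepend regulator/cofactor series so the fit stage can find them
    full = ExpressionMatrix(
        gene_ids=["regulator", "cofactor"] + matrix.gene_ids,
        times=times,
        values=np.vstack([reg(times, clip_negative=True),
                          cof(times, clip_negative=True), matrix.values]),
    )
    paths = {"expression": outdir / "expression.tsv",
             "expression_truth": outdir / "expression_truth.tsv"}
    expression_data.write_expression_matrix(full, paths["expression"])
    truth.to_csv(paths["expression_truth"], sep="\t", index=False)
    return paths
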