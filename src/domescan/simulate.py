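"""Synthetic inputs with the statistical structure the scan assumes.

The generators stand in for the study-scale resequencing and RNA-seq data so
that every downstream stage is testable without downloads.  They are
first-class, documented models, not fixtures:

* Two-population diploid SNP matrices follow the Balding–Nichols law —
  each deme's allele frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around an
  ancestral frequency p, so the differentiation parameter F is also the
  expected Fst, which makes estimator calibration testable.  A planted
  "sweep" interval uses an elevated F in the domesticated deme plus a
  fixation bias toward the reference allele, emulating reduced diversity and
  strong differentiation at an artificially selected locus.
* Gene models are non-overlapping single-CDS genes on random strands with
  SNPs planted at known codon positions, so effect-annotation recovery can
  be checked against truth.
* Expression tables are FPKM-scale (2^Normal) with a configurable fraction
  of differentially expressed genes of known direction.
* Term annotations plant one term enriched in the true DE genes.
* Protein sets have exact planted methionine counts.

All generators are deterministic given their config seed; identical config
produces byte-identical files.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .popgen import GeneModel, VariantTable, classify_codon_change
from ._util import round_half_up

_BASES = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimTruth:
    """Ground truth of the planted features, for parameter-recovery tests."""

    sweep: tuple | None = None               # (contig, start, end) 0-based half-open
    de_genes: dict = field(default_factory=dict)      # gene -> 'up'|'down'
    enriched_term: str | None = None
    snp_effects: dict = field(default_factory=dict)   # position -> (gene, class, aa_change)
    protein_met: dict = field(default_factory=dict)   # id -> planted Met fraction
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# two-population SNP matrix

@dataclass
class SweepSimConfig:
    """Balding–Nichols two-population simulation with one planted sweep.

    Defaults mirror the study design: 19 domesticated + 18 wild diploids, a
    multi-megabase contig with a background differentiation of F=0.1 and a
    200 kb swept interval where the domesticated deme is strongly
    differentiated (sweep_F) and pushed toward fixation of the reference
    allele with probability ``sweep_fix_bias``.
    """

    seed: int = 0
    n_dom: int = 19
    n_wild: int = 18
    contig_length: int = 5_000_000
    n_snps: int = 5_000
    background_F: float = 0.1
    ancestral_freq_range: tuple = (0.05, 0.95)
    sweep_start: int = 2_400_000
    sweep_end: int = 2_600_000
    sweep_F: float = 0.8
    sweep_fix_bias: float = 0.9
    contig: str = "chr1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_F < self.sweep_F < 1.0):
            raise ValueError("require 0 <= background_F < sweep_F < 1")
        if not (0 <= self.sweep_start < self.sweep_end <= self.contig_length):
            raise ValueError("sweep interval outside contig")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not (0.0 <= self.sweep_fix_bias <= 1.0):
            raise ValueError("sweep_fix_bias must be a probability")


def _balding_nichols(rng, p: np.ndarray, F: float) -> np.ndarray:
    """Deme allele frequencies around ancestral ``p`` at differentiation F."""
    if F < 1e-12:
        return p.copy()
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_two_pop_variants(cfg: SweepSimConfig) -> tuple:
    """Simulate the two-population SNP matrix; returns (VariantTable, SimTruth).

    Positions are uniform over the contig; each deme's frequency follows the
    Balding–Nichols law, except that in the sweep interval the domesticated
    deme uses ``sweep_F`` and, with probability ``sweep_fix_bias``, is
    instead driven to near-fixation of the reference allele (alt frequency
    Beta(1, 50)).  Diploid genotypes are Binomial(2, freq).
    """
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(
        rng.choice(cfg.contig_length, size=cfg.n_snps, replace=False)
    ) + 1  # 1-based
    ref_idx = rng.integers(0, 4, cfg.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, cfg.n_snps)) % 4
    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, cfg.n_snps)  # ancestral alt-allele frequency

    freq_dom = _balding_nichols(rng, p, cfg.background_F)
    freq_wild = _balding_nichols(rng, p, cfg.background_F)

    in_sweep = (positions - 1 >= cfg.sweep_start) & (positions - 1 < cfg.sweep_end)
    truth = SimTruth(sweep=(cfg.contig, cfg.sweep_start, cfg.sweep_end))
    if in_sweep.any():
        k = int(in_sweep.sum())
        swept = _balding_nichols(rng, p[in_sweep], cfg.sweep_F)
        fixed = rng.random(k) < cfg.sweep_fix_bias
        near_zero = rng.beta(1.0, 50.0, k)  # alt freq ~0: reference nearly fixed
        freq_dom[in_sweep] = np.where(fixed, near_zero, swept)
    else:
        truth.warnings.append("sweep region contains zero SNPs")

    g_dom = rng.binomial(2, freq_dom[:, None], (cfg.n_snps, cfg.n_dom))
    g_wild = rng.binomial(2, freq_wild[:, None], (cfg.n_snps, cfg.n_wild))
    samples = [f"DOM_{i:02d}" for i in range(1, cfg.n_dom + 1)] + [
        f"WILD_{i:02d}" for i in range(1, cfg.n_wild + 1)
    ]
    table = VariantTable(
        contigs=np.array([cfg.contig] * cfg.n_snps, dtype=object),
        positions=positions,
        ref=_BASES[ref_idx].astype(object),
        alt=_BASES[alt_idx].astype(object),
        samples=samples,
        genotypes=np.hstack([g_dom, g_wild]).astype(np.int8),
        contig_lengths={cfg.contig: cfg.contig_length},
    )
    return table, truth


def population_spec(cfg: SweepSimConfig) -> dict:
    """Sample -> group map matching :func:`simulate_two_pop_variants`."""
    spec = {f"DOM_{i:02d}": "domestic" for i in range(1, cfg.n_dom + 1)}
    spec.update({f"WILD_{i:02d}": "wild" for i in range(1, cfg.n_wild + 1)})
    return spec


def write_groups(popspec: dict, path) -> None:
    with open(path, "w") as fh:
        for sample, group in popspec.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# gene models with planted coding SNPs

@dataclass
class GeneSimConfig:
    seed: int = 0
    n_genes: int = 5
    n_codons: int = 100          # CDS length per gene, in codons
    spacing: int = 500           # intergenic gap, bp
    n_coding_snps: int = 10
    n_noncoding_snps: int = 5
    contig: str = "chr1"
    planted: list = field(default_factory=list)
    # optional explicit plants: (gene_index, codon_index, offset, ref_codon, alt_base)


def simulate_gene_models_and_effects(cfg: GeneSimConfig, contig_length: int
                                     ) -> tuple:
    """Random reference + non-overlapping genes + SNPs of known effect class.

    Returns ``(reference, genes, variants, truth)`` where ``reference`` is a
    {contig: sequence} dict and ``truth.snp_effects`` maps each planted SNP
    position (1-based) to (gene_id or None, class, aa_change).
    """
    rng = np.random.default_rng(cfg.seed)
    cds_len = 3 * cfg.n_codons
    span = cfg.spacing + cds_len
    if cfg.spacing + cfg.n_genes * span > contig_length:
        raise ValueError("requested genes exceed contig capacity")
    seq = rng.choice(4, contig_length)

    genes = []
    for gi in range(cfg.n_genes):
        start = cfg.spacing + gi * span
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"gene_{gi:03d}", cfg.contig, strand,
                      [(start, start + cds_len)])
        )

    # force explicitly planted codons into the reference first
    explicit = []
    for gene_i, codon_i, off, ref_codon, alt_base in cfg.planted:
        g = genes[gene_i]
        mrna = g.cds_positions()
        for k, base in enumerate(ref_codon):
            b = base if g.strand == "+" else base.translate(
                str.maketrans("ACGT", "TGCA"))
            seq[mrna[3 * codon_i + k]] = "ACGT".index(b)
        explicit.append((gene_i, codon_i, off, alt_base))

    truth = SimTruth()
    positions, refs, alts = [], [], []

    def plant_coding(gene_i, codon_i, off, alt_base=None):
        g = genes[gene_i]
        mrna = g.cds_positions()
        codon_gpos = mrna[3 * codon_i: 3 * codon_i + 3]
        comp = str.maketrans("ACGT", "TGCA")
        bases = ["ACGT"[seq[p]] for p in codon_gpos]
        if g.strand == "-":
            bases = [b.translate(comp) for b in bases]
        ref_codon = "".join(bases)
        if alt_base is None:
            choices = [b for b in "ACGT" if b != ref_codon[off]]
            alt_base = choices[rng.integers(0, 3)]
        klass, change = classify_codon_change(ref_codon, off, alt_base)
        gpos = int(codon_gpos[off])              # 0-based genomic
        ref_base = "ACGT"[seq[gpos]]
        alt_genomic = alt_base if g.strand == "+" else alt_base.translate(comp)
        positions.append(gpos + 1)
        refs.append(ref_base)
        alts.append(alt_genomic)
        truth.snp_effects[gpos + 1] = (g.gene_id, klass, change)

    for gene_i, codon_i, off, alt_base in explicit:
        plant_coding(gene_i, codon_i, off, alt_base)

    n_random = max(cfg.n_coding_snps - len(explicit), 0)
    seen = set(positions)
    while n_random > 0:
        gi = int(rng.integers(0, cfg.n_genes))
        ci = int(rng.integers(0, cfg.n_codons))
        off = int(rng.integers(0, 3))
        gpos = int(genes[gi].cds_positions()[3 * ci + off])
        if gpos + 1 in seen:
            continue
        seen.add(gpos + 1)
        plant_coding(gi, ci, off)
        n_random -= 1

    # intergenic SNPs
    intergenic = np.ones(contig_length, dtype=bool)
    for g in genes:
        intergenic[g.start:g.end] = False
    candidates = np.flatnonzero(intergenic)
    for gpos in rng.choice(candidates, cfg.n_noncoding_snps, replace=False):
        gpos = int(gpos)
        if gpos + 1 in seen:
            continue
        seen.add(gpos + 1)
        ref_base = "ACGT"[seq[gpos]]
        alt_base = [b for b in "ACGT" if b != ref_base][int(rng.integers(0, 3))]
        positions.append(gpos + 1)
        refs.append(ref_base)
        alts.append(alt_base)
        truth.snp_effects[gpos + 1] = (None, "non-coding", None)

    order = np.argsort(positions)
    geno = np.tile(np.array([1, 1], dtype=np.int8), (len(positions), 1))
    table = VariantTable(
        contigs=np.array([cfg.contig] * len(positions), dtype=object),
        positions=np.array(positions)[order],
        ref=np.array(refs, dtype=object)[order],
        alt=np.array(alts, dtype=object)[order],
        samples=["S1", "S2"],
        genotypes=geno,
        contig_lengths={cfg.contig: contig_length},
    )
    reference = {cfg.contig: "".join("ACGT"[b] for b in seq)}
    return reference, genes, table, truth


# ---------------------------------------------------------------------------
# expression tables

@dataclass
class ExprSimConfig:
    """FPKM-scale two-group expression simulation.

    Three replicates per group by default, matching the study's ova RNA-seq
    design.  A ``de_fraction`` of genes is shifted by ``effect_l2fc`` in
    group B, down-regulated with probability ``down_fraction`` (default 0.6,
    the study's observed down-share among knockout DEGs).
    """

    seed: int = 0
    n_genes: int = 2_000
    n_reps: int = 3
    baseline_mean: float = 5.0   # log2 FPKM
    baseline_sd: float = 2.0
    rep_sd: float = 0.3
    de_fraction: float = 0.1
    effect_l2fc: float = 2.0
    down_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0,1]")
        if not (0.0 <= self.down_fraction <= 1.0):
            raise ValueError("down_fraction must be in [0,1]")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.de_fraction > 0 and abs(self.effect_l2fc) < 1.0:
            raise ValueError("DE effect size must be >= 1 log2 unit")


def simulate_expression_table(cfg: ExprSimConfig) -> tuple:
    """Returns ``(fpkm, stats, truth)``.

    ``fpkm`` is a gene x sample DataFrame (samples A_1..A_n then B_1..B_n);
    ``stats`` carries the per-gene log2FC and BH-corrected p the DEG caller
    consumes, from the built-in two-group t-test on log2(FPKM+1).
    """
    from .expression import two_group_log2_ttest

    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, n_de, replace=False)
    down = rng.random(n_de) < cfg.down_fraction
    shift = np.zeros(cfg.n_genes)
    shift[de_idx] = np.where(down, -cfg.effect_l2fc, cfg.effect_l2fc)

    a = base[:, None] + rng.normal(0, cfg.rep_sd, (cfg.n_genes, cfg.n_reps))
    b = (base + shift)[:, None] + rng.normal(0, cfg.rep_sd,
                                             (cfg.n_genes, cfg.n_reps))
    cols_a = [f"A_{j + 1}" for j in range(cfg.n_reps)]
    cols_b = [f"B_{j + 1}" for j in range(cfg.n_reps)]
    fpkm = pd.DataFrame(
        np.power(2.0, np.hstack([a, b])), index=genes, columns=cols_a + cols_b
    )
    fpkm.index.name = "gene"
    truth = SimTruth(
        de_genes={genes[i]: ("down" if d else "up")
                  for i, d in zip(de_idx, down)}
    )
    stats = two_group_log2_ttest(fpkm, cols_a, cols_b)
    return fpkm, stats, truth


def simulate_term_annotation(genes, truth: SimTruth, *, n_terms: int = 20,
                             term_size: int = 50, enriched_de_share: float = 0.5,
                             seed: int = 0) -> pd.DataFrame:
    """Flat term -> gene map with one term enriched in the true DE genes.

    The planted term draws ``enriched_de_share`` of its members from
    ``truth.de_genes`` (planted fold well above 3 at the default DE
    fraction); the other terms sample genes uniformly.  Returns a two-column
    DataFrame (term, gene) and records the planted term in the truth.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    de = [g for g in genes if g in truth.de_genes]
    non_de = [g for g in genes if g not in truth.de_genes]
    rows = []
    n_from_de = min(int(round(enriched_de_share * term_size)), len(de))
    planted = "TERM0000"
    members = list(rng.choice(de, n_from_de, replace=False)) + list(
        rng.choice(non_de, term_size - n_from_de, replace=False)
    )
    rows += [(planted, g) for g in members]
    for t in range(1, n_terms):
        for g in rng.choice(genes, term_size, replace=False):
            rows.append((f"TERM{t:04d}", g))
    truth.enriched_term = planted
    return pd.DataFrame(rows, columns=["term", "gene"])


# ---------------------------------------------------------------------------
# protein sets

def simulate_protein_set(met_fractions, lengths=747, seed: int = 0) -> tuple:
    """Protein sequences with exact planted methionine counts.

    ``met_fractions`` maps id -> target Met fraction (or is a sequence of
    fractions, ids auto-named).  Each sequence of length L carries exactly
    ``round(fraction * L)`` methionines (half-up rounding); remaining
    residues are drawn uniformly from the other 19 standard letters and the
    whole sequence is shuffled.  Returns ``(records, truth)`` where records
    are (id, sequence) pairs.
    """
    if not isinstance(met_fractions, dict):
        met_fractions = {
            f"prot_{i:03d}": f for i, f in enumerate(met_fractions)
        }
    if isinstance(lengths, int):
        lengths = {pid: lengths for pid in met_fractions}
    rng = np.random.default_rng(seed)
    others = np.array(list(_AA20.replace("M", "")))
    records, truth = [], SimTruth()
    for pid, frac in met_fractions.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{pid}: Met fraction must be in [0,1]")
        length = lengths[pid]
        n_met = int(round_half_up(frac * length, 0))
        letters = np.concatenate(
            [np.repeat("M", n_met), rng.choice(others, length - n_met)]
        )
        rng.shuffle(letters)
        records.append((pid, "".join(letters)))
        truth.protein_met[pid] = frac
    return records, truth


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
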