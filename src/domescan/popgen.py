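"""Windowed pi/Fst selection-signature scan over a two-population SNP table.

The scan follows the standard resequencing-study recipe for detecting
artificial-selection (domestication) signatures: slide windows along each
chromosome, compute within-group nucleotide diversity (pi) and between-group
differentiation (Fst), rank windows empirically, and call signature regions
where extreme Fst (top quantile) coincides with depressed diversity in the
focal (domesticated) group.  SNP functional annotation against gene models
classifies variants as synonymous / non-synonymous / non-coding.

Coordinates are 0-based half-open internally; VCF positions are 1-based and
region outputs are written 1-based inclusive.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as _stats

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# containers

@dataclass
class VariantTable:
    """Biallelic SNPs with diploid genotype dosages for named samples.

    ``genotypes`` holds the alternate-allele dosage per SNP x sample
    (0 hom-ref, 1 het, 2 hom-alt, -1 missing).
    """

    contigs: np.ndarray          # str, per SNP
    positions: np.ndarray        # int, 1-based VCF positions
    ref: np.ndarray              # str, per SNP
    alt: np.ndarray              # str, per SNP
    samples: list
    genotypes: np.ndarray        # (n_snps, n_samples) int8
    contig_lengths: dict = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for contig in np.unique(self.contigs):
            pos = self.positions[self.contigs == contig]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {contig}")
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("genotype matrix shape inconsistent with samples/positions")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in lookup]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return np.array([lookup[s] for s in names], dtype=int)

    def snp_mask(self, contig: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of SNPs on ``contig`` in [start, end) (0-based)."""
        return (
            (self.contigs == contig)
            & (self.positions - 1 >= start)
            & (self.positions - 1 < end)
        )


@dataclass(frozen=True)
class Window:
    contig: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SignatureRegion:
    """Run of doubly-flagged windows: a candidate selective sweep."""

    contig: str
    start: int            # 1-based inclusive
    end: int              # 1-based inclusive
    windows: list
    min_focal_pi: float
    max_fst: float


@dataclass
class SnpEffect:
    contig: str
    position: int         # 1-based
    gene_id: str | None
    effect_class: str     # synonymous | non-synonymous | non-coding
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if (self.effect_class == "non-synonymous") != (self.aa_change is not None):
            raise ValueError("aa_change present iff non-synonymous")


@dataclass
class GeneModel:
    """Protein-coding gene with one or more CDS segments (0-based half-open)."""

    gene_id: str
    contig: str
    strand: str               # '+' | '-'
    cds: list                 # [(start, end), ...] genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_positions(self) -> np.ndarray:
        """Genomic positions (0-based) in mRNA (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds])
        return pos[::-1] if self.strand == "-" else pos


# ---------------------------------------------------------------------------
# I/O

def read_vcf(path, region: str | None = None) -> VariantTable:
    """Load biallelic SNPs from a VCF 4.x file with GT genotypes.

    Multiallelic records and indels are skipped (count kept in
    ``n_skipped``); missing genotypes become dosage -1.  ``region`` is an
    optional ``"contig:start-end"`` string (1-based inclusive).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    try:
        contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header without contig lengths
        contig_lengths = {}

    want = None
    if region is not None:
        contig, _, span = region.partition(":")
        if span:
            lo, _, hi = span.partition("-")
            want = (contig, int(lo), int(hi))
        else:
            want = (contig, 1, np.inf)

    contigs, positions, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        if want is not None:
            c, lo, hi = want
            if v.CHROM != c or not (lo <= v.POS <= hi):
                continue
        contigs.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        # with gts012=True: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = -1
        rows.append(g)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    geno = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return VariantTable(
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        samples=samples,
        genotypes=geno,
        contig_lengths=contig_lengths,
        n_skipped=n_skipped,
    )


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(table: VariantTable, path) -> None:
    """Write a GT-only VCF 4.2 file (byte-deterministic: no timestamps)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=domescan\n")
        for contig, length in sorted(table.contig_lengths.items()):
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_snps):
            gts = "\t".join(_GT_STR[int(g)] for g in table.genotypes[i])
            fh.write(
                f"{table.contigs[i]}\t{table.positions[i]}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_groups(path) -> dict:
    """Two-column sample->group TSV; returns {sample: group}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     comment="#", dtype=str)
    spec = dict(zip(df["sample"], df["group"]))
    if len(set(spec.values())) < 2:
        raise ValueError("need at least two population groups")
    return spec


def group_samples(popspec: dict, label: str) -> list:
    out = [s for s, g in popspec.items() if g == label]
    if not out:
        raise ValueError(f"population group {label!r} is empty")
    return out


def write_gff(genes, path, contig_lengths=None) -> None:
    """Minimal GFF3 writer for single-mRNA gene models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in sorted((contig_lengths or {}).items()):
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tdomescan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            # frame of each CDS segment relative to mRNA order
            offsets, acc = [], 0
            segs = g.cds if g.strand == "+" else list(reversed(g.cds))
            for s, e in segs:
                offsets.append((s, e, acc % 3))
                acc += e - s
            for s, e, frame in sorted(offsets):
                fh.write(
                    f"{g.contig}\tdomescan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{frame}\tID=cds-{g.gene_id};Parent={g.gene_id}\n"
                )


def read_gff(path) -> list:
    """Read gene models written by :func:`write_gff` (gene + CDS lines)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = f[:9]
            tags = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                genes[tags["ID"]] = {
                    "contig": contig, "strand": strand, "cds": [],
                }
            elif ftype == "CDS":
                parent = tags.get("Parent") or tags.get("ID")
                genes.setdefault(
                    parent, {"contig": contig, "strand": strand, "cds": []}
                )["cds"].append((int(start) - 1, int(end)))
    return [
        GeneModel(gene_id=gid, contig=v["contig"], strand=v["strand"], cds=v["cds"])
        for gid, v in genes.items()
        if v["cds"]
    ]


def read_reference(path) -> dict:
    """FASTA -> {contig: sequence} (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# windows and per-window statistics

def make_windows(contig_length: int, size: int, step: int,
                 contig: str = "chr1") -> list:
    """Full sliding windows: starts 0, step, 2*step, ... while start+size fits."""
    if not (0 < step <= size):
        raise ValueError("require 0 < step <= size")
    if size > contig_length:
        warnings.warn("window size exceeds contig length; no windows produced")
        return []
    starts = range(0, contig_length - size + 1, step)
    return [Window(contig, s, s + size) for s in starts]


def _site_counts(geno: np.ndarray):
    """Per-site called allele copies, alt-allele counts, het counts."""
    called = geno >= 0
    n = 2 * called.sum(axis=1)
    alt = np.where(called, geno, 0).sum(axis=1)
    het = (geno == 1).sum(axis=1)
    return n.astype(float), alt.astype(float), het.astype(float)


def site_pi(n: np.ndarray, alt: np.ndarray, min_called: int = 4) -> np.ndarray:
    """Unbiased per-site heterozygosity (n/(n-1) * 2*p*q form).

    Equals the mean pairwise difference among the n called allele copies.
    Sites with fewer than ``min_called`` copies contribute NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * alt * (n - alt) / (n * (n - 1.0))
    pi[(n < min_called) | (n < 2)] = np.nan
    return pi


def window_pi(table: VariantTable, group, window: Window,
              min_called: int = 4) -> tuple:
    """Nucleotide diversity per bp in ``window`` for the given sample group.

    Returns ``(pi, n_sites_used)``; the denominator is the window length in
    bp.  An empty window gives (0.0, 0).
    """
    idx = table.sample_indices(group)
    mask = table.snp_mask(window.contig, window.start, window.end)
    if not mask.any():
        return 0.0, 0
    n, alt, _ = _site_counts(table.genotypes[mask][:, idx])
    pi = site_pi(n, alt, min_called)
    usable = ~np.isnan(pi)
    if not usable.any():
        return 0.0, 0
    return float(np.nansum(pi)) / window.length, int(usable.sum())


def hudson_fst_components(n1, alt1, n2, alt2):
    """Hudson estimator per-site numerator/denominator (Bhatia et al. 2013).

    ``n`` are called allele copies, ``alt`` alternate-allele counts.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = alt1 / n1, alt2 / n2
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def wc_fst_components(n1, alt1, het1, n2, alt2, het2):
    """Weir & Cockerham (1984) variance components a, a+b+c for two demes.

    ``n`` are called allele copies (2x individuals), ``het`` heterozygote
    individual counts.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ni1, ni2 = n1 / 2.0, n2 / 2.0          # individuals
        r = 2.0
        nbar = (ni1 + ni2) / r
        nc = (r * nbar - (ni1**2 + ni2**2) / (r * nbar)) / (r - 1.0)
        p1, p2 = alt1 / n1, alt2 / n2
        h1, h2 = het1 / ni1, het2 / ni2
        pbar = (ni1 * p1 + ni2 * p2) / (r * nbar)
        s2 = (ni1 * (p1 - pbar) ** 2 + ni2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (ni1 * h1 + ni2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, a + b + c


def window_fst(table: VariantTable, group_a, group_b, window: Window,
               estimator: str = "wc", min_called: int = 4,
               min_snps: int = 10) -> tuple:
    """Ratio-of-sums Fst over the sites of a window.

    Returns ``(fst, n_sites_used)``; ``fst`` is NaN when fewer than
    ``min_snps`` usable sites, or the summed denominator is zero.  Negative
    estimates are retained (not clamped).
    """
    ia, ib = table.sample_indices(group_a), table.sample_indices(group_b)
    mask = table.snp_mask(window.contig, window.start, window.end)
    if not mask.any():
        return float("nan"), 0
    ga, gb = table.genotypes[mask][:, ia], table.genotypes[mask][:, ib]
    na, aa, ha = _site_counts(ga)
    nb, ab, hb = _site_counts(gb)
    usable = (na >= max(min_called, 2)) & (nb >= max(min_called, 2))
    if estimator == "hudson":
        num, den = hudson_fst_components(na, aa, nb, ab)
    elif estimator == "wc":
        num, den = wc_fst_components(na, aa, ha, nb, ab, hb)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    num, den = num[usable], den[usable]
    n_used = int(usable.sum())
    if n_used < min_snps:
        return float("nan"), n_used
    dsum = float(np.nansum(den))
    if dsum == 0.0:
        return float("nan"), n_used
    nsum = float(np.nansum(num))
    # fixed differences make numerator and denominator analytically equal;
    # snap rounding noise so they give exactly 1
    if abs(nsum - dsum) <= 1e-12 * abs(dsum):
        return 1.0, n_used
    return nsum / dsum, n_used


# ---------------------------------------------------------------------------
# genome-wide scan, outlier flagging, region calling

def scan_windows(table: VariantTable, popspec: dict, *,
                 focal_group: str = "domestic", other_group: str = "wild",
                 window_size: int = 50_000, window_step: int = 25_000,
                 estimator: str = "wc", min_called: int = 4,
                 min_snps: int = 10, contig_lengths: dict | None = None
                 ) -> pd.DataFrame:
    """Per-window pi (both groups) and Fst across every contig.

    Contig lengths come from the VCF header unless supplied; a contig absent
    from both falls back to its maximum SNP position.
    """
    dom = group_samples(popspec, focal_group)
    wild = group_samples(popspec, other_group)
    table.sample_indices(dom + wild)  # validate sample names early
    lengths = dict(table.contig_lengths)
    lengths.update(contig_lengths or {})
    rows = []
    for contig in pd.unique(table.contigs):
        clen = int(lengths.get(contig) or table.positions[table.contigs == contig].max())
        for w in make_windows(clen, window_size, window_step, contig=contig):
            pi_d, _ = window_pi(table, dom, w, min_called)
            pi_w, _ = window_pi(table, wild, w, min_called)
            fst, n_used = window_fst(
                table, dom, wild, w, estimator, min_called, min_snps
            )
            rows.append(
                dict(contig=contig, start=w.start, end=w.end, n_snps=n_used,
                     pi_dom=pi_d, pi_wild=pi_w, fst=fst)
            )
    return pd.DataFrame(rows)


def flag_outlier_windows(stats: pd.DataFrame, fst_top_q: float = 0.01,
                         pi_low_q: float = 0.05, plot_q: float = 0.05,
                         focal_pi: str = "pi_dom") -> tuple:
    """Z-scores and empirical-quantile outlier flags on the window table.

    Adds columns ``z``, ``p_z`` (one-sided upper normal), ``flag_fst``
    (Fst strictly above the 1-fst_top_q quantile) and ``flag_pi`` (focal
    group pi strictly below the pi_low_q quantile).  Quantiles use the
    linear-interpolation empirical definition; ties are never flagged.
    Returns ``(table, cutoffs)`` where cutoffs records the calling and
    plotting thresholds.
    """
    stats = stats.copy()
    defined = stats["fst"].notna()
    if defined.sum() < 20:
        raise ValueError("need at least 20 windows with defined Fst")
    fst = stats.loc[defined, "fst"].to_numpy()
    mean, sd = float(fst.mean()), float(fst.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):   # all-equal up to rounding noise
        sd = 0.0
    if sd > 0:
        stats["z"] = (stats["fst"] - mean) / sd
        stats["p_z"] = _stats.norm.sf(stats["z"])
    else:
        stats["z"] = np.nan
        stats["p_z"] = np.nan
    fst_cut = float(np.quantile(fst, 1.0 - fst_top_q))
    plot_cut = float(np.quantile(fst, 1.0 - plot_q))
    pi_vals = stats.loc[defined, focal_pi].to_numpy()
    pi_cut = float(np.quantile(pi_vals, pi_low_q))
    stats["flag_fst"] = defined & (stats["fst"] > fst_cut)
    stats["flag_pi"] = defined & (stats[focal_pi] < pi_cut)
    cutoffs = {
        "fst_mean": mean, "fst_sd": sd,
        "fst_top_cutoff": fst_cut, "fst_plot_cutoff": plot_cut,
        "pi_low_cutoff": pi_cut,
    }
    return stats, cutoffs


def call_signature_regions(stats: pd.DataFrame, step: int,
                           focal_pi: str = "pi_dom") -> list:
    """Merge doubly-flagged windows into candidate sweep regions.

    Windows carrying both flags are merged while consecutive starts differ
    by at most ``step`` (same contig only).  Region coordinates are reported
    1-based inclusive.
    """
    hits = stats[stats["flag_fst"] & stats["flag_pi"]]
    regions = []
    for contig, sub in hits.groupby("contig", sort=False):
        sub = sub.sort_values("start")
        run = []
        for row in sub.itertuples():
            if run and row.start - run[-1].start > step:
                regions.append(_close_region(contig, run, focal_pi))
                run = []
            run.append(row)
        if run:
            regions.append(_close_region(contig, run, focal_pi))
    return regions


def _close_region(contig, run, focal_pi) -> SignatureRegion:
    return SignatureRegion(
        contig=contig,
        start=int(run[0].start) + 1,
        end=int(max(r.end for r in run)),
        windows=[Window(contig, int(r.start), int(r.end)) for r in run],
        min_focal_pi=float(min(getattr(r, focal_pi) for r in run)),
        max_fst=float(max(r.fst for r in run)),
    )


# ---------------------------------------------------------------------------
# allele-frequency profile

def ref_allele_frequency_profile(table: VariantTable, group,
                                 contig: str, start: int, end: int
                                 ) -> pd.DataFrame:
    """Reference-allele and ref-homozygote frequencies per SNP in a region.

    ``start``/``end`` are 0-based half-open.  The wording "frequency of the
    reference genotype" is ambiguous between allele frequency and homozygote
    frequency, so both columns are emitted; missing genotypes are excluded
    from the denominators, and a SNP with no called genotype in the group
    yields NaN frequencies.
    """
    idx = table.sample_indices(group)
    mask = table.snp_mask(contig, start, end)
    geno = table.genotypes[mask][:, idx]
    called = (geno >= 0).sum(axis=1).astype(float)
    hom_ref = (geno == 0).sum(axis=1).astype(float)
    het = (geno == 1).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ref_af = (2 * hom_ref + het) / (2 * called)
        ref_hom = hom_ref / called
    return pd.DataFrame(
        dict(
            contig=table.contigs[mask],
            position=table.positions[mask],
            ref=table.ref[mask],
            alt=table.alt[mask],
            ref_allele_freq=ref_af,
            ref_hom_freq=ref_hom,
            n_called=called.astype(int),
        )
    )


# ---------------------------------------------------------------------------
# SNP effect annotation

def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_codon_change(ref_codon: str, offset: int, alt_base: str) -> tuple:
    """Effect of substituting ``alt_base`` at ``offset`` (0-2) of a codon.

    Returns ``(effect_class, aa_change)`` with amino acids in one-letter
    code and stop written ``*``.
    """
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
    aa_ref, aa_alt = _translate(ref_codon), _translate(alt_codon)
    if aa_ref == aa_alt:
        return "synonymous", None
    return "non-synonymous", f"{aa_ref}->{aa_alt}"


def annotate_snp_effects(table: VariantTable, genes, reference: dict
                         ) -> tuple:
    """Classify every SNP as synonymous / non-synonymous / non-coding.

    Codons are reconstructed strand-aware from the reference sequence with
    the alternate allele substituted; the standard genetic code is used.  A
    SNP inside CDS of several genes is annotated once per gene.  Genes whose
    total CDS length is not a multiple of 3 are skipped with a warning.
    Returns ``(effects, per_gene_nonsyn_counts)``.
    """
    # genomic position -> [(gene, mRNA index)] for all usable genes
    cds_index: dict[tuple, list] = {}
    usable_genes = []
    for g in genes:
        if g.cds_length % 3 != 0:
            warnings.warn(f"gene {g.gene_id}: CDS length not divisible by 3; skipped")
            continue
        usable_genes.append(g)
        for j, gpos in enumerate(g.cds_positions()):
            cds_index.setdefault((g.contig, int(gpos)), []).append((g, j))

    effects = []
    nonsyn_counts = {g.gene_id: 0 for g in usable_genes}
    for i in range(table.n_snps):
        contig = table.contigs[i]
        gpos = int(table.positions[i]) - 1
        hits = cds_index.get((contig, gpos))
        if not hits:
            effects.append(
                SnpEffect(contig, int(table.positions[i]), None, "non-coding")
            )
            continue
        for gene, j in hits:
            seq = reference[contig]
            mrna_pos = gene.cds_positions()
            ci, off = divmod(j, 3)
            codon_gpos = mrna_pos[3 * ci: 3 * ci + 3]
            bases = [seq[p] for p in codon_gpos]
            alt = str(table.alt[i])
            if gene.strand == "-":
                bases = [b.translate(_COMPLEMENT) for b in bases]
                alt = alt.translate(_COMPLEMENT)
            ref_codon = "".join(bases)
            klass, change = classify_codon_change(ref_codon, off, alt)
            if klass == "non-synonymous":
                nonsyn_counts[gene.gene_id] += 1
            effects.append(
                SnpEffect(contig, int(table.positions[i]), gene.gene_id,
                          klass, change)
            )
    return effects, nonsyn_counts
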