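"""Downstream transcriptome statistics.

Read-level QC filtering, the expressed-gene background, DEG thresholding,
the down/up direction-asymmetry chi-squared test (with Yates continuity
correction), DEG-set intersection, hypergeometric over-representation with
Benjamini–Hochberg FDR, qPCR relative quantification (2^-ddCt), and the
split-group t-test / FDR procedure used for unbalanced phenotype
comparisons.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# FASTQ quality filtering

@dataclass
class FastqFilterStats:
    n_input: int = 0
    n_kept: int = 0
    discarded: dict = field(default_factory=lambda: {
        "n_content": 0, "adapter": 0, "low_quality": 0,
    })


def adapter_matches(seq: str, adapter: str, min_overlap: int = 10,
                    max_mismatch_rate: float = 0.10) -> bool:
    """Best ungapped alignment of adapter against the read at any offset.

    True when some overlap longer than ``min_overlap`` nt aligns with a
    mismatch rate of at most ``max_mismatch_rate`` (overhangs allowed at
    either end, so partial adapters at the 3' end count).
    """
    ls, la = len(seq), len(adapter)
    for shift in range(-la + 1, ls):
        lo, hi = max(0, shift), min(ls, shift + la)
        overlap = hi - lo
        if overlap <= min_overlap:
            continue
        mism = sum(
            seq[i] != adapter[i - shift] for i in range(lo, hi)
        )
        if mism <= max_mismatch_rate * overlap:
            return True
    return False


def read_passes_qc(seq: str, quals, adapter: str | None, *,
                   max_n_fraction: float = 0.10, adapter_min_overlap: int = 10,
                   adapter_max_mismatch_rate: float = 0.10,
                   low_q: int = 5, max_low_q_fraction: float = 0.50):
    """Apply the three discard rules; returns (kept, failed_rule or None).

    Rules (first matching rule attributed): (1) N fraction >= 10 %;
    (2) > 10 nt align to the adapter with <= 10 % mismatches; (3) > 50 % of
    bases below phred quality 5.
    """
    if len(seq) != len(quals):
        raise ValueError("sequence and quality length mismatch")
    n = len(seq)
    if n and seq.upper().count("N") / n >= max_n_fraction:
        return False, "n_content"
    if adapter and adapter_matches(seq.upper(), adapter.upper(),
                                   adapter_min_overlap,
                                   adapter_max_mismatch_rate):
        return False, "adapter"
    if n and sum(q < low_q for q in quals) / n > max_low_q_fraction:
        return False, "low_quality"
    return True, None


def fastq_quality_filter(path, adapter: str | None = None, **kwargs):
    """Filter a Phred+33 FASTQ file; returns (kept records, FastqFilterStats).

    Kept records are Biopython ``SeqRecord`` objects.
    """
    from Bio import SeqIO

    stats = FastqFilterStats()
    kept = []
    for rec in SeqIO.parse(str(path), "fastq"):
        stats.n_input += 1
        ok, rule = read_passes_qc(
            str(rec.seq), rec.letter_annotations["phred_quality"], adapter,
            **kwargs,
        )
        if ok:
            kept.append(rec)
            stats.n_kept += 1
        else:
            stats.discarded[rule] += 1
    return kept, stats


# ---------------------------------------------------------------------------
# expressed background and DEG calling

def filter_expressed_background(fpkm: pd.DataFrame, samples=None,
                                fpkm_min: float = 1.0) -> set:
    """Genes whose mean FPKM over the reference condition is strictly > min.

    ``samples`` selects the reference-condition columns (default: all).
    """
    if fpkm.empty:
        return set()
    sub = fpkm if samples is None else fpkm[list(samples)]
    means = sub.mean(axis=1)
    return set(means.index[means > fpkm_min])


def two_group_log2_ttest(fpkm: pd.DataFrame, samples_a, samples_b
                         ) -> pd.DataFrame:
    """Per-gene two-group t-test on log2(FPKM+1) with BH correction.

    A deliberately simple self-contained test for the synthetic path (the
    study-scale pipeline would take a dedicated differential-expression
    tool's output instead).  log2FC is mean_B - mean_A on the log2(FPKM+1)
    scale.  Returns columns gene, log2fc, p, q.
    """
    a = np.log2(fpkm[list(samples_a)].to_numpy() + 1.0)
    b = np.log2(fpkm[list(samples_b)].to_numpy() + 1.0)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    t, p = _stats.ttest_ind(b, a, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        dict(gene=fpkm.index, log2fc=log2fc, p=p, q=bh_fdr(p))
    )


def call_degs(stats: pd.DataFrame, q_max: float = 0.05,
              min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Threshold per-gene statistics into a DEG table.

    A gene is differentially expressed iff q < q_max AND |log2FC| >
    min_abs_log2fc (both strict); direction is the sign of log2FC.  Genes
    with missing q or log2FC are skipped with a warning.
    """
    needed = {"gene", "log2fc", "q"}
    if not needed.issubset(stats.columns):
        raise ValueError(f"stats table must have columns {sorted(needed)}")
    bad = stats["q"].isna() | stats["log2fc"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} genes with missing q/log2fc skipped")
        stats = stats[~bad]
    hits = stats[(stats["q"] < q_max)
                 & (stats["log2fc"].abs() > min_abs_log2fc)].copy()
    hits["direction"] = np.where(hits["log2fc"] > 0, "up", "down")
    return hits.reset_index(drop=True)


def direction_asymmetry_test(n_down: int, n_up: int) -> tuple:
    """Chi-squared goodness-of-fit vs a 50:50 split, Yates-corrected.

    statistic = 2 * max(|O - E| - 0.5, 0)^2 / E with E = (n_down + n_up)/2;
    p from chi-squared with 1 df.  Balanced counts give statistic 0, p 1.
    """
    total = n_down + n_up
    if total <= 0:
        raise ValueError("need at least one gene")
    e = total / 2.0
    dev = max(abs(n_down - e) - 0.5, 0.0)
    stat = 2.0 * dev * dev / e
    return stat, float(_stats.chi2.sf(stat, df=1))


def intersect_deg_sets(degs_a: pd.DataFrame, degs_b: pd.DataFrame) -> dict:
    """Set intersection of two DEG tables with Venn and concordance counts."""
    sa, sb = set(degs_a["gene"]), set(degs_b["gene"])
    common = sa & sb
    out = {
        "common": common,
        "a_only": len(sa - sb),
        "b_only": len(sb - sa),
        "both": len(common),
    }
    if "direction" in degs_a.columns and "direction" in degs_b.columns:
        da = dict(zip(degs_a["gene"], degs_a["direction"]))
        db = dict(zip(degs_b["gene"], degs_b["direction"]))
        out["concordant"] = sum(da[g] == db[g] for g in common)
        out["discordant"] = len(common) - out["concordant"]
    return out


# ---------------------------------------------------------------------------
# enrichment

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(deg_genes, background, term_map: pd.DataFrame
                              ) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per term, with BH FDR.

    ``term_map`` is a (term, gene) table; genes outside the background are
    ignored, terms left empty by that restriction are skipped.  Per term
    with K background genes, of which k are among the n DEGs drawn from the
    N-gene background: p = P(X >= k), fold = (k/n)/(K/N).  Terms with k = 0
    get p = 1.
    """
    background = set(background)
    deg_genes = set(deg_genes)
    stray = deg_genes - background
    if stray:
        raise ValueError(
            f"DEG genes missing from background: {sorted(stray)[:5]}"
        )
    n, big_n = len(deg_genes), len(background)
    rows = []
    for term, sub in term_map.groupby("term", sort=True):
        members = set(sub["gene"]) & background
        big_k = len(members)
        if big_k == 0:
            continue
        k = len(members & deg_genes)
        p = 1.0 if k == 0 else float(
            _stats.hypergeom.sf(k - 1, big_n, big_k, n)
        )
        fold = (k / n) / (big_k / big_n) if n else 0.0
        rows.append(dict(term=term, k=k, n=n, K=big_k, N=big_n,
                         fold=fold, p=p))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# qPCR relative quantification

@dataclass
class QpcrRecord:
    """One sample's triplicate CTs for the target and the reference gene."""

    sample: str
    target_cts: tuple
    ref_cts: tuple
    is_calibrator: bool = False
    dct: float | None = None
    ddct: float | None = None
    rq: float | None = None


def ddct_quantify(records, calibrator: str) -> list:
    """Relative quantification by the 2^-ddCt method.

    CT = mean of triplicates; dCt = CT_target - CT_reference; ddCt =
    dCt_sample - dCt_calibrator; RQ = 2^-ddCt (calibrator RQ = 1 by
    construction).  Samples with missing reference CTs are skipped with a
    warning.
    """
    by_sample = {}
    for rec in records:
        if rec.ref_cts is None or any(
            c is None or np.isnan(c) for c in rec.ref_cts
        ):
            warnings.warn(f"sample {rec.sample}: missing reference CTs; skipped")
            continue
        by_sample[rec.sample] = rec
    if calibrator not in by_sample:
        raise ValueError(f"calibrator sample {calibrator!r} not found")
    for rec in by_sample.values():
        rec.dct = float(np.mean(rec.target_cts) - np.mean(rec.ref_cts))
    cal_dct = by_sample[calibrator].dct
    out = []
    for rec in by_sample.values():
        rec.is_calibrator = rec.sample == calibrator
        rec.ddct = rec.dct - cal_dct
        rec.rq = float(2.0 ** -rec.ddct)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# split-group phenotype t-tests

def grouped_ttest_fdr(values_large, values_small, n_splits: int) -> tuple:
    """Split-group two-sample t-tests for unbalanced phenotype comparisons.

    The larger sample is partitioned, in input order, into ``n_splits``
    near-equal blocks (sizes differing by at most 1); each block is compared
    to the smaller sample with a two-sided Student t-test.  Returns
    ``(per_split_p, mean_p)``; FDR correction across a battery of traits is
    applied by :func:`phenotype_battery`.
    """
    large = np.asarray(values_large, dtype=float)
    small = np.asarray(values_small, dtype=float)
    if len(large) < n_splits:
        raise ValueError("large group smaller than the number of splits")
    if len(small) < 2:
        raise ValueError("small group must have at least 2 values")
    blocks = np.array_split(large, n_splits)
    if any(len(b) < 2 for b in blocks):
        raise ValueError("every block needs at least 2 values")
    ps = []
    for b in blocks:
        t, p = _stats.ttest_ind(b, small)
        ps.append(1.0 if np.isnan(p) else float(p))
    return ps, float(np.mean(ps))


def phenotype_battery(traits: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Mean split-group p per trait, BH-corrected across the battery.

    ``traits`` maps trait name -> (values_large, values_small, n_splits).
    """
    rows = []
    for name, (large, small, n_splits) in traits.items():
        ps, mean_p = grouped_ttest_fdr(large, small, n_splits)
        rows.append(dict(trait=name, n_splits=n_splits, mean_p=mean_p))
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["mean_p"].to_numpy())
    df["significant"] = df["q"] < alpha
    return df
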