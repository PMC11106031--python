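"""Binomial testing and multiple-testing correction.

The count of RNA i in bin j is modelled as X_ij ~ Binomial(N_i, p_ij), with
N_i the RNA's total contacts outside its gene body and p_ij assembled from
the heterogeneity background and (for cis bins) the distance-decay factor,
renormalized so probabilities sum to one per RNA with the cis compartment
carrying exactly the RNA's observed cis contact fraction. Right-sided
binomial p-values from non-empty bins get Benjamini-Hochberg correction two
ways: pooled over all RNAs (global q-values, the default peak criterion)
and within each RNA (RNA q-values).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTACTS = 1000
DEFAULT_QVALUE = 0.05


def binom_right_pvalue(o, n, p) -> np.ndarray:
    """P[X >= o] for X ~ Binomial(n, p), right-sided, stable in the tail."""
    o = np.asarray(o, np.int64)
    p = np.asarray(p, float)
    # sf(o-1) = P[X > o-1] = P[X >= o]; sf handles small tails in log space
    out = stats.binom.sf(o - 1, n, p)
    return np.asarray(out, float)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    pvalues = np.asarray(pvalues, float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def correct_dual(pvalues, rna_ids) -> tuple[np.ndarray, np.ndarray]:
    """BH applied two ways: pooled over all RNAs, and within each RNA.

    Only p-values of non-empty bins should be passed in. Returns
    (qvalue_global, qvalue_rna) aligned with the input.
    """
    pvalues = np.asarray(pvalues, float)
    rna_ids = np.asarray(rna_ids)
    q_global = bh_adjust(pvalues)
    q_rna = np.empty_like(q_global)
    for rna in pd.unique(rna_ids):
        sel = rna_ids == rna
        q_rna[sel] = bh_adjust(pvalues[sel])
    return q_global, q_rna


def filter_rnas(contacts: pd.DataFrame, min_contacts: int = DEFAULT_MIN_CONTACTS) -> list[str]:
    """RNAs with strictly more than ``min_contacts`` total contacts."""
    totals = contacts["rna_name"].value_counts()
    return [str(r) for r in totals.index[totals > min_contacts]]


def assemble_probs(
    bg_prob: np.ndarray,
    scaling_factor: np.ndarray,
    is_cis: np.ndarray,
    testable: np.ndarray,
    n_cis: int,
    n_trans: int,
) -> np.ndarray:
    """Per-bin success probabilities p_ij, summing to 1 over testable bins.

    Raw cis values f(d_j) * p_bg_j are rescaled so the cis compartment sums
    to N_cis/N; raw trans values p_bg_j so the trans compartment sums to
    N_trans/N. With N_cis = 0 the cis bins get probability 0 (untested).
    """
    bg_prob = np.asarray(bg_prob, float)
    is_cis = np.asarray(is_cis, bool)
    testable = np.asarray(testable, bool)
    n = n_cis + n_trans
    if n <= 0:
        raise ValueError("RNA has no contacts outside the gene body")
    p = np.zeros(len(bg_prob))
    cis = is_cis & testable
    trans = ~is_cis & testable
    raw_cis = np.asarray(scaling_factor, float)[cis] * bg_prob[cis]
    for mask, raw, mass in ((cis, raw_cis, n_cis / n), (trans, bg_prob[trans], n_trans / n)):
        if mass == 0:
            if mask.any():
                logger.warning(
                    "compartment with zero contacts left untested (%d bins)",
                    int(mask.sum()),
                )
            continue
        total = raw.sum()
        if total <= 0:
            raise ValueError("zero total probability in a non-empty compartment")
        p[mask] = raw / total * mass
    return p


def call_peaks(
    table: pd.DataFrame,
    q_threshold: float = DEFAULT_QVALUE,
    mode: str = "global",
) -> pd.DataFrame:
    """Select significant bins from a results table.

    Bins with the chosen q-value below threshold and at least one contact,
    the gene-body bin always excluded. Each significant bin is one peak;
    adjacent bins are not merged (see :func:`merge_adjacent`).
    """
    if mode not in ("global", "per_rna", "rna"):
        raise ValueError(f"unknown q-value mode {mode!r}")
    col = "qvalue_global" if mode == "global" else "qvalue_rna"
    keep = (
        (table["count"] > 0)
        & ~table["is_gene_body"].astype(bool)
        & (table[col] < q_threshold)
    )
    return table[keep.fillna(False)].reset_index(drop=True)


def merge_adjacent(peaks: pd.DataFrame) -> pd.DataFrame:
    """Optional post-processing: merge book-ended bins of the same RNA.

    Merged records keep the best (smallest) p- and q-values and the
    count-weighted fold of their members.
    """
    if len(peaks) == 0:
        return peaks
    peaks = peaks.sort_values(["rna_name", "chrom", "start"], kind="stable")
    merged: list[dict] = []
    for row in peaks.to_dict("records"):
        cur = merged[-1] if merged else None
        if (
            cur is not None
            and row["rna_name"] == cur["rna_name"]
            and row["chrom"] == cur["chrom"]
            and row["start"] == cur["end"]
        ):
            cur["end"] = row["end"]
            cur["count"] += row["count"]
            cur["pvalue"] = min(cur["pvalue"], row["pvalue"])
            cur["qvalue_global"] = min(cur["qvalue_global"], row["qvalue_global"])
            cur["qvalue_rna"] = min(cur["qvalue_rna"], row["qvalue_rna"])
            cur["fold"] = max(cur["fold"], row["fold"])
        else:
            merged.append(row)
    return pd.DataFrame(merged)
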