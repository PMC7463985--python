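"""Copy-number-aware differential screen of the glycogen gene panel.

Expression values are log2(FPKM-uq+1).  Samples are labelled monosomy-3
when both chromosome-3 arms (3p and 3q) are called lost; samples missing
either arm call are excluded.  Per gene, the effect size is the signed
median fold change

    delta = median(monosomy3) - median(disomy3)            [log2 units]
    fc    = 2**delta        if delta >= 0
          = -2**(-delta)    otherwise

so magnitudes are never inside (0, 1) and a negative sign means
downregulation in the monosomy-3 tumors.  Group comparison uses the
two-sided Mann-Whitney U test with Bonferroni correction over the panel.

Because chromosome-3 dosage is confounded with the grouping itself, each
gene off chromosome 3 is re-tested after omitting samples with an
aberrant (lost or gained) copy-number call at its locus; chromosome-3
genes are marked not-applicable.  A gene is "differential regardless of
copy number" when the all-patients adjusted p is significant AND the
rerun is either significant or not-applicable by chromosome 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .util import round_half_away

__all__ = [
    "CopyNumberCalls",
    "label_monosomy3",
    "signed_fold_change",
    "median_fold_change",
    "mwu_test",
    "bonferroni",
    "copy_number_rerun",
    "run_screen",
    "differential_gene_set",
    "summarize_fold_changes",
]

NOT_APPLICABLE_CHR3 = "chr3"
NOT_APPLICABLE_EMPTY = "empty_group_after_omission"


@dataclass
class CopyNumberCalls:
    """Arm-level chromosome-3 calls plus per-(gene, sample) locus calls.

    ``arm_calls``: DataFrame indexed by sample with boolean columns
    ``arm3p_loss`` and ``arm3q_loss`` (NaN = missing).
    ``gene_calls``: DataFrame (genes x samples) of strings in
    {loss, neutral, gain, missing}; chromosome-3 genes may be absent.
    """

    arm_calls: pd.DataFrame
    gene_calls: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for col in ("arm3p_loss", "arm3q_loss"):
            if col not in self.arm_calls.columns:
                raise ValueError(f"arm_calls is missing column {col!r}")


def label_monosomy3(cn: CopyNumberCalls) -> pd.Series:
    """Per-sample label: monosomy3 (both arms lost), disomy3, or excluded."""
    p = cn.arm_calls["arm3p_loss"]
    q = cn.arm_calls["arm3q_loss"]
    labels = pd.Series("disomy3", index=cn.arm_calls.index, dtype=object)
    labels[p.isna() | q.isna()] = "excluded"
    both = (p == True) & (q == True)  # noqa: E712 -- object dtype with NaN
    labels[both & (labels != "excluded")] = "monosomy3"
    return labels


def signed_fold_change(delta_log2: float) -> float:
    """Map a log2 difference to the signed fold-change convention."""
    if delta_log2 >= 0:
        return float(2.0**delta_log2)
    return float(-(2.0**-delta_log2))


def median_fold_change(m3_values, d3_values) -> float:
    """Signed fold change from group medians of log2 expression."""
    m3 = np.asarray(m3_values, dtype=float)
    d3 = np.asarray(d3_values, dtype=float)
    if m3.size == 0 or d3.size == 0:
        raise ValueError("both groups must be nonempty")
    return signed_fold_change(float(np.median(m3) - np.median(d3)))


def mwu_test(a, b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when the smaller group has <= 8 observations and
    there are no ties; otherwise the tie-corrected normal approximation
    (no continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= 8 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(min(res.pvalue, 1.0))
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
    var_u = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    if var_u <= 0:  # all observations identical
        return 1.0
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var_u)
    return float(min(2.0 * sps.norm.sf(abs(z)), 1.0))


def bonferroni(p: float, m: int) -> float:
    """min(1, p * m)."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return min(1.0, p * m)


def _is_chr3(chrom: str) -> bool:
    return str(chrom).removeprefix("chr") == "3"


def copy_number_rerun(
    symbol: str,
    chrom: str,
    values: pd.Series,
    labels: pd.Series,
    cn: CopyNumberCalls,
):
    """Re-test a gene after omitting samples with an aberrant locus call.

    Returns ``(fc, p, None)`` or ``(nan, nan, reason)`` where the reason
    is "chr3" (copy number confounded with the grouping) or an
    empty-group condition after omission.  A gene with all-neutral calls
    reproduces the all-patients result exactly.
    """
    if _is_chr3(chrom):
        return float("nan"), float("nan"), NOT_APPLICABLE_CHR3
    labels = labels.reindex(values.index)
    if symbol in cn.gene_calls.index:
        calls = cn.gene_calls.loc[symbol].reindex(values.index)
        aberrant = calls.isin(["loss", "gain"]).to_numpy()
    else:
        aberrant = np.zeros(len(values), dtype=bool)
    return _rerun_arrays(
        values.to_numpy(dtype=float), labels.to_numpy(dtype=object), aberrant
    )


def _rerun_arrays(vals: np.ndarray, lab: np.ndarray, aberrant: np.ndarray):
    keep = ~aberrant
    m3 = vals[keep & (lab == "monosomy3")]
    d3 = vals[keep & (lab == "disomy3")]
    if m3.size == 0 or d3.size == 0:
        return float("nan"), float("nan"), NOT_APPLICABLE_EMPTY
    return median_fold_change(m3, d3), mwu_test(m3, d3), None


def run_screen(
    expr: pd.DataFrame,
    cn: CopyNumberCalls,
    panel: pd.DataFrame,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Full panel screen: fold changes, tests, rerun, differential calls.

    ``expr`` is genes x samples in log2(FPKM-uq+1); ``panel`` provides
    symbol/chrom; ``n_comparisons`` defaults to the number of panel genes
    actually tested (the Bonferroni multiplier).
    """
    if expr.index.duplicated().any():
        raise ValueError("expression matrix has duplicate gene symbols")
    labels = label_monosomy3(cn).reindex(expr.columns)
    m3_samples = labels.index[labels == "monosomy3"]
    d3_samples = labels.index[labels == "disomy3"]
    if len(m3_samples) == 0 or len(d3_samples) == 0:
        raise ValueError("need at least one sample in each monosomy-3 group")
    genes = [g for g in panel["symbol"] if g in expr.index]
    if not genes:
        raise ValueError("no panel genes found in the expression matrix")
    m = len(genes) if n_comparisons is None else n_comparisons
    chrom_of = dict(zip(panel["symbol"], panel["chrom"]))

    matrix = expr.loc[genes].to_numpy(dtype=float)
    lab_arr = labels.to_numpy(dtype=object)
    is_m3 = lab_arr == "monosomy3"
    is_d3 = lab_arr == "disomy3"
    calls_aligned = cn.gene_calls.reindex(columns=expr.columns)

    rows = []
    for gi, gene in enumerate(genes):
        vals = matrix[gi]
        m3 = vals[is_m3]
        d3 = vals[is_d3]
        fc_all = median_fold_change(m3, d3)
        p_all = mwu_test(m3, d3)
        p_all_bonf = bonferroni(p_all, m)
        if _is_chr3(chrom_of[gene]):
            fc_f, p_f, na_reason = float("nan"), float("nan"), NOT_APPLICABLE_CHR3
        else:
            if gene in calls_aligned.index:
                aberrant = calls_aligned.loc[gene].isin(["loss", "gain"]).to_numpy()
            else:
                aberrant = np.zeros(vals.size, dtype=bool)
            fc_f, p_f, na_reason = _rerun_arrays(vals, lab_arr, aberrant)
        p_f_bonf = bonferroni(p_f, m) if na_reason is None else float("nan")
        rows.append(
            {
                "symbol": gene,
                "chrom": chrom_of[gene],
                "n_m3": len(m3_samples),
                "n_d3": len(d3_samples),
                "fc_all": fc_all,
                "fc_all_display": round_half_away(fc_all),
                "p_all": p_all,
                "p_all_bonf": p_all_bonf,
                "p_all_bonf_display": round_half_away(p_all_bonf),
                "fc_filtered": fc_f,
                "p_filtered": p_f,
                "p_filtered_bonf": p_f_bonf,
                "na_reason": na_reason,
            }
        )
    out = pd.DataFrame(rows)
    sig_all = out["p_all_bonf"] < alpha
    sig_filtered = (out["na_reason"] == NOT_APPLICABLE_CHR3) | (
        out["p_filtered_bonf"] < alpha
    )
    out["differential"] = sig_all & sig_filtered
    out["direction"] = np.where(
        ~out["differential"], "ns", np.where(out["fc_all"] < 0, "down", "up")
    )
    out.attrs["alpha"] = alpha
    out.attrs["n_comparisons"] = m
    return out


def differential_gene_set(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Genes differential regardless of copy number.

    Significant in the all-patients test AND (significant in the rerun OR
    not applicable because the gene lies on chromosome 3).
    """
    sig_all = results["p_all_bonf"] < alpha
    sig_filtered = (results["na_reason"] == NOT_APPLICABLE_CHR3) | (
        results["p_filtered_bonf"] < alpha
    )
    return results[sig_all & sig_filtered].copy()


def summarize_fold_changes(fold_changes) -> dict:
    """Median and range of the negative and positive fold changes.

    Returns keys median_down / range_down and median_up / range_up; a
    side with no genes is omitted.  Ranges are (closest-to-1, extreme)
    following the signed convention.
    """
    fcs = np.asarray(fold_changes, dtype=float)
    if fcs.size == 0:
        raise ValueError("no fold changes to summarize")
    out: dict[str, object] = {}
    down = fcs[fcs < 0]
    up = fcs[fcs > 0]
    if down.size:
        out["median_down"] = float(np.median(down))
        out["range_down"] = (float(down.max()), float(down.min()))
    if up.size:
        out["median_up"] = float(np.median(up))
        out["range_up"] = (float(up.min()), float(up.max()))
    return out
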