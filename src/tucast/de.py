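"""Two-library differential expression without replicates.

Fold change is computed on readcounts with the deletion strain in the
numerator: log2FC = log2(count_mut / count_orig). There is deliberately no
pseudocount: a gene with zero reads in exactly one library has an undefined
fold change and is reported as ``excluded`` rather than forced onto the
volcano plot (the deleted gene itself, with no mapped reads, is the
canonical case).

Significance comes from a pooled two-proportion z statistic

    z = (p1 - p2) / sqrt(pbar (1-pbar) (1/N1 + 1/N2)),

treating each library as a draw of its total fragments, with an exact
hypergeometric (Fisher) alternative. Genes with |log2FC| > 1 and
p < 0.005 are called up or down. A Benjamini-Hochberg q-value column is
emitted for information only; the classification uses the raw p cut.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .models import DEConfig


def log2_fold_change(count_mut: float, count_orig: float) -> float:
    """log2(count_mut / count_orig); nan when either count is zero."""
    if count_mut < 0 or count_orig < 0:
        raise InputError("counts must be non-negative")
    if count_mut == 0 or count_orig == 0:
        return float("nan")
    return math.log2(count_mut / count_orig)


def de_test(
    count_mut: float,
    total_mut: float,
    count_orig: float,
    total_orig: float,
    method: str = "z",
) -> float:
    """Two-sided p-value that the two libraries express the gene equally.

    ``method="z"`` uses the pooled two-proportion z statistic;
    ``method="fisher"`` the exact hypergeometric test. Degenerate input
    (both proportions zero, or both saturated) gives p = 1 by convention.
    """
    for c, n in ((count_mut, total_mut), (count_orig, total_orig)):
        if n <= 0:
            raise InputError("library totals must be positive")
        if c < 0 or c > n:
            raise InputError("counts must satisfy 0 <= count <= total")
    if method == "fisher":
        table = [
            [round(count_mut), round(total_mut - count_mut)],
            [round(count_orig), round(total_orig - count_orig)],
        ]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method != "z":
        raise InputError(f"unknown test method {method!r}")
    p1 = count_mut / total_mut
    p2 = count_orig / total_orig
    pooled = (count_mut + count_orig) / (total_mut + total_orig)
    if pooled == 0 or pooled == 1:
        return 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / total_mut + 1 / total_orig))
    z = (p1 - p2) / se
    return float(2 * stats.norm.sf(abs(z)))


def classify(
    log2fc: np.ndarray, p_value: np.ndarray, config: DEConfig | None = None
) -> np.ndarray:
    """Assign up / down / not_significant / excluded per gene.

    ``up`` iff log2fc > lfc_threshold and p < p_threshold; ``down`` is the
    mirror; an undefined (nan) fold change is ``excluded``.
    """
    config = config or DEConfig()
    log2fc = np.asarray(log2fc, float)
    p_value = np.asarray(p_value, float)
    status = np.full(log2fc.shape, "not_significant", dtype=object)
    sig = p_value < config.p_threshold
    status[(log2fc > config.lfc_threshold) & sig] = "up"
    status[(log2fc < -config.lfc_threshold) & sig] = "down"
    status[np.isnan(log2fc)] = "excluded"
    return status


def differential_expression(
    counts: pd.DataFrame,
    totals: tuple[float, float] | None = None,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Full two-library analysis of a counts table.

    ``counts`` must hold columns ``gene_id``, ``count_orig`` and
    ``count_mut`` (or be indexed by gene id). ``totals`` are the
    (mutant, original) library sizes; when omitted they default to the
    column sums. Returns one row per gene with log2fc, p, BH q and status.
    """
    config = config or DEConfig()
    df = counts.set_index("gene_id") if "gene_id" in counts.columns else counts.copy()
    if df.index.has_duplicates:
        raise InputError("duplicate gene ids in counts table")
    for col in ("count_orig", "count_mut"):
        if col not in df.columns:
            raise InputError(f"counts table lacks column {col!r}")
    if totals is None:
        totals = (float(df["count_mut"].sum()), float(df["count_orig"].sum()))
    total_mut, total_orig = totals

    out = pd.DataFrame(index=df.index)
    out["count_orig"] = df["count_orig"].astype(float)
    out["count_mut"] = df["count_mut"].astype(float)
    out["log2fc"] = [
        log2_fold_change(m, o) for m, o in zip(out["count_mut"], out["count_orig"])
    ]
    out["p_value"] = [
        de_test(m, total_mut, o, total_orig, method=config.method)
        for m, o in zip(out["count_mut"], out["count_orig"])
    ]
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["status"] = classify(
        out["log2fc"].to_numpy(), out["p_value"].to_numpy(), config
    )
    out.index.name = "gene_id"
    return out


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """(log2fc, -log10 p) pairs for defined fold changes."""
    defined = results[~results["log2fc"].isna()]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(defined["p_value"].to_numpy())
    return pd.DataFrame(
        {"log2fc": defined["log2fc"].to_numpy(), "neg_log10_p": neglog},
        index=defined.index,
    )


def regulon_report(
    results: pd.DataFrame,
    cluster_membership: set[str] | Mapping[str, bool],
    categories: Mapping[str, str] | None = None,
) -> dict:
    """Partition differential genes into cluster vs non-cluster groups.

    Non-cluster differential genes are grouped by the supplied category
    labels (e.g. transporters / oxidoreductases / metabolic enzymes /
    hypothetical); genes without a label are reported under ``ungrouped``.
    """
    categories = categories or {}
    if isinstance(cluster_membership, Mapping):
        in_cluster = {g for g, v in cluster_membership.items() if v}
    else:
        in_cluster = set(cluster_membership)

    report: dict = {
        "cluster": {"up": [], "down": [], "excluded": []},
        "noncluster": {"up": [], "down": [], "groups": {}, "ungrouped": []},
        "counts": {},
    }
    for gene, row in results.iterrows():
        status = row["status"]
        if status == "not_significant":
            continue
        if gene in in_cluster:
            report["cluster"][status].append(gene)
            continue
        if status == "excluded":
            continue
        report["noncluster"][status].append(gene)
        label = categories.get(gene)
        if label is None:
            report["noncluster"]["ungrouped"].append(gene)
        else:
            group = report["noncluster"]["groups"].setdefault(
                label, {"up": [], "down": []}
            )
            group[status].append(gene)
    report["counts"] = {
        "cluster_down": len(report["cluster"]["down"]),
        "cluster_up": len(report["cluster"]["up"]),
        "cluster_excluded": len(report["cluster"]["excluded"]),
        "noncluster_down": len(report["noncluster"]["down"]),
        "noncluster_up": len(report["noncluster"]["up"]),
    }
    return report
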