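"""Relative gene-expression quantification by the ΔΔCt method.

Within each group, a gene's mean Ct is normalized to the housekeeping gene
(ΔCt = meanCt(gene) − meanCt(housekeeping)); the test group is then
normalized to the reference group (ΔΔCt = ΔCt(test) − ΔCt(reference)) and
the fold change is 2^−ΔΔCt. Replicate scatter is propagated to the
ΔΔCt scale by quadrature over the four standard errors involved. Genes
absent from a group are reported with a not-detected status rather than a
numeric fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["FoldChangeResult", "delta_delta_ct"]

REQUIRED_COLUMNS = ("group", "gene", "replicate", "ct")


@dataclass(frozen=True)
class FoldChangeResult:
    """ΔΔCt outcome for one gene.

    ``fold_change == 2 ** -delta_delta_ct``; for genes undetected in one
    group the numeric fields are NaN and ``status`` names the missing side.
    ``replicate_sd`` is the quadrature-propagated standard deviation of
    ΔΔCt in cycles (equal to the SD of log2 fold change).
    """

    gene: str
    delta_ct_reference: float
    delta_ct_test: float
    delta_delta_ct: float
    fold_change: float
    replicate_sd: float
    status: str = "ok"


def _group_stats(table: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = table[table["group"] == group]
    if sub.empty:
        raise DataError(f"group {group!r} has no rows")
    stats = sub.groupby("gene")["ct"].agg(["mean", "std", "count"])
    return stats.fillna({"std": 0.0})


def delta_delta_ct(
    table: pd.DataFrame,
    reference_group: str,
    test_group: str,
    housekeeping_gene: str | None = None,
) -> list[FoldChangeResult]:
    """Fold changes of every non-housekeeping gene, test vs reference group.

    Parameters
    ----------
    table : DataFrame
        Tidy Ct table with columns ``group, gene, replicate, ct``; the
        housekeeping label may ride along in ``table.attrs``.
    reference_group, test_group : str
        Group labels to difference (ΔΔCt = ΔCt(test) − ΔCt(reference)).
    housekeeping_gene : str, optional
        Defaults to ``table.attrs['housekeeping_gene']``, else ``'GAPDH'``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"Ct table lacks required columns: {missing}")
    hk = housekeeping_gene or table.attrs.get("housekeeping_gene", "GAPDH")

    ref = _group_stats(table, reference_group)
    test = _group_stats(table, test_group)
    for label, stats in ((reference_group, ref), (test_group, test)):
        if hk not in stats.index:
            raise DataError(
                f"housekeeping gene {hk!r} missing from group {label!r}"
            )

    def se2(stats: pd.DataFrame, gene: str) -> float:
        row = stats.loc[gene]
        return float(row["std"]) ** 2 / float(row["count"])

    genes = sorted((set(ref.index) | set(test.index)) - {hk})
    results: list[FoldChangeResult] = []
    for gene in genes:
        in_ref = gene in ref.index
        in_test = gene in test.index
        if not (in_ref and in_test):
            side = test_group if not in_test else reference_group
            results.append(
                FoldChangeResult(
                    gene=gene,
                    delta_ct_reference=(
                        float(ref.loc[gene, "mean"] - ref.loc[hk, "mean"])
                        if in_ref else math.nan
                    ),
                    delta_ct_test=(
                        float(test.loc[gene, "mean"] - test.loc[hk, "mean"])
                        if in_test else math.nan
                    ),
                    delta_delta_ct=math.nan,
                    fold_change=math.nan,
                    replicate_sd=math.nan,
                    status=f"not_detected_in_{side}",
                )
            )
            continue
        dct_ref = float(ref.loc[gene, "mean"] - ref.loc[hk, "mean"])
        dct_test = float(test.loc[gene, "mean"] - test.loc[hk, "mean"])
        ddct = dct_test - dct_ref
        sd = math.sqrt(
            se2(ref, gene) + se2(ref, hk) + se2(test, gene) + se2(test, hk)
        )
        results.append(
            FoldChangeResult(
                gene=gene,
                delta_ct_reference=dct_ref,
                delta_ct_test=dct_test,
                delta_delta_ct=ddct,
                fold_change=2.0 ** (-ddct),
                replicate_sd=sd,
            )
        )
    return results


def results_to_frame(results: list[FoldChangeResult]) -> pd.DataFrame:
    """Tabulate fold-change results (one row per gene)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "delta_ct_reference": r.delta_ct_reference,
                "delta_ct_test": r.delta_ct_test,
                "delta_delta_ct": r.delta_delta_ct,
                "fold_change": r.fold_change,
                "replicate_sd": r.replicate_sd,
                "status": r.status,
            }
            for r in results
        ]
    )
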