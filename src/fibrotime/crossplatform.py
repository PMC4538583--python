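"""Cross-platform concordance of RNA-seq with qPCR and protein measurements.

qPCR expression is quantified as 2^-dCT (dCT = CT_target - CT_reference);
per-gene concordance with RNA-seq is the Spearman correlation of RPKM and
2^-dCT across all samples of one cell line.  First-vs-last fold changes are
compared across platforms: log2 of the RPKM group-mean ratio (pseudocount
0.5), -ddCT for qPCR (ddCT = mean dCT_last - mean dCT_first), and log2 of
the protein expression ratio.  A gene is sign-concordant when every
available platform fold change shares one sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, ttest_ind

REQUIRED_QPCR_COLUMNS = ("gene", "sample", "ct_target", "ct_reference")


def _validate_qpcr(qpcr: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_QPCR_COLUMNS if c not in qpcr.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    if (qpcr["ct_reference"].dropna() <= 0).any() or (
        qpcr["ct_target"].dropna() <= 0
    ).any():
        raise ValueError("CT values must be positive")
    return qpcr


def delta_ct_expression(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample matrix of 2^-dCT; missing CTs yield NaN entries."""
    qpcr = _validate_qpcr(qpcr)
    dct = qpcr["ct_target"] - qpcr["ct_reference"]
    values = qpcr.assign(expr=2.0 ** (-dct))
    return values.pivot(index="gene", columns="sample", values="expr")


def protein_ttest(intensities_a, intensities_b) -> float:
    """Welch two-sample t-test p-value on protein intensity replicates."""
    return float(ttest_ind(intensities_a, intensities_b, equal_var=False).pvalue)


def platform_fold_changes(
    rpkm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    qpcr: pd.DataFrame,
    cell_line: str,
    first_pd,
    last_pd,
    protein_ratios: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene cross-platform concordance rows for one cell line.

    Returns, per qPCR-measured gene: the Spearman rho of RPKM vs 2^-dCT over
    all the line's samples (pairwise-complete; flagged unreliable below 3
    pairs), the three platform log2 fold changes between ``first_pd`` and
    ``last_pd``, and a sign-concordance flag over the available platforms.
    ``protein_ratios`` has columns (gene, cell_line, ratio).
    """
    qexpr = delta_ct_expression(qpcr)
    sub = sample_meta[sample_meta["cell_line"] == cell_line]
    line_samples = [s for s in sub.index if s in qexpr.columns]
    first_samples = sub[sub["pd"] == first_pd].index
    last_samples = sub[sub["pd"] == last_pd].index
    if len(first_samples) == 0 or len(last_samples) == 0:
        raise ValueError(f"no samples at PD {first_pd} or {last_pd} for {cell_line!r}")

    dct = (qpcr["ct_target"] - qpcr["ct_reference"]).to_frame("dct")
    dct = pd.concat([qpcr[["gene", "sample"]], dct], axis=1).pivot(
        index="gene", columns="sample", values="dct"
    )

    prot = None
    if protein_ratios is not None:
        prot = protein_ratios[protein_ratios["cell_line"] == cell_line].set_index(
            "gene"
        )["ratio"]

    rows = []
    for gene in qexpr.index:
        x = rpkm.loc[gene, line_samples].to_numpy(dtype=float)
        y = qexpr.loc[gene, line_samples].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() >= 3:
            rho = float(spearmanr(x[ok], y[ok]).statistic)
            unreliable = False
        else:
            rho, unreliable = np.nan, True
        mean_first = rpkm.loc[gene, first_samples].mean()
        mean_last = rpkm.loc[gene, last_samples].mean()
        fc_rna = float(np.log2((mean_last + 0.5) / (mean_first + 0.5)))
        ddct = float(
            dct.loc[gene, [s for s in last_samples if s in dct.columns]].mean()
            - dct.loc[gene, [s for s in first_samples if s in dct.columns]].mean()
        )
        fc_qpcr = -ddct
        fc_prot = (
            float(np.log2(prot.loc[gene]))
            if prot is not None and gene in prot.index
            else np.nan
        )
        fcs = [fc for fc in (fc_rna, fc_qpcr, fc_prot) if not np.isnan(fc)]
        concordant = bool(all(fc > 0 for fc in fcs) or all(fc < 0 for fc in fcs))
        rows.append(
            {
                "gene": gene,
                "spearman_rho": rho,
                "rho_unreliable": unreliable,
                "log2fc_rnaseq": fc_rna,
                "log2fc_qpcr": fc_qpcr,
                "log2fc_protein": fc_prot,
                "sign_concordant": concordant,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
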