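"""DEG bookkeeping across ordered comparisons and between cell lines.

``recurrence_partition`` reproduces the intersection-barplot logic: every DEG
in a comparison is labeled by the earliest comparison (in plot order) in
which it already appeared, so bars decompose into "recurrent" and "new"
segments.  ``crossline_common`` splits the genes called in both cell lines by
fold-change sign agreement, and ``select_validation_genes`` applies the
strong-expression-or-curated filter used to pick bench-validation candidates.
"""

from __future__ import annotations

import dataclasses

import pandas as pd


def recurrence_partition(ordered_sets: list) -> "RecurrencePartition":
    """Label each DEG by the earliest comparison in which it appeared.

    ``ordered_sets`` is an ordered list of (comparison_name, set_of_genes).
    For comparison t, each gene is labeled min{t' <= t : gene in DEG(t')};
    the labels partition each comparison's DEG set.
    """
    if not ordered_sets:
        raise ValueError("need at least one comparison")
    names = [name for name, _ in ordered_sets]
    first_seen: dict = {}
    labels_per_comparison = []
    for t, (_, genes) in enumerate(ordered_sets):
        labels: dict = {}
        for gene in genes:
            if gene not in first_seen:
                first_seen[gene] = t
            labels.setdefault(first_seen[gene], set()).add(gene)
        labels_per_comparison.append(labels)
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for t, labels in enumerate(labels_per_comparison):
        for t0, genes in labels.items():
            counts.iloc[t, t0] = len(genes)
    return RecurrencePartition(
        comparisons=names, labels=labels_per_comparison, counts=counts
    )


@dataclasses.dataclass
class RecurrencePartition:
    comparisons: list
    #: one dict per comparison mapping origin-comparison index -> gene set
    labels: list
    #: rows = comparisons, columns = origin comparison, values = gene counts
    counts: pd.DataFrame

    def new_counts(self) -> pd.Series:
        """Number of first-time DEG per comparison (the diagonal)."""
        import numpy as np

        return pd.Series(np.diag(self.counts.to_numpy()), index=self.comparisons)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclasses.dataclass
class CrossLinePartition:
    intersection: set
    common_up: set
    common_down: set
    discordant: set


def crossline_common(deg_line1: set, deg_line2: set, signs1, signs2) -> CrossLinePartition:
    """Split the two-line DEG intersection by fold-change sign agreement.

    ``signs1``/``signs2`` map gene -> signed fold change (any real; only the
    sign is used).  Raises if a sign is missing for an intersected gene.
    """
    intersection = set(deg_line1) & set(deg_line2)
    common_up, common_down, discordant = set(), set(), set()
    for gene in intersection:
        for signs, which in ((signs1, "line 1"), (signs2, "line 2")):
            if gene not in signs or pd.isna(signs[gene]):
                raise ValueError(f"missing fold-change sign for gene {gene!r} in {which}")
        s1, s2 = signs1[gene], signs2[gene]
        if s1 > 0 and s2 > 0:
            common_up.add(gene)
        elif s1 < 0 and s2 < 0:
            common_down.add(gene)
        else:
            discordant.add(gene)
    return CrossLinePartition(
        intersection=intersection,
        common_up=common_up,
        common_down=common_down,
        discordant=discordant,
    )


def select_validation_genes(
    rows: pd.DataFrame, rpkm_threshold: float, curated=()
) -> set:
    """Pick genes for bench validation.

    ``rows`` is indexed by gene with boolean columns ``deg_strict_line1`` and
    ``deg_strict_line2`` and a numeric ``max_mean_rpkm`` (maximum per-group
    mean RPKM over both lines).  A gene is selected when it is a strict DEG
    in both lines and either its strongest group mean strictly exceeds the
    RPKM threshold or it belongs to the curated pathway list.
    """
    if rpkm_threshold <= 0:
        raise ValueError("rpkm_threshold must be positive")
    curated = set(curated)
    both = rows["deg_strict_line1"].astype(bool) & rows["deg_strict_line2"].astype(bool)
    strong = rows["max_mean_rpkm"] > rpkm_threshold
    selected = rows.index[both & (strong | rows.index.isin(curated))]
    return set(selected)
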