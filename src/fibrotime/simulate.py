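"""Seeded synthetic RNA-seq count data for the senescence time-course design.

The generator emulates the structure of the study design the pipeline was
built for: two fibroblast cell lines sampled at five population doublings
(PDs) with three biological replicates each (30 samples), ~20k expressed
genes, negative-binomial counts with a mean-dependent dispersion
alpha(mu) = a0 + a1/mu, unequal library sizes, and per-gene temporal
archetypes (flat, monotone up/down, early step, late step, parabolic) that
may be shared between the lines or line-specific.  Ground-truth labels for
every downstream stage (archetype, per-PD mean, monotone class, DEG status
per comparison) are returned alongside the counts.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import CountMatrix

ARCHETYPES = (
    "flat",
    "monotone_up",
    "monotone_down",
    "early_step",
    "late_step",
    "parabolic",
)

DEFAULT_ARCHETYPE_FRACTIONS = {
    "flat": 0.70,
    "monotone_up": 0.06,
    "monotone_down": 0.06,
    "early_step": 0.06,
    "late_step": 0.06,
    "parabolic": 0.06,
}

DEFAULT_PD_LABELS = {"A": (32, 42, 52, 62, 72), "B": (16, 26, 46, 64, 74)}


class ConfigurationError(ValueError):
    pass


def archetype_multiplier(archetype: str, pd_index: int, effect_size: float) -> float:
    """Mean-expression multiplier of an archetype at time-point ``pd_index``.

    ``effect_size`` is the log2 change per PD step (monotone archetypes) or
    per step event (step archetypes).  ``flat`` is 1 everywhere; the parabolic
    shape is a symmetric rise-and-fall in log2 peaking at the middle PD.
    """
    if archetype not in ARCHETYPES:
        raise ConfigurationError(f"unknown archetype {archetype!r}")
    if not 0 <= pd_index <= 4:
        raise ConfigurationError(f"pd_index {pd_index} out of range 0..4")
    if archetype == "flat":
        return 1.0
    if archetype == "monotone_up":
        return 2.0 ** (effect_size * pd_index)
    if archetype == "monotone_down":
        return 2.0 ** (-effect_size * pd_index)
    if archetype == "early_step":
        return 1.0 if pd_index == 0 else 2.0**effect_size
    if archetype == "late_step":
        return 1.0 if pd_index < 4 else 2.0**effect_size
    # parabolic: log2 multiplier e * (1 - ((i-2)/2)^2), symmetric about i=2
    return 2.0 ** (effect_size * (1.0 - ((pd_index - 2) / 2.0) ** 2))


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the design the pipeline targets: 2 lines x 5 PDs x 3
    replicates, mostly flat genes with ~30% regulated, one log2 unit of
    change per PD step or step event, NB dispersion alpha(mu) = a0 + a1/mu,
    and log-normal library-size variation so size-factor estimation is
    exercised.
    """

    n_genes: int = 20000
    cell_lines: tuple = ("A", "B")
    pd_labels: dict = dataclasses.field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PD_LABELS.items()}
    )
    n_replicates: int = 3
    archetype_fractions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_FRACTIONS)
    )
    shared_fraction: float = 0.7
    effect_size: float = 1.0
    dispersion_params: tuple = (0.05, 1.0)  # alpha(mu) = a0 + a1/mu
    library_size_spread: float = 0.2  # log-normal sigma of library factors
    length_range: tuple = (500, 10000)  # bp
    baseline_meanlog: float = math.log(60.0)
    baseline_sdlog: float = 1.2
    line_offset_sdlog: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        fr = self.archetype_fractions
        unknown = set(fr) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetypes in fractions: {unknown}")
        vals = [fr.get(a, 0.0) for a in ARCHETYPES]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ConfigurationError("archetype fractions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigurationError(f"archetype fractions sum to {sum(vals)}, not 1")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        for line in self.cell_lines:
            if line not in self.pd_labels or len(self.pd_labels[line]) != 5:
                raise ConfigurationError(f"cell line {line!r} needs 5 PD labels")
        a0, a1 = self.dispersion_params
        if a0 < 0 or a1 < 0:
            raise ConfigurationError("dispersion parameters must be >= 0")


_COMPARISON_KEYS = ("c1", "c2", "c3", "c4", "first_last")
_COMPARISON_INDEX_PAIRS = ((0, 1), (1, 2), (2, 3), (3, 4), (0, 4))


@dataclasses.dataclass
class GroundTruth:
    """Per-gene, per-line truth labels in one tidy table.

    Columns: gene_id, cell_line, archetype, monotone_class,
    mean_pd0..mean_pd4 (reads-scale means at unit library factor), and DEG
    status deg_c1..deg_c4 (consecutive PD pairs) and deg_first_last.
    """

    table: pd.DataFrame

    def line(self, cell_line: str) -> pd.DataFrame:
        sub = self.table[self.table["cell_line"] == cell_line]
        return sub.set_index("gene_id")

    def archetypes(self) -> pd.DataFrame:
        return self.table.pivot(index="gene_id", columns="cell_line", values="archetype")

    def monotone_classes(self) -> pd.DataFrame:
        return self.table.pivot(
            index="gene_id", columns="cell_line", values="monotone_class"
        )

    def write_tsv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        for key in _COMPARISON_KEYS:
            df[f"deg_{key}"] = df[f"deg_{key}"].astype(bool)
        return cls(table=df)


def _monotone_class(archetype: str) -> str:
    if archetype == "monotone_up":
        return "up"
    if archetype == "monotone_down":
        return "down"
    return "nonuniform"


def _assign_archetypes(config: SimulationConfig, rng: np.random.Generator):
    """Assign each gene a primary archetype and decide which lines express it.

    Fractions allocate the primary archetype; of the regulated (non-flat)
    genes, a ``shared_fraction`` express the same archetype in both lines,
    the rest are regulated in one randomly chosen line and flat in the other.
    """
    n = config.n_genes
    counts = {a: int(round(config.archetype_fractions.get(a, 0.0) * n)) for a in ARCHETYPES}
    # fix rounding drift on the flat bucket
    counts["flat"] += n - sum(counts.values())
    order = rng.permutation(n)
    primary = np.empty(n, dtype=object)
    pos = 0
    for a in ARCHETYPES:
        primary[order[pos : pos + counts[a]]] = a
        pos += counts[a]
    per_line = {line: np.array(["flat"] * n, dtype=object) for line in config.cell_lines}
    regulated = primary != "flat"
    shared = rng.random(n) < config.shared_fraction
    which_line = rng.integers(0, len(config.cell_lines), size=n)
    for gi in np.nonzero(regulated)[0]:
        if shared[gi]:
            for line in config.cell_lines:
                per_line[line][gi] = primary[gi]
        else:
            per_line[config.cell_lines[which_line[gi]]][gi] = primary[gi]
    return per_line


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """NB draws with variance mu + alpha(mu) * mu^2; Poisson when alpha == 0."""
    mu = np.asarray(mu, dtype=float)
    alpha = a0 + np.divide(a1, mu, out=np.full_like(mu, np.inf), where=mu > 0)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    alpha_pos = alpha[pos]
    mu_pos = mu[pos]
    nb = alpha_pos > 1e-12
    res = np.empty(mu_pos.shape, dtype=np.int64)
    if nb.any():
        r = 1.0 / alpha_pos[nb]
        p = r / (r + mu_pos[nb])
        res[nb] = rng.negative_binomial(r, p)
    if (~nb).any():
        res[~nb] = rng.poisson(mu_pos[~nb])
    out[pos] = res
    return out


def generate_dataset(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a seeded count matrix plus ground truth under ``config``.

    Counts for gene i in sample j of line l at PD index t are NB with mean
    baseline_i * offset_il * multiplier(archetype_il, t) * lib_j and variance
    mu + alpha(mu) mu^2.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    lengths = pd.Series(
        rng.integers(config.length_range[0], config.length_range[1] + 1, size=n),
        index=genes,
        name="length_bp",
    )
    baseline = np.exp(rng.normal(config.baseline_meanlog, config.baseline_sdlog, size=n))
    offsets = {
        line: np.exp(rng.normal(0.0, config.line_offset_sdlog, size=n))
        for line in config.cell_lines
    }
    per_line_arch = _assign_archetypes(config, rng)

    a0, a1 = config.dispersion_params
    sample_ids, meta_rows, count_cols = [], [], []
    truth_rows = {line: None for line in config.cell_lines}
    for line in config.cell_lines:
        pds = config.pd_labels[line]
        mult = np.empty((n, 5))
        for t in range(5):
            mult[:, t] = [
                archetype_multiplier(a, t, config.effect_size) for a in per_line_arch[line]
            ]
        means = baseline[:, None] * offsets[line][:, None] * mult  # genes x 5
        truth_rows[line] = (per_line_arch[line], means, mult)
        for t, pd_label in enumerate(pds):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{line}_PD{pd_label}_R{rep}"
                lib = float(np.exp(rng.normal(0.0, config.library_size_spread)))
                counts = _nb_draw(rng, means[:, t] * lib, a0, a1)
                sample_ids.append(sid)
                meta_rows.append({"cell_line": line, "pd": pd_label, "replicate": rep})
                count_cols.append(counts)

    counts_df = pd.DataFrame(
        np.column_stack(count_cols), index=genes, columns=sample_ids
    )
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    cm = CountMatrix(counts=counts_df, sample_meta=meta, gene_lengths=lengths)

    records = []
    for line in config.cell_lines:
        arch, means, mult = truth_rows[line]
        for gi, gene in enumerate(genes):
            rec = {
                "gene_id": gene,
                "cell_line": line,
                "archetype": arch[gi],
                "monotone_class": _monotone_class(arch[gi]),
            }
            for t in range(5):
                rec[f"mean_pd{t}"] = means[gi, t]
            for key, (ta, tb) in zip(_COMPARISON_KEYS, _COMPARISON_INDEX_PAIRS):
                rec[f"deg_{key}"] = bool(not np.isclose(mult[gi, ta], mult[gi, tb]))
            records.append(rec)
    truth = GroundTruth(table=pd.DataFrame.from_records(records))
    return cm, truth


def simulate_qpcr(
    rpkm: pd.DataFrame,
    genes,
    reference_gene: str = "RAB10",
    ct_scale: float = 22.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic qPCR CT table derived from RPKM values.

    Target CT is a noisy affine function of -log2(RPKM) (qPCR CT decreases by
    one per doubling of template); the reference gene is flat by construction.
    Returns a tidy table (gene, sample, ct_target, ct_reference) suitable for
    the cross-platform concordance stage.  Synthetic stand-in for bench data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        expr = rpkm.loc[gene]
        for sample, value in expr.items():
            ct_t = ct_scale - np.log2(max(value, 1e-6)) + rng.normal(0.0, noise_sd)
            ct_r = 20.0 + rng.normal(0.0, 0.05)
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "ct_target": ct_t,
                    "ct_reference": ct_r,
                    "reference_gene": reference_gene,
                }
            )
    return pd.DataFrame(rows)


def simulate_protein_ratios(
    truth: GroundTruth,
    genes,
    cell_lines=("A", "B"),
    noise_sdlog: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic first-vs-last protein expression ratios from the truth table."""
    rng = np.random.default_rng(seed)
    rows = []
    for line in cell_lines:
        tl = truth.line(line)
        for gene in genes:
            true_ratio = tl.loc[gene, "mean_pd4"] / tl.loc[gene, "mean_pd0"]
            rows.append(
                {
                    "gene": gene,
                    "cell_line": line,
                    "ratio": float(true_ratio * np.exp(rng.normal(0.0, noise_sdlog))),
                }
            )
    return pd.DataFrame(rows)
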