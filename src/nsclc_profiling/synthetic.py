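"""Synthetic cohort generator.

Emulates the statistical structure of a pan-cancer AD/SCC cohort: a sparse
binary gene-by-sample mutation matrix with histology-biased driver genes
(including samples forced to carry drivers of *both* histologies, the proxy
for mixed-type tumors), a dense expression z-score matrix in which the two
histologies are nearly linearly separable, and optional exponential
progression-free-survival annotations. All distributional choices are
stand-ins for real tumor data: mutations are independent Bernoulli draws
given histology, and expression is Gaussian with a mean shift on a
configured set of informative genes.

The generator is fully deterministic given ``seed``; independent sub-streams
drive the mutation, expression, mixed-driver and survival draws so each
component is reproducible independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import AD, SCC, CohortDataset

__all__ = [
    "DriverGene",
    "SurvivalSpec",
    "SimulationConfig",
    "default_config",
    "generate_cohort",
    "cohort_summary",
    "write_cohort",
    "read_config",
]

#: Canonical NSCLC driver genes used to name synthetic driver columns, so the
#: driver-subgroup analysis runs unchanged on simulated cohorts.
LUAD_DRIVER_NAMES = ("KRAS", "EGFR", "BRAF", "STK11")
LUSC_DRIVER_NAMES = ("CDKN2A", "NFE2L2", "PIK3CA", "PTEN")


@dataclass(frozen=True)
class DriverGene:
    """A gene whose mutation frequency depends on histology."""

    gene_index: int
    histology: str  # the histology this driver marks ("AD" or "SCC")
    p_marked: float  # mutation probability in that histology
    p_other: float  # mutation probability in the other histology
    name: str | None = None


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential progression-free-time model per histology."""

    hazard_ad: float
    hazard_scc: float
    censoring_rate: float


@dataclass
class SimulationConfig:
    n_samples_per_group: int
    n_genes: int
    driver_spec: list[DriverGene]
    background_mutation_rate: float
    expression_effect_size: float
    n_informative_expression_genes: int
    mixed_driver_fraction: float
    tissue_labels: list[str] = field(default_factory=lambda: ["lung", "other"])
    lung_tissue_label: str = "lung"
    informative_gene_indices: list[int] | None = None
    survival_spec: SurvivalSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be positive")
        for name, p in [
            ("background_mutation_rate", self.background_mutation_rate),
            ("mixed_driver_fraction", self.mixed_driver_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.expression_effect_size < 0:
            raise ValueError("expression_effect_size must be nonnegative")
        seen: set[int] = set()
        for d in self.driver_spec:
            if d.histology not in (AD, SCC):
                raise ValueError(f"driver_spec histology must be AD/SCC, got {d.histology!r}")
            if not (0 <= d.gene_index < self.n_genes):
                raise ValueError(
                    f"driver_spec gene_index {d.gene_index} outside [0, {self.n_genes})"
                )
            if d.gene_index in seen:
                raise ValueError(f"driver_spec gene_index {d.gene_index} duplicated")
            seen.add(d.gene_index)
            for pname, p in [("p_marked", d.p_marked), ("p_other", d.p_other)]:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"driver_spec {pname} must lie in [0, 1], got {p}")
        if self.n_informative_expression_genes > self.n_genes:
            raise ValueError("n_informative_expression_genes exceeds n_genes")
        if self.tissue_labels.count(self.lung_tissue_label) != 1:
            raise ValueError("tissue_labels must contain the lung label exactly once")
        if self.mixed_driver_fraction > 0:
            marked = {d.histology for d in self.driver_spec}
            if marked != {AD, SCC}:
                raise ValueError(
                    "mixed_driver_fraction > 0 requires driver_spec genes for both histologies"
                )
        if self.survival_spec is not None:
            s = self.survival_spec
            if s.hazard_ad <= 0 or s.hazard_scc <= 0:
                raise ValueError("survival_spec hazards must be positive")
            if not 0.0 <= s.censoring_rate <= 1.0:
                raise ValueError("survival_spec censoring_rate must lie in [0, 1]")

    def informative_genes(self) -> list[int]:
        """Informative-expression gene indices; by default the highest-index
        genes that are not drivers (mutation and expression signal disjoint)."""
        if self.informative_gene_indices is not None:
            return list(self.informative_gene_indices)
        drivers = {d.gene_index for d in self.driver_spec}
        out: list[int] = []
        for g in range(self.n_genes - 1, -1, -1):
            if g not in drivers:
                out.append(g)
            if len(out) == self.n_informative_expression_genes:
                break
        return sorted(out)

    def gene_names(self) -> list[str]:
        names = [f"G{g:04d}" for g in range(self.n_genes)]
        ad_names = iter(LUAD_DRIVER_NAMES)
        scc_names = iter(LUSC_DRIVER_NAMES)
        for d in self.driver_spec:
            if d.name is not None:
                names[d.gene_index] = d.name
                continue
            pool = ad_names if d.histology == AD else scc_names
            names[d.gene_index] = next(pool, f"DRV_{d.histology}_{d.gene_index}")
        return names


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale defaults: 600 NSCLC + 600 non-lung samples, 200 genes,
    4 drivers per histology (25% vs 3% mutation frequency), 2% background
    rate, 15% mixed-driver samples, expression effect 2.0 on 20 genes."""
    drivers = [
        DriverGene(g, AD, 0.25, 0.03) for g in range(4)
    ] + [
        DriverGene(4 + g, SCC, 0.25, 0.03) for g in range(4)
    ]
    cfg = SimulationConfig(
        n_samples_per_group=300,
        n_genes=200,
        driver_spec=drivers,
        background_mutation_rate=0.02,
        expression_effect_size=2.0,
        n_informative_expression_genes=20,
        mixed_driver_fraction=0.15,
        survival_spec=SurvivalSpec(hazard_ad=0.030, hazard_scc=0.045, censoring_rate=0.3),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Draw a cohort from the configured generative model.

    Mutations are independent Bernoulli per gene given histology; driver
    genes use their histology-conditional probabilities, everything else the
    background rate. ``round(mixed_driver_fraction * n)`` samples, chosen
    uniformly, then have one driver of each histology forced to 1.
    Expression is standard normal except on the informative genes, whose
    means are +effect/2 (AD) and -effect/2 (SCC).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_mut, rng_expr, rng_mix, rng_surv = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    histology: list[str] = []
    tissue: list[str] = []
    for t in config.tissue_labels:
        for h in (AD, SCC):
            histology.extend([h] * config.n_samples_per_group)
            tissue.extend([t] * config.n_samples_per_group)
    n = len(histology)
    hist_arr = np.asarray(histology, dtype=object)
    is_ad = hist_arr == AD

    # histology-conditional Bernoulli probabilities, background elsewhere
    probs = np.full((n, config.n_genes), config.background_mutation_rate)
    for d in config.driver_spec:
        marked = is_ad if d.histology == AD else ~is_ad
        probs[marked, d.gene_index] = d.p_marked
        probs[~marked, d.gene_index] = d.p_other
    mutations = (rng_mut.random((n, config.n_genes)) < probs).astype(np.uint8)

    n_forced = int(round(config.mixed_driver_fraction * n))
    if n_forced > 0:
        ad_drivers = [d.gene_index for d in config.driver_spec if d.histology == AD]
        scc_drivers = [d.gene_index for d in config.driver_spec if d.histology == SCC]
        forced = rng_mix.choice(n, size=n_forced, replace=False)
        for s in forced:
            mutations[s, rng_mix.choice(ad_drivers)] = 1
            mutations[s, rng_mix.choice(scc_drivers)] = 1

    expression = rng_expr.standard_normal((n, config.n_genes))
    if config.n_informative_expression_genes > 0 and config.expression_effect_size > 0:
        info = config.informative_genes()
        shift = np.where(is_ad, config.expression_effect_size / 2.0,
                         -config.expression_effect_size / 2.0)
        expression[:, info] += shift[:, None]

    pfs_time = pfs_event = None
    if config.survival_spec is not None:
        s = config.survival_spec
        hazards = np.where(is_ad, s.hazard_ad, s.hazard_scc)
        pfs_time = rng_surv.exponential(1.0 / hazards)
        pfs_event = (rng_surv.random(n) >= s.censoring_rate).astype(int)
        # censored samples are observed for a uniform fraction of their time
        censored = pfs_event == 0
        pfs_time[censored] *= rng_surv.random(censored.sum())

    return CohortDataset(
        mutation_matrix=mutations,
        expression_matrix=expression,
        sample_ids=[f"SYN-{i:04d}-01" for i in range(n)],
        gene_ids=config.gene_names(),
        histology=hist_arr,
        tissue=np.asarray(tissue, dtype=object),
        is_lung=np.asarray([t == config.lung_tissue_label for t in tissue]),
        pfs_time=pfs_time,
        pfs_event=pfs_event,
        lung_tissue_label=config.lung_tissue_label,
    )


def cohort_summary(data: CohortDataset) -> dict:
    """Per-(histology, tissue) counts, per-gene mutation frequency by
    histology, and overall mutation-matrix sparsity."""
    if data.n_samples == 0:
        raise ValueError("cohort is empty")
    counts = pd.crosstab(
        pd.Series(data.histology, name="histology"),
        pd.Series(data.tissue, name="tissue"),
    )
    freq = {}
    for h in (AD, SCC):
        mask = data.histology == h
        freq[h] = (
            data.mutation_matrix[mask].mean(axis=0)
            if mask.any()
            else np.zeros(data.n_genes)
        )
    mutation_frequency = pd.DataFrame(freq, index=data.gene_ids)
    sparsity = 1.0 - float(data.mutation_matrix.mean())
    return {
        "counts": counts,
        "mutation_frequency": mutation_frequency,
        "sparsity": sparsity,
    }


# ---------------------------------------------------------------------------
# plain-text writers (round-trip tested against data_prep readers)

def write_cohort(data: CohortDataset, outdir) -> None:
    """Write mutation/expression matrices and sample annotations as TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mut = pd.DataFrame(data.mutation_matrix, index=data.sample_ids, columns=data.gene_ids)
    mut.to_csv(outdir / "mutations.tsv", sep="\t", index_label="sample_id")
    expr = pd.DataFrame(data.expression_matrix, index=data.sample_ids, columns=data.gene_ids)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="sample_id",
                float_format="%.17g")
    ann = pd.DataFrame(
        {
            "sample_id": data.sample_ids,
            "histology": data.histology,
            "tissue": data.tissue,
            "is_lung": data.is_lung.astype(int),
        }
    )
    if data.pfs_time is not None:
        ann["pfs_time"] = [f"{t:.17g}" for t in data.pfs_time]
        ann["pfs_event"] = data.pfs_event
    ann.to_csv(outdir / "samples.tsv", sep="\t", index=False)


def write_config(config: SimulationConfig, path) -> None:
    """Flat key=value dump of a simulation configuration."""
    lines = []
    for key, value in vars(config).items():
        if key == "driver_spec":
            value = ";".join(
                f"{d.gene_index},{d.histology},{d.p_marked},{d.p_other}"
                for d in value
            )
        elif key == "survival_spec" and value is not None:
            value = f"{value.hazard_ad},{value.hazard_scc},{value.censoring_rate}"
        elif isinstance(value, list):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key}={value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_config(path) -> SimulationConfig:
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                raw[key] = value
    drivers = []
    if raw.get("driver_spec"):
        for chunk in raw["driver_spec"].split(";"):
            g, h, pm, po = chunk.split(",")
            drivers.append(DriverGene(int(g), h, float(pm), float(po)))
    surv = None
    if raw.get("survival_spec", "None") != "None":
        ha, hs, c = (float(x) for x in raw["survival_spec"].split(","))
        surv = SurvivalSpec(ha, hs, c)
    info = None
    if raw.get("informative_gene_indices", "None") != "None":
        info = [int(x) for x in raw["informative_gene_indices"].split(",")]
    return SimulationConfig(
        n_samples_per_group=int(raw["n_samples_per_group"]),
        n_genes=int(raw["n_genes"]),
        driver_spec=drivers,
        background_mutation_rate=float(raw["background_mutation_rate"]),
        expression_effect_size=float(raw["expression_effect_size"]),
        n_informative_expression_genes=int(raw["n_informative_expression_genes"]),
        mixed_driver_fraction=float(raw["mixed_driver_fraction"]),
        tissue_labels=raw["tissue_labels"].split(","),
        lung_tissue_label=raw["lung_tissue_label"],
        informative_gene_indices=info,
        survival_spec=surv,
        seed=int(raw["seed"]),
    )
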