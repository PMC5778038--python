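"""Synthetic expression datasets with planted structure for pipeline validation.

The generator emulates the design of a cellulose-degradation RNA-Seq
experiment: three fungal "species", each grown on two carbon sources
(cellulose vs glucose) in biological triplicate. On the log2 scale, gene g
in sample s is

    y_gs = mu_g + a * z_{m(g), s} + delta_g * [s in glucose] + eps_gs

where mu_g ~ Uniform(baseline range) is the gene's baseline, z_{m,s} a
per-module per-sample standard-normal latent factor shared by all genes of
module m (loading ``a`` = module_corr_strength), delta_g = ±de_log2fc for
planted differentially expressed genes, and eps_gs ~ Normal(0, noise_sd).
Linear-scale values 2**y_gs are then zeroed independently per cell with
probability dropout_prob, mimicking dropout/undetected genes. The planted
truth (module membership, DE direction, CAZy families, secreted flags) is
returned alongside, so every downstream stage can be scored against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from coregnet.integration import CAZY_CLASSES, AnnotationSet, ProteomeTable
from coregnet.preprocessing import ExpressionDataset

DEFAULT_SPECIES = ("Ta", "Tr", "Th")
DEFAULT_CONDITIONS = ("cellulose", "glucose")

# relative frequency of CAZy classes among annotated genes; glycoside
# hydrolases dominate fungal lignocellulolytic repertoires
_CLASS_WEIGHTS = (0.5, 0.15, 0.15, 0.1, 0.1)


class ConfigurationError(ValueError):
    """A simulation parameter violates its documented bound."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic expression generator.

    module_size may be a single count applied to every module or a list of
    per-module counts. Fractions are of the total gene count (de_fraction,
    cazy_fraction) or of the CAZy set (secreted_fraction).
    """

    n_genes: int = 2000
    n_modules: int = 5
    module_size: int | list[int] = 15
    n_conditions: int = 2
    n_replicates: int = 3
    module_corr_strength: float = 0.9
    de_fraction: float = 0.1
    de_log2fc: float = 1.0
    noise_sd: float = 0.3
    dropout_prob: float = 0.05
    cazy_fraction: float = 0.1
    secreted_fraction: float = 0.3
    baseline_range: tuple[float, float] = (2.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def module_sizes(self) -> list[int]:
        if isinstance(self.module_size, int):
            return [self.module_size] * self.n_modules
        return list(self.module_size)

    @property
    def conditions(self) -> tuple[str, ...]:
        if self.n_conditions <= len(DEFAULT_CONDITIONS):
            return DEFAULT_CONDITIONS[: self.n_conditions]
        extra = tuple(
            f"cond{i + 1}" for i in range(len(DEFAULT_CONDITIONS), self.n_conditions)
        )
        return DEFAULT_CONDITIONS + extra

    @property
    def n_samples(self) -> int:
        return self.n_conditions * self.n_replicates

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be ≥ 1, got {self.n_genes}")
        if self.n_modules < 0:
            raise ConfigurationError(f"n_modules must be ≥ 0, got {self.n_modules}")
        sizes = self.module_sizes
        if len(sizes) != self.n_modules:
            raise ConfigurationError(
                f"module_size list length {len(sizes)} != n_modules {self.n_modules}"
            )
        if self.n_modules and self.n_modules * max(sizes) > self.n_genes:
            raise ConfigurationError(
                f"n_modules × max(module_size) = {self.n_modules * max(sizes)} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.n_conditions < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_conditions and n_replicates must be ≥ 1")
        if not 0 <= self.module_corr_strength < 1:
            raise ConfigurationError(
                f"module_corr_strength must be in [0, 1), got {self.module_corr_strength}"
            )
        for name in ("de_fraction", "dropout_prob", "cazy_fraction", "secreted_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        lo, hi = self.baseline_range
        if not lo < hi:
            raise ConfigurationError(f"baseline_range must be increasing, got {self.baseline_range}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "baseline_range" in raw:
            raw["baseline_range"] = tuple(raw["baseline_range"])
        return cls(**raw)


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic dataset.

    ``de_genes_up``/``de_genes_down`` are relative to the second condition
    (glucose): "up" genes carry +de_log2fc there. ``cazy_genes`` and
    ``secreted_genes`` are filled in by :func:`generate_annotation`.
    """

    module_members: list[set[str]] = field(default_factory=list)
    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    cazy_genes: dict[str, str] = field(default_factory=dict)
    secreted_genes: set[str] = field(default_factory=set)

    def module_labels(self) -> dict[str, int]:
        return {g: m for m, members in enumerate(self.module_members) for g in members}

    def to_tsv(self, path) -> None:
        labels = self.module_labels()
        rows = []
        genes = set(labels) | self.de_genes_up | self.de_genes_down | set(self.cazy_genes)
        for g in sorted(genes):
            de = "up" if g in self.de_genes_up else "down" if g in self.de_genes_down else "none"
            rows.append(
                (
                    g,
                    labels.get(g, -1),
                    de,
                    self.cazy_genes.get(g, ""),
                    g in self.secreted_genes,
                )
            )
        pd.DataFrame(
            rows, columns=["gene_id", "module", "de", "cazy_family", "secreted"]
        ).to_csv(path, sep="\t", index=False)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(
    config: SimulationConfig, species: str = "Ta"
) -> tuple[ExpressionDataset, PlantedTruth]:
    """Draw one species' expression matrix and its planted truth.

    Module members occupy the leading gene IDs in consecutive blocks;
    planted DE genes are drawn from the non-module genes (so co-expression
    and fold-change signals stay separable), spilling into module genes
    only if the non-module pool is exhausted. Identical config (including
    seed) reproduces the output bitwise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, s = config.n_genes, config.n_samples
    genes = _gene_ids(n)
    conditions = config.conditions

    lo, hi = config.baseline_range
    mu = rng.uniform(lo, hi, size=n)

    # module assignment: consecutive blocks at the start of the gene list
    module_of = np.full(n, -1)
    start = 0
    members: list[set[str]] = []
    for m, size in enumerate(config.module_sizes):
        module_of[start : start + size] = m
        members.append(set(genes[start : start + size]))
        start += size

    # planted fold-change effects, applied to the second condition
    delta = np.zeros(n)
    n_de = int(round(config.de_fraction * n))
    non_module = np.flatnonzero(module_of < 0)
    pool = rng.permutation(non_module)
    if n_de > len(pool):
        extra = rng.permutation(np.flatnonzero(module_of >= 0))
        pool = np.concatenate([pool, extra])
    de_idx = pool[:n_de]
    half = n_de // 2
    delta[de_idx[:half]] = config.de_log2fc
    delta[de_idx[half:]] = -config.de_log2fc

    cond_index = np.repeat(np.arange(config.n_conditions), config.n_replicates)
    second = (cond_index == 1).astype(float) if config.n_conditions > 1 else np.zeros(s)

    z = rng.standard_normal((max(config.n_modules, 1), s))
    eps = rng.standard_normal((n, s)) * config.noise_sd
    y = mu[:, None] + delta[:, None] * second[None, :] + eps
    in_module = module_of >= 0
    if in_module.any():
        y[in_module] += config.module_corr_strength * z[module_of[in_module]]

    x = np.power(2.0, y)
    if config.dropout_prob > 0:
        x[rng.random((n, s)) < config.dropout_prob] = 0.0

    columns = [
        f"{species}_{conditions[c]}_{r + 1}"
        for c in range(config.n_conditions)
        for r in range(config.n_replicates)
    ]
    ds = ExpressionDataset(pd.DataFrame(x, index=genes, columns=columns))
    truth = PlantedTruth(
        module_members=members,
        de_genes_up={genes[i] for i in de_idx[:half]},
        de_genes_down={genes[i] for i in de_idx[half:]},
    )
    return ds, truth


def generate_annotation(
    config: SimulationConfig,
    truth: PlantedTruth,
    species: tuple[str, ...] = DEFAULT_SPECIES,
) -> AnnotationSet:
    """Assign CAZy families to a gene subset and flag secreted genes.

    CAZy labels preferentially cover the planted modules (so the
    CAZy-filtered subnetwork retains testable structure), then extend to
    randomly chosen remaining genes up to ``cazy_fraction`` of the genome.
    ``secreted_fraction`` of the CAZy genes are flagged as detected in at
    least one species × condition cell. Updates ``truth`` in place.
    """
    rng = np.random.default_rng([config.seed, 104729])
    genes = _gene_ids(config.n_genes)
    n_cazy = int(round(config.cazy_fraction * config.n_genes))
    module_genes = [g for members in truth.module_members for g in sorted(members)]
    chosen = module_genes[:n_cazy]
    if len(chosen) < n_cazy:
        rest = [g for g in genes if g not in set(chosen)]
        extra = rng.choice(len(rest), size=n_cazy - len(chosen), replace=False)
        chosen = chosen + [rest[i] for i in sorted(extra)]

    rows = {}
    for g in chosen:
        cls = CAZY_CLASSES[rng.choice(len(CAZY_CLASSES), p=_CLASS_WEIGHTS)]
        fam = f"{cls}{rng.integers(1, 100)}"
        rows[g] = (cls, fam)
    cazy = pd.DataFrame.from_dict(rows, orient="index", columns=["cazy_class", "cazy_family"])

    n_secreted = int(round(config.secreted_fraction * len(chosen)))
    secreted_genes = [chosen[i] for i in rng.choice(len(chosen), size=n_secreted, replace=False)] if n_secreted else []
    conditions = config.conditions
    sec_rows = []
    for g in sorted(secreted_genes):
        cells = [(sp, cond) for sp in species for cond in conditions]
        mask = rng.random(len(cells)) < 0.5
        if not mask.any():
            mask[rng.integers(len(cells))] = True  # detected somewhere by construction
        sec_rows.extend((g, sp, cond) for (sp, cond), hit in zip(cells, mask) if hit)
    secreted = pd.DataFrame(sec_rows, columns=["gene_id", "species", "condition"])

    truth.cazy_genes = {g: rows[g][1] for g in chosen}
    truth.secreted_genes = set(secreted_genes)
    return AnnotationSet(cazy=cazy, secreted=secreted)


def generate_proteome(ann: AnnotationSet, prefix: str = "P") -> ProteomeTable:
    """Build a proteome detection table from the annotation's secreted flags.

    One protein per flagged (gene, species, condition) cell, with protein
    IDs derived from gene IDs — a stand-in for the mass-spectrometry
    detection table whose protein→gene mapping is consumed as input.
    """
    rows = [
        (f"{prefix}_{r.gene_id}", r.gene_id, r.species, r.condition, True)
        for r in ann.secreted.itertuples(index=False)
    ]
    table = pd.DataFrame(
        rows, columns=["protein_id", "gene_id", "species", "condition", "detected"]
    )
    return ProteomeTable(table)


def generate_multispecies(
    config: SimulationConfig,
    species: tuple[str, ...] = DEFAULT_SPECIES,
) -> tuple[ExpressionDataset, dict[str, PlantedTruth]]:
    """Independent datasets for several species, sharing the gene universe.

    Each species is drawn from the same config with a species-specific
    derived seed; the columns are concatenated into one wide table
    (species × condition × replicate). No cross-species correlation is
    modelled.
    """
    blocks = []
    truths: dict[str, PlantedTruth] = {}
    for i, sp in enumerate(species):
        sub = SimulationConfig(
            **{
                **{f.name: getattr(config, f.name) for f in fields(SimulationConfig)},
                "seed": (config.seed * 1009 + i) % (2**31),
            }
        )
        ds, truth = generate_dataset(sub, species=sp)
        blocks.append(ds.values)
        truths[sp] = truth
    combined = pd.concat(blocks, axis=1)
    return ExpressionDataset(combined), truths
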